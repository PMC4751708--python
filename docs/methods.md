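# Methods

## Model and hypotheses

A weighted biological network is an undirected graph `G = (V, E)` with `M`
named vertices and `K` edges. Each individual `l = 1..N` carries a binary
group label `Y_l` (1 = case, 0 = control) and one continuous measurement per
vertex, `x_li`. Edge weights are not observed; they are population
association strengths between the endpoint variables, estimated from the
data. The null hypothesis is that cases and controls share the same network:
equal vertex-level means *and* equal edge connection strengths. The
alternative is any departure in either, so the tests are sensitive to
vertex-only, edge-only and combined changes.

## The NetDifM score statistic

The score vector has one entry per network element:

* `Dᵢⱽ = Σ_l (Y_l − Ȳ) x_li` — covariance-like contrast of vertex `i`'s
  level with the label;
* `Dₖᴱ = Σ_l (Y_l − Ȳ)(x_li − x̄_i)(x_lj − x̄_j)` — the same contrast applied
  to the centered cross-product of edge `k = (i, j)`'s endpoints, with the
  means `x̄` pooled over all `N` individuals.

Writing the working-variable matrix `W = [X | Z]` with
`Z_k = (X_i − X̄_i)(X_j − X̄_j)`, the stacked score is `D = Wᵀ(Y − Ȳ)` and its
covariance is estimated blockwise as `σ_pq = Σ_l (Y_l − Ȳ)² cov(W_p, W_q)`.
Because the pairwise covariance term does not depend on `l`, the whole
matrix factorizes:

```
Σ = [Σ_l (Y_l − Ȳ)²] × cov(W)
```

a factorization the implementation both exploits and asserts (an
entry-by-entry evaluation of every block formula is compared against the
factorized form in the test suite). The statistic is the quadratic form
`NetDifM = Dᵀ Σ⁻¹ D`, asymptotically χ² with `M + K` degrees of freedom
under the null. Two consequences of the factorization matter in practice:

* `Σ` is invariant under any relabeling of `Y` with the same group sizes,
  so the permutation null recomputes only `D` (one matrix product per batch
  of permutations) — this is what makes 1000 replicates × 1000 permutations
  a desk-scale computation;
* label swap `Y → 1 − Y` negates `D` and leaves the statistic unchanged.

**Covariance denominator.** The sample covariance uses the unbiased `N − 1`
denominator. The choice is asymptotically immaterial (the two versions
differ by a factor `(N−1)/N` in `Σ`); the χ²-calibration simulation is the
arbiter, and it is satisfied: under the null at `N = 800` on the
10-vertex/21-edge fixture the statistic's mean is within 5% of 31 and its
asymptotic p-values pass a Kolmogorov–Smirnov uniformity check.

**Numerical solve.** The quadratic form is computed by solving the linear
system (Cholesky/positive-definite solve), never by forming `Σ⁻¹`. A
condition-number guard (threshold 1e12) raises an explicit error when `Σ` is
numerically singular — which happens when working variables are collinear,
e.g. duplicated columns or near-zero-correlation edges. The error message
names the remedies: `prune_edges` (drop edges whose pooled |Pearson r| falls
below a threshold, computed label-blind so topology selection cannot bias
the test) or the opt-in `pseudoinverse` / `ridge(λ)` solvers. No silent
fallback ever happens.

**Labels.** Only exact 0/1 coding is accepted; any other coding is rejected
rather than silently recoded, because a mis-coded label column would
otherwise flip or rescale every score.

## The VEWDM element-wise comparator

`VEWDM = (1/M) Σᵢ Tᵢ² + (1/K) Σ U²` combines per-vertex standardized mean
differences `Tᵢ = (x̄ᵢᴰ − x̄ᵢᶜ)/√(var(x̄ᵢᴰ) + var(x̄ᵢᶜ))` (Welch-style, with
`var(x̄) = s²/n` per group) and per-edge Fisher r-to-z contrasts
`U_ij = (z_ijᴰ − z_ijᶜ)/√(1/(n_D−3) + 1/(n_C−3))` of the per-group Pearson
correlations. The U-sum ranges over the `K` edges of `E(G)`, each unordered
edge counted once, normalized by `K`; a double-sum over ordered pairs would
simply double both numerator and normalizer, so permutation inference is
unaffected, but the printed value of the statistic needs one fixed
convention and this is it. Pearson correlation is the edge-weight estimator
throughout; regression-slope weights are out of scope.

No asymptotic p-value is offered: the joint law of the `T`s and `U`s depends
on the network topology, so the null is built by permutation. Correlations
of exactly ±1 (possible in degenerate finite samples) are clipped to
±(1 − 1e−12) with a warning before the z-transform; a column that is
constant within a group makes the statistic undefined and raises.

## Permutation inference

Labels are reassigned uniformly at random with both group sizes fixed; the
empirical p-value is the proportion of permuted statistics **strictly**
exceeding the observed one, `p = (1/Q) Σ I(stat* > stat)`. Exact ties count
as non-exceedances, so a completely label-free statistic would give p = 0;
an add-one correction `(1 + count)/(1 + Q)` is available behind a flag and
off by default, keeping the default estimator identical to the plain
Monte-Carlo form used to calibrate the tests. For small `N` an exhaustive
mode enumerates all `C(N, n_case)` assignments (capped, default 200 000).
A single seeded generator owned by the plan makes every run reproducible.

## Per-vertex subnetwork tests

A vertex together with its incident edges is treated as a small network: the
score vector holds the focal vertex's own score plus its incident edges'
scores, giving df = 1 + degree for the asymptotic version. Neighbors'
vertex levels are deliberately *not* scored: a mean shift at vertex `v`
enters only `D_vⱽ` (the pooled-centered edge products carry no first-order
mean-shift signal for unshifted endpoints), so the restriction keeps the
per-vertex screen specific — scoring neighbors would let one shifted vertex
light up every adjacent star. Degree-0 vertices are untestable and raise.

## Simulation design

Each group is drawn from `N_M(μ, Σ)` with `Σ` carrying the topology: unit
variances on the diagonal (the model leaves the scale free; unit variance
makes `β` a correlation), `β_ij` at edge positions, zero elsewhere. Matrices
are checked for positive definiteness (minimum eigenvalue > 1e−10) and an
indefinite request is an error, never silently repaired.

* **Baseline correlation** `β = 0.3` on every edge. Type I error is
  insensitive to this baseline; absolute power levels shift with it.
* **Scenarios.** `null`: identical groups. `vertex`: case means of a few
  randomly chosen vertices shifted (+0.2, +0.2 by default). `edge`: case
  correlations of a few randomly chosen edges shifted (−0.2, +0.2, +0.2 by
  default). `both`: the combination. Which elements are shifted is drawn
  once from a fixed seed, so a (topology, seed) pair defines a reproducible
  scenario.
* **Sample size** `n` means the total, split equally between the groups
  (the balanced design keeps the VEWDM `n − 3` denominators well-defined at
  the smallest settings).
* **Fixture topologies.** Study-scale networks with 10 vertices / 21 edges
  and 20 vertices / 45 edges are shipped as edge-list files, generated once
  by `random_connected_network` (uniform random attachment tree + random
  extra edges) with fixed seeds. At the larger density most random
  topologies are *not* positive definite at uniform β = 0.3 — hub vertices
  accumulate too much shared correlation — so the shipped seeds were
  screened for positive definiteness of the baseline and of the shifted
  scenario covariances before any operating characteristics were estimated.
  Because published diagrams pin down such topologies only graphically,
  power levels are comparable across methods and sample sizes *within* this
  package, but only qualitatively against other topologies.
* **Non-normal robustness.** An elementwise exponential transform applied
  after the draw — to a seed-chosen subset of 5 of the 10 vertices, or to
  all — produces log-normal marginals. Under the null the transform is
  applied identically to both groups, so the permutation tests remain exact
  in level; the simulations confirm the empirical rate stays within two
  binomial standard errors of 0.05.
* **Rejection rates** are estimated over independent replicates (1000 for
  type I error, 500 for power curves) as the fraction of p-values below
  α = 0.05, reported with the binomial standard error and the full
  per-replicate p-values for diagnostics.

What the generator does *not* emulate: real expression data's heavy tails
beyond the log-normal check, missingness, batch structure, and uncertainty
in the network topology itself (the graph is treated as known, which is the
method's stated scope). Passing simulations therefore demonstrate
calibration and relative power under the stated sampling model, not
robustness to misspecified topology.

## Preprocessing collapses

Raw features are mapped to vertices by a 2-column (vertex, feature) table.
`average_features` takes the per-sample arithmetic mean (the usual probe-set
to gene-symbol reduction). `first_pc` standardizes each feature block
(correlation-matrix PCA) and returns the first principal-component score,
computed on the pooled sample so group labels cannot leak into vertex
construction; the sign is fixed by making the largest-magnitude loading
positive, because the vertex score is not sign-invariant and an arbitrary
SVD sign would make results run-dependent. Zero-variance features are an
error rather than being dropped silently.

## Problem sizes and defaults

The shipped operating-characteristic runs use 1000 replicates × 1000
permutations for type I error cells and 500 replicates for power cells —
the same order as the designs they emulate — which the factorized
permutation engine completes in a few minutes on one CPU. Default
α = 0.05, permutation count Q = 1000, condition-number threshold 1e12,
positive-definiteness tolerance 1e−10, correlation clip 1 − 1e−12.

## Known limitations

* Case/control labels only: no covariates, continuous traits or >2 groups.
* The topology is fixed input; no structure learning.
* The asymptotic NetDifM test is conservative at small `N` (empirically
  ~0.01–0.03 at N = 100 for 31 df); use the permutation version there.
* `Σ` grows as `(M+K)²`; very dense networks with weakly correlated
  endpoints can approach singularity — prune first.
* Power levels depend on the unpublished baseline correlations and exact
  topologies of the original study designs; orderings and trends are the
  reproducible quantities.
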