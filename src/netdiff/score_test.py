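"""Score-based network difference measure (NetDifM).

The test compares a weighted network between cases and controls through a
score vector with one entry per vertex and one per edge.  For individual
``l`` with label ``Y_l`` and measurements ``x_li``:

* vertex score   ``D_i^V = Σ_l (Y_l − Ȳ) x_li`` — group difference in the
  vertex level;
* edge score     ``D_k^E = Σ_l (Y_l − Ȳ)(x_li − x̄_i)(x_lj − x̄_j)`` for edge
  ``k = (i, j)`` — group difference in connection strength, with pooled
  means ``x̄``.

Stacking ``D = (D^V, D^E)`` and estimating ``Σ = cov(D)`` blockwise gives the
quadratic form ``NetDifM = Dᵀ Σ⁻¹ D``, asymptotically χ²(M+K) under the null
of identical networks.  Each covariance entry is
``σ_pq = Σ_l (Y_l − Ȳ)² cov(W_p, W_q)`` where ``W`` collects the working
variables: the X columns themselves and the centered cross-products
``Z_k = (X_i − X̄_i)(X_j − X̄_j)``.  Because the per-pair covariance does not
depend on ``l``, the whole matrix factorizes as ``Σ_l (Y_l − Ȳ)²`` times the
pooled sample covariance of ``[X | Z]`` — which also makes Σ invariant under
any relabeling of ``Y``, a fact the permutation engine exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import linalg, stats

from .data import LabeledDataset
from .network_model import NetworkError, NetworkSpec, VertexRef, incident_subnetwork

Solver = Literal["direct", "pseudoinverse", "ridge"]

#: Condition number above which Σ is treated as numerically singular.
COND_THRESHOLD = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Score covariance is (numerically) not invertible."""


class UntestableVertexError(ValueError):
    """A vertex with no incident edges cannot form a subnetwork test."""


@dataclass(frozen=True)
class ScoreDecomposition:
    """The score vector D, its estimated covariance Σ, and the internals
    needed to recompute D cheaply under label permutations."""

    D_vertex: np.ndarray
    D_edge: np.ndarray
    Sigma: np.ndarray
    label_weight_sum: float
    #: N × (M+K) working-variable matrix [X | Z]; D = working.T @ (y − ȳ).
    working: np.ndarray = field(repr=False)

    @property
    def D(self) -> np.ndarray:
        return np.concatenate([self.D_vertex, self.D_edge])

    @property
    def df(self) -> int:
        return self.D_vertex.size + self.D_edge.size


@dataclass(frozen=True)
class TestResult:
    """Outcome of one network comparison."""

    statistic: float
    p_value: float
    method: str
    df: int | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# -- score components ------------------------------------------------------


def _centered_labels(data: LabeledDataset) -> np.ndarray:
    y = data.y.astype(float)
    return y - y.mean()


def _working_matrix(
    x: np.ndarray,
    edges: Sequence[tuple[int, int]],
    vertices: Sequence[int] | None = None,
) -> np.ndarray:
    """[X | Z] with Z the centered endpoint cross-products, one per edge.

    ``vertices`` restricts the X block to the given columns (the Z block
    always covers every edge); pooled means are taken over all columns first.
    """
    xc = x - x.mean(axis=0)
    if edges:
        ii = np.fromiter((e[0] for e in edges), int, count=len(edges))
        jj = np.fromiter((e[1] for e in edges), int, count=len(edges))
        z = xc[:, ii] * xc[:, jj]
    else:
        z = np.empty((x.shape[0], 0))
    xv = x if vertices is None else x[:, list(vertices)]
    return np.hstack([xv, z])


def vertex_scores(data: LabeledDataset, net: NetworkSpec | None = None) -> np.ndarray:
    """Length-M vertex score vector D^V (in network vertex order if given)."""
    x = data.aligned(net) if net is not None else data.X
    return x.T @ _centered_labels(data)


def edge_scores(data: LabeledDataset, net: NetworkSpec) -> np.ndarray:
    """Length-K edge score vector D^E, ordered by the canonical edge index."""
    x = data.aligned(net)
    xc = x - x.mean(axis=0)
    c = _centered_labels(data)
    return np.array([(c * xc[:, i] * xc[:, j]).sum() for i, j in net.edges])


def score_covariance(
    data: LabeledDataset,
    net: NetworkSpec,
    vertices: Sequence[int] | None = None,
) -> ScoreDecomposition:
    """Score vector and blockwise covariance estimate for a network.

    ``vertices`` restricts the vertex block of D and Σ to the given vertex
    positions while keeping every edge of ``net``; the per-vertex
    star-subnetwork test uses it to score only the focal vertex.
    """
    if data.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate the score covariance")
    x = data.aligned(net)
    c = _centered_labels(data)
    s = float((c**2).sum())
    w = _working_matrix(x, net.edges, vertices)
    m = w.shape[1] - net.n_edges
    pooled = np.atleast_2d(np.cov(w, rowvar=False, ddof=1))
    d = w.T @ c
    return ScoreDecomposition(
        D_vertex=d[:m],
        D_edge=d[m:],
        Sigma=s * pooled,
        label_weight_sum=s,
        working=w,
    )


# -- the quadratic form ----------------------------------------------------


def netdifm_statistic(
    dec: ScoreDecomposition,
    solver: Solver = "direct",
    ridge: float = 0.0,
    cond_threshold: float = COND_THRESHOLD,
) -> float:
    """The quadratic form ``Dᵀ Σ⁻¹ D``.

    ``direct`` solves the linear system (no explicit inverse) and refuses a
    numerically singular Σ; ``pseudoinverse`` and ``ridge`` are opt-in
    fallbacks for the rank-deficient case.
    """
    sigma, d = dec.Sigma, dec.D
    if solver == "direct":
        cond = np.linalg.cond(sigma)
        if not np.isfinite(cond) or cond > cond_threshold:
            raise SingularCovarianceError(
                f"score covariance is numerically singular (condition number {cond:.3g}); "
                "the statistic is undefined for a non-invertible covariance — simplify the "
                "network first, e.g. prune_edges() to drop weak-correlation edges, or use "
                "solver='pseudoinverse' or solver='ridge'"
            )
        sol = linalg.solve(sigma, d, assume_a="pos")
    elif solver == "pseudoinverse":
        sol = np.linalg.pinv(sigma, hermitian=True) @ d
    elif solver == "ridge":
        if ridge <= 0:
            raise ValueError("ridge solver needs a positive ridge penalty")
        sol = linalg.solve(sigma + ridge * np.eye(len(d)), d, assume_a="pos")
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return max(float(d @ sol), 0.0)


def netdifm_test(
    data: LabeledDataset,
    net: NetworkSpec,
    solver: Solver = "direct",
    ridge: float = 0.0,
) -> TestResult:
    """Asymptotic NetDifM test: χ² with M + K degrees of freedom."""
    dec = score_covariance(data, net)
    stat = netdifm_statistic(dec, solver=solver, ridge=ridge)
    df = dec.df
    return TestResult(
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df)),
        method="netdifm_asymptotic",
        df=df,
    )


# -- per-vertex subnetwork testing -----------------------------------------


def vertex_subnetwork_test(
    data: LabeledDataset,
    net: NetworkSpec,
    vertex: VertexRef,
    method: str = "asymptotic",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> TestResult:
    """Test one vertex together with its incident edges as a small network.

    The score vector is restricted to the focal vertex's own score plus the
    scores of its incident edges (df = 1 + degree), so the result isolates
    that vertex's level change and the changes of its direct connections;
    scoring the neighbors' levels as well would let a neighbor's signal leak
    into every adjacent vertex's test and blur the per-vertex screen.
    ``method`` is ``asymptotic``, ``permutation`` (NetDifM null by label
    permutation) or ``vewdm`` (element-wise measure, permutation only).
    """
    from .permutation import PermutationPlan, permutation_pvalue  # cycle guard

    v = net.vertex_position(vertex)
    if net.degree(v) == 0:
        raise UntestableVertexError(
            f"vertex {net.vertex_names[v]!r} has no incident edges and is untestable"
        )
    sub = incident_subnetwork(net, v)
    focal = [sub.vertex_position(net.vertex_names[v])]
    if method == "asymptotic":
        dec = score_covariance(data, sub, vertices=focal)
        stat = netdifm_statistic(dec)
        return TestResult(
            statistic=stat,
            p_value=float(stats.chi2.sf(stat, dec.df)),
            method="netdifm_asymptotic",
            df=dec.df,
        )
    if method in ("permutation", "vewdm"):
        plan = PermutationPlan(n_permutations=n_permutations, seed=seed)
        statistic = "netdifm" if method == "permutation" else "vewdm"
        return permutation_pvalue(data, sub, statistic=statistic, plan=plan, vertices=focal)
    raise ValueError(f"unknown method {method!r}")
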