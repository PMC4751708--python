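"""Synthetic two-group network data and operating-characteristic estimation.

Each group is drawn from a multivariate normal N_M(μ, Σ) whose covariance
carries the network: Σ has the per-vertex variances on the diagonal (unit by
default), the edge correlation β_ij at each edge position, and zero
elsewhere.  Under the null both groups share μ and every β; the alternatives
shift a few vertex means (``vertex`` scenario), a few edge correlations
(``edge``), or both (``both``).  An optional elementwise exponential
transform — on a random subset of vertices or on all of them — produces
skewed, non-normal marginals for robustness checks.

The baseline edge correlation defaults to 0.3 on every edge, a moderate
co-expression-scale association that keeps the fixture covariances
comfortably positive definite; type I error is insensitive to this choice,
while absolute power levels shift with it (see docs/methods.md).

Study-scale fixture topologies (10 vertices / 21 edges and 20 vertices / 45
edges) ship as edge-list files so every simulation is bit-reproducible; they
were generated once by :func:`random_connected_network` with fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np

from .data import LabeledDataset
from .network_model import NetworkSpec, load_edge_list
from .score_test import netdifm_test
from .permutation import PermutationPlan, permutation_pvalue

Transform = None | Literal["exp_all"] | tuple[int, ...]

#: Default baseline correlation on every edge of a simulated network.
DEFAULT_BETA = 0.3

_FIXTURE_FILES = {
    "small": "network_10v_21e.tsv",   # 10 vertices, 21 edges
    "large": "network_20v_45e.tsv",   # 20 vertices, 45 edges
}


def fixture_network(name: str = "small") -> NetworkSpec:
    """Load a shipped study-scale topology (``small``: 10v/21e, ``large``: 20v/45e)."""
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}") from None
    ref = resources.files("netdiff.fixtures").joinpath(fname)
    with resources.as_file(ref) as path:
        return load_edge_list(path)


def build_sigma(
    net: NetworkSpec,
    beta: float | Sequence[float],
    diag: Sequence[float] | None = None,
) -> np.ndarray:
    """Network-structured covariance: ``diag`` on the diagonal, β at edges, 0 off-network.

    Positive definiteness is verified (no silent repair): an indefinite
    request is a design error in the scenario, not something to patch.
    """
    m = net.n_vertices
    betas = np.broadcast_to(np.asarray(beta, dtype=float), (net.n_edges,))
    sigma = np.zeros((m, m))
    for (i, j), b in zip(net.edges, betas):
        sigma[i, j] = sigma[j, i] = b
    sigma[np.diag_indices(m)] = 1.0 if diag is None else np.asarray(diag, dtype=float)
    min_eig = float(np.linalg.eigvalsh(sigma).min())
    if min_eig <= 1e-10:
        raise ValueError(
            f"implied covariance is not positive definite (min eigenvalue {min_eig:.3g})"
        )
    return sigma


def random_connected_network(m: int, k: int, seed: int | None = None) -> NetworkSpec:
    """Connected undirected graph with exactly ``m`` vertices and ``k`` edges.

    A uniform random attachment tree guarantees connectivity; the remaining
    ``k − m + 1`` edges are sampled without replacement from the non-tree
    pairs.  Deterministic given the seed.
    """
    max_edges = m * (m - 1) // 2
    if not m - 1 <= k <= max_edges:
        raise ValueError(f"edge count must be in [{m - 1}, {max_edges}] for {m} vertices")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    edges = set()
    for pos in range(1, m):
        a, b = order[pos], order[rng.integers(pos)]
        edges.add((min(a, b), max(a, b)))
    pool = [
        (i, j) for i in range(m) for j in range(i + 1, m) if (i, j) not in edges
    ]
    extra = rng.choice(len(pool), size=k - len(edges), replace=False)
    edges.update(pool[idx] for idx in extra)
    names = tuple(f"v{i + 1}" for i in range(m))
    return NetworkSpec(names, tuple(sorted(edges)))


@dataclass(frozen=True)
class SimulationScenario:
    """One fully specified two-group setting (H0 or an alternative)."""

    net: NetworkSpec
    mu_case: np.ndarray
    mu_control: np.ndarray
    beta_case: np.ndarray
    beta_control: np.ndarray
    n_case: int
    n_control: int
    transform: Transform = None
    diag: np.ndarray | None = None

    def __post_init__(self) -> None:
        m, k = self.net.n_vertices, self.net.n_edges
        for name, arr, size in (
            ("mu_case", self.mu_case, m),
            ("mu_control", self.mu_control, m),
            ("beta_case", self.beta_case, k),
            ("beta_control", self.beta_control, k),
        ):
            a = np.asarray(arr, dtype=float)
            if a.shape != (size,):
                raise ValueError(f"{name} must have length {size}")
            object.__setattr__(self, name, a)
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both groups need at least one sample")
        # validates positive definiteness for both groups
        self.sigma_case
        self.sigma_control

    @property
    def sigma_case(self) -> np.ndarray:
        return build_sigma(self.net, self.beta_case, self.diag)

    @property
    def sigma_control(self) -> np.ndarray:
        return build_sigma(self.net, self.beta_control, self.diag)

    @property
    def is_null(self) -> bool:
        return bool(
            np.array_equal(self.mu_case, self.mu_control)
            and np.array_equal(self.beta_case, self.beta_control)
        )


def default_scenario(
    net: NetworkSpec,
    kind: Literal["null", "vertex", "edge", "both"],
    n_total: int,
    *,
    beta0: float = DEFAULT_BETA,
    transform: Transform = None,
    seed: int = 13,
    vertex_shifts: Sequence[float] = (0.2, 0.2),
    edge_shifts: Sequence[float] = (-0.2, 0.2, 0.2),
) -> SimulationScenario:
    """The study's standard settings on an arbitrary topology.

    The alternatives perturb a few elements: ``vertex`` adds ``vertex_shifts``
    to the case means of randomly chosen vertices, ``edge`` adds
    ``edge_shifts`` to the case correlations of randomly chosen edges, and
    ``both`` combines them.  Which elements are shifted is drawn once from
    ``seed`` so a given (topology, seed) pair defines a fixed scenario.
    ``n_total`` is split equally between the groups.
    """
    rng = np.random.default_rng(seed)
    m, k = net.n_vertices, net.n_edges
    mu_control = np.zeros(m)
    mu_case = mu_control.copy()
    beta_control = np.full(k, beta0)
    beta_case = beta_control.copy()
    if kind not in ("null", "vertex", "edge", "both"):
        raise ValueError(f"unknown scenario kind {kind!r}")
    if kind in ("vertex", "both"):
        which = rng.choice(m, size=len(vertex_shifts), replace=False)
        mu_case[which] += np.asarray(vertex_shifts)
    if kind in ("edge", "both"):
        which = rng.choice(k, size=len(edge_shifts), replace=False)
        beta_case[which] += np.asarray(edge_shifts)
    n_case = n_total // 2
    return SimulationScenario(
        net=net,
        mu_case=mu_case,
        mu_control=mu_control,
        beta_case=beta_case,
        beta_control=beta_control,
        n_case=n_case,
        n_control=n_total - n_case,
        transform=transform,
    )


def random_transform_subset(net: NetworkSpec, size: int, seed: int = 13) -> tuple[int, ...]:
    """A fixed-seed random vertex subset for the exponential-transform scenarios."""
    rng = np.random.default_rng(seed)
    return tuple(sorted(rng.choice(net.n_vertices, size=size, replace=False)))


def simulate_group(
    mu: np.ndarray,
    sigma: np.ndarray,
    n: int,
    transform: Transform = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """``n`` i.i.d. multivariate-normal rows, optionally exp-transformed columnwise."""
    rng = rng or np.random.default_rng()
    x = rng.multivariate_normal(np.asarray(mu, float), sigma, size=n, method="cholesky")
    if transform == "exp_all":
        x = np.exp(x)
    elif transform is not None:
        cols = list(transform)
        x[:, cols] = np.exp(x[:, cols])
    return x


def simulate_case_control(
    scn: SimulationScenario, rng: np.random.Generator | None = None
) -> LabeledDataset:
    """Stack one case-group and one control-group draw with 1/0 labels."""
    rng = rng or np.random.default_rng()
    xd = simulate_group(scn.mu_case, scn.sigma_case, scn.n_case, scn.transform, rng)
    xc = simulate_group(scn.mu_control, scn.sigma_control, scn.n_control, scn.transform, rng)
    x = np.vstack([xd, xc])
    y = np.concatenate([np.ones(scn.n_case, int), np.zeros(scn.n_control, int)])
    return LabeledDataset(x, y, scn.net.vertex_names)


@dataclass(frozen=True)
class RejectionRateResult:
    """Empirical rejection rate with its binomial standard error."""

    rate: float
    se: float
    alpha: float
    method: str
    n_replicates: int
    n_permutations: int | None
    seed: int | None
    p_values: np.ndarray = field(repr=False)


METHODS = ("netdifm_asymptotic", "netdifm_permutation", "vewdm_permutation")


def replicate_pvalue(
    data: LabeledDataset,
    net: NetworkSpec,
    method: str,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> float:
    """One p-value by any of the three supported methods."""
    if method == "netdifm_asymptotic":
        return netdifm_test(data, net).p_value
    if method in ("netdifm_permutation", "vewdm_permutation"):
        plan = PermutationPlan(n_permutations=n_permutations, seed=seed)
        statistic = method.split("_")[0]
        return permutation_pvalue(data, net, statistic=statistic, plan=plan).p_value
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def estimate_rejection_rate(
    scn: SimulationScenario,
    method: str,
    alpha: float = 0.05,
    n_replicates: int = 1000,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> RejectionRateResult:
    """Fraction of simulated replicates rejected at level ``alpha``.

    Estimates the type I error when ``scn`` is a null scenario and the power
    otherwise.  Per-replicate p-values are kept for diagnostics.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        data = simulate_case_control(scn, rng)
        perm_seed = int(rng.integers(2**31))
        pvals[r] = replicate_pvalue(data, scn.net, method, n_permutations, perm_seed)
    rate = float((pvals < alpha).mean())
    se = float(np.sqrt(rate * (1 - rate) / n_replicates))
    return RejectionRateResult(
        rate=rate,
        se=se,
        alpha=alpha,
        method=method,
        n_replicates=n_replicates,
        n_permutations=None if method == "netdifm_asymptotic" else n_permutations,
        seed=seed,
        p_values=pvals,
    )
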