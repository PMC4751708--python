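"""Label-permutation inference engine.

The empirical null is built by reassigning case/control labels at random
while keeping both group sizes fixed, recomputing the statistic each time,
and counting strict exceedances:

    p = (1/Q) Σ_i I(stat_i* > stat_observed)

Exact ties therefore count as non-exceedances; an optional add-one
correction ((1 + count)/(1 + Q)) is available but off by default so the
estimator matches the plain Monte-Carlo form.

Two structural facts keep this fast enough for simulation studies:

* the NetDifM covariance Σ factorizes as Σ_l (Y_l − Ȳ)² × a label-free
  pooled covariance, so it is computed once and only the score vector D is
  recomputed per permutation (a single matrix product for all Q draws);
* every VEWDM group moment is linear in the 0/1 case mask, so all Q
  permutations are evaluated with a handful of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import LabeledDataset
from .network_model import NetworkSpec
from .score_test import (
    COND_THRESHOLD,
    ScoreDecomposition,
    SingularCovarianceError,
    TestResult,
    score_covariance,
)
from .vewdm import _vewdm_from_masks


@dataclass(frozen=True)
class PermutationPlan:
    """How to build the empirical null.

    ``exhaustive`` enumerates every label assignment with the observed group
    sizes instead of sampling, provided C(N, n_case) does not exceed
    ``exhaustive_cap``.  ``add_one`` switches to the (1+count)/(1+Q)
    estimator, which cannot return an exact zero.
    """

    n_permutations: int = 1000
    seed: int | None = None
    exhaustive: bool = False
    exhaustive_cap: int = 200_000
    add_one: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


def permute_labels(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One uniformly random relabeling; the label multiset is preserved."""
    y = np.asarray(y)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be coded 0/1")
    return rng.permutation(y)


def _label_assignments(y: np.ndarray, plan: PermutationPlan) -> np.ndarray:
    """Q × N matrix of relabelings (exhaustive or Monte-Carlo)."""
    n = len(y)
    n_case = int(np.sum(y))
    if plan.exhaustive:
        total = comb(n, n_case)
        if total > plan.exhaustive_cap:
            raise ValueError(
                f"exhaustive enumeration of C({n}, {n_case}) = {total} assignments "
                f"exceeds the cap ({plan.exhaustive_cap})"
            )
        out = np.zeros((total, n), dtype=int)
        for row, case_idx in enumerate(combinations(range(n), n_case)):
            out[row, list(case_idx)] = 1
        return out
    rng = np.random.default_rng(plan.seed)
    tiled = np.tile(np.asarray(y, dtype=int), (plan.n_permutations, 1))
    return rng.permuted(tiled, axis=1)


def _empirical_p(observed: float, permuted: np.ndarray, plan: PermutationPlan) -> float:
    count = int((permuted > observed).sum())
    q = len(permuted)
    if plan.add_one:
        return (1 + count) / (1 + q)
    return count / q


def _netdifm_perm_stats(dec: ScoreDecomposition, assignments: np.ndarray) -> np.ndarray:
    """NetDifM under each relabeling, reusing the label-invariant Σ."""
    cond = np.linalg.cond(dec.Sigma)
    if not np.isfinite(cond) or cond > COND_THRESHOLD:
        raise SingularCovarianceError(
            f"score covariance is numerically singular (condition number {cond:.3g}); "
            "prune weak edges before permutation testing"
        )
    cho = cho_factor(dec.Sigma)
    centered = assignments - assignments.mean(axis=1, keepdims=True)
    d_all = dec.working.T @ centered.T  # (M+K) × Q
    return np.einsum("pq,pq->q", d_all, cho_solve(cho, d_all))


def permutation_pvalue(
    data: LabeledDataset,
    net: NetworkSpec,
    statistic: str = "netdifm",
    plan: PermutationPlan | None = None,
    vertices: Sequence[int] | None = None,
) -> TestResult:
    """Permutation p-value for the named statistic (``netdifm`` or ``vewdm``).

    The observed statistic is computed on the original labels and compared
    against the permuted values by strict inequality.  ``vertices`` restricts
    the vertex part of the statistic (star-subnetwork testing).
    """
    plan = plan or PermutationPlan()
    assignments = _label_assignments(data.y, plan)
    q = len(assignments)
    if statistic == "netdifm":
        dec = score_covariance(data, net, vertices=vertices)
        permuted = _netdifm_perm_stats(dec, assignments)  # also validates Σ
        cho = cho_factor(dec.Sigma)
        observed = float(dec.D @ cho_solve(cho, dec.D))
    elif statistic == "vewdm":
        x = data.aligned(net)
        observed = float(_vewdm_from_masks(x, net.edges, data.case_mask[None, :], vertices)[0])
        permuted = _vewdm_from_masks(x, net.edges, assignments == 1, vertices)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if not np.isfinite(permuted).all():
        raise ValueError(f"{statistic} was non-finite under some permutation")
    return TestResult(
        statistic=observed,
        p_value=_empirical_p(observed, permuted, plan),
        method=f"{statistic}_permutation",
        n_permutations=q,
        seed=plan.seed,
    )
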