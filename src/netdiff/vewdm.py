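"""Element-wise network comparator (VEWDM).

Compares the two groups one network element at a time: a standardized mean
difference ``T_i`` per vertex and a Fisher r-to-z difference ``U_ij`` per
edge, combined as

    VEWDM = (1/M) Σ_i T_i²  +  (1/K) Σ_{(i,j) ∈ E} U_ij²

with each unordered edge counted once.  T uses the Welch-style denominator
``√(var(x̄^D) + var(x̄^C))`` with ``var(x̄) = s²/n`` per group; U compares the
per-group Pearson correlations on the variance-stabilized z scale with the
classical standard error ``√(1/(n_D−3) + 1/(n_C−3))``.

No asymptotic null is offered: the joint distribution of the T's and U's
depends on the network structure, so inference is by label permutation (see
:mod:`netdiff.permutation`).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .data import LabeledDataset
from .network_model import NetworkSpec, VertexRef

#: Correlations this close to ±1 are clipped before the z transform.
_R_CLIP = 1.0 - 1e-12


def fisher_z(r) -> np.ndarray | float:
    """Fisher's variance-stabilizing transform ``z = ½ ln((1+r)/(1−r))``.

    Values at exactly ±1 (possible on degenerate finite samples) are clipped
    to ±(1 − 1e−12) with a warning rather than returning ±inf.
    """
    r = np.asarray(r, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("correlation input must be finite")
    if (np.abs(r) >= 1).any():
        warnings.warn("correlation at ±1 clipped before Fisher z", RuntimeWarning)
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _group_split(data: LabeledDataset, column: np.ndarray):
    mask = data.case_mask
    return column[mask], column[~mask]


def vertex_t(data: LabeledDataset, vertex: VertexRef) -> float:
    """Standardized case-vs-control mean difference for one vertex."""
    xd, xc = _group_split(data, data.column(vertex))
    if len(xd) < 2 or len(xc) < 2:
        raise ValueError("both groups need ≥2 observations for vertex T")
    denom = xd.var(ddof=1) / len(xd) + xc.var(ddof=1) / len(xc)
    if denom == 0:
        raise ValueError("zero variance in both groups: vertex T undefined")
    return float((xd.mean() - xc.mean()) / np.sqrt(denom))


def edge_u(data: LabeledDataset, edge: tuple[VertexRef, VertexRef]) -> float:
    """Fisher-z difference of the per-group Pearson correlations of one edge."""
    a, b = (data.column(v) for v in edge)
    mask = data.case_mask
    n_d, n_c = int(mask.sum()), int((~mask).sum())
    if n_d <= 3 or n_c <= 3:
        raise ValueError("edge U needs more than 3 samples per group (n − 3 > 0)")
    rs = []
    for g in (mask, ~mask):
        xa, xb = a[g], b[g]
        if xa.std() == 0 or xb.std() == 0:
            raise ValueError("constant endpoint column within a group: correlation undefined")
        rs.append(np.corrcoef(xa, xb)[0, 1])
    se = np.sqrt(1.0 / (n_d - 3) + 1.0 / (n_c - 3))
    return float((fisher_z(rs[0]) - fisher_z(rs[1])) / se)


def vewdm_statistic(
    data: LabeledDataset,
    net: NetworkSpec,
    vertices: Sequence[int] | None = None,
) -> float:
    """Mean squared T over the scored vertices plus mean squared U over the
    K edges.  ``vertices`` restricts the T term to the given vertex positions
    (the per-vertex star-subnetwork test scores only the focal vertex)."""
    x = data.aligned(net)
    return float(_vewdm_from_masks(x, net.edges, data.case_mask[None, :], vertices)[0])


def _vewdm_from_masks(
    x: np.ndarray,
    edges: Sequence[tuple[int, int]],
    case_masks: np.ndarray,
    vertices: Sequence[int] | None = None,
) -> np.ndarray:
    """VEWDM for many label assignments at once.

    ``case_masks`` is a Q × N boolean matrix, each row one assignment with
    the same number of cases.  All group moments are linear in the mask, so
    a handful of matrix products evaluates every permutation; this is the
    engine behind the permutation p-value.
    """
    if len(edges) == 0:
        raise ValueError("VEWDM needs at least one edge")
    n = x.shape[0]
    b = case_masks.astype(float)
    n_d = float(b[0].sum())
    n_c = n - n_d
    if n_d <= 3 or n_c <= 3:
        raise ValueError("VEWDM needs more than 3 samples per group (n − 3 > 0)")

    tot1, tot2 = x.sum(axis=0), (x**2).sum(axis=0)
    s1, s2 = b @ x, b @ x**2
    mean_d = s1 / n_d
    mean_c = (tot1 - s1) / n_c
    var_d = (s2 - n_d * mean_d**2) / (n_d - 1)
    var_c = (tot2 - s2 - n_c * mean_c**2) / (n_c - 1)

    ii = [e[0] for e in edges]
    jj = [e[1] for e in edges]
    prod = x[:, ii] * x[:, jj]
    sp = b @ prod
    cov_d = (sp - n_d * mean_d[:, ii] * mean_d[:, jj]) / (n_d - 1)
    cov_c = (prod.sum(axis=0) - sp - n_c * mean_c[:, ii] * mean_c[:, jj]) / (n_c - 1)
    with np.errstate(invalid="raise", divide="raise"):
        try:
            r_d = cov_d / np.sqrt(var_d[:, ii] * var_d[:, jj])
            r_c = cov_c / np.sqrt(var_c[:, ii] * var_c[:, jj])
            t_num = mean_d - mean_c
            t_den = np.sqrt(var_d / n_d + var_c / n_c)
            if vertices is not None:
                sel = list(vertices)
                t_num, t_den = t_num[:, sel], t_den[:, sel]
            t = t_num / t_den
        except FloatingPointError:
            raise ValueError(
                "VEWDM undefined: a column is constant within a group under some "
                "label assignment"
            ) from None
    u = (np.arctanh(np.clip(r_d, -_R_CLIP, _R_CLIP)) - np.arctanh(np.clip(r_c, -_R_CLIP, _R_CLIP)))
    u /= np.sqrt(1.0 / (n_d - 3) + 1.0 / (n_c - 3))
    return (t**2).mean(axis=1) + (u**2).mean(axis=1)
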