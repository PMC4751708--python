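"""Undirected weighted-network topology: edge-list I/O and canonical edge indexing.

A network here is a fixed, known topology over named biomolecule vertices
(genes, metabolites, SNP-block scores ...).  Edge *weights* are never stored on
the graph itself: they are estimated from data by the test statistics.  What
this module pins down is the bookkeeping every statistic depends on — a stable
vertex order and a stable edge order, so that position ``M + k`` of a score
vector always refers to the same unordered pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence, Union

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .data import LabeledDataset

logger = logging.getLogger(__name__)

VertexRef = Union[int, str]


class NetworkError(ValueError):
    """Invalid network topology or edge-list input."""


@dataclass(frozen=True)
class NetworkSpec:
    """An undirected graph with a canonical vertex and edge ordering.

    Parameters
    ----------
    vertex_names
        Ordered, unique vertex identifiers; defines the column order expected
        of any paired data matrix.
    edges
        Ordered pairs ``(i, j)`` of vertex indices with ``i < j``, sorted
        lexicographically.  The position of a pair in this tuple is the
        canonical edge index used by every downstream score vector.
    """

    vertex_names: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(set(self.vertex_names)) != len(self.vertex_names):
            raise NetworkError("vertex names must be unique")
        m = len(self.vertex_names)
        for i, j in self.edges:
            if not (0 <= i < m and 0 <= j < m):
                raise NetworkError(f"edge ({i}, {j}) references a vertex outside [0, {m})")
            if i == j:
                raise NetworkError(f"self-loop on vertex index {i}")
            if i > j:
                raise NetworkError(f"edge ({i}, {j}) not normalized to i < j")
        if len(set(self.edges)) != len(self.edges):
            raise NetworkError("duplicate edges")
        if tuple(sorted(self.edges)) != tuple(self.edges):
            raise NetworkError("edges not in canonical lexicographic order")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        vertex_names: Sequence[str] | None = None,
    ) -> "NetworkSpec":
        """Build a network from name pairs, normalizing and deduplicating.

        Self-loops and duplicate unordered pairs are dropped (with a log
        message).  Vertices are taken in first-appearance order unless an
        explicit ``vertex_names`` universe is given, in which case every edge
        endpoint must belong to it.
        """
        pairs = list(pairs)
        if vertex_names is None:
            seen: dict[str, int] = {}
            for a, b in pairs:
                for name in (a, b):
                    if name not in seen:
                        seen[name] = len(seen)
            index = seen
            names = tuple(index)
        else:
            names = tuple(str(v) for v in vertex_names)
            index = {name: k for k, name in enumerate(names)}
        n_self = n_dup = 0
        edge_set: set[tuple[int, int]] = set()
        for a, b in pairs:
            try:
                i, j = index[a], index[b]
            except KeyError as exc:
                raise NetworkError(
                    f"edge endpoint {exc.args[0]!r} is not in the vertex universe"
                ) from None
            if i == j:
                n_self += 1
                continue
            e = (i, j) if i < j else (j, i)
            if e in edge_set:
                n_dup += 1
            else:
                edge_set.add(e)
        if n_self or n_dup:
            logger.info("dropped %d self-loop(s) and %d duplicate edge(s)", n_self, n_dup)
        return cls(names, tuple(sorted(edge_set)))

    # -- basic accessors ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_index(self) -> dict[tuple[int, int], int]:
        """Bijection from normalized vertex-index pair to edge position."""
        return {pair: k for k, pair in enumerate(self.edges)}

    def vertex_position(self, vertex: VertexRef) -> int:
        if isinstance(vertex, str):
            try:
                return self.vertex_names.index(vertex)
            except ValueError:
                raise NetworkError(f"unknown vertex {vertex!r}") from None
        if not 0 <= vertex < self.n_vertices:
            raise NetworkError(f"vertex index {vertex} out of range")
        return int(vertex)

    def degree(self, vertex: VertexRef) -> int:
        v = self.vertex_position(vertex)
        return sum(v in pair for pair in self.edges)

    def neighbors(self, vertex: VertexRef) -> tuple[int, ...]:
        v = self.vertex_position(vertex)
        out = [j if i == v else i for i, j in self.edges if v in (i, j)]
        return tuple(sorted(out))

    def edge_names(self) -> tuple[tuple[str, str], ...]:
        return tuple((self.vertex_names[i], self.vertex_names[j]) for i, j in self.edges)


# -- I/O -------------------------------------------------------------------


def load_edge_list(
    path: str | Path,
    delimiter: str = "\t",
    header: bool = False,
    vertex_names: Sequence[str] | None = None,
) -> NetworkSpec:
    """Read a two-column edge list into a :class:`NetworkSpec`.

    Each row names the two endpoints of one undirected edge; extra columns
    are ignored.  Duplicate unordered pairs and self-loops are dropped with a
    log message.  An empty edge set is an error: a network comparison needs
    at least one edge.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.strip()
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise NetworkError(f"{path}:{lineno}: expected ≥2 fields, got {len(fields)}")
            pairs.append((fields[0].strip(), fields[1].strip()))
    net = NetworkSpec.from_pairs(pairs, vertex_names=vertex_names)
    if net.n_edges == 0:
        raise NetworkError(f"{path}: no edges after normalization")
    return net


def write_edge_list(net: NetworkSpec, path: str | Path, delimiter: str = "\t") -> None:
    """Write the canonical edge list (one name pair per row)."""
    with Path(path).open("w") as fh:
        for a, b in net.edge_names():
            fh.write(f"{a}{delimiter}{b}\n")


# -- derived networks ------------------------------------------------------


def incident_subnetwork(net: NetworkSpec, vertex: VertexRef) -> NetworkSpec:
    """The star subnetwork of one vertex: itself, its neighbors, and exactly
    the edges incident to it.

    This is the unit used for per-vertex testing, where a vertex together
    with its connected edges is treated as a small network in its own right.
    A degree-0 vertex yields ``n_edges == 0``; downstream tests flag it as
    untestable.
    """
    v = net.vertex_position(vertex)
    members = sorted({v, *net.neighbors(v)})
    names = tuple(net.vertex_names[i] for i in members)
    remap = {old: new for new, old in enumerate(members)}
    sub_edges = sorted(
        tuple(sorted((remap[i], remap[j]))) for i, j in net.edges if v in (i, j)
    )
    return NetworkSpec(names, tuple(sub_edges))


def prune_edges(net: NetworkSpec, data: "LabeledDataset", threshold: float) -> NetworkSpec:
    """Drop edges whose pooled Pearson correlation is weaker than ``threshold``.

    This is the shrinkage remedy for a rank-deficient score covariance: near
    zero-correlation edges contribute nearly collinear working variables, and
    removing them restores invertibility.  The correlation is computed on the
    pooled sample (both groups combined) so that the retained topology does
    not depend on the group labels.  The vertex set is unchanged.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    x = data.aligned(net)
    corr = np.corrcoef(x, rowvar=False)
    kept = tuple(pair for pair in net.edges if abs(corr[pair]) >= threshold)
    n_dropped = net.n_edges - len(kept)
    if n_dropped:
        logger.info("pruned %d edge(s) below |r| = %g", n_dropped, threshold)
    return NetworkSpec(net.vertex_names, kept)
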