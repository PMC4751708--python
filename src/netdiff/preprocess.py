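"""Collapse multi-feature biomolecules to one continuous value per vertex.

Network vertices are genes (or other biomolecules), but raw measurements are
often finer-grained: several microarray probe sets per gene symbol, or many
SNPs per gene region.  Two label-blind collapses are provided:

* ``average_features`` — the per-sample arithmetic mean of a vertex's
  feature columns (the standard probe-set-to-gene reduction);
* ``first_pc`` — the first principal-component score of the standardized
  feature block (the standard SNP-set-to-gene reduction), computed on the
  pooled sample so group labels cannot leak into vertex construction.

PC1 has a deterministic sign: it is flipped so the loading with the largest
absolute value is positive (the downstream vertex score is not sign
invariant, so an arbitrary SVD sign would make results run-dependent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class FeatureMapError(ValueError):
    """Invalid vertex → feature mapping."""


@dataclass(frozen=True)
class FeatureMap:
    """Mapping from vertex name to the raw feature columns that measure it."""

    mapping: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean = {}
        for vertex, feats in self.mapping.items():
            feats = tuple(str(f) for f in feats)
            if not feats:
                raise FeatureMapError(f"vertex {vertex!r} has an empty feature list")
            clean[str(vertex)] = feats
        object.__setattr__(self, "mapping", clean)

    @classmethod
    def from_table(cls, path: str | Path, delimiter: str = "\t") -> "FeatureMap":
        """Read a 2-column (vertex, feature) table."""
        df = pd.read_csv(path, sep=delimiter, header=None, names=["vertex", "feature"])
        grouped = df.groupby("vertex", sort=False)["feature"].apply(tuple)
        return cls(dict(grouped))

    def validate(self, columns: Sequence[str]) -> None:
        missing = [
            f for feats in self.mapping.values() for f in feats if f not in columns
        ]
        if missing:
            raise FeatureMapError(f"mapped features absent from the raw matrix: {missing}")


def average_features(raw: pd.DataFrame, fmap: FeatureMap) -> pd.DataFrame:
    """Per-sample mean of each vertex's mapped feature columns."""
    fmap.validate(raw.columns)
    out = {v: raw[list(feats)].mean(axis=1) for v, feats in fmap.mapping.items()}
    return pd.DataFrame(out, index=raw.index)


def first_pc(raw: pd.DataFrame, fmap: FeatureMap) -> pd.DataFrame:
    """First principal-component score of each vertex's standardized feature block."""
    fmap.validate(raw.columns)
    if len(raw) < 2:
        raise FeatureMapError("PCA collapse needs at least 2 samples")
    out = {}
    for vertex, feats in fmap.mapping.items():
        block = raw[list(feats)].to_numpy(dtype=float)
        sd = block.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [f for f, s in zip(feats, sd) if s == 0]
            raise FeatureMapError(f"zero-variance feature(s) for vertex {vertex!r}: {bad}")
        z = (block - block.mean(axis=0)) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        loadings = vt[0]
        sign = np.sign(loadings[np.argmax(np.abs(loadings))])
        out[vertex] = sign * u[:, 0] * s[0]
    return pd.DataFrame(out, index=raw.index)
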