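"""Two-group labeled data: the N×M continuous matrix every statistic consumes."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network_model import NetworkError, NetworkSpec


class DataError(ValueError):
    """Invalid labeled-dataset input."""


@dataclass
class LabeledDataset:
    """Continuous vertex measurements with a binary case/control label.

    Rows are individuals, columns are network vertices (one continuous value
    per vertex, e.g. a gene expression level or a per-gene principal-component
    score).  Labels must be coded exactly 0 (control) / 1 (case); any other
    coding is rejected rather than silently recoded, and both groups must be
    present.  Missing values are not accepted — resolve them upstream.
    """

    X: np.ndarray
    y: np.ndarray
    vertex_names: tuple[str, ...]
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise DataError("X must be a 2-D samples × vertices matrix")
        if not np.isfinite(self.X).all():
            raise DataError("X contains missing or non-finite values")
        if y.shape != (self.X.shape[0],):
            raise DataError("y length must equal the number of rows of X")
        vals = np.unique(y)
        if not np.isin(vals, [0, 1]).all():
            raise DataError(f"labels must be coded exactly 0/1, got values {vals!r}")
        if len(vals) != 2:
            raise DataError("both labels (cases and controls) must be present")
        self.y = y.astype(int)
        self.vertex_names = tuple(str(v) for v in self.vertex_names)
        if len(self.vertex_names) != self.X.shape[1]:
            raise DataError("vertex_names length must match the number of columns")
        if len(set(self.vertex_names)) != len(self.vertex_names):
            raise DataError("vertex names must be unique")
        if self.sample_ids is not None:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
            if len(self.sample_ids) != self.X.shape[0]:
                raise DataError("sample_ids length must match the number of rows")

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_case(self) -> int:
        return int(self.y.sum())

    @property
    def n_control(self) -> int:
        return self.n_samples - self.n_case

    @property
    def case_mask(self) -> np.ndarray:
        return self.y == 1

    def column(self, vertex: int | str) -> np.ndarray:
        idx = self.vertex_names.index(vertex) if isinstance(vertex, str) else int(vertex)
        return self.X[:, idx]

    def aligned(self, net: NetworkSpec) -> np.ndarray:
        """Columns reordered to the network's vertex order.

        Every network vertex must be a data column; extra data columns are
        dropped.  This is the one place column/vertex alignment happens, so a
        name mismatch fails loudly instead of silently misaligning scores.
        """
        positions = []
        for name in net.vertex_names:
            try:
                positions.append(self.vertex_names.index(name))
            except ValueError:
                raise NetworkError(f"network vertex {name!r} has no data column") from None
        return self.X[:, positions]

    def with_labels(self, y: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X, y, self.vertex_names, self.sample_ids)

    # -- pandas bridge -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str) -> "LabeledDataset":
        if label_col not in df.columns:
            raise DataError(f"label column {label_col!r} not found")
        y = df[label_col].to_numpy()
        x = df.drop(columns=[label_col])
        return cls(
            x.to_numpy(dtype=float),
            y,
            tuple(map(str, x.columns)),
            tuple(map(str, df.index)),
        )

    def to_dataframe(self, label_col: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.vertex_names), index=self.sample_ids)
        df.insert(0, label_col, self.y)
        return df


def load_labeled_data(
    path: str | Path,
    label_col: str = "label",
    delimiter: str = "\t",
    sample_id_col: str | None = None,
    transpose: bool = False,
) -> LabeledDataset:
    """Read a delimited samples × features table with a header of vertex names.

    ``transpose`` is the escape hatch for features × samples files (labels are
    then taken from the row named ``label_col``).
    """
    df = pd.read_csv(path, sep=delimiter)
    if transpose:
        df = df.set_index(df.columns[0]).T
        df = df.apply(pd.to_numeric)
    if sample_id_col is not None:
        df = df.set_index(sample_id_col)
    return LabeledDataset.from_dataframe(df, label_col=label_col)
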