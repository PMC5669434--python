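"""Symmetric labeled distance matrices shared by the Rst, MDS and tree code."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """A symmetric matrix of pairwise distances with a zero diagonal."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        np.fill_diagonal(self.values, 0.0)
        self.values = (self.values + self.values.T) / 2.0

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "DistanceMatrix":
        return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))
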