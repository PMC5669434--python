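"""Classical (Torgerson) multi-dimensional scaling of a distance matrix.

Used to visualize an Rst matrix in two dimensions. Negative entries (small
negative Rst estimates) are clipped to zero before scaling; the Gram matrix
is obtained by double centering, ``B = -1/2 J D^2 J``, and the top two
eigenpairs give the coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

__all__ = ["Embedding2D", "classical_mds"]

log = logging.getLogger(__name__)


@dataclass
class Embedding2D:
    """A two-dimensional metric-MDS embedding."""

    labels: List[str]
    coordinates: np.ndarray  # n x 2, centered
    eigenvalues: np.ndarray  # all eigenvalues of B, non-increasing
    goodness: float  # (lam1+lam2) / sum(positive eigenvalues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates, index=self.labels, columns=["dim1", "dim2"]
        )

    def pairwise_distances(self) -> np.ndarray:
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))


def classical_mds(matrix: DistanceMatrix, clip_negative: bool = True) -> Embedding2D:
    """Embed a symmetric distance matrix into the plane by Torgerson scaling.

    Axes are ordered by eigenvalue; each axis's sign is fixed so that its
    largest-magnitude coordinate is positive. An all-zero matrix yields the
    degenerate embedding at the origin (with a warning).
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("classical MDS needs at least 3 points")
    d = matrix.values.copy()
    if clip_negative:
        d = np.clip(d, 0.0, None)
    if np.allclose(d, 0.0):
        log.warning("all-zero distance matrix: degenerate embedding at origin")
        return Embedding2D(
            list(matrix.labels), np.zeros((n, 2)), np.zeros(n), 0.0
        )
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    coords = np.zeros((n, 2))
    for axis in range(2):
        lam = eigval[axis]
        if lam > 0:
            v = eigvec[:, axis] * np.sqrt(lam)
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, axis] = v
    coords -= coords.mean(axis=0)

    pos = eigval[eigval > 0]
    goodness = float(eigval[:2].clip(min=0).sum() / pos.sum()) if pos.size else 0.0
    return Embedding2D(list(matrix.labels), coords, eigval, goodness)
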