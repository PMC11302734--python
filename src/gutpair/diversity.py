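"""Bray-Curtis dissimilarity and classical PCoA.

Bray-Curtis d(u,v) = sum|u-v| / sum(u+v), with d = 0 between two all-zero
profiles by convention. PCoA eigendecomposes the Gower-centered matrix
-1/2 J D^2 J; coordinates are eigenvectors scaled by the square root of their
(positive) eigenvalues. Negative eigenvalues — possible because Bray-Curtis is
not Euclidean-embeddable — are reported but excluded from coordinates and from
the variance-explained denominator unless a Lingoes correction is requested.
Each axis is oriented so its largest-magnitude coordinate is positive, making
outputs deterministic up to that convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import AbundanceTable
from .exceptions import ValidationError

_EIG_TOL = 1e-10


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix must be square and match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValidationError("row and column labels must match")
        return cls(sample_ids=list(frame.index), values=frame.to_numpy(dtype=float))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between the table's sample columns."""
    data = table.data.to_numpy(dtype=float).T  # samples x features
    if data.shape[0] < 2:
        raise ValidationError("Bray-Curtis needs at least two samples")
    if np.any(data < 0):
        raise ValidationError("abundances must be non-negative")
    dist = squareform(pdist(data, metric="braycurtis"))
    dist = np.nan_to_num(dist, nan=0.0)  # two all-zero profiles: distance 0 by convention
    return DistanceMatrix(sample_ids=table.sample_ids, values=dist)


def pcoa(
    dist: DistanceMatrix,
    n_axes: Optional[int] = None,
    negative_eigenvalue_correction: Optional[str] = None,
) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    ``negative_eigenvalue_correction='lingoes'`` adds the smallest constant to
    all squared off-diagonal distances that makes the centered matrix positive
    semi-definite; by default negatives are reported as-is.
    """
    d = dist.values
    n = d.shape[0]
    if n_axes is not None and not 1 <= n_axes <= n - 1:
        raise ValidationError("n_axes must lie in [1, n_samples - 1]")

    def center(dsq: np.ndarray) -> np.ndarray:
        j = np.eye(n) - np.ones((n, n)) / n
        return -0.5 * j @ dsq @ j

    b = center(d ** 2)
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    if negative_eigenvalue_correction == "lingoes" and eigval.min() < -_EIG_TOL:
        c = -eigval.min()
        dsq = d ** 2 + 2.0 * c * (1.0 - np.eye(n))
        b = center(dsq)
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    elif negative_eigenvalue_correction not in (None, "lingoes"):
        raise ValidationError(
            f"unknown correction {negative_eigenvalue_correction!r}; use None or 'lingoes'"
        )

    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    scale = max(abs(eigval[0]), 1.0)
    positive = eigval > _EIG_TOL * scale
    n_pos = int(positive.sum())
    keep = n_pos if n_axes is None else min(n_axes, n_pos)

    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    # deterministic orientation: largest-|loading| entry of each axis positive
    for ax in range(keep):
        col = coords[:, ax]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, ax] = -col
    pos_total = eigval[positive].sum()
    proportion = (eigval[:keep] / pos_total) if pos_total > 0 else np.zeros(keep)

    frame = pd.DataFrame(
        coords,
        index=dist.sample_ids,
        columns=[f"PCo{i + 1}" for i in range(keep)],
    )
    return OrdinationResult(
        coordinates=frame, eigenvalues=eigval, proportion_explained=proportion
    )
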