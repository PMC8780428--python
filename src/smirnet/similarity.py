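"""Similarity matrices from latent vectors.

The similarity of two entities is one minus their normalised Euclidean
distance in latent space:

    s_ij = 1 - d_ij / max_kl d_kl

Normalisation is per matrix (per entity type) by the maximum pairwise
distance, so every entry lies in [0, 1], the diagonal is exactly 1, and the
most distant pair has similarity 0.  If all vectors coincide the matrix is
all ones by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity set."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"expected {(n, n)} matrix, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("similarity matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.ids)


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two latent vectors of equal dimension."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def similarity_matrix(
    vectors: np.ndarray, ids: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Negated max-normalised Euclidean distances of an (n, D) vector stack."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need at least 2 vectors of common dimension")
    if not np.all(np.isfinite(vectors)):
        raise ValueError("latent vectors must be finite")
    if ids is None:
        ids = [str(i) for i in range(vectors.shape[0])]
    if len(ids) != vectors.shape[0]:
        raise ValueError("id count does not match vector count")

    d = squareform(pdist(vectors, metric="euclidean"))
    dmax = d.max()
    if dmax == 0.0:
        sims = np.ones_like(d)
    else:
        sims = 1.0 - d / dmax
    np.fill_diagonal(sims, 1.0)
    sims = np.clip((sims + sims.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(ids=tuple(str(i) for i in ids), values=sims)
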