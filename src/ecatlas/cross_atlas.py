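"""Cross-dataset EC-subtype similarity.

Marker sets from two (or more) atlases are compared by the Jaccard
coefficient |A∩B| / |A∪B| over case-normalized gene symbols, and the
resulting similarity matrix is embedded in the plane by classical
(Torgerson) multidimensional scaling of the dissimilarity d = 1 − J:
double-center −½ d², eigendecompose, and scale the top eigenvectors by
the square roots of their (nonnegative-clamped) eigenvalues.  Axis signs
are fixed by making each axis's largest-magnitude loading positive so
output files are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneSet

__all__ = [
    "jaccard",
    "SimilarityMatrix",
    "jaccard_matrix",
    "Embedding",
    "classical_mds",
    "congruent_markers",
]


def _symbols(s) -> tuple[str, ...]:
    genes = getattr(s, "genes", s)
    genes = getattr(genes, "genes", genes)  # MarkerSet -> GeneSet -> tuple
    return tuple(genes)


def jaccard(a, b) -> float:
    """Jaccard similarity of two gene sets, case-normalized symbols."""
    sa = {g.upper() for g in _symbols(a)}
    sb = {g.upper() for g in _symbols(b)}
    if not sa or not sb:
        raise ValueError("jaccard requires non-empty sets")
    return len(sa & sb) / len(sa | sb)


@dataclass
class SimilarityMatrix:
    labels: list[str]
    J: np.ndarray  # symmetric, unit diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        n = len(self.labels)
        if self.J.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.J), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        if self.J.min() < -1e-12 or self.J.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.J, index=self.labels, columns=self.labels)


def jaccard_matrix(
    sets: Mapping[str, object] | Sequence[tuple[str, object]],
) -> SimilarityMatrix:
    """All pairwise Jaccard coefficients over labelled marker sets.

    Labels should be dataset-qualified (e.g. ``gbm/Co1``, ``lung/tip``) so
    clusters from different atlases stay distinct; duplicates are an error.
    """
    items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
    if len(items) < 2:
        raise ValueError("need at least 2 sets")
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate qualified labels: {dupes}")
    n = len(items)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jaccard(items[i][1], items[j][1])
    return SimilarityMatrix(labels=labels, J=J)


@dataclass
class Embedding:
    coordinates: np.ndarray  # points × dims
    eigenvalues: np.ndarray  # all eigenvalues, descending
    stress: float
    clamped_mass: float  # total magnitude of negative eigenvalues set to zero
    labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i+1}" for i in range(self.coordinates.shape[1])]
        idx = self.labels or list(range(len(self.coordinates)))
        return pd.DataFrame(self.coordinates, index=idx, columns=cols)


def classical_mds(
    S: SimilarityMatrix, dims: int = 2, transform: str = "one_minus"
) -> Embedding:
    """Torgerson scaling of the dissimilarity derived from ``S``.

    ``transform``: ``one_minus`` uses d = 1 − J (default); ``sqrt`` uses
    d = sqrt(1 − J), which is metric for Jaccard similarities.  Negative
    eigenvalues (possible because 1 − J need not be Euclidean) are clamped
    to zero and their total magnitude reported.
    """
    n = len(S.labels)
    if dims < 1:
        raise ValueError("dims must be ≥ 1")
    if dims >= n:
        raise ValueError(f"dims={dims} must be below the number of points {n}")
    d = 1.0 - S.J
    if transform == "sqrt":
        d = np.sqrt(d)
    elif transform != "one_minus":
        raise ValueError(f"unknown transform {transform!r}")
    b = _double_center(d)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    clamped_mass = float(-eigval[eigval < 0].sum())
    lam = np.clip(eigval[:dims], 0.0, None)
    coords = eigvec[:, :dims] * np.sqrt(lam)[None, :]
    for k in range(dims):  # sign convention: largest-magnitude loading positive
        col = coords[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    emb_d = _pairwise_dist(coords)
    denom = np.sum(d**2)
    stress = float(np.sqrt(np.sum((emb_d - d) ** 2) / denom)) if denom > 0 else 0.0
    return Embedding(
        coordinates=coords,
        eigenvalues=eigval,
        stress=stress,
        clamped_mass=clamped_mass,
        labels=list(S.labels),
    )


def _double_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def _pairwise_dist(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def congruent_markers(a, b) -> tuple[str, ...]:
    """Ordered intersection of two marker sets, in the first set's ranking."""
    sb = {g.upper() for g in _symbols(b)}
    return tuple(g for g in _symbols(a) if g.upper() in sb)
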