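"""Embeddings and silhouette evaluation of cell-type clustering.

The baseline embedding reduces the binary cell-LP matrix with PCA and drops
the first principal component (which tracks per-cell coverage rather than
biology).  The topic-space embedding applies a 2-D reducer (UMAP by
default, pluggable) directly to the cell-topic matrix.  Clustering quality
is summarized by the silhouette coefficient

    s(i) = (p(i) - q(i)) / max(p(i), q(i))

with Euclidean distances, where q(i) is the mean distance from cell i to the
other cells of its own type and p(i) the minimum over other types of the
mean distance to that type's cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .lp_matrix import CellLPMatrix

__all__ = ["pca_baseline", "Embedding2D", "embed_2d", "SilhouetteResult", "silhouette"]


def pca_baseline(
    matrix: CellLPMatrix | np.ndarray | sp.spmatrix,
    n_components: int = 50,
    drop_first: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """PCA reduction of the (centered) binary matrix, optionally dropping PC1.

    With ``drop_first`` the first principal component — dominated by
    per-cell coverage — is removed, so 50 requested components yield 49
    output columns.
    """
    if isinstance(matrix, CellLPMatrix):
        X = matrix.matrix.toarray().astype(float)
    elif sp.issparse(matrix):
        X = matrix.toarray().astype(float)
    else:
        X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two cells")
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} exceeds rank bound {max_rank}")
    scores = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    return scores[:, 1:] if drop_first else scores


@dataclass
class Embedding2D:
    """2-D coordinates plus provenance of how they were produced."""

    coords: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding must be n x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in embedding")


def embed_2d(
    matrix: np.ndarray,
    reducer: str | Callable[[np.ndarray], np.ndarray] = "umap",
    seed: int = 0,
    **kwargs,
) -> Embedding2D:
    """Embed rows of a matrix into 2-D with a pluggable reducer.

    ``reducer`` may be ``"umap"`` (default; deterministic for a fixed
    ``seed``), ``"pca"``, ``"identity"`` (input must already have two
    columns), or any callable mapping an (n, d) array to an (n, 2) array.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least three rows to embed")
    name = reducer if isinstance(reducer, str) else getattr(reducer, "__name__", "callable")
    if callable(reducer):
        coords = reducer(X)
    elif reducer == "identity":
        if X.shape[1] != 2:
            raise ValueError("identity reducer requires a 2-column input")
        coords = X
    elif reducer == "pca":
        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif reducer == "umap":
        import umap

        try:
            coords = umap.UMAP(n_components=2, random_state=seed, **kwargs).fit_transform(X)
        except Exception as exc:  # surface reducer failures with context
            raise RuntimeError(f"UMAP reducer failed: {exc}") from exc
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    return Embedding2D(coords, {"reducer": name, "seed": seed, "input_dim": X.shape[1], **kwargs})


@dataclass
class SilhouetteResult:
    per_cell: np.ndarray
    per_type: dict[str, float]
    overall: float


def silhouette(
    embedding: Embedding2D | np.ndarray, labels: Sequence
) -> SilhouetteResult:
    """Silhouette coefficients with per-cell-type and overall averages.

    Euclidean distance; a cell in a singleton cluster receives s(i) = 0
    (standard convention).  q(i) excludes the cell itself from its
    intra-cluster average.  Every coefficient lies in [-1, 1].
    """
    X = embedding.coords if isinstance(embedding, Embedding2D) else np.asarray(embedding, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("one label per row required")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("silhouette needs at least two label classes")
    s = silhouette_samples(X, y, metric="euclidean")
    per_type = {ct: float(s[y == ct].mean()) for ct in classes}
    return SilhouetteResult(per_cell=s, per_type=per_type, overall=float(s.mean()))
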