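"""Dimensionality reduction and clustering.

Hierarchical clustering uses the correlation distance (1 - Pearson r
between cell profiles) by default; the agglomeration rule is selectable.
k-means, PCA, Isomap and LLE wrap scikit-learn/SciPy behind small,
typed result objects whose rows always align 1:1 with the input cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import Isomap, LocallyLinearEmbedding
from sklearn.neighbors import kneighbors_graph

from .errors import InputError

LINKAGES = ("single", "complete", "average", "ward")

MatrixLike = Union[np.ndarray, pd.DataFrame]


def _as_frame(matrix: MatrixLike) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr, index=[str(i) for i in range(arr.shape[0])])


@dataclass
class DistanceMatrix:
    values: np.ndarray  # n x n, symmetric, zero diagonal
    metric: str
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError("distance matrix must be square")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise InputError("distance matrix not symmetric within 1e-12")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class ClusterTree:
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge sequence
    linkage: str
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


@dataclass
class GroupAssignment:
    """Total map cell -> group index 1..k."""

    assignment: dict[str, int]

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, cells: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[c] for c in cells])


@dataclass
class Embedding:
    coords: pd.DataFrame  # cells x k
    method: str
    params: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# distances & clustering


def correlation_distance(matrix: MatrixLike) -> DistanceMatrix:
    """Pairwise ``1 - Pearson r`` between rows.

    Rows with zero variance have no defined correlation and indicate
    cells that should have been filtered out; they raise an error that
    names them.
    """
    df = _as_frame(matrix)
    x = df.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise InputError("need at least two rows for a distance matrix")
    sd = x.std(axis=1)
    bad = np.where(~(sd > 0))[0]
    if bad.size:
        names = [str(df.index[i]) for i in bad]
        raise InputError(f"zero-variance rows have no correlation distance: {names}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.clip(d, 0.0, 2.0, out=d)
    return DistanceMatrix(d, metric="correlation", labels=[str(i) for i in df.index])


def hcluster(dist: DistanceMatrix, linkage: str = "complete") -> ClusterTree:
    """Agglomerative clustering of a precomputed distance matrix.

    Note: ``ward`` assumes (squared-)Euclidean geometry; it is accepted
    here for use on Euclidean distances over z-scores but is not
    meaningful on correlation distances.
    """
    if linkage not in LINKAGES:
        raise InputError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    z = hierarchy.linkage(dist.condensed(), method=linkage)
    return ClusterTree(z, linkage=linkage, labels=list(dist.labels))


def cut_tree(tree: ClusterTree, k: int) -> GroupAssignment:
    """Cut the merge sequence into exactly ``k`` groups (indices 1..k)."""
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise InputError(f"k must be in [1, {n}], got {k}")
    flat = hierarchy.cut_tree(tree.linkage_matrix, n_clusters=k).ravel()
    return GroupAssignment({c: int(g) + 1 for c, g in zip(tree.labels, flat)})


def kmeans_cluster(
    matrix: MatrixLike, k: int, seed: int = 0, restarts: int = 10
) -> GroupAssignment:
    """Best-inertia k-means assignment over ``restarts`` k-means++ starts;
    deterministic for a fixed seed."""
    df = _as_frame(matrix)
    n = df.shape[0]
    if not 1 <= k <= n:
        raise InputError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, init="k-means++")
    labels = km.fit_predict(df.to_numpy(dtype=float))
    return GroupAssignment({str(c): int(g) + 1 for c, g in zip(df.index, labels)})


# ---------------------------------------------------------------------------
# embeddings


def pca_embed(matrix: MatrixLike, k: int) -> Embedding:
    """Project onto the top-k principal axes of the column-centred matrix."""
    df = _as_frame(matrix)
    n, g = df.shape
    if not 1 <= k <= min(n, g):
        raise InputError(f"k must be in [1, {min(n, g)}], got {k}")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(df.to_numpy(dtype=float))
    return Embedding(
        coords=pd.DataFrame(
            coords, index=df.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        method="pca",
        params={
            "k": k,
            "explained_variance": pca.explained_variance_.tolist(),
            "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        },
    )


def _check_neighbors(n: int, n_neighbors: int) -> None:
    if n_neighbors >= n:
        raise InputError(f"n_neighbors must be < n rows ({n}), got {n_neighbors}")
    if n_neighbors < 1:
        raise InputError("n_neighbors must be >= 1")


def isomap_embed(matrix: MatrixLike, k: int, n_neighbors: int = 15) -> Embedding:
    """Geodesic (Isomap) embedding; requires a connected k-NN graph."""
    df = _as_frame(matrix)
    x = df.to_numpy(dtype=float)
    _check_neighbors(x.shape[0], n_neighbors)
    graph = kneighbors_graph(x, n_neighbors=n_neighbors, include_self=False)
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise InputError(
            f"neighbourhood graph has {n_comp} connected components; "
            "increase n_neighbors"
        )
    iso = Isomap(n_neighbors=n_neighbors, n_components=k)
    coords = iso.fit_transform(x)
    return Embedding(
        coords=pd.DataFrame(
            coords, index=df.index, columns=[f"ISO{i + 1}" for i in range(k)]
        ),
        method="isomap",
        params={"k": k, "n_neighbors": n_neighbors},
    )


def lle_embed(
    matrix: MatrixLike, k: int, n_neighbors: int = 15, seed: int = 0
) -> Embedding:
    """Locally linear embedding (standard LLE)."""
    df = _as_frame(matrix)
    x = df.to_numpy(dtype=float)
    _check_neighbors(x.shape[0], n_neighbors)
    lle = LocallyLinearEmbedding(
        n_neighbors=n_neighbors, n_components=k, random_state=seed
    )
    coords = lle.fit_transform(x)
    return Embedding(
        coords=pd.DataFrame(
            coords, index=df.index, columns=[f"LLE{i + 1}" for i in range(k)]
        ),
        method="lle",
        params={"k": k, "n_neighbors": n_neighbors, "seed": seed},
    )
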