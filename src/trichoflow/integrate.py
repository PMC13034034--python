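"""Harmony-style soft k-means batch correction and graph clustering.

The correction implements the iterative centroid scheme: cells are softly
assigned to clusters (Gaussian affinity on L2-normalized coordinates,
down-weighted for clusters whose batch composition deviates from the
global batch proportions), then for every cluster the global centroid and
the per-batch centroids are computed and each cell is moved by the
responsibility-weighted difference between the global centroid and its own
batch's centroid. Iteration continues until the cluster centroids
stabilize. This is the described skeleton of the procedure, not a clone of
the published Harmony algorithm (no ridge-regression correction model).

Clustering builds a kNN graph on the corrected embedding, weights edges by
shared-nearest-neighbor (Jaccard) overlap, and partitions it with the
Leiden algorithm at a given resolution; singleton communities are merged
into the nearest cluster by centroid distance and labels are canonicalized
by decreasing cluster size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus
from sklearn.neighbors import NearestNeighbors

from ._rng import substream, substream_int

__all__ = [
    "SoftAssignment",
    "ClusterLabels",
    "soft_kmeans_correct",
    "cluster_cells",
    "layout_2d",
    "batch_mixing_entropy",
]


@dataclass
class SoftAssignment:
    """State of the soft k-means correction at convergence."""

    responsibilities: np.ndarray          # cells × clusters, rows sum to 1
    global_centroids: np.ndarray          # clusters × dims
    batch_centroids: dict[str, np.ndarray]  # batch -> clusters × dims
    n_iter: int
    trace: list[float]                    # max centroid movement per iteration


@dataclass
class ClusterLabels:
    labels: np.ndarray  # per-cell integer IDs, contiguous from 0

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def _l2_normalize(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def soft_kmeans_correct(
    embedding: np.ndarray,
    batch_labels: np.ndarray,
    k: int | None = None,
    sigma: float = 0.3,
    diversity_strength: float = 2.0,
    max_iter: int = 20,
    tol: float = 1e-4,
    seed: int = 0,
) -> tuple[np.ndarray, SoftAssignment]:
    """Correct batch effects in an embedding by soft k-means centroids.

    Soft assignments use cosine geometry (rows L2-normalized); the
    corrections themselves are applied in the original coordinate space.
    With a single batch the input is returned unchanged (zero correction).

    Parameters
    ----------
    k
        Number of soft clusters; defaults to ``min(100, n_cells // 30)``
        (at least 2).
    sigma
        Bandwidth of the Gaussian affinity on normalized coordinates.
    diversity_strength
        Exponent of the batch-diversity penalty ``(expected/observed)``
        applied to cluster–batch affinities; 0 disables it.
    """
    Z = np.array(embedding, dtype=np.float64, copy=True)
    batches = np.asarray(batch_labels)
    if Z.ndim != 2 or len(batches) != Z.shape[0]:
        raise ValueError("embedding and batch labels are inconsistent")
    n = Z.shape[0]
    unique_batches = np.unique(batches)
    if len(unique_batches) < 2:
        warnings.warn("single batch: correction is the identity", stacklevel=2)
        assign = SoftAssignment(
            responsibilities=np.ones((n, 1)),
            global_centroids=Z.mean(axis=0, keepdims=True),
            batch_centroids={str(unique_batches[0]): Z.mean(axis=0, keepdims=True)},
            n_iter=0,
            trace=[],
        )
        return Z, assign

    if k is None:
        k = max(2, min(100, n // 30))
    if k < 2:
        raise ValueError("k must be >= 2")

    onehot = np.stack([batches == b for b in unique_batches], axis=1).astype(float)
    batch_share = onehot.mean(axis=0)  # global batch proportions

    Y = _l2_normalize(Z)
    rng_int = substream_int(seed, "soft_kmeans")
    centers, _ = kmeans_plusplus(Y, n_clusters=k, random_state=rng_int)
    centers = _l2_normalize(centers)

    O = np.ones((k, len(unique_batches))) * batch_share[None, :]  # observed mass
    E = O.copy()
    trace: list[float] = []
    prev_global = None
    R = np.full((n, k), 1.0 / k)
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        Y = _l2_normalize(Z)
        d2 = np.maximum(2.0 - 2.0 * (Y @ centers.T), 0.0)
        log_aff = -d2 / sigma
        # diversity penalty from the previous iteration's composition:
        # clusters over-representing a batch are down-weighted for it
        penalty = diversity_strength * (np.log(E + 1.0) - np.log(O + 1.0))
        log_r = log_aff + (onehot @ penalty.T)
        log_r -= logsumexp(log_r, axis=1, keepdims=True)
        R = np.exp(log_r)

        cluster_mass = R.sum(axis=0)  # k
        O = R.T @ onehot              # k × batches
        E = cluster_mass[:, None] * batch_share[None, :]

        safe_mass = np.maximum(cluster_mass, 1e-12)
        G = (R.T @ Z) / safe_mass[:, None]  # global centroids, original space

        correction = np.zeros_like(Z)
        batch_centroids: dict[str, np.ndarray] = {}
        for j, b in enumerate(unique_batches):
            in_b = onehot[:, j].astype(bool)
            mass_b = np.maximum(R[in_b].sum(axis=0), 1e-12)
            C_b = (R[in_b].T @ Z[in_b]) / mass_b[:, None]
            # clusters with no mass in this batch contribute no correction
            empty = R[in_b].sum(axis=0) < 1e-8
            diff = G - C_b
            diff[empty] = 0.0
            correction[in_b] = R[in_b] @ diff
            batch_centroids[str(b)] = C_b
        Z = Z + correction

        centers = _l2_normalize((R.T @ _l2_normalize(Z)) / safe_mass[:, None])

        if prev_global is not None:
            move = float(np.max(np.linalg.norm(G - prev_global, axis=1)))
            trace.append(move)
            if move < tol:
                break
        prev_global = G

    assign = SoftAssignment(
        responsibilities=R,
        global_centroids=G,
        batch_centroids=batch_centroids,
        n_iter=n_iter,
        trace=trace,
    )
    return Z, assign


def cluster_cells(
    embedding: np.ndarray,
    n_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    prune: float = 1 / 15,
) -> ClusterLabels:
    """Graph-based clustering of cells on the (corrected) embedding.

    Shared-nearest-neighbor graph (an edge joins every pair of cells
    sharing kNN-list members, Jaccard-weighted, pruned below ``prune``),
    partitioned by Leiden at the given resolution. Deterministic under
    the seed; singletons are merged into the nearest cluster by centroid
    distance; labels are renumbered by decreasing cluster size.
    """
    import scipy.sparse as sp

    X_input = np.asarray(embedding, dtype=np.float64)
    n = X_input.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")

    # canonical internal ordering makes the partition independent of the
    # caller's cell order
    canon = np.lexsort(X_input.T)
    X = X_input[canon]

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    rows = np.repeat(np.arange(n), n_neighbors + 1)
    incidence = sp.csr_matrix(
        (np.ones(idx.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (incidence @ incidence.T).tocoo()  # shared-neighbor counts
    upper = shared.row < shared.col
    src, dst, inter = shared.row[upper], shared.col[upper], shared.data[upper]
    jaccard = inter / (2 * (n_neighbors + 1) - inter)
    keep = jaccard >= prune
    src, dst, weight = src[keep], dst[keep], list(jaccard[keep])

    graph = ig.Graph(n=n, edges=list(zip(src, dst)))
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weight,
        resolution_parameter=resolution,
        seed=substream_int(seed, "leiden"),
        n_iterations=2,
    )
    labels = np.asarray(partition.membership)

    # merge singleton communities into the nearest cluster by centroid
    sizes = np.bincount(labels)
    singletons = np.flatnonzero(sizes == 1)
    if len(singletons) and len(sizes) > len(singletons):
        big = [c for c in range(len(sizes)) if sizes[c] > 1]
        centroids = np.stack([X[labels == c].mean(axis=0) for c in big])
        for c in singletons:
            i = int(np.flatnonzero(labels == c)[0])
            labels[i] = big[int(np.argmin(np.linalg.norm(centroids - X[i], axis=1)))]

    # canonical relabeling: by decreasing size, ties by first occurrence
    uniq, counts = np.unique(labels, return_counts=True)
    first_pos = {c: int(np.flatnonzero(labels == c)[0]) for c in uniq}
    order = sorted(uniq, key=lambda c: (-counts[list(uniq).index(c)], first_pos[c]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in labels])

    out = np.empty(n, dtype=int)
    out[canon] = labels  # back to the caller's cell order
    return ClusterLabels(labels=out)


def layout_2d(embedding: np.ndarray, seed: int = 0, method: str = "pca") -> np.ndarray:
    """2-D layout of the corrected embedding, for plots only.

    ``pca`` (default) projects onto the top two principal axes with a
    fixed sign convention — fast and exactly reproducible. ``umap`` uses
    umap-learn when available.
    """
    X = np.asarray(embedding, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("embedding must be 2-D with at least two cells")
    if method == "umap":
        import umap  # optional

        return umap.UMAP(
            n_components=2, random_state=substream_int(seed, "layout")
        ).fit_transform(X)
    if method != "pca":
        raise ValueError(f"unknown layout method {method!r}")
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:2]
    for j in range(comps.shape[0]):
        i_max = np.argmax(np.abs(comps[j]))
        if comps[j, i_max] < 0:
            comps[j] *= -1
    return Xc @ comps.T


def batch_mixing_entropy(
    embedding: np.ndarray,
    batch_labels: np.ndarray,
    n_neighbors: int = 30,
    seed: int = 0,
    subsample: int | None = None,
) -> float:
    """Mean per-cell entropy of batch labels among the nearest neighbors.

    Higher values mean batches are better mixed locally. Used to quantify
    the effect of batch correction.
    """
    X = np.asarray(embedding, dtype=np.float64)
    batches = np.asarray(batch_labels)
    uniq = {b: i for i, b in enumerate(np.unique(batches))}
    codes = np.array([uniq[b] for b in batches])
    n = X.shape[0]
    query = np.arange(n)
    if subsample is not None and subsample < n:
        query = substream(seed, "entropy").choice(n, size=subsample, replace=False)
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n)).fit(X)
    _, idx = nn.kneighbors(X[query])
    idx = idx[:, 1:]
    ent = np.zeros(len(query))
    for row, neigh in enumerate(idx):
        counts = np.bincount(codes[neigh], minlength=len(uniq)).astype(float)
        p = counts / counts.sum()
        nz = p > 0
        ent[row] = -np.sum(p[nz] * np.log(p[nz]))
    return float(ent.mean())
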