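"""Transitional-cluster detection, rooted pseudotime and branch analysis.

Pseudotime here is a deliberately minimal, fully specified construction —
seeded k-means landmarks, a Euclidean minimum spanning tree over the
landmark centroids, geodesic distance from the landmark nearest the root
cluster's centroid, plus each cell's distance to its own landmark. It is
not a re-implementation of reversed-graph-embedding trajectory methods;
the claims it supports are structural: a rooted ordering, one branch
point, and branch states. The branch point is the internal tree node of
degree >= 3 whose removal best balances the downstream cell mass; state 1
is the root side and the two downstream branches become states 2 and 3
(state 3 = the branch with the greater mean pseudotime, matching the
convention that the trichome-like terminal branch gets the last state).

Branch-dependent expression is tested with a two-branch rank-sum contrast
(one p-value per gene plus each branch's fold change against the pre-
branch state), a simplified substitute for spline-likelihood branch
models; gene trends along pseudotime are clustered into modules with
k-means on per-bin z-scaled means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from ._rng import substream_int
from .cellcycle import module_score
from .markers import _tie_terms, _vectorized_ranksum, compute_log2fc

__all__ = [
    "TrajectoryResult",
    "detect_transitional_clusters",
    "smooth_embedding",
    "compute_pseudotime",
    "gene_trend_modules",
    "branch_dependence_test",
]


def smooth_embedding(
    embedding: np.ndarray, n_neighbors: int = 30, rounds: int = 2
) -> np.ndarray:
    """kNN-average the embedding to suppress within-population noise.

    Each round replaces every cell's coordinates by the mean of itself and
    its nearest neighbors. Applied before landmark fitting so the minimum
    spanning tree follows the manifold backbone instead of wandering
    inside noisy cell clouds.
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(embedding, dtype=np.float64)
    k = min(n_neighbors, X.shape[0] - 1)
    for _ in range(rounds):
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, idx = nn.kneighbors(X)
        X = X[idx].mean(axis=1)
    return X


@dataclass
class TrajectoryResult:
    pseudotime: np.ndarray        # per cell, >= 0
    state: np.ndarray             # per cell in {1, 2, 3} (or {1, 2} on a path)
    landmark_of_cell: np.ndarray  # per-cell landmark index
    landmarks: np.ndarray         # n_landmarks × dims centroids
    mst_edges: np.ndarray         # (n_edges, 3): node_i, node_j, weight
    root_landmark: int
    branch_landmark: int | None
    root_cluster: object

    @property
    def n_states(self) -> int:
        return len(np.unique(self.state))


def detect_transitional_clusters(
    cluster_labels: np.ndarray,
    sample_labels: np.ndarray,
    epidermis_markers: list[str],
    trichome_markers: list[str],
    normalized: sp.spmatrix,
    genes: np.ndarray,
    ratio_window: tuple[float, float] = (0.5, 2.0),
    coexpr_min: float = 0.25,
    sample_class: dict[str, str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag clusters that sit between the epidermal and trichome programs.

    For each cluster the CL/CT cell-count ratio is computed (samples are
    classed by the prefix before the first ``-`` unless an explicit
    ``sample_class`` mapping is given; a cluster entirely from one class
    has an infinite or zero ratio and is never flagged) together with the
    dual co-expression score: the fraction of the cluster's cells whose
    module scores for BOTH the epidermis and trichome marker sets are
    positive. A cluster is transitional when its ratio lies inside the
    window and the co-expression fraction reaches ``coexpr_min``. The
    criterion is symmetric in the two marker sets.
    """
    cluster_labels = np.asarray(cluster_labels)
    sample_labels = np.asarray(sample_labels)
    if sample_class is None:
        classes = np.array([s.split("-")[0] for s in sample_labels])
    else:
        classes = np.array([sample_class[s] for s in sample_labels])
    uniq = np.unique(classes)
    if len(uniq) < 2:
        raise ValueError(
            f"need two sample classes for a ratio; found only {list(uniq)}"
        )
    cl_name = "CL" if "CL" in uniq else sorted(uniq)[0]
    ct_name = "CT" if "CT" in uniq else sorted(uniq)[1]

    ep_score = module_score(normalized, genes, epidermis_markers, seed=seed)
    tr_score = module_score(normalized, genes, trichome_markers, seed=seed + 1)
    both = (ep_score > 0) & (tr_score > 0)

    lo, hi = ratio_window
    rows = []
    for c in np.unique(cluster_labels):
        in_c = cluster_labels == c
        n_cl = int(np.sum(in_c & (classes == cl_name)))
        n_ct = int(np.sum(in_c & (classes == ct_name)))
        ratio = n_cl / n_ct if n_ct else np.inf
        coexpr = float(both[in_c].mean())
        flagged = (lo <= ratio <= hi) and coexpr >= coexpr_min
        rows.append({
            "cluster": c,
            "n_cl": n_cl,
            "n_ct": n_ct,
            "cl_ct_ratio": ratio,
            "coexpression": coexpr,
            "transitional": flagged,
        })
    return pd.DataFrame(rows)


def _mst_adjacency(landmarks: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    dist = cdist(landmarks, landmarks)
    mst = minimum_spanning_tree(sp.csr_matrix(dist))
    sym = mst + mst.T
    coo = sp.triu(sym).tocoo()
    edges = np.column_stack([coo.row, coo.col, coo.data])
    return sym.tocsr(), edges


def compute_pseudotime(
    embedding: np.ndarray,
    cluster_labels: np.ndarray,
    root_cluster,
    n_landmarks: int = 50,
    seed: int = 0,
) -> TrajectoryResult:
    """Rooted pseudotime over a landmark minimum spanning tree.

    Cells are summarized by seeded k-means landmarks; the MST over the
    landmark centroids is rooted at the landmark nearest the root
    cluster's centroid; a cell's pseudotime is the tree geodesic from the
    root to its landmark plus its Euclidean distance to that landmark
    (zero geodesic component for root-landmark cells). A tree with no
    node of degree >= 3 yields two states with a warning.
    """
    X = np.asarray(embedding, dtype=np.float64)
    cluster_labels = np.asarray(cluster_labels)
    if root_cluster not in set(cluster_labels):
        raise ValueError(f"root cluster {root_cluster!r} not present")
    n = X.shape[0]
    n_landmarks = min(n_landmarks, n)

    # canonical internal ordering: k-means initialization samples rows,
    # so fitting on lexicographically sorted cells makes the landmarks
    # (and hence pseudotime) independent of the caller's cell order
    canon = np.lexsort(X.T)
    km = KMeans(
        n_clusters=n_landmarks,
        random_state=substream_int(seed, "landmarks"),
        n_init=10,
    ).fit(X[canon])
    landmarks = km.cluster_centers_
    landmark_of_cell = np.empty(n, dtype=int)
    landmark_of_cell[canon] = km.labels_

    adj, edges = _mst_adjacency(landmarks)
    root_centroid = X[cluster_labels == root_cluster].mean(axis=0)
    root = int(np.argmin(np.linalg.norm(landmarks - root_centroid, axis=1)))

    geodesic, pred = shortest_path(adj, indices=root, directed=False,
                                   return_predecessors=True)
    tip1 = int(np.argmax(geodesic))

    # a cell's pseudotime is its landmark's geodesic plus the SIGNED
    # projection of the cell's offset onto the landmark's incoming tree
    # edge, so ordering within a landmark's cells follows the path
    # direction (root landmark: direction of the first edge toward the
    # farthest tip); clipped at zero
    directions = np.zeros_like(landmarks)
    for l in range(n_landmarks):
        if l == root:
            step = tip1
            while pred[step] != root and pred[step] >= 0:
                step = int(pred[step])
            ref = landmarks[step] - landmarks[root] if step != root else None
        else:
            ref = landmarks[l] - landmarks[int(pred[l])]
        if ref is not None:
            norm = np.linalg.norm(ref)
            if norm > 0:
                directions[l] = ref / norm
    offsets = X - landmarks[landmark_of_cell]
    proj = np.einsum("ij,ij->i", offsets, directions[landmark_of_cell])
    pseudotime = np.clip(geodesic[landmark_of_cell] + proj, 0.0, None)

    # --- branch point: degree >= 3 node best balancing downstream mass ---
    degree = np.zeros(n_landmarks, dtype=int)
    neighbors: list[list[int]] = [[] for _ in range(n_landmarks)]
    for i, j, _w in edges:
        i, j = int(i), int(j)
        degree[i] += 1
        degree[j] += 1
        neighbors[i].append(j)
        neighbors[j].append(i)
    cell_mass = np.bincount(landmark_of_cell, minlength=n_landmarks)

    def _components_without(v: int) -> list[list[int]]:
        seen = {v}
        comps = []
        for start in neighbors[v]:
            if start in seen:
                continue
            comp = []
            stack = [start]
            seen.add(start)
            while stack:
                u = stack.pop()
                comp.append(u)
                for w in neighbors[u]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            comps.append(comp)
        return comps

    # Branch point: where the paths to the tree's two dominant tips
    # diverge. Tip 1 is the landmark farthest (geodesic) from the root;
    # tip 2 is the landmark farthest OFF the root->tip1 path, provided
    # its side subtree extends far enough and carries enough cells to be
    # a real branch rather than a noise twig inside a dense cell cloud.
    # The branch node is where tip 2's subtree attaches to the main
    # path — an internal node of degree >= 3 except in the degenerate
    # root-attachment case.
    full_geo = shortest_path(adj, directed=False)
    path = [tip1]
    while path[-1] != root:
        path.append(int(pred[path[-1]]))
    path = path[::-1]
    on_path = np.zeros(n_landmarks, dtype=bool)
    on_path[path] = True
    # attachment node and off-path distance for every landmark
    off_dist = np.array([full_geo[u][path].min() for u in range(n_landmarks)])
    attach = np.array([path[int(np.argmin(full_geo[u][path]))]
                       for u in range(n_landmarks)])

    min_mass = max(3, n // 50)   # a real branch carries non-trivial mass
    min_depth = 0.1 * float(geodesic[tip1])  # and real geodesic extent

    branch = None
    tip2 = None
    for u in np.argsort(-off_dist):
        u = int(u)
        if on_path[u] or off_dist[u] < min_depth:
            break
        a = int(attach[u])
        comps = _components_without(a)
        side = next(c for c in comps if u in c)
        if tip1 in side or root in side:
            continue
        if int(cell_mass[side].sum()) >= min_mass:
            branch = a
            tip2 = u
            break

    state = np.ones(n, dtype=int)
    if branch is None:
        warnings.warn(
            "no branch point (path-like tree): emitting two states", stacklevel=2
        )
        cut = float(np.median(geodesic[np.isfinite(geodesic)]))
        state[geodesic[landmark_of_cell] > cut] = 2
    else:
        comps = _components_without(branch)
        comp_main = next(c for c in comps if tip1 in c)
        comp_side = next(c for c in comps if tip2 in c)
        two = [list(comp_main), list(comp_side)]
        root_comp = next((c for c in comps if root in c), [])
        extras = [c for c in comps
                  if c is not comp_main and c is not comp_side and root not in c]
        # leftover twigs at the junction join the nearer branch
        for extra in extras:
            cen = landmarks[extra].mean(axis=0)
            d = [np.linalg.norm(landmarks[c].mean(axis=0) - cen) for c in two]
            two[int(np.argmin(d))].extend(extra)
        lm_state = np.ones(n_landmarks, dtype=int)
        lm_state[two[0]] = 2
        lm_state[two[1]] = 3
        lm_state[root_comp] = 1
        state = lm_state[landmark_of_cell]
        # state 3 = branch with greater mean pseudotime
        mean2 = pseudotime[state == 2].mean() if (state == 2).any() else -np.inf
        mean3 = pseudotime[state == 3].mean() if (state == 3).any() else -np.inf
        if mean2 > mean3:
            swap = state.copy()
            swap[state == 2] = 3
            swap[state == 3] = 2
            state = swap

    return TrajectoryResult(
        pseudotime=pseudotime,
        state=state,
        landmark_of_cell=landmark_of_cell,
        landmarks=landmarks,
        mst_edges=edges,
        root_landmark=root,
        branch_landmark=branch,
        root_cluster=root_cluster,
    )


def gene_trend_modules(
    normalized: sp.spmatrix,
    genes: np.ndarray,
    pseudotime: np.ndarray,
    gene_list: list[str] | None = None,
    n_bins: int = 20,
    n_modules: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster smoothed pseudotime trends into expression modules.

    Per gene: mean normalized expression within equal-count pseudotime
    bins, z-scaled; k-means with ``n_modules`` clusters on the trend
    vectors; modules renumbered 1..k by the position of their mean trend
    peak (early to late). Constant genes are dropped with a warning.
    Returns (gene → module assignment, per-gene binned trend matrix).
    """
    X = sp.csr_matrix(normalized)
    genes = np.asarray(genes)
    pseudotime = np.asarray(pseudotime, dtype=float)
    if gene_list is None:
        gene_list = list(genes)
    index = {g: i for i, g in enumerate(genes)}
    cols = [index[g] for g in gene_list if g in index]
    names = [g for g in gene_list if g in index]
    if len(cols) < n_modules:
        raise ValueError(
            f"{len(cols)} genes available but {n_modules} modules requested"
        )

    order = np.argsort(pseudotime, kind="stable")
    bin_of = np.empty(len(pseudotime), dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(len(pseudotime)) * n_bins) // len(pseudotime), n_bins - 1
    )
    dense = np.asarray(X[:, cols].todense())
    trends = np.stack([
        np.array([dense[bin_of == b, j].mean() for b in range(n_bins)])
        for j in range(dense.shape[1])
    ])

    sd = trends.std(axis=1)
    keep = sd > 1e-12
    if not keep.all():
        dropped = [names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping {len(dropped)} constant-trend genes: {dropped[:5]}",
            stacklevel=2,
        )
    trends = trends[keep]
    names = [n for n, k in zip(names, keep) if k]
    if len(names) < n_modules:
        raise ValueError("too few non-constant genes for the requested modules")
    z = (trends - trends.mean(axis=1, keepdims=True)) / trends.std(axis=1, keepdims=True)

    km = KMeans(
        n_clusters=n_modules,
        random_state=substream_int(seed, "trend_modules"),
        n_init=10,
    ).fit(z)
    raw = km.labels_
    # order modules by trend-peak location, early -> late
    peaks = [z[raw == m].mean(axis=0).argmax() if (raw == m).any() else n_bins
             for m in range(n_modules)]
    order_mod = np.argsort(peaks, kind="stable")
    remap = {int(old): rank + 1 for rank, old in enumerate(order_mod)}
    modules = np.array([remap[int(m)] for m in raw])

    assignment = pd.DataFrame({"gene": names, "module": modules})
    trend_df = pd.DataFrame(
        z, index=names, columns=[f"bin{b + 1}" for b in range(n_bins)]
    )
    trend_df.index.name = "gene"
    return assignment, trend_df


def branch_dependence_test(
    normalized: sp.spmatrix,
    genes: np.ndarray,
    states: np.ndarray,
    gene_list: list[str] | None = None,
) -> pd.DataFrame:
    """Rank-sum contrast of the two branches, per gene.

    Requires exactly the states {1, 2, 3}: state 1 is the pre-branch
    segment, states 2 and 3 the branches. Reports the two-sided rank-sum
    p-value between branch cells, the branch-2-vs-branch-3 log2FC, and
    each branch's log2FC against the pre-branch state, sorted by p.
    """
    X = sp.csr_matrix(normalized)
    genes = np.asarray(genes)
    states = np.asarray(states)
    present = set(np.unique(states))
    if not {2, 3}.issubset(present):
        raise ValueError(f"need two branch states (2 and 3); found {sorted(present)}")
    if gene_list is not None:
        index = {g: i for i, g in enumerate(genes)}
        cols = np.array([index[g] for g in gene_list if g in index])
        X = X[:, cols]
        genes = genes[cols]

    in2 = states == 2
    in3 = states == 3
    pre = states == 1
    low_power = in2.sum() < 3 or in3.sum() < 3
    if low_power:
        warnings.warn("a branch has fewer than 3 cells; tests are low-power",
                      stacklevel=2)

    branch_cells = in2 | in3
    Xb = X[branch_cells]
    dense = np.asarray(Xb.todense(), dtype=np.float64)
    ranks = rankdata(dense, axis=0)
    ties = _tie_terms(np.sort(dense, axis=0))
    p, z = _vectorized_ranksum(dense, ranks, ties, in2[branch_cells],
                               return_z=True)

    fc_2_vs_3 = compute_log2fc(X, np.flatnonzero(in2), np.flatnonzero(in3))
    if pre.any():
        fc2 = compute_log2fc(X, np.flatnonzero(in2), np.flatnonzero(pre))
        fc3 = compute_log2fc(X, np.flatnonzero(in3), np.flatnonzero(pre))
    else:
        fc2 = np.full(X.shape[1], np.nan)
        fc3 = np.full(X.shape[1], np.nan)

    out = pd.DataFrame({
        "gene": genes,
        "p_value": p,
        "z": z,
        "log2fc_branch2_vs_branch3": fc_2_vs_3,
        "log2fc_branch2_vs_pre": fc2,
        "log2fc_branch3_vs_pre": fc3,
        "low_power": low_power,
    })
    # |z| breaks the ties left by underflowed p-values
    out["_absz"] = -np.abs(out["z"])
    out = out.sort_values(["p_value", "_absz", "gene"]).drop(columns="_absz")
    return out.reset_index(drop=True)
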