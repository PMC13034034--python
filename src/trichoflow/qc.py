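"""Per-cell quality filtering, normalization, HVG selection and PCA.

Cells are retained when the number of detected genes (count > 0) lies in
``[min_genes, max_genes]`` and the total UMI count is strictly below
``max_umi``. Expression is then normalized per cell to a fixed scale and
natural-log transformed: ``x' = ln(1 + scale * x / total)``. Variable
genes are ranked by a binned dispersion of the normalized values, and the
standardized variable-gene submatrix is embedded with PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from ._rng import substream_int
from .containers import CountMatrix

__all__ = [
    "QCReport",
    "Embedding",
    "filter_cells",
    "normalize_log1p",
    "select_variable_genes",
    "pca_embed",
]


@dataclass
class QCReport:
    n_before: int
    n_after: int
    retention_by_sample: dict[str, float]
    genes_detected_quantiles: dict[str, float]
    umi_quantiles: dict[str, float]

    @property
    def retention(self) -> float:
        return self.n_after / self.n_before if self.n_before else 0.0

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "retention": self.retention,
            "retention_by_sample": self.retention_by_sample,
            "genes_detected_quantiles": self.genes_detected_quantiles,
            "umi_quantiles": self.umi_quantiles,
        }


@dataclass
class Embedding:
    """Cells × k PCA coordinates plus the loadings that produced them."""

    coords: np.ndarray
    variance_ratio: np.ndarray
    loadings: np.ndarray  # k × n_variable_genes
    genes: np.ndarray     # the variable genes, in loading column order

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def _quantile_summary(values: np.ndarray) -> dict[str, float]:
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    labels = ["min", "q25", "median", "q75", "max"]
    if values.size == 0:
        return {k: float("nan") for k in labels}
    return {k: float(v) for k, v in zip(labels, np.quantile(values, qs))}


def filter_cells(
    cm: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 8000,
    max_umi: int = 50_000,
) -> tuple[CountMatrix, QCReport]:
    """Retain cells with min_genes <= detected genes <= max_genes and
    UMI total strictly below max_umi."""
    n_detected = cm.genes_detected_per_cell()
    n_umi = cm.umi_per_cell()
    mask = (n_detected >= min_genes) & (n_detected <= max_genes) & (n_umi < max_umi)
    if not mask.any():
        raise ValueError(
            "no cells pass QC: detected-gene range "
            f"[{n_detected.min()}, {n_detected.max()}] vs bounds "
            f"[{min_genes}, {max_genes}]; UMI range "
            f"[{n_umi.min()}, {n_umi.max()}] vs cap {max_umi}"
        )
    retention_by_sample = {}
    for s in np.unique(cm.sample_labels):
        in_sample = cm.sample_labels == s
        retention_by_sample[str(s)] = float(mask[in_sample].mean())
    report = QCReport(
        n_before=cm.n_cells,
        n_after=int(mask.sum()),
        retention_by_sample=retention_by_sample,
        genes_detected_quantiles=_quantile_summary(n_detected[mask]),
        umi_quantiles=_quantile_summary(n_umi[mask]),
    )
    return cm.subset_cells(mask), report


def normalize_log1p(counts: sp.spmatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Library-size normalize and log-transform: x' = ln(1 + scale*x/total)."""
    counts = sp.csr_matrix(counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError(
            f"{int((totals == 0).sum())} cells have zero total counts; "
            "filter cells before normalizing"
        )
    inv = sp.diags(scale / totals)
    out = inv @ counts
    out.data = np.log1p(out.data)
    return out.tocsr()


def _mean_var(matrix: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = matrix.shape[0]
    mean = np.asarray(matrix.mean(axis=0)).ravel()
    sq = matrix.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_variable_genes(
    normalized: sp.spmatrix,
    genes: np.ndarray,
    n_top: int = 2000,
    n_bins: int = 20,
) -> np.ndarray:
    """Rank genes by within-mean-bin standardized variance; return top IDs.

    Genes are binned by mean normalized expression into equal-frequency
    bins; within each bin the variance is z-scored, so the score measures
    excess dispersion relative to genes of similar abundance. Ties break
    by gene ID (ascending); zero-variance genes are never selected while a
    positive-variance gene remains.
    """
    normalized = sp.csr_matrix(normalized)
    genes = np.asarray(genes)
    n_genes = normalized.shape[1]
    if n_top > n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds {n_genes} genes; returning all", stacklevel=2
        )
        n_top = n_genes
    mean, var = _mean_var(normalized)

    # equal-frequency mean bins (rank-based, stable under monotone shifts)
    order = np.argsort(mean, kind="stable")
    bin_ids = np.empty(n_genes, dtype=int)
    bin_ids[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1
    )

    score = np.zeros(n_genes)
    for b in range(n_bins):
        in_bin = bin_ids == b
        if not in_bin.any():
            continue
        v = var[in_bin]
        sd = v.std()
        score[in_bin] = (v - v.mean()) / sd if sd > 1e-12 else 0.0
    score[var == 0] = -np.inf

    ranked = np.lexsort((genes, -score))
    top = ranked[:n_top]
    # keep at most the number of positive-variance genes
    top = top[np.isfinite(score[top]) | (var[top] > 0)]
    if len(top) < n_top:
        warnings.warn(
            f"only {len(top)} genes with positive variance; returning those",
            stacklevel=2,
        )
    return genes[np.sort(top)]


def pca_embed(
    normalized: sp.spmatrix,
    genes: np.ndarray,
    variable_genes: np.ndarray,
    k: int = 30,
    clip: float = 10.0,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    scale: bool = True,
) -> Embedding:
    """PCA on the standardized variable-gene submatrix.

    Each variable gene is centered and (by default) scaled to unit
    variance, values clipped at ±``clip``; the top-``k`` components are
    returned with a fixed sign convention (largest-magnitude loading
    positive). ``scale=False`` keeps genes on their natural log-expression
    amplitude (centered only) — preferable for trajectory embeddings,
    where unit-variance scaling over-inflates markers of small
    populations.

    ``covariates`` (cells × p, e.g. log library size) are regressed out of
    every gene before clipping — the standard guard against technical axes
    such as sequencing depth dominating the leading components.
    """
    genes = np.asarray(genes)
    idx = {g: i for i, g in enumerate(genes)}
    missing = [g for g in variable_genes if g not in idx]
    if missing:
        raise KeyError(f"variable genes absent from matrix: {missing[:5]}...")
    cols = np.array([idx[g] for g in variable_genes])
    X = np.asarray(sp.csr_matrix(normalized)[:, cols].todense(), dtype=np.float64)

    mu = X.mean(axis=0)
    X = X - mu
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if C.shape[0] != X.shape[0]:
            C = C.T
        if C.shape[0] != X.shape[0]:
            raise ValueError("covariates must have one row per cell")
        C = C - C.mean(axis=0)
        beta, *_ = np.linalg.lstsq(C, X, rcond=None)
        X = X - C @ beta
    X = np.clip(X, -clip, clip)

    max_k = min(X.shape[0], X.shape[1])
    if k > max_k:
        warnings.warn(f"k={k} exceeds rank bound {max_k}; reducing", stacklevel=2)
        k = max_k
    pca = PCA(n_components=k, svd_solver="auto",
              random_state=substream_int(seed, "pca"))
    coords = pca.fit_transform(X)
    loadings = pca.components_

    # sign convention: the largest-|loading| entry of each component is positive
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[j]))
        if loadings[j, i_max] < 0:
            loadings[j] *= -1
            coords[:, j] *= -1

    return Embedding(
        coords=coords,
        variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
        genes=np.asarray(variable_genes),
    )


def embedding_to_frame(emb: Embedding, barcodes: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(
        emb.coords, columns=[f"PC{i + 1}" for i in range(emb.n_components)]
    )
    df.insert(0, "barcode", barcodes)
    return df
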