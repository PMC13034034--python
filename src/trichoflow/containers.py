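"""In-memory containers shared across pipeline stages.

The central object is :class:`CountMatrix`, a cells-by-genes sparse UMI
matrix with barcode, gene and per-cell sample labels. On disk, 10x-style
bundles store genes as rows; the conversion to the internal cells-first
orientation happens at the I/O boundary only (see :mod:`trichoflow.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = ["CountMatrix", "BarcodeProfile"]


def _as_str_array(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind not in "US":
        arr = arr.astype(str)
    return arr


@dataclass
class CountMatrix:
    """Cells × genes UMI count matrix.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells as rows. Any scipy sparse format
        or dense array is accepted; stored as CSR.
    barcodes
        Unique cell identifiers, one per row.
    genes
        Unique gene identifiers, one per column.
    sample_labels
        Per-cell sample/batch identifier (e.g. ``CL-1``, ``CL-2``, ``CT``).
    gene_names
        Optional display names (second column of a 10x features file);
        defaults to ``genes``.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    genes: np.ndarray
    sample_labels: np.ndarray
    gene_names: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.counts.eliminate_zeros()
        self.barcodes = _as_str_array(self.barcodes)
        self.genes = _as_str_array(self.genes)
        self.sample_labels = _as_str_array(self.sample_labels)
        if self.gene_names is None:
            self.gene_names = self.genes.copy()
        else:
            self.gene_names = _as_str_array(self.gene_names)
        n_cells, n_genes = self.counts.shape
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"barcode count {len(self.barcodes)} != matrix rows {n_cells}"
            )
        if len(self.genes) != n_genes or len(self.gene_names) != n_genes:
            raise ValueError(
                f"gene count {len(self.genes)} != matrix columns {n_genes}"
            )
        if len(self.sample_labels) != n_cells:
            raise ValueError("sample_labels must have one entry per cell")
        if len(np.unique(self.barcodes)) != n_cells:
            raise ValueError("duplicate barcodes")
        if len(np.unique(self.genes)) != n_genes:
            raise ValueError("duplicate gene IDs")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if not np.all(np.isfinite(self.counts.data)):
            raise ValueError("non-finite counts")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    # -- per-cell summaries --------------------------------------------
    def umi_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected_per_cell(self) -> np.ndarray:
        return np.diff(self.counts.indptr)

    # -- subsetting -----------------------------------------------------
    def subset_cells(self, index) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            counts=self.counts[index],
            barcodes=self.barcodes[index],
            sample_labels=self.sample_labels[index],
        )

    def subset_genes(self, index) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            counts=self.counts[:, index].tocsr(),
            genes=self.genes[index],
            gene_names=self.gene_names[index],
        )

    def gene_indexer(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class BarcodeProfile:
    """Per-barcode total UMI counts prior to cell calling."""

    barcodes: np.ndarray
    umi_counts: np.ndarray

    def __post_init__(self) -> None:
        self.barcodes = _as_str_array(self.barcodes)
        self.umi_counts = np.asarray(self.umi_counts)
        if self.umi_counts.dtype.kind not in "iu":
            if np.any(self.umi_counts != np.round(self.umi_counts)):
                raise ValueError("UMI counts must be integers")
            self.umi_counts = self.umi_counts.astype(np.int64)
        if len(self.barcodes) != len(self.umi_counts):
            raise ValueError("barcodes and counts differ in length")
        if len(np.unique(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if self.umi_counts.size and self.umi_counts.min() < 0:
            raise ValueError("negative UMI counts")

    @classmethod
    def from_count_matrix(cls, cm: CountMatrix) -> "BarcodeProfile":
        return cls(barcodes=cm.barcodes.copy(), umi_counts=cm.umi_per_cell())

    def __len__(self) -> int:
        return len(self.barcodes)
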