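"""Reading and writing standard single-cell formats and pipeline tables.

Count bundles follow the 10x v3 layout: ``matrix.mtx[.gz]`` (Matrix Market
triplet, genes as rows), ``barcodes.tsv[.gz]`` and ``features.tsv[.gz]``
(three columns: id, name, type). Bundles written here additionally carry a
``samples.tsv[.gz]`` with one sample label per barcode; when reading a
bundle without one, the sample is taken from the suffix after the last
``-`` in each barcode (the 10x multi-sample convention), or a single
constant label when no suffix exists.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_marker_db",
    "write_marker_db",
    "read_homology_table",
    "write_homology_table",
    "read_gene_sets",
    "write_gene_sets",
    "write_table",
    "write_json",
]

FLOAT_FORMAT = "%.6g"  # floats in emitted tables carry 6 significant digits


def _find(path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        candidate = path / name
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"{stem}[.gz] not found in {path}")


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_tsv(path: Path, n_cols: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if n_cols is not None and df.shape[1] < n_cols:
        raise ValueError(f"{path} has {df.shape[1]} columns, expected >= {n_cols}")
    return df


def read_mtx_bundle(path: str | Path) -> CountMatrix:
    """Read a 10x-style bundle into a cells × genes :class:`CountMatrix`.

    The on-disk matrix is genes × cells; it is transposed here so that the
    rest of the pipeline only ever sees the cells-first orientation.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"bundle directory {path} does not exist")
    mtx_path = _find(path, "matrix.mtx")
    barcodes_path = _find(path, "barcodes.tsv")
    try:
        features_path = _find(path, "features.tsv")
    except FileNotFoundError:
        features_path = _find(path, "genes.tsv")  # 10x v2 naming

    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat.T)  # genes × cells on disk -> cells × genes

    barcodes = _read_tsv(barcodes_path)[0].to_numpy()
    feat = _read_tsv(features_path)
    genes = feat[0].to_numpy()
    gene_names = feat[1].to_numpy() if feat.shape[1] > 1 else genes.copy()

    if mat.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[0]} cells but barcodes.tsv lists {len(barcodes)}"
        )
    if mat.shape[1] != len(genes):
        raise ValueError(
            f"matrix has {mat.shape[1]} genes but features.tsv lists {len(genes)}"
        )

    try:
        samples_path = _find(path, "samples.tsv")
        sample_labels = _read_tsv(samples_path)[0].to_numpy()
        if len(sample_labels) != len(barcodes):
            raise ValueError("samples.tsv length does not match barcodes.tsv")
    except FileNotFoundError:
        if all("-" in b for b in barcodes):
            sample_labels = np.array([b.rsplit("-", 1)[1] for b in barcodes])
        else:
            sample_labels = np.full(len(barcodes), "S1")

    if mat.nnz:
        data = mat.data
        if not np.allclose(data, np.round(data)):
            raise ValueError("count matrix contains non-integer values")
    mat = mat.astype(np.int64)
    return CountMatrix(
        counts=mat,
        barcodes=barcodes,
        genes=genes,
        gene_names=gene_names,
        sample_labels=sample_labels,
    )


def write_mtx_bundle(cm: CountMatrix, path: str | Path, compress: bool = False) -> Path:
    """Write a :class:`CountMatrix` as a 10x-style bundle (genes as rows)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    mtx_path = path / f"matrix.mtx{suffix}"
    mat = sp.coo_matrix(cm.counts.T.astype(np.int64))  # back to genes × cells
    with _open_maybe_gz(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, mat, field="integer")

    def _write_lines(name: str, lines: list[str]) -> None:
        with _open_maybe_gz(path / f"{name}{suffix}", "wt") as fh:
            fh.write("\n".join(lines) + "\n")

    _write_lines("barcodes.tsv", list(cm.barcodes))
    _write_lines(
        "features.tsv",
        [f"{g}\t{n}\tGene Expression" for g, n in zip(cm.genes, cm.gene_names)],
    )
    _write_lines("samples.tsv", list(cm.sample_labels))
    return path


# ---------------------------------------------------------------------------
# marker / homology / gene-set tables
# ---------------------------------------------------------------------------

def read_marker_db(path: str | Path) -> dict[str, list[str]]:
    """Read a marker database TSV (columns: cell_type, reference_gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_type", "reference_gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker DB must have columns {sorted(required)}")
    db: dict[str, list[str]] = {}
    for cell_type, group in df.groupby("cell_type", sort=True):
        db[str(cell_type)] = list(group["reference_gene_id"])
    return db


def write_marker_db(db: dict[str, list[str]], path: str | Path) -> Path:
    rows = [
        {"cell_type": t, "reference_gene_id": g}
        for t in sorted(db)
        for g in db[t]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_homology_table(path: str | Path) -> pd.DataFrame:
    """Read a homology TSV (reference_gene_id, target_gene_id, evalue)."""
    df = pd.read_csv(path, sep="\t", dtype={"evalue": float})
    required = {"reference_gene_id", "target_gene_id", "evalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"homology table must have columns {sorted(required)}")
    if (df["evalue"] < 0).any():
        raise ValueError("negative e-values in homology table")
    return df[["reference_gene_id", "target_gene_id", "evalue"]].copy()


def write_homology_table(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.3g")
    return Path(path)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read named gene sets from a two-column TSV (set_name, gene_id).

    Used for cell-cycle phase marker sets, among others.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("gene-set table needs two columns (set_name, gene_id)")
    name_col, gene_col = df.columns[:2]
    out: dict[str, list[str]] = {}
    for name, group in df.groupby(name_col, sort=True):
        out[str(name)] = list(group[gene_col])
    return out


def write_gene_sets(sets: dict[str, list[str]], path: str | Path,
                    name_col: str = "set_name", gene_col: str = "gene_id") -> Path:
    rows = [{name_col: s, gene_col: g} for s in sorted(sets) for g in sets[s]]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# generic outputs
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with a header and 6-sig-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
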