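"""Cross-species cluster annotation by weighted marker scoring.

Reference-species marker genes (e.g. an Arabidopsis cell-type marker
database) are transferred to the target species through a homology table
filtered at an e-value cutoff (default 1e-5, best hit per reference gene).
Each (cluster, cell type) pair is then scored from the cluster's
upregulated genes with three metrics, each mapped to [0, 1]:

* m1 — the fraction of the type's transferred markers detected among the
  cluster's upregulated genes (marker quantity, weight 0.20);
* m2 — the mean log2 fold change of the detected markers on a saturating
  linear ramp (expression-fold magnitude, weight 0.50);
* m3 — the mean expressing fraction of the detected markers within the
  cluster (expressing proportion, weight 0.30).

The weighted score is ``S = 0.20 m1 + 0.50 m2 + 0.30 m3`` and the
highest-scoring type is assigned to each cluster. The mapping of the three
raw metrics onto [0, 1] (detected fraction, saturating ramp with default
saturation 3.0 ~ 8-fold, mean expressing fraction) is this module's main
interpretive choice; the weights themselves operate on those normalized
scales so they remain interpretable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["transfer_markers", "score_clusters", "assign_types"]


def transfer_markers(
    marker_db: dict[str, list[str]],
    homology: pd.DataFrame,
    evalue_max: float = 1e-5,
    policy: str = "best_hit",
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Map reference marker genes to target-species genes.

    Records with e-value above ``evalue_max`` are dropped. Under
    ``best_hit`` each reference gene keeps only its smallest-e-value
    target (ties by lexicographic target ID); ``keep_all`` keeps every
    surviving pair. Returns per-type sorted target marker lists and a
    per-type transfer-rate report.
    """
    if policy not in ("best_hit", "keep_all"):
        raise ValueError(f"unknown policy {policy!r}")
    hom = homology[homology["evalue"] <= evalue_max].copy()
    if policy == "best_hit":
        hom = hom.sort_values(
            ["reference_gene_id", "evalue", "target_gene_id"]
        ).drop_duplicates("reference_gene_id", keep="first")

    targets_by_ref: dict[str, list[str]] = {}
    for ref, group in hom.groupby("reference_gene_id"):
        targets_by_ref[str(ref)] = list(group["target_gene_id"])

    marker_sets: dict[str, list[str]] = {}
    report_rows = []
    for cell_type, refs in marker_db.items():
        targets: set[str] = set()
        n_transferred = 0
        for ref in refs:
            hits = targets_by_ref.get(ref, [])
            if hits:
                n_transferred += 1
                targets.update(hits)
        if not targets:
            warnings.warn(
                f"cell type {cell_type!r} lost all markers in transfer",
                stacklevel=2,
            )
        marker_sets[cell_type] = sorted(targets)
        report_rows.append({
            "cell_type": cell_type,
            "n_reference": len(refs),
            "n_transferred": n_transferred,
            "transfer_rate": n_transferred / len(refs) if refs else 0.0,
        })
    return marker_sets, pd.DataFrame(report_rows)


def score_clusters(
    de_table: pd.DataFrame,
    marker_sets: dict[str, list[str]],
    dataset_genes: np.ndarray,
    weights: tuple[float, float, float] = (0.20, 0.50, 0.30),
    fold_saturation: float = 3.0,
) -> pd.DataFrame:
    """Score every (cluster, cell type) pair from the DE table.

    Only genes flagged ``passed`` in the DE table count as upregulated.
    m1 is normalized by the number of the type's markers present in the
    dataset, so absent genes do not penalize a type.
    """
    w1, w2, w3 = weights
    if abs(w1 + w2 + w3 - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    if fold_saturation <= 0:
        raise ValueError("fold_saturation must be positive")
    dataset_genes = set(np.asarray(dataset_genes))

    passing = de_table[de_table["passed"]]
    up_by_cluster = {
        c: g.set_index("gene")[["log2fc", "pct_in"]]
        for c, g in passing.groupby("cluster")
    }
    clusters = sorted(de_table["cluster"].unique())

    rows = []
    for c in clusters:
        up = up_by_cluster.get(c)
        up_genes = set(up.index) if up is not None else set()
        for cell_type in sorted(marker_sets):
            present = [g for g in marker_sets[cell_type] if g in dataset_genes]
            detected = sorted(set(present) & up_genes)
            if detected and present:
                m1 = len(detected) / len(present)
                mean_fc = float(up.loc[detected, "log2fc"].mean())
                m2 = min(1.0, max(0.0, mean_fc / fold_saturation))
                m3 = float(up.loc[detected, "pct_in"].mean())
            else:
                m1 = m2 = m3 = 0.0
            rows.append({
                "cluster": c,
                "cell_type": cell_type,
                "m1_quantity": m1,
                "m2_fold": m2,
                "m3_pct": m3,
                "score": w1 * m1 + w2 * m2 + w3 * m3,
                "n_detected": len(detected),
                "n_markers_present": len(present),
                "detected_markers": ",".join(detected),
            })
    return pd.DataFrame(rows)


def assign_types(
    score_table: pd.DataFrame,
    min_score: float = 0.05,
    tie_tol: float = 1e-12,
) -> pd.DataFrame:
    """Assign each cluster the highest-scoring cell type.

    Exact ties produce the label ``ambiguous`` with all tied types listed;
    a best score below ``min_score`` yields ``unassigned``.
    """
    rows = []
    for c, group in score_table.groupby("cluster"):
        group = group.sort_values(["score", "cell_type"], ascending=[False, True])
        best = group.iloc[0]
        tied = group[group["score"] >= best["score"] - tie_tol]
        if best["score"] < min_score:
            label, tie = "unassigned", False
        elif len(tied) > 1:
            label, tie = "ambiguous", True
        else:
            label, tie = best["cell_type"], False
        rows.append({
            "cluster": c,
            "assigned_type": label,
            "score": float(best["score"]),
            "tie": tie,
            "tied_types": ",".join(sorted(tied["cell_type"])) if tie else "",
        })
    return pd.DataFrame(rows)
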