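"""End-to-end pipeline: call-cells → QC → normalize → integrate → cluster
→ markers → annotate → cell cycle → trajectory.

``run_pipeline`` executes the nine stages on a count matrix, returns every
intermediate result in a :class:`PipelineResult`, and (when ``outdir`` is
given) writes each table as TSV plus a JSON run manifest recording the
seed, package versions and completed stages. Two runs with the same seed
and config produce byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .annotate import assign_types, score_clusters, transfer_markers
from .cellcalling import CellCallResult, call_cells_knee
from .cellcycle import assign_phase, phase_composition, score_phases
from .config import PipelineConfig
from .containers import BarcodeProfile, CountMatrix
from .integrate import (SoftAssignment, batch_mixing_entropy, cluster_cells,
                        layout_2d, soft_kmeans_correct)
from .io import write_json, write_table
from .markers import find_upregulated
from .qc import (Embedding, QCReport, filter_cells, normalize_log1p,
                 pca_embed, select_variable_genes)
from .trajectory import (TrajectoryResult, branch_dependence_test,
                         compute_pseudotime, detect_transitional_clusters,
                         gene_trend_modules, smooth_embedding)

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "STAGES"]

STAGES = (
    "call_cells", "qc", "normalize", "integrate", "cluster",
    "markers", "annotate", "cellcycle", "trajectory",
)

TRAJECTORY_TYPES = ("epidermis", "transitional", "trichome", "guard")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    config: PipelineConfig
    cell_calls: dict[str, CellCallResult] = field(default_factory=dict)
    counts: CountMatrix | None = None          # after QC
    qc_report: QCReport | None = None
    normalized = None                          # sparse, cells × genes
    variable_genes: np.ndarray | None = None
    embedding: Embedding | None = None
    corrected: np.ndarray | None = None
    soft_assignment: SoftAssignment | None = None
    cluster_labels: np.ndarray | None = None
    layout: np.ndarray | None = None
    de_table: pd.DataFrame | None = None
    marker_sets: dict[str, list[str]] | None = None
    transfer_report: pd.DataFrame | None = None
    score_table: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None
    phase_scores: pd.DataFrame | None = None
    phase_by_sample: pd.DataFrame | None = None
    phase_by_cluster: pd.DataFrame | None = None
    transitional: pd.DataFrame | None = None
    trajectory: TrajectoryResult | None = None
    trajectory_cells: np.ndarray | None = None  # indices into `counts`
    trend_modules: pd.DataFrame | None = None
    trend_matrix: pd.DataFrame | None = None
    branch_test: pd.DataFrame | None = None
    manifest: dict[str, Any] = field(default_factory=dict)

    def annotation_of(self, cluster) -> str:
        row = self.annotation[self.annotation["cluster"] == cluster]
        return str(row["assigned_type"].iloc[0]) if len(row) else "unassigned"


def _versions() -> dict[str, str]:
    import scipy
    import sklearn
    return {
        "trichoflow": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_pipeline(
    counts: CountMatrix,
    marker_db: dict[str, list[str]],
    homology: pd.DataFrame,
    phase_gene_sets: dict[str, list[str]],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    skip_cell_calling: bool = False,
    doublet_exclude: list[str] | None = None,
) -> PipelineResult:
    """Run all nine stages on a raw count matrix.

    Parameters
    ----------
    counts
        Unfiltered cells × genes matrix (ambient barcodes included unless
        ``skip_cell_calling``).
    marker_db, homology
        Reference marker database and homology table for annotation.
    phase_gene_sets
        Cell-cycle phase marker sets (phase → gene IDs).
    doublet_exclude
        Optional externally computed barcode exclusion list (e.g. from a
        doublet-detection tool), removed before QC.
    """
    cfg = (config or PipelineConfig()).validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(config=cfg)
    completed: list[str] = []
    seed = cfg.seed

    def _write(df: pd.DataFrame, name: str) -> None:
        if out is not None:
            write_table(df, out / name)

    # ---- stage 1: cell calling ---------------------------------------
    stage = "call_cells"
    try:
        if skip_cell_calling:
            called = counts
        else:
            keep = np.zeros(counts.n_cells, dtype=bool)
            for sample in np.unique(counts.sample_labels):
                in_s = counts.sample_labels == sample
                profile = BarcodeProfile(
                    barcodes=counts.barcodes[in_s],
                    umi_counts=counts.umi_per_cell()[in_s],
                )
                result = call_cells_knee(
                    profile, cfg.expected_cells,
                    knee_percentile=cfg.knee_percentile,
                    knee_fraction=cfg.knee_fraction,
                )
                res.cell_calls[str(sample)] = result
                keep |= in_s & np.isin(counts.barcodes, result.retained)
            called = counts.subset_cells(keep)
        if doublet_exclude:
            called = called.subset_cells(~np.isin(called.barcodes, doublet_exclude))
        if out is not None:
            write_json({
                s: {"m": r.m, "threshold": r.threshold,
                    "expected_cells": r.expected_cells,
                    "n_retained": r.n_retained}
                for s, r in res.cell_calls.items()
            }, out / "cell_calling.json")
            _write(pd.DataFrame({"barcode": called.barcodes}),
                   "retained_barcodes.tsv")
        completed.append(stage)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage 2: QC ---------------------------------------------------
    stage = "qc"
    try:
        filtered, report = filter_cells(
            called, min_genes=cfg.min_genes, max_genes=cfg.max_genes,
            max_umi=cfg.max_umi,
        )
        res.counts, res.qc_report = filtered, report
        if out is not None:
            write_json(report.to_dict(), out / "qc_report.json")
        completed.append(stage)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage 3: normalize + HVG + PCA --------------------------------
    stage = "normalize"
    try:
        normalized = normalize_log1p(filtered.counts, scale=cfg.normalize_scale)
        res.normalized = normalized
        res.variable_genes = select_variable_genes(
            normalized, filtered.genes, n_top=cfg.n_top_genes
        )
        depth = np.log(filtered.umi_per_cell()) if cfg.regress_depth else None
        res.embedding = pca_embed(
            normalized, filtered.genes, res.variable_genes,
            k=cfg.n_pcs, seed=seed, covariates=depth,
        )
        if out is not None:
            emb = pd.DataFrame(res.embedding.coords,
                               columns=[f"PC{i+1}" for i in range(res.embedding.n_components)])
            emb.insert(0, "barcode", filtered.barcodes)
            _write(emb, "embedding.tsv")
        completed.append(stage)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage 4: batch correction -------------------------------------
    stage = "integrate"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-batch warning is fine here
            corrected, assign = soft_kmeans_correct(
                res.embedding.coords, filtered.sample_labels,
                k=cfg.soft_k, sigma=cfg.sigma,
                diversity_strength=cfg.diversity_strength,
                max_iter=cfg.max_iter, tol=cfg.tol, seed=seed,
            )
        res.corrected, res.soft_assignment = corrected, assign
        if out is not None:
            emb = pd.DataFrame(corrected,
                               columns=[f"PC{i+1}" for i in range(corrected.shape[1])])
            emb.insert(0, "barcode", filtered.barcodes)
            _write(emb, "corrected_embedding.tsv")
            _write(pd.DataFrame({"iteration": range(1, len(assign.trace) + 1),
                                 "max_centroid_move": assign.trace}),
                   "convergence_trace.tsv")
        completed.append(stage)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage 5: clustering + 2-D layout -------------------------------
    stage = "cluster"
    try:
        labels = cluster_cells(
            corrected, n_neighbors=cfg.n_neighbors,
            resolution=cfg.resolution, seed=seed,
        ).labels
        res.cluster_labels = labels
        res.layout = layout_2d(corrected, seed=seed)
        if out is not None:
            _write(pd.DataFrame({
                "barcode": filtered.barcodes, "cluster": labels,
                "sample": filtered.sample_labels,
            }), "clusters.tsv")
            lay = pd.DataFrame(res.layout, columns=["dim1", "dim2"])
            lay.insert(0, "barcode", filtered.barcodes)
            _write(lay, "layout_2d.tsv")
        completed.append(stage)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage 6: marker detection --------------------------------------
    stage = "markers"
    try:
        de = find_upregulated(
            normalized, labels, log2fc_min=cfg.log2fc_min,
            p_max=cfg.p_max, min_pct=cfg.min_pct, genes=filtered.genes,
        )
        res.de_table = de
        _write(de[de["passed"]], "markers_passing.tsv")
        _write(de, "de_table.tsv")
        completed.append(stage)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage 7: annotation --------------------------------------------
    stage = "annotate"
    try:
        marker_sets, transfer_report = transfer_markers(
            marker_db, homology, evalue_max=cfg.evalue_max
        )
        score_table = score_clusters(
            de, marker_sets, filtered.genes,
            weights=cfg.weights, fold_saturation=cfg.fold_saturation,
        )
        annotation = assign_types(score_table, min_score=cfg.min_score)
        res.marker_sets = marker_sets
        res.transfer_report = transfer_report
        res.score_table = score_table
        res.annotation = annotation
        _write(transfer_report, "marker_transfer.tsv")
        _write(score_table, "annotation_scores.tsv")
        _write(annotation, "cluster_annotation.tsv")
        completed.append(stage)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage 8: cell cycle ---------------------------------------------
    stage = "cellcycle"
    try:
        scores = score_phases(
            normalized, filtered.genes, phase_gene_sets,
            n_bins=cfg.score_bins, n_control=cfg.score_controls, seed=seed,
        )
        scored = assign_phase(scores, noncycling_threshold=cfg.noncycling_threshold)
        scored.insert(0, "barcode", filtered.barcodes)
        res.phase_scores = scored
        res.phase_by_sample = phase_composition(
            scored["phase"].to_numpy(), filtered.sample_labels
        )
        res.phase_by_cluster = phase_composition(scored["phase"].to_numpy(), labels)
        _write(scored, "phase_scores.tsv")
        _write(res.phase_by_sample.reset_index(), "phase_composition_by_sample.tsv")
        _write(res.phase_by_cluster.reset_index(), "phase_composition_by_cluster.tsv")
        completed.append(stage)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- stage 9: trajectory ----------------------------------------------
    stage = "trajectory"
    try:
        ep_markers = marker_sets.get("epidermis", [])
        tr_markers = marker_sets.get("trichome", [])
        if not ep_markers or not tr_markers:
            raise ValueError("epidermis and trichome marker sets are required")
        transitional = detect_transitional_clusters(
            labels, filtered.sample_labels, ep_markers, tr_markers,
            normalized, filtered.genes,
            ratio_window=cfg.transitional_ratio_window,
            coexpr_min=cfg.coexpr_min, seed=seed,
        )
        res.transitional = transitional
        _write(transitional, "transitional_clusters.tsv")

        traj_clusters = set(
            res.annotation.loc[
                res.annotation["assigned_type"].isin(TRAJECTORY_TYPES), "cluster"
            ]
        ) | set(transitional.loc[transitional["transitional"], "cluster"])
        in_traj = np.isin(labels, sorted(traj_clusters))
        if in_traj.sum() < cfg.n_landmarks:
            warnings.warn(
                "too few trajectory cells; using all cells", stacklevel=2
            )
            in_traj = np.ones(len(labels), dtype=bool)
        traj_idx = np.flatnonzero(in_traj)
        res.trajectory_cells = traj_idx

        # root: the epidermis cluster. Annotation is the reliable signal;
        # the transitional flag only breaks ties among several
        # epidermis-annotated clusters (preferring the unflagged, i.e.
        # "reselected" epidermal cluster).
        ep_scores = res.score_table[res.score_table["cell_type"] == "epidermis"]
        flagged = set(transitional.loc[transitional["transitional"], "cluster"])
        ep_annotated = set(
            res.annotation.loc[
                res.annotation["assigned_type"] == "epidermis", "cluster"
            ]
        ) & traj_clusters
        pool = ep_scores[ep_scores["cluster"].isin(ep_annotated)]
        if len(pool) > 1 and len(pool[~pool["cluster"].isin(flagged)]):
            pool = pool[~pool["cluster"].isin(flagged)]
        if len(pool) == 0:
            pool = ep_scores[ep_scores["cluster"].isin(traj_clusters)]
        if len(pool) == 0:
            pool = ep_scores
        root_cluster = pool.sort_values(
            ["score", "cluster"], ascending=[False, True]
        )["cluster"].iloc[0]

        # re-embed the trajectory subset on its ordering genes (the genes
        # upregulated in any trajectory cluster), centered but unscaled so
        # small-population markers keep their natural amplitude, then
        # batch-correct and denoise before landmark fitting
        sub_norm = res.normalized[traj_idx]
        traj_de = de[(de["passed"]) & (de["cluster"].isin(traj_clusters))]
        ordering_genes = np.array(sorted(traj_de["gene"].unique()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(ordering_genes) < 2 * cfg.traj_n_pcs:
                ordering_genes = select_variable_genes(
                    sub_norm, filtered.genes, n_top=cfg.n_top_genes
                )
            sub_emb = pca_embed(
                sub_norm, filtered.genes, ordering_genes,
                k=min(cfg.traj_n_pcs, len(ordering_genes) - 1), seed=seed,
                covariates=depth[traj_idx] if depth is not None else None,
                scale=False,
            )
            sub_corr, _ = soft_kmeans_correct(
                sub_emb.coords, filtered.sample_labels[traj_idx],
                k=cfg.soft_k, sigma=cfg.sigma,
                diversity_strength=cfg.diversity_strength,
                max_iter=cfg.max_iter, tol=cfg.tol, seed=seed,
            )
            sub_smooth = smooth_embedding(
                sub_corr, n_neighbors=cfg.traj_smooth_neighbors,
                rounds=cfg.traj_smooth_rounds,
            )
            traj = compute_pseudotime(
                sub_smooth, labels[traj_idx], root_cluster,
                n_landmarks=cfg.n_landmarks, seed=seed,
            )
        res.trajectory = traj
        if out is not None:
            _write(pd.DataFrame({
                "barcode": filtered.barcodes[traj_idx],
                "pseudotime": traj.pseudotime,
                "state": traj.state,
                "cluster": labels[traj_idx],
            }), "pseudotime.tsv")
            _write(pd.DataFrame(traj.mst_edges,
                                columns=["node_i", "node_j", "weight"]),
                   "mst_edges.tsv")

        # trend modules over genes upregulated in any trajectory cluster
        trend_genes = sorted(traj_de["gene"].unique())
        if len(trend_genes) >= cfg.n_trend_modules:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assignment, trend_matrix = gene_trend_modules(
                    sub_norm, filtered.genes, traj.pseudotime,
                    gene_list=trend_genes, n_bins=cfg.n_trend_bins,
                    n_modules=cfg.n_trend_modules, seed=seed,
                )
            res.trend_modules = assignment
            res.trend_matrix = trend_matrix
            _write(assignment, "trend_modules.tsv")
            _write(trend_matrix.reset_index(), "trend_matrix.tsv")

        if traj.n_states == 3 and len(trend_genes):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res.branch_test = branch_dependence_test(
                    sub_norm, filtered.genes, traj.state, gene_list=trend_genes
                )
            _write(res.branch_test, "branch_test.tsv")
        completed.append(stage)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    res.manifest = {
        "stages_completed": completed,
        "seed": seed,
        "config": cfg.to_dict(),
        "versions": _versions(),
        "n_cells_input": counts.n_cells,
        "n_cells_called": called.n_cells,
        "n_cells_qc": filtered.n_cells,
        "n_clusters": int(labels.max()) + 1,
        "n_states": res.trajectory.n_states if res.trajectory else None,
    }
    if out is not None:
        write_json(res.manifest, out / "manifest.json")
    return res
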