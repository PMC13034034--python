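"""Cell-cycle phase scoring and assignment.

Each phase (G1, S, G2, M) has a marker gene set; a cell's phase score is
the mean normalized expression of the set minus the mean of an
expression-matched control set (genes sampled from the same
average-expression bin as each target gene). A cell is assigned the
highest-scoring phase, or classified as noncycling when every phase score
falls below the threshold (default 0.3; the stricter variant using 0 can
be selected through the config).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import substream

__all__ = ["module_score", "score_phases", "assign_phase", "phase_composition"]

PHASE_ORDER = ("G1", "S", "G2", "M")


def module_score(
    normalized: sp.spmatrix,
    genes: np.ndarray,
    gene_set: list[str],
    n_bins: int = 25,
    n_control: int = 50,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binned-control module score for one gene set.

    Genes are ordered by mean expression over all cells and cut into
    ``n_bins`` equal-size bins; for every target gene, ``n_control``
    control genes are sampled without replacement from its bin (the whole
    bin when smaller). The score is the mean over the target set minus the
    mean over the pooled (unique) control set, per cell.
    """
    X = sp.csr_matrix(normalized)
    genes = np.asarray(genes)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    index = {g: i for i, g in enumerate(genes)}
    target = [index[g] for g in gene_set if g in index]
    if not target:
        raise ValueError(f"gene set entirely absent from the matrix: {list(gene_set)[:5]}")
    if rng is None:
        rng = substream(seed, "module_score")

    avg = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(avg, kind="stable")
    n_genes = len(genes)
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)

    members: dict[int, np.ndarray] = {
        b: order[bin_of[order] == b] for b in range(n_bins)
    }
    target_set = set(target)
    controls: set[int] = set()
    for gi in target:
        pool = members[bin_of[gi]]
        pool = pool[pool != gi]
        if len(pool) <= n_control:
            chosen = pool
        else:
            chosen = rng.choice(pool, size=n_control, replace=False)
        controls.update(int(c) for c in chosen)
    controls -= target_set
    if not controls:
        raise ValueError("no control genes available outside the target set")

    target_mean = np.asarray(X[:, sorted(target_set)].mean(axis=1)).ravel()
    control_mean = np.asarray(X[:, sorted(controls)].mean(axis=1)).ravel()
    return target_mean - control_mean


def score_phases(
    normalized: sp.spmatrix,
    genes: np.ndarray,
    phase_gene_sets: dict[str, list[str]],
    n_bins: int = 25,
    n_control: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Module score per cell for every phase marker set."""
    rng = substream(seed, "cellcycle")
    scores = {}
    for phase in sorted(phase_gene_sets):
        scores[phase] = module_score(
            normalized, genes, phase_gene_sets[phase],
            n_bins=n_bins, n_control=n_control, rng=rng,
        )
    return pd.DataFrame(scores)


def assign_phase(
    phase_scores: pd.DataFrame,
    noncycling_threshold: float = 0.3,
) -> pd.DataFrame:
    """Assign each cell its highest-scoring phase, or ``noncycling``.

    A cell is noncycling exactly when all phase scores fall below the
    threshold. Argmax ties break by the fixed phase order G1 < S < G2 < M
    and are flagged.
    """
    phases = [p for p in PHASE_ORDER if p in phase_scores.columns]
    missing = set(phase_scores.columns) - set(phases)
    if missing:
        phases += sorted(missing)
    if not phases:
        raise ValueError("no phase score columns")
    S = phase_scores[phases].to_numpy()
    best_idx = np.argmax(S, axis=1)  # first (fixed-order) max wins
    best = S[np.arange(len(S)), best_idx]
    labels = np.array([phases[i] for i in best_idx], dtype=object)
    labels[best < noncycling_threshold] = "noncycling"
    n_at_max = (S >= best[:, None] - 1e-12).sum(axis=1)
    tie = (n_at_max > 1) & (best >= noncycling_threshold)
    out = phase_scores.copy()
    out["phase"] = labels.astype(str)
    out["tie"] = tie
    return out


def phase_composition(labels: np.ndarray, grouping: np.ndarray) -> pd.DataFrame:
    """Per-group phase fractions (rows sum to 1, noncycling included)."""
    labels = np.asarray(labels)
    grouping = np.asarray(grouping)
    if len(labels) != len(grouping):
        raise ValueError("labels and grouping differ in length")
    if len(labels) == 0:
        raise ValueError("empty input")
    table = pd.crosstab(grouping, labels, normalize="index")
    table.index.name = "group"
    table.columns.name = "phase"
    return table
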