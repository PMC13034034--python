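"""Ground-truthed synthetic snRNA-seq data.

The generator emulates the study design this pipeline targets: three
samples — two leaf-protoplast samples (``CL-1``, ``CL-2``) and one
trichome-enriched nucleus sample (``CT``) — containing epidermis,
trichome, transitional, guard, mesophyll and vascular lineages. The
epidermis → transitional → trichome axis is a latent trajectory in
``t ∈ [0, 1]`` with a guard-cell branch departing at ``branch_point``;
trichome cells are enriched for the G2 phase (share 0.375 by default).

Count model
-----------
Per-gene baseline means are log-normal; a type's marker genes are
multiplied by the fold effect ``theta`` inside that type; trajectory
programs follow per-gene logistic sigmoids in ``t`` (epidermal module
falling, trichome module rising, the guard branch diverging after the
branch point); each sample applies a per-gene multiplicative log-normal
batch shift of scale ``batch_lfc_scale``; cell-cycle phase genes are
multiplied by ``phase_fold`` in cells of the matching phase. Counts are
negative binomial around ``mean x library-size factor`` with the given
size (Poisson in the infinite-size limit). Ambient (empty-droplet)
barcodes draw from the pooled baseline profile at a much smaller total
and carry no type labels.

Everything returned is paired with a :class:`SyntheticTruth` holding the
per-cell and per-gene ground truth, so downstream stages can be tested as
recovery problems without any external data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .containers import BarcodeProfile, CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_barcode_profile",
    "CELL_TYPES",
    "PHASES",
]

CELL_TYPES = ("epidermis", "trichome", "transitional", "guard", "mesophyll", "vascular")
TRAJECTORY_TYPES = ("epidermis", "transitional", "trichome", "guard")
PHASES = ("G1", "S", "G2", "M")

_TYPE_CODE = {
    "epidermis": "EPI",
    "trichome": "TRI",
    "transitional": "TRA",
    "guard": "GUA",
    "mesophyll": "MES",
    "vascular": "VAS",
}

# CT is the trichome-enriched preparation; CL samples carry mostly
# mesophyll/vascular/epidermal cells. Guard cells are depleted in CT.
_DEFAULT_PROPORTIONS = {
    "CL": {
        "epidermis": 0.22, "trichome": 0.05, "transitional": 0.08,
        "guard": 0.08, "mesophyll": 0.40, "vascular": 0.17,
    },
    "CT": {
        "epidermis": 0.15, "trichome": 0.35, "transitional": 0.20,
        "guard": 0.04, "mesophyll": 0.18, "vascular": 0.08,
    },
}

_BASE_PHASE_PROPS = {"G1": 0.325, "S": 0.20, "G2": 0.25, "M": 0.125, "NC": 0.10}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment."""

    n_cells_per_sample: int = 1000
    samples: tuple[str, ...] = ("CL-1", "CL-2", "CT")
    type_proportions: dict[str, dict[str, float]] | None = None
    n_genes: int = 2000
    n_markers_per_type: int = 20
    theta: float = 4.0              # marker fold effect
    batch_lfc_scale: float = 0.3    # sigma of per-gene log batch shift
    lib_sigma: float = 0.35         # log-normal library-size factor sd
    mean_umi: float = 2500.0        # expected per-cell total at unit library
    dispersion: float = 10.0        # NB size; math.inf -> Poisson
    branch_point: float = 0.4       # guard branch departs at this t
    branch_ramp: float = 0.15       # t-width over which the branch programs
                                    # switch (keeps the Y continuous at b)
    sigmoid_midpoint: tuple[float, float] = (0.35, 0.65)
    sigmoid_slope: tuple[float, float] = (6.0, 12.0)
    transient_ramp: float = 0.05    # t-width of the transitional program's
                                    # on/off ramps (trapezoid profile)
    phase_fold: float = 2.5
    n_phase_genes: int = 15
    trichome_g2: float = 0.375      # G2 share of trichome cells
    phase_proportions: dict[str, dict[str, float]] | None = None
    n_ambient_per_sample: int = 300
    ambient_mean_umi: float = 40.0
    n_decoy_homologs: int = 10      # homology rows above the e-value cutoff
    n_secondary_homologs: int = 10  # worse-but-valid hits (best-hit fodder)
    evalue_max: float = 1e-5
    store_means: bool = True        # keep the dense truth mean matrix
    seed: int = 0

    def resolved_type_proportions(self) -> dict[str, dict[str, float]]:
        if self.type_proportions is not None:
            props = self.type_proportions
        else:
            props = {
                s: _DEFAULT_PROPORTIONS["CT" if s.startswith("CT") else "CL"]
                for s in self.samples
            }
        for s, p in props.items():
            if abs(sum(p.values()) - 1.0) > 1e-9:
                raise ValueError(f"type proportions for sample {s} do not sum to 1")
        return props

    def resolved_phase_proportions(self) -> dict[str, dict[str, float]]:
        if self.phase_proportions is not None:
            props = self.phase_proportions
        else:
            tri = {
                "G1": 0.225, "S": 0.15, "G2": self.trichome_g2,
                "M": 0.15, "NC": 1.0 - 0.225 - 0.15 - self.trichome_g2 - 0.15,
            }
            props = {
                t: (tri if t == "trichome" else dict(_BASE_PHASE_PROPS))
                for t in CELL_TYPES
            }
        for t, p in props.items():
            if abs(sum(p.values()) - 1.0) > 1e-9:
                raise ValueError(f"phase proportions for type {t} do not sum to 1")
        return props

    def validate(self) -> "SimConfig":
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if not 0 < self.branch_point < 1:
            raise ValueError("branch_point must lie strictly inside (0, 1)")
        needed = len(CELL_TYPES) * self.n_markers_per_type + len(PHASES) * self.n_phase_genes
        if needed > self.n_genes:
            raise ValueError(
                f"{needed} marker/phase genes requested but only {self.n_genes} genes"
            )
        self.resolved_type_proportions()
        self.resolved_phase_proportions()
        return self


@dataclass
class SyntheticTruth:
    """Ground truth paired with a simulated experiment.

    Per-cell arrays align with the rows of the returned count matrix
    (ambient barcodes included, flagged by ``is_cell``). ``latent_time``
    is NaN for cells off the trajectory; ``branch`` is ``main`` on the
    epidermis→trichome path, ``guard`` on the stomatal branch, and empty
    otherwise.
    """

    type_label: np.ndarray
    sample_label: np.ndarray
    phase_label: np.ndarray
    latent_time: np.ndarray
    branch: np.ndarray
    is_cell: np.ndarray
    markers_by_type: dict[str, list[str]]
    phase_genes: dict[str, list[str]]
    trend_class: dict[str, str]
    reference_markers: dict[str, list[str]]
    branch_point: float
    mean_matrix: np.ndarray | None = field(default=None, repr=False)

    def cells_frame(self, barcodes: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "barcode": barcodes,
            "type": self.type_label,
            "sample": self.sample_label,
            "phase": self.phase_label,
            "latent_time": self.latent_time,
            "branch": self.branch,
            "is_cell": self.is_cell,
        })


@dataclass
class SimulatedExperiment:
    counts: CountMatrix
    truth: SyntheticTruth
    marker_db: dict[str, list[str]]
    homology: pd.DataFrame


def _random_barcodes(rng: np.random.Generator, n: int, sample: str) -> list[str]:
    letters = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(rng.choice(letters, size=14))
        if seq not in seen:
            seen.add(seq)
            out.append(f"{seq}-{sample}")
    return out


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    if math.isinf(size):
        return rng.poisson(mean)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(config: SimConfig | None = None) -> SimulatedExperiment:
    """Simulate a three-sample experiment with full ground truth.

    Returns the count matrix (ambient barcodes included), the truth
    object, a marker database keyed by cell type holding reference-species
    gene IDs, and a homology table mapping those reference IDs to target
    gene IDs with BLAST-style e-values (including decoy pairs above the
    cutoff and secondary weaker hits).
    """
    cfg = (config or SimConfig()).validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x51]))

    n_genes = cfg.n_genes
    genes = np.array([f"CsTF{i + 1:05d}" for i in range(n_genes)])

    # ---- gene roles ---------------------------------------------------
    markers_by_type: dict[str, list[str]] = {}
    cursor = 0
    for t in CELL_TYPES:
        markers_by_type[t] = list(genes[cursor:cursor + cfg.n_markers_per_type])
        cursor += cfg.n_markers_per_type
    phase_genes: dict[str, list[str]] = {}
    for p in PHASES:
        phase_genes[p] = list(genes[cursor:cursor + cfg.n_phase_genes])
        cursor += cfg.n_phase_genes

    marker_idx = {t: np.arange(i * cfg.n_markers_per_type,
                               (i + 1) * cfg.n_markers_per_type)
                  for i, t in enumerate(CELL_TYPES)}
    phase_idx = {p: np.arange(len(CELL_TYPES) * cfg.n_markers_per_type + i * cfg.n_phase_genes,
                              len(CELL_TYPES) * cfg.n_markers_per_type + (i + 1) * cfg.n_phase_genes)
                 for i, p in enumerate(PHASES)}
    special = cursor  # genes below this index carry structure

    trend_class: dict[str, str] = {}
    for g in markers_by_type["epidermis"]:
        trend_class[g] = "early"
    for g in markers_by_type["trichome"]:
        trend_class[g] = "late"
    for g in markers_by_type["transitional"]:
        trend_class[g] = "transient"
    for g in markers_by_type["guard"]:
        trend_class[g] = "branch"

    # ---- baselines ----------------------------------------------------
    base = np.empty(n_genes)
    base[special:] = rng.lognormal(0.0, 1.25, n_genes - special)
    # marker/phase genes get moderate baselines so fold effects are
    # detectable at realistic sequencing depth
    base[:special] = rng.lognormal(0.5, 0.5, special)
    base *= cfg.mean_umi / base.sum()

    # per-gene sigmoid parameters for the trajectory programs
    mid = rng.uniform(*cfg.sigmoid_midpoint, n_genes)
    slope = rng.uniform(*cfg.sigmoid_slope, n_genes)

    # per-sample per-gene batch shift
    batch_factor = {
        s: np.exp(rng.normal(0.0, cfg.batch_lfc_scale, n_genes))
        for s in cfg.samples
    }

    type_props = cfg.resolved_type_proportions()
    phase_props = cfg.resolved_phase_proportions()

    # ---- cells --------------------------------------------------------
    rows_counts: list[sp.csr_matrix] = []
    barcodes: list[str] = []
    type_lab: list[str] = []
    sample_lab: list[str] = []
    phase_lab: list[str] = []
    latent: list[float] = []
    branch_lab: list[str] = []
    is_cell: list[bool] = []
    mean_rows: list[np.ndarray] = []

    # disjoint spans keep the type labels well defined at the
    # boundaries; the expression programs themselves remain continuous
    # across the small gaps
    t_range = {
        "epidermis": (0.0, 0.30),
        "transitional": (0.34, 0.66),
        "trichome": (0.70, 1.0),
        "guard": (cfg.branch_point, 1.0),
    }
    amp = cfg.theta - 1.0

    for sample in cfg.samples:
        props = type_props[sample]
        n_by_type = rng.multinomial(
            cfg.n_cells_per_sample, [props[t] for t in CELL_TYPES]
        )
        cell_types = np.repeat(CELL_TYPES, n_by_type)
        rng.shuffle(cell_types)
        n_real = len(cell_types)

        lib = rng.lognormal(0.0, cfg.lib_sigma, n_real)
        fold = np.ones((n_real, n_genes))

        # latent time and branch identity
        t_arr = np.full(n_real, np.nan)
        br = np.array([""] * n_real, dtype=object)
        for t_name in TRAJECTORY_TYPES:
            sel = cell_types == t_name
            lo, hi = t_range[t_name]
            t_arr[sel] = rng.uniform(lo, hi, sel.sum())
            br[sel] = "guard" if t_name == "guard" else "main"

        # discrete type markers (non-trajectory lineages)
        for t_name in ("mesophyll", "vascular"):
            sel = cell_types == t_name
            if sel.any():
                fold[np.ix_(sel, marker_idx[t_name])] = cfg.theta

        # trajectory programs — every program is CONTINUOUS in t so the
        # trajectory is a genuine Y in expression space:
        #   * epidermal module falls along the main path; guard cells
        #     keep it frozen at its branch-point level (they retain
        #     epidermal identity), so the guard arm cannot shadow the
        #     late main path;
        #   * trichome module rises along the main path; on the guard
        #     branch it decays back to baseline over the branch_ramp
        #     window after b;
        #   * transitional module is a trapezoid in t — full strength
        #     across the transitional span, short linear ramps at both
        #     ends — likewise released on the guard branch;
        #   * guard module ramps on over the branch_ramp window after b,
        #     on the guard branch only.
        on_traj = np.isfinite(t_arr)
        if on_traj.any():
            ti = t_arr[on_traj]
            is_guard = (br == "guard")
            guard_t = t_arr[is_guard]
            # 0 at the branch point, 1 once branch_ramp past it
            guard_switch = np.clip(
                (guard_t - cfg.branch_point) / cfg.branch_ramp, 0.0, 1.0
            )
            t_eff = np.where(is_guard[on_traj],
                             np.minimum(ti, cfg.branch_point), ti)
            for gi in marker_idx["epidermis"]:
                s = expit(slope[gi] * (t_eff - mid[gi]))
                fold[on_traj, gi] = 1.0 + amp * (1.0 - s)
            for gi in marker_idx["trichome"]:
                fold[on_traj, gi] = 1.0 + amp * expit(slope[gi] * (ti - mid[gi]))
                fold[is_guard, gi] = 1.0 + (fold[is_guard, gi] - 1.0) * (1.0 - guard_switch)
            lo, hi = t_range["transitional"]
            w = cfg.transient_ramp
            bump = np.clip(np.minimum((ti - (lo - w)) / (2 * w),
                                      ((hi + w) - ti) / (2 * w)), 0.0, 1.0)
            for gi in marker_idx["transitional"]:
                fold[on_traj, gi] = 1.0 + amp * bump
                fold[is_guard, gi] = 1.0 + (fold[is_guard, gi] - 1.0) * (1.0 - guard_switch)
            for gi in marker_idx["guard"]:
                fold[is_guard, gi] = 1.0 + amp * guard_switch

        # cell-cycle phases
        phases = np.empty(n_real, dtype=object)
        phase_names = list(_BASE_PHASE_PROPS)
        for t_name in CELL_TYPES:
            sel = cell_types == t_name
            if not sel.any():
                continue
            pp = phase_props[t_name]
            phases[sel] = rng.choice(
                phase_names, size=sel.sum(), p=[pp[p] for p in phase_names]
            )
        for p in PHASES:
            sel = phases == p
            if sel.any():
                fold[np.ix_(sel, phase_idx[p])] *= cfg.phase_fold

        mean = lib[:, None] * base[None, :] * fold * batch_factor[sample][None, :]
        counts = _draw_counts(rng, mean, cfg.dispersion)

        barcodes.extend(_random_barcodes(rng, n_real, sample))
        rows_counts.append(sp.csr_matrix(counts))
        type_lab.extend(cell_types)
        sample_lab.extend([sample] * n_real)
        phase_lab.extend("noncycling" if p == "NC" else p for p in phases)
        latent.extend(t_arr)
        branch_lab.extend(br)
        is_cell.extend([True] * n_real)
        if cfg.store_means:
            mean_rows.append(mean.astype(np.float32))

        # ambient barcodes: pooled baseline soup at low depth
        n_amb = cfg.n_ambient_per_sample
        if n_amb:
            amb_tot = rng.lognormal(math.log(cfg.ambient_mean_umi), 0.5, n_amb)
            amb_mean = amb_tot[:, None] * (base * batch_factor[sample])[None, :] / base.sum()
            amb_counts = rng.poisson(amb_mean)
            barcodes.extend(_random_barcodes(rng, n_amb, sample))
            rows_counts.append(sp.csr_matrix(amb_counts))
            type_lab.extend(["ambient"] * n_amb)
            sample_lab.extend([sample] * n_amb)
            phase_lab.extend([""] * n_amb)
            latent.extend([np.nan] * n_amb)
            branch_lab.extend([""] * n_amb)
            is_cell.extend([False] * n_amb)

    counts = sp.vstack(rows_counts).tocsr().astype(np.int64)
    cm = CountMatrix(
        counts=counts,
        barcodes=np.array(barcodes),
        genes=genes,
        sample_labels=np.array(sample_lab),
    )

    # ---- marker DB and homology table --------------------------------
    marker_db: dict[str, list[str]] = {}
    reference_markers: dict[str, list[str]] = {}
    hom_rows: list[dict] = []
    for t in CELL_TYPES:
        refs = [f"At{_TYPE_CODE[t]}{j + 1:02d}" for j in range(cfg.n_markers_per_type)]
        marker_db[t] = refs
        reference_markers[t] = refs
        for ref, target in zip(refs, markers_by_type[t]):
            hom_rows.append({
                "reference_gene_id": ref,
                "target_gene_id": target,
                "evalue": 10.0 ** rng.uniform(-30, -10),
            })
    all_refs = [r for refs in reference_markers.values() for r in refs]
    background_genes = genes[special:]
    # secondary (weaker but below-cutoff) hits exercise best-hit resolution
    for ref in rng.choice(all_refs, size=min(cfg.n_secondary_homologs, len(all_refs)),
                          replace=False):
        hom_rows.append({
            "reference_gene_id": str(ref),
            "target_gene_id": str(rng.choice(background_genes)),
            "evalue": 10.0 ** rng.uniform(-9, -6),
        })
    # decoys above the cutoff must never survive filtering
    for ref in rng.choice(all_refs, size=min(cfg.n_decoy_homologs, len(all_refs)),
                          replace=False):
        hom_rows.append({
            "reference_gene_id": str(ref),
            "target_gene_id": str(rng.choice(background_genes)),
            "evalue": 10.0 ** rng.uniform(-4, -1),
        })
    homology = pd.DataFrame(hom_rows)

    truth = SyntheticTruth(
        type_label=np.array(type_lab),
        sample_label=np.array(sample_lab),
        phase_label=np.array(phase_lab),
        latent_time=np.array(latent),
        branch=np.array(branch_lab, dtype=str),
        is_cell=np.array(is_cell),
        markers_by_type=markers_by_type,
        phase_genes=phase_genes,
        trend_class=trend_class,
        reference_markers=reference_markers,
        branch_point=cfg.branch_point,
        mean_matrix=np.vstack(mean_rows) if cfg.store_means else None,
    )
    return SimulatedExperiment(counts=cm, truth=truth, marker_db=marker_db,
                               homology=homology)


def simulate_barcode_profile(
    n_real: int = 1000,
    n_ambient: int = 20000,
    real_log_mu: float = math.log(2000.0),
    real_log_sigma: float = 0.4,
    ambient_log_mu: float = math.log(30.0),
    ambient_log_sigma: float = 0.8,
    seed: int = 0,
) -> tuple[BarcodeProfile, np.ndarray]:
    """Simulate a barcode-rank profile with known real/ambient flags.

    Real and ambient totals are log-normal; the defaults keep the 1st
    percentile of the real distribution far above the knee threshold so a
    rank-based caller can separate them cleanly. Returns the shuffled
    profile and a boolean truth flag per barcode (True = real cell).
    A warning (not an error) is raised when the two distributions overlap
    substantially.
    """
    if n_real < 0 or n_ambient < 0:
        raise ValueError("n_real and n_ambient must be >= 0")
    if n_real + n_ambient == 0:
        raise ValueError("profile would be empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x52]))

    real_q01 = math.exp(real_log_mu - 2.326 * real_log_sigma)
    amb_q99 = math.exp(ambient_log_mu + 2.326 * ambient_log_sigma)
    if n_real and n_ambient and real_q01 < amb_q99:
        warnings.warn(
            "real and ambient UMI distributions overlap; knee calling may "
            "be unreliable", stacklevel=2,
        )

    totals = np.concatenate([
        np.round(rng.lognormal(real_log_mu, real_log_sigma, n_real)),
        np.round(rng.lognormal(ambient_log_mu, ambient_log_sigma, n_ambient)),
    ]).astype(np.int64)
    flags = np.concatenate([
        np.ones(n_real, dtype=bool), np.zeros(n_ambient, dtype=bool)
    ])
    order = rng.permutation(len(totals))
    totals, flags = totals[order], flags[order]

    letters = np.array(list("ACGT"))
    seen: set[str] = set()
    barcodes = []
    while len(barcodes) < len(totals):
        b = "".join(rng.choice(letters, size=16))
        if b not in seen:
            seen.add(b)
            barcodes.append(b)
    return BarcodeProfile(barcodes=np.array(barcodes), umi_counts=totals), flags
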