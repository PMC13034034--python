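"""Knee-point cell calling from a barcode-rank UMI profile.

The rule: rank barcodes by descending total UMI count, take the top ``N``
(the expected cell count), let ``m`` be the UMI count at the 99th
percentile of that top-N slice (nearest rank counted from the high end),
and retain every barcode in the full profile whose count is at least
``knee_fraction * m`` (barcodes strictly below the threshold are filtered
out). The percentile is the robust-max convention used by droplet cell
callers: the count at position ``max(1, ceil((1 - p/100) * N))`` of the
descending-sorted slice.

The threshold is applied to *all* barcodes, not only the top-N slice, so
barcodes ranked below N can still be rescued if their counts clear it.
An externally computed rescue list (e.g. from an ambient-profile method)
can be merged via the ``extra_barcodes`` hook.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .containers import BarcodeProfile

__all__ = ["CellCallResult", "call_cells_knee"]


@dataclass
class CellCallResult:
    """Outcome of knee-point cell calling.

    ``m`` is the 99th-percentile UMI count within the top-N slice and
    ``threshold = knee_fraction * m`` exactly; every retained barcode has
    a UMI count >= threshold (plus any externally rescued barcodes).
    """

    retained: np.ndarray  # barcode IDs, sorted
    m: int
    threshold: float
    expected_cells: int
    n_retained: int

    def retained_set(self) -> set[str]:
        return set(self.retained)


def call_cells_knee(
    profile: BarcodeProfile,
    expected_cells: int,
    knee_percentile: float = 99.0,
    knee_fraction: float = 0.10,
    extra_barcodes: Iterable[str] | None = None,
) -> CellCallResult:
    """Call cells from a barcode-rank profile.

    Parameters
    ----------
    profile
        Per-barcode total UMI counts.
    expected_cells
        The expected number of cells ``N``; clamped (with a warning) to the
        number of barcodes when larger.
    knee_percentile
        Percentile of the top-N slice defining the robust maximum ``m``.
    knee_fraction
        Fraction of ``m`` below which barcodes are filtered out.
    extra_barcodes
        Optional externally supplied rescue list (e.g. an ambient-model
        caller); merged into the retained set after thresholding.
    """
    if len(profile) == 0:
        raise ValueError("empty barcode profile")
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    n = len(profile)
    if expected_cells > n:
        warnings.warn(
            f"expected_cells={expected_cells} exceeds {n} barcodes; clamping",
            stacklevel=2,
        )
        expected_cells = n

    counts = profile.umi_counts
    # descending by count, ties broken by barcode lexicographic order
    order = np.lexsort((profile.barcodes, -counts))
    top_counts = counts[order[:expected_cells]]

    rank = max(1, math.ceil((1.0 - knee_percentile / 100.0) * expected_cells))
    m = int(top_counts[rank - 1])

    if m == 0:
        warnings.warn("all-zero top slice; no cells retained", stacklevel=2)
        retained_mask = np.zeros(n, dtype=bool)
        threshold = 0.0
    else:
        threshold = knee_fraction * m
        retained_mask = counts >= threshold

    retained = set(profile.barcodes[retained_mask])
    if extra_barcodes is not None:
        known = set(profile.barcodes)
        for b in extra_barcodes:
            if b in known:
                retained.add(b)
    retained_arr = np.array(sorted(retained), dtype=str)
    return CellCallResult(
        retained=retained_arr,
        m=m,
        threshold=threshold,
        expected_cells=expected_cells,
        n_retained=len(retained_arr),
    )
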