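"""Peak occupancy statistics: group comparison and Y479-dependence categories.

The occupancy comparison contrasts the mean wild-type peak height (FPKM) of
the adjacent-FBE subset against all peaks (the subset is included in "all
peaks", not complemented out), using a two-sided unpaired t-test assuming
equal variance with no multiple-testing correction.  Y479A categorization
splits adjacent-FBE peaks by whether occupancy drops, rises, or is unchanged
when the Y479A substitution disrupts FBF-2 partnerships; the fold-change
criterion is an explicit, logged parameter because no canonical numeric
threshold exists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from fbescan.records import PeakRecord

__all__ = [
    "HeightComparison",
    "Y479Partition",
    "compare_peak_heights",
    "categorize_y479",
]

logger = logging.getLogger(__name__)

_Y479_GROUPS = ("lower", "higher", "unchanged")


@dataclass(frozen=True)
class HeightComparison:
    mean_all: float
    mean_adjacent: float
    t_statistic: float
    p_value: float
    n_all: int
    n_adjacent: int


@dataclass(frozen=True)
class Y479Partition:
    """Disjoint, exhaustive split of peaks by Y479A response."""

    groups: dict[str, list[str]]
    mean_wt_height: dict[str, float]
    fold_threshold: float


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t with guards for zero pooled variance."""
    n1, n2 = len(x), len(y)
    ss = np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
    if ss == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn(
            "zero pooled variance with unequal means; reporting smallest "
            "representable p-value",
            RuntimeWarning,
            stacklevel=3,
        )
        t = np.inf if x.mean() > y.mean() else -np.inf
        return float(t), float(np.finfo(float).tiny)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def compare_peak_heights(
    all_peaks: Sequence[PeakRecord],
    adjacent_ids: Iterable[str],
) -> HeightComparison:
    """Compare mean wild-type peak height of the adjacent-FBE subset vs all peaks."""
    adjacent_ids = set(adjacent_ids)
    ids = {p.peak_id for p in all_peaks}
    missing = sorted(adjacent_ids - ids)
    if missing:
        raise KeyError(f"adjacent ids not among peaks: {missing}")

    all_h = np.array([p.wt_height for p in sorted(all_peaks, key=lambda p: p.peak_id)])
    adj_h = np.array(
        [p.wt_height for p in sorted(all_peaks, key=lambda p: p.peak_id) if p.peak_id in adjacent_ids]
    )
    if len(all_h) < 2 or len(adj_h) < 2:
        raise ValueError("need at least 2 peaks per group for the t-test")

    t, p = _pooled_t(adj_h, all_h)
    return HeightComparison(
        mean_all=float(all_h.mean()),
        mean_adjacent=float(adj_h.mean()),
        t_statistic=t,
        p_value=p,
        n_all=len(all_h),
        n_adjacent=len(adj_h),
    )


def categorize_y479(
    adjacent_peaks: Sequence[PeakRecord],
    fold_threshold: float = 1.5,
) -> Y479Partition:
    """Partition peaks into lower / higher / unchanged Y479A occupancy.

    A peak is "lower" when y479a_height < wt_height / fold_threshold,
    "higher" when y479a_height > wt_height * fold_threshold, else
    "unchanged".  The threshold is a deliberate analysis choice and is
    logged so any report of the partition carries it.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    missing = [p.peak_id for p in adjacent_peaks if p.y479a_height is None]
    if missing:
        raise ValueError(f"peaks missing y479a_height: {missing}")

    logger.info("Y479A categorization with fold_threshold=%g", fold_threshold)
    groups: dict[str, list[str]] = {g: [] for g in _Y479_GROUPS}
    heights: dict[str, list[float]] = {g: [] for g in _Y479_GROUPS}
    for p in sorted(adjacent_peaks, key=lambda p: p.peak_id):
        if p.y479a_height < p.wt_height / fold_threshold:
            g = "lower"
        elif p.y479a_height > p.wt_height * fold_threshold:
            g = "higher"
        else:
            g = "unchanged"
        groups[g].append(p.peak_id)
        heights[g].append(p.wt_height)

    means = {
        g: (float(np.mean(h)) if h else float("nan")) for g, h in heights.items()
    }
    return Y479Partition(groups=groups, mean_wt_height=means, fold_threshold=fold_threshold)
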