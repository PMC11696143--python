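"""Spatial expression-profile quantitation along the germline distal-proximal axis.

Line-profile intensities (e.g. GLD-1 or a GFP reporter measured in µm from
the gonad's distal end) are resampled to a common 1-µm grid, and the mean
profiles of every genotype are normalized to the maximum of the wild-type
mean within the distal 100 µm, so the wild-type normalized maximum is
exactly 1.  Confidence bands are 95% t-intervals across gonads at each
position.  Regional comparisons pool per-gonad mean intensity within a
window (within-gonad first, so the replicate unit is the gonad) and apply a
two-sided unpaired equal-variance t-test, uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from fbescan.peakstats import _pooled_t

__all__ = [
    "DISTAL_WINDOW_UM",
    "ExpressionProfile",
    "NormalizedProfile",
    "RegionComparison",
    "resample_to_grid",
    "normalize_profiles",
    "pooled_region_test",
]

#: Normalization window: distal 0-100 µm of the wild-type germline.
DISTAL_WINDOW_UM = (0.0, 100.0)


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gonad intensity vectors on a shared position grid (µm)."""

    genotype: str
    positions: np.ndarray  # (n_positions,)
    intensities: np.ndarray  # (n_gonads, n_positions), arbitrary units >= 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if inten.shape[1] != pos.shape[0]:
            raise ValueError("intensity columns must match position grid")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    @property
    def n_gonads(self) -> int:
        return self.intensities.shape[0]

    def mean(self) -> np.ndarray:
        return self.intensities.mean(axis=0)


@dataclass(frozen=True)
class NormalizedProfile:
    genotype: str
    positions: np.ndarray
    intensities: np.ndarray  # per-gonad, after scaling
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


@dataclass(frozen=True)
class RegionComparison:
    window: tuple[float, float]
    mean_wt: float
    mean_mut: float
    t_statistic: float
    p_value: float
    n_wt: int
    n_mut: int


def resample_to_grid(
    positions: np.ndarray,
    intensities: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of one gonad's line profile onto a 1-µm grid.

    The instrument pixel grid varies between images; a fixed grid makes
    gonads comparable position-by-position.
    """
    if grid is None:
        grid = np.arange(DISTAL_WINDOW_UM[0], DISTAL_WINDOW_UM[1] + 1.0, 1.0)
    order = np.argsort(positions)
    return grid, np.interp(grid, np.asarray(positions)[order], np.asarray(intensities)[order])


def _ci_band(
    intensities: np.ndarray, mean: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    n = intensities.shape[0]
    if n < 2:
        raise ValueError("need >= 2 gonads for a confidence interval")
    sem = intensities.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    return mean - tcrit * sem, mean + tcrit * sem


def normalize_profiles(
    wt: ExpressionProfile,
    mutants: list[ExpressionProfile] | None = None,
) -> tuple[NormalizedProfile, list[NormalizedProfile]]:
    """Scale all profiles by the wild-type distal maximum.

    Every profile (wild-type and mutants alike) is divided by the maximum of
    the wild-type mean profile within the distal 0-100 µm window, so the
    normalized wild-type mean peaks at exactly 1 there.  The 95% CI is a
    t-interval across gonads at each position, computed on the scaled
    per-gonad values.
    """
    mutants = mutants or []
    for m in mutants:
        if not np.array_equal(m.positions, wt.positions):
            raise ValueError(f"profile {m.genotype!r} not on the wild-type position grid")

    in_window = (wt.positions >= DISTAL_WINDOW_UM[0]) & (wt.positions <= DISTAL_WINDOW_UM[1])
    if not np.any(in_window):
        raise ValueError("wild-type profile does not cover the distal 0-100 um window")
    scale = float(wt.mean()[in_window].max())
    if scale <= 0:
        raise ValueError("wild-type distal maximum is zero; cannot normalize")

    def _norm(p: ExpressionProfile) -> NormalizedProfile:
        scaled = p.intensities / scale
        # divide the mean, not the per-gonad values, so the wild-type maximum
        # normalizes to exactly 1.0 rather than within rounding of it
        mean = p.mean() / scale
        lo, hi = _ci_band(scaled, mean)
        return NormalizedProfile(
            genotype=p.genotype,
            positions=p.positions,
            intensities=scaled,
            mean=mean,
            ci_low=lo,
            ci_high=hi,
        )

    return _norm(wt), [_norm(m) for m in mutants]


def _window_means(profile: NormalizedProfile | ExpressionProfile, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi < lo:
        raise ValueError("window end precedes start")
    mask = (profile.positions >= lo) & (profile.positions <= hi)
    if not np.any(mask):
        raise ValueError(f"window {window} contains no profile positions")
    return profile.intensities[:, mask].mean(axis=1)


def pooled_region_test(
    wt: NormalizedProfile | ExpressionProfile,
    mut: NormalizedProfile | ExpressionProfile,
    window: tuple[float, float],
) -> RegionComparison:
    """Equal-variance t-test of per-gonad mean intensity within a window.

    Intensity is first averaged within each gonad over the window (the gonad
    is the replicate unit; pooling pixels directly would pseudo-replicate),
    then the two genotypes are compared with a two-sided unpaired t-test
    assuming equal variance.  The p-value is reported uncorrected.
    """
    x = _window_means(wt, window)
    y = _window_means(mut, window)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 gonads per genotype")
    t, p = _pooled_t(x, y)
    return RegionComparison(
        window=(float(window[0]), float(window[1])),
        mean_wt=float(x.mean()),
        mean_mut=float(y.mean()),
        t_statistic=t,
        p_value=p,
        n_wt=len(x),
        n_mut=len(y),
    )
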