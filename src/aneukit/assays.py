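"""Biochemical-readout calculators and the small statistics they use.

Covers the beta-galactosidase (Miller unit) reporter, the ER-GFP folding
reporter, pulse-chase turnover (percent remaining, half-life, endpoint
Student t test), Welch's t test, HAC1 splicing fractions, growth-curve
doubling times, and the Pearson correlation of doubling time against extra
ORF burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def miller_units(od420: float, od550: float, od600: float, t_min: float) -> float:
    """Beta-galactosidase activity: 1000 * (OD420 - 1.75 * OD550) / (2 * t * OD600).

    ``t_min`` is the reaction time in minutes. The factor ``2 * t * OD600``
    is applied literally; supply your own volume correction if needed.
    """
    if t_min <= 0:
        raise ValueError("reaction time must be positive")
    if od600 <= 0:
        raise ValueError("OD600 must be positive")
    return 1000.0 * (od420 - 1.75 * od550) / (2.0 * t_min * od600)


def normalize_to_wt(values: np.ndarray | list[float], wt_value: float) -> np.ndarray:
    """Express activities as percent of the wild-type control (WT = 100%)."""
    if wt_value == 0:
        raise ValueError("wild-type value must be nonzero")
    return 100.0 * np.asarray(values, dtype=float) / wt_value


def ergfp_ratio(fluorescence: float, total_gfp_level: float, loading_ref: float = 1.0) -> float:
    """Folded-GFP proxy: fluorescence over loading-normalized total GFP protein."""
    if total_gfp_level <= 0 or loading_ref <= 0:
        raise ValueError("protein levels must be positive")
    return fluorescence / (total_gfp_level / loading_ref)


def normalized_ergfp(
    fluorescence: float,
    total_gfp_level: float,
    loading_ref: float,
    wt_ratio: float,
) -> float:
    """ER-GFP folding readout as percent of the wild-type ratio (WT = 100%)."""
    if wt_ratio <= 0:
        raise ValueError("wild-type ratio must be positive")
    return 100.0 * ergfp_ratio(fluorescence, total_gfp_level, loading_ref) / wt_ratio


def percent_remaining(series: pd.DataFrame) -> pd.DataFrame:
    """Convert pulse-chase intensities to percent of each replicate's t=0 value.

    ``series`` has timepoints (minutes) as index and replicates as columns;
    the first row must be the zero timepoint.
    """
    t = np.asarray(series.index, dtype=float)
    if t[0] != 0:
        raise ValueError("chase series must start at t=0")
    t0 = series.iloc[0]
    if (t0 <= 0).any():
        raise ValueError("zero or negative intensity at t=0")
    return 100.0 * series / t0


def fit_half_life(timepoints: np.ndarray | list[float], percents: np.ndarray | list[float]) -> float:
    """Half-life (same units as the timepoints) from a log-linear least-squares fit.

    Fits log2(percent remaining) against time; the slope is -1/half-life
    under single-exponential decay. Non-positive intensities are excluded.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(percents, dtype=float)
    ok = y > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive intensities to fit a half-life")
    slope = stats.linregress(t[ok], np.log2(y[ok])).slope
    if slope >= 0:
        return float("inf")
    return -1.0 / slope


@dataclass(frozen=True)
class TurnoverResult:
    """Pulse-chase summary: mean percent-remaining curve, replicate SD, half-life."""

    timepoints: np.ndarray
    mean_percent: np.ndarray
    sd_percent: np.ndarray
    half_life: float


def pulse_chase_turnover(series: pd.DataFrame) -> TurnoverResult:
    """Summarize a chase series: per-timepoint mean and SD across replicates,
    and the half-life fitted to all replicate points jointly."""
    pct = percent_remaining(series)
    t = np.asarray(pct.index, dtype=float)
    stacked_t = np.repeat(t, pct.shape[1])
    stacked_y = pct.to_numpy().ravel()
    return TurnoverResult(
        timepoints=t,
        mean_percent=pct.mean(axis=1).to_numpy(),
        sd_percent=pct.std(axis=1, ddof=1).to_numpy(),
        half_life=fit_half_life(stacked_t, stacked_y),
    )


def student_t(x, y) -> tuple[float, float, float]:
    """Two-tailed unpaired Student's t test (pooled variance).

    Returns (t, df, p) with df = n_x + n_y - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(len(x) + len(y) - 2), float(res.pvalue)


def compare_final(strain_a: pd.DataFrame, strain_b: pd.DataFrame) -> tuple[float, float, float]:
    """Student t test between two strains' percent remaining at the last
    shared chase timepoint."""
    a = percent_remaining(strain_a).iloc[-1].to_numpy()
    b = percent_remaining(strain_b).iloc[-1].to_numpy()
    if strain_a.index[-1] != strain_b.index[-1]:
        raise ValueError("final timepoints differ between strains")
    return student_t(a, b)


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-tailed Welch's t test with Satterthwaite degrees of freedom.

    Returns (t, df, p); appropriate when group sizes or variances differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def significance_label(p: float) -> str:
    """Star notation: *** p<0.001, ** p<0.01, * p<0.05, '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def hac1_splice_fraction(
    spliced_intensity: float, unspliced_intensity: float, act1_intensity: float = 1.0
) -> float:
    """Fraction of spliced transcript: S / (S + U) after control normalization.

    Band intensities are divided by the internal ACT1 control before being
    combined; the control cancels algebraically but is applied explicitly so
    intensities from different lanes are on a common scale.
    """
    if act1_intensity <= 0:
        raise ValueError("control intensity must be positive")
    if spliced_intensity < 0 or unspliced_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    s = spliced_intensity / act1_intensity
    u = unspliced_intensity / act1_intensity
    if s + u == 0:
        raise ValueError("no signal in either band")
    return s / (s + u)


def doubling_time(
    time_h: np.ndarray | list[float],
    od600: np.ndarray | list[float],
    window: tuple[float, float] | None = None,
) -> float:
    """Doubling time (hours) from the exponential phase of a growth curve.

    Fits ln(OD600) against time by least squares over the optional time
    ``window`` and returns ln(2) / slope. Requires at least 3 points.
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if (od <= 0).any():
        raise ValueError("OD600 values must be positive")
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, od = t[keep], od[keep]
    if len(t) < 3:
        raise ValueError("need at least 3 points in the fitted window")
    slope = stats.linregress(t, np.log(od)).slope
    if slope <= 0:
        raise ValueError("no growth detected in the fitted window")
    return float(np.log(2.0) / slope)


def orf_burden_correlation(doubling_times, extra_orf_counts) -> float:
    """Pearson correlation of doubling times vs extra duplicated-ORF counts."""
    return float(stats.pearsonr(doubling_times, extra_orf_counts).statistic)
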