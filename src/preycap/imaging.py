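"""Fluorescence-response analysis: ΔF/F, condition-ratio maps, ROI
tuning curves, and normality-gated two-group statistics.

The baseline for ΔF/F is the pixel's value "during a period of low
activity", estimated as a low percentile (default: 8th) of the pixel's
fluorescence over a sliding temporal window (default: 25 frames,
centered, truncated at the edges). Percentiles use linear interpolation
between order statistics throughout this module.

Input movies are assumed motion-registered; :func:`detect_drift` warns
when the frame-to-frame translation estimated by phase correlation
exceeds a tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidWindowError,
)

DEFAULT_WINDOW = 25
DEFAULT_PERCENTILE = 8.0
RATIO_MASK_FLOOR = 0.05


@dataclass
class DeltaFOverF:
    """Pixelwise ΔF/F stack with its baseline definition.

    values : (T, H, W) unitless ratios; NaN marks masked pixels (baseline
        non-positive somewhere in time).
    baseline : the (T, H, W) baseline stack used.
    """

    values: np.ndarray
    baseline: np.ndarray
    window: int = DEFAULT_WINDOW
    percentile: float = DEFAULT_PERCENTILE
    source_id: str | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class ROIResponse:
    """Mean-ΔF/F time course and its peak for one ROI in one trial."""

    roi_name: str
    time_course: np.ndarray
    peak: float
    condition: object = None


def sliding_percentile_baseline(
    movie: np.ndarray, window: int = DEFAULT_WINDOW, percentile: float = DEFAULT_PERCENTILE
) -> np.ndarray:
    """Per-pixel sliding-window percentile of the raw fluorescence.

    The window is centered on each frame and truncated at the movie's
    edges; percentiles interpolate linearly between order statistics.
    """
    movie = np.asarray(movie, dtype=float)
    T = movie.shape[0]
    if window >= T:
        raise InvalidWindowError(f"window ({window}) must be shorter than the movie ({T})")
    if not 0 <= percentile <= 100:
        raise InvalidParameterError("percentile must be in [0, 100]")
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    out = np.empty_like(movie)
    for t in range(T):
        lo = max(0, t - half_lo)
        hi = min(T, t + half_hi + 1)
        out[t] = np.percentile(movie[lo:hi], percentile, axis=0)
    return out


def compute_dff(
    movie: np.ndarray,
    baseline: np.ndarray,
    window: int = DEFAULT_WINDOW,
    percentile: float = DEFAULT_PERCENTILE,
    source_id: str | None = None,
) -> DeltaFOverF:
    """(raw − baseline) / baseline per pixel per frame.

    Pixels whose baseline is non-positive at any frame are masked (NaN
    across all frames), counted, and warned about.
    """
    movie = np.asarray(movie, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if movie.shape != baseline.shape:
        raise InvalidParameterError("movie and baseline shapes differ")
    bad = (baseline <= 0).any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (movie - baseline) / baseline
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pixels have non-positive baseline; masked")
        values[:, bad] = np.nan
    return DeltaFOverF(
        values=values, baseline=baseline, window=window,
        percentile=percentile, source_id=source_id,
    )


def condition_ratio_map(
    dff_pre: DeltaFOverF, dff_post: DeltaFOverF, mask_floor: float = RATIO_MASK_FLOOR
) -> np.ndarray:
    """Ratio of temporal-max projections: post / pre, per pixel.

    Pixels whose pre-segment max ΔF/F is below ``mask_floor`` are masked
    (NaN) to avoid dividing by noise.
    """
    if dff_pre.values.shape[1:] != dff_post.values.shape[1:]:
        raise InvalidParameterError("spatial shapes differ")
    pre = np.nanmax(dff_pre.values, axis=0)
    post = np.nanmax(dff_post.values, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = post / pre
    ratio[~(pre >= mask_floor)] = np.nan
    return ratio


def roi_response(
    dff: DeltaFOverF, mask: np.ndarray, roi_name: str = "roi", condition: object = None
) -> ROIResponse:
    """Spatial-mean ΔF/F time course over a pixel mask, with its peak."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dff.values.shape[1:]:
        raise InvalidParameterError("mask shape does not match the movie")
    if not mask.any():
        raise InvalidParameterError("empty ROI mask")
    tc = np.nanmean(dff.values[:, mask], axis=1)
    return ROIResponse(
        roi_name=roi_name, time_course=tc, peak=float(np.nanmax(tc)), condition=condition
    )


def response_tuning(responses: pd.DataFrame) -> pd.DataFrame:
    """Normalized tuning across larvae.

    ``responses``: rows = larvae, columns = stimulus conditions, values =
    peak ΔF/F. Each larva's responses are divided by that larva's maximum
    (× 100); larvae with no positive maximum are excluded with a warning.
    Returns condition-indexed DataFrame with 'mean', 'sem', 'n'.
    """
    rows, kept = [], []
    for larva, row in responses.iterrows():
        vals = row.to_numpy(dtype=float)
        m = np.nanmax(vals) if np.isfinite(vals).any() else 0.0
        if not m > 0:
            warnings.warn(f"larva {larva!r} has no positive response; excluded")
            continue
        rows.append(100.0 * vals / m)
        kept.append(larva)
    if not rows:
        raise InvalidParameterError("no larva has a positive response")
    from .classifier import _nansem

    norm = np.vstack(rows)
    n = np.sum(np.isfinite(norm), axis=0)
    mean = np.nanmean(norm, axis=0)
    sem = _nansem(norm, n)
    return pd.DataFrame({"mean": mean, "sem": sem, "n": n}, index=responses.columns)


@dataclass
class GroupComparison:
    """Outcome of the normality-gated two-group comparison."""

    test_name: str
    statistic: float
    p_value: float
    normal_a: bool
    normal_b: bool
    jarque_bera_p: tuple[float, float]
    levene_statistic: float
    levene_p: float


def rank_sum(a: np.ndarray, b: np.ndarray):
    """Wilcoxon rank-sum test: exact when both samples are small and
    tie-free, otherwise the normal approximation (no continuity
    correction, so elementwise-equal samples give p = 1 exactly)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (not has_ties and a.size + b.size <= 25) else "asymptotic"
    return stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )


def compare_groups(a, b, alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with a normality gate.

    Jarque–Bera is applied to each sample; if both are consistent with
    normality at ``alpha``, a two-sample t-test is used, otherwise the
    Wilcoxon rank-sum test (exact when sample sizes permit and there are
    no ties, normal approximation otherwise). Levene's variance test is
    reported alongside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each sample needs at least 3 values")
    jb_a = stats.jarque_bera(a).pvalue
    jb_b = stats.jarque_bera(b).pvalue
    normal_a = bool(jb_a > alpha)
    normal_b = bool(jb_b > alpha)
    lev = stats.levene(a, b)
    if normal_a and normal_b:
        res = stats.ttest_ind(a, b)
        name = "t-test"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        res = rank_sum(a, b)
        name = "wilcoxon_rank_sum"
        statistic, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        test_name=name,
        statistic=statistic,
        p_value=p,
        normal_a=normal_a,
        normal_b=normal_b,
        jarque_bera_p=(float(jb_a), float(jb_b)),
        levene_statistic=float(lev.statistic),
        levene_p=float(lev.pvalue),
    )


def detect_drift(movie: np.ndarray, tolerance_px: float = 2.0) -> float:
    """Estimate the largest translation of any frame relative to frame 0
    by phase correlation; warn when it exceeds ``tolerance_px``."""
    from skimage.registration import phase_cross_correlation

    movie = np.asarray(movie, dtype=float)
    ref = movie[0]
    worst = 0.0
    for t in range(1, movie.shape[0]):
        shift, _, _ = phase_cross_correlation(ref, movie[t], upsample_factor=4)
        worst = max(worst, float(np.hypot(*shift)))
    if worst > tolerance_px:
        warnings.warn(
            f"movie appears unregistered: max drift {worst:.2f} px exceeds "
            f"{tolerance_px} px"
        )
    return worst
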