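"""Per-frame kinematic signals and swim-bout segmentation.

Converts a :class:`~preycap.core.TailTrace` into the angle/position/
curvature series the bout features are built from, and segments trials
into bouts by thresholding the normalized, smoothed first derivative of
the tail bend angle — the same operation used to count swims in
optomotor assays.

Sign convention: deflection toward +x (rightward in the image) is
positive. Angles are reported in degrees, curvature in units of
1 / tail length (so a tail bent into a full quarter circle has curvature
~pi/2 regardless of its pixel size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Bout, TailTrace

__all__ = [
    "KinematicSeries",
    "compute_series",
    "segment_bouts",
    "longest_bend_duration",
    "bout_amplitude",
]


@dataclass
class KinematicSeries:
    """Per-frame kinematic signals derived from a tail trace.

    tail_angle : deflection angle of the tail's center of mass from the
        rest axis, degrees, signed.
    tip_angle : angle of the line fitted through the last eight points,
        relative to the rest axis, degrees, signed.
    tip_position : horizontal deflection of the tail tip (last point) from
        the rest axis, as a fraction of tail length, signed.
    tip_region_position : same, for the centroid of the last eight points
        (the "tail tip" region used by the mean-tip-position feature).
    tail_position_12plus : same, for the centroid of points 12..end.
    curvature : per-frame maximum absolute local curvature, in units of
        1 / tail length.
    """

    tail_angle: np.ndarray
    tip_angle: np.ndarray
    tip_position: np.ndarray
    tip_region_position: np.ndarray
    tail_position_12plus: np.ndarray
    curvature: np.ndarray
    frame_rate: float
    tail_length: float

    @property
    def n_frames(self) -> int:
        return self.tail_angle.shape[0]


def _signed_angle_from_axis(vec: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Signed angle (degrees) of ``vec`` relative to unit ``axis``;
    positive when ``vec`` lies on the +x side of the axis."""
    along = vec @ axis
    # perpendicular component along the axis normal chosen so that +x is positive
    normal = np.array([axis[1], -axis[0]])
    if normal[0] < 0:
        normal = -normal
    perp = vec @ normal
    return np.degrees(np.arctan2(perp, along))


def _local_curvature(points: np.ndarray, tail_length: float) -> float:
    """Maximum absolute three-point circumscribed-circle curvature,
    normalized to 1 / tail length."""
    a, b, c = points[:-2], points[1:-1], points[2:]
    ab = b - a
    bc = c - b
    ac = c - a
    cross = ab[:, 0] * bc[:, 1] - ab[:, 1] * bc[:, 0]
    la = np.linalg.norm(ab, axis=1)
    lb = np.linalg.norm(bc, axis=1)
    lc = np.linalg.norm(ac, axis=1)
    denom = la * lb * lc
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * np.abs(cross) / denom, 0.0)
    return float(np.nanmax(kappa) * tail_length)


def rest_axis_from_trace(trace: TailTrace) -> np.ndarray:
    """Resting body axis estimated as the modal base-to-tip direction.

    Resting frames cluster extremely tightly in direction while swim and
    hold postures spread over many degrees, so the densest 1° bin of the
    base-to-tip angle histogram identifies rest even in trials dominated
    by sustained bends; the axis is the median direction within ±2° of
    that bin. A config override is available in :func:`compute_series`.
    """
    vec = trace.points[:, -1] - trace.points[:, 0]
    ang = np.degrees(np.arctan2(vec[:, 0], vec[:, 1]))  # from +y toward +x
    ang = ang[np.isfinite(ang)]
    edges = np.arange(-180.0, 181.0, 1.0)
    hist, _ = np.histogram(ang, bins=edges)
    center = edges[int(np.argmax(hist))] + 0.5
    sel = np.abs(ang - center) <= 2.0
    med = np.radians(float(np.median(ang[sel])))
    return np.array([np.sin(med), np.cos(med)])


def compute_series(
    trace: TailTrace,
    rest_axis: np.ndarray | None = None,
) -> KinematicSeries:
    """Derive all kinematic signals from a trace.

    Frames with coincident/degenerate points are carried as NaN in every
    series. ``rest_axis`` (unit 2-vector, default: median base-to-tip
    direction over frames) overrides the automatic rest-axis estimate.
    """
    pts = trace.points
    if pts.shape[1] < 10:
        raise ValueError("need at least 10 points per frame")
    axis = (
        np.asarray(rest_axis, dtype=float)
        if rest_axis is not None
        else rest_axis_from_trace(trace)
    )
    axis = axis / np.linalg.norm(axis)
    n = trace.n_frames
    L = trace.tail_length_px
    tail_angle = np.full(n, np.nan)
    tip_angle = np.full(n, np.nan)
    tip_position = np.full(n, np.nan)
    tip_region = np.full(n, np.nan)
    pos12 = np.full(n, np.nan)
    curvature = np.full(n, np.nan)
    normal = np.array([axis[1], -axis[0]])
    if normal[0] < 0:
        normal = -normal
    # the preparation is head-embedded, so the tail base is stationary:
    # the trace-wide median base suppresses per-frame jitter that would
    # otherwise dominate resting angle noise
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fixed_base = np.nanmedian(pts[:, 0, :], axis=0)
    for i in range(n):
        p = pts[i]
        if not np.isfinite(p).all():
            continue
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        if np.any(seg <= 1e-9):
            continue  # degenerate frame: coincident points
        base = fixed_base if np.isfinite(fixed_base).all() else p[0]
        com = p.mean(axis=0) - base
        tail_angle[i] = _signed_angle_from_axis(com, axis)
        # tip angle: principal direction of the last eight points
        tail8 = p[-8:]
        centered = tail8 - tail8.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d = vt[0]
        if d @ axis < 0:  # orient base->tip
            d = -d
        tip_angle[i] = _signed_angle_from_axis(d, axis)
        tip_position[i] = ((p[-1] - base) @ normal) / L
        tip_region[i] = ((tail8.mean(axis=0) - base) @ normal) / L
        pos12[i] = ((p[12:].mean(axis=0) - base) @ normal) / L
        curvature[i] = _local_curvature(p, L)
    return KinematicSeries(
        tail_angle=tail_angle,
        tip_angle=tip_angle,
        tip_position=tip_position,
        tip_region_position=tip_region,
        tail_position_12plus=pos12,
        curvature=curvature,
        frame_rate=trace.frame_rate,
        tail_length=L,
    )


def _interp_nan(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN runs (edges held at nearest valid value)."""
    out = x.copy()
    bad = ~np.isfinite(out)
    if bad.all():
        return out
    idx = np.arange(len(out))
    out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def segment_bouts(
    series: KinematicSeries,
    smooth_window: int = 5,
    threshold: float = 3.0,
    min_gap: int = 15,
    min_duration: int = 10,
) -> list[Bout]:
    """Detect swim bouts from the tail-angle derivative.

    Pipeline: first difference of tail_angle → moving-average smoothing
    over ``smooth_window`` frames → normalization by the robust scale
    (1.4826 × MAD) → frames with |value| > ``threshold`` marked active →
    active runs closed over gaps shorter than ``min_gap`` frames → runs
    shorter than ``min_duration`` frames dropped.
    """
    if series.n_frames <= smooth_window:
        raise ValueError("series must be longer than smooth_window")
    angle = series.tail_angle
    if not np.isfinite(angle).any():
        warnings.warn("all-missing tail angle; no bouts detected")
        return []
    angle = _interp_nan(angle)
    d = np.diff(angle, prepend=angle[0])
    kernel = np.ones(smooth_window) / smooth_window
    d = np.convolve(d, kernel, mode="same")
    # robust scale from a low quantile of absolute deviations so that the
    # estimate reflects resting noise even in bout-heavy trials (the
    # classical MAD breaks down once half the frames are active);
    # 0.3186 is the Gaussian 25th percentile of |x|/sigma
    q25 = np.quantile(np.abs(d - np.median(d)), 0.25)
    scale = q25 / 0.3186
    if scale <= 0:
        scale = np.std(d) or 1.0
    active = np.abs(d / scale) > threshold
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return []
    starts = [int(idx[0])]
    ends = []
    gaps = np.flatnonzero(np.diff(idx) > 1)
    for g in gaps:
        ends.append(int(idx[g]) + 1)
        starts.append(int(idx[g + 1]))
    ends.append(int(idx[-1]) + 1)
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [
        Bout(start_frame=s, end_frame=e)
        for s, e in merged
        if e - s >= min_duration
    ]


def longest_bend_duration(
    series: KinematicSeries, bout: Bout, angle_threshold: float = 20.0
) -> float:
    """Duration (ms) of the longest run of frames with |tail angle| above
    ``angle_threshold`` degrees within the bout; 0 if none."""
    a = series.tail_angle[bout.start_frame : bout.end_frame]
    above = np.abs(a) > angle_threshold
    best = cur = 0
    for flag in above:
        cur = cur + 1 if (flag and np.isfinite(flag)) else 0
        best = max(best, cur)
    return 1000.0 * best / series.frame_rate


def _alternating_extrema(x: np.ndarray, prominence: float) -> np.ndarray:
    """Values of alternating maxima/minima of ``x`` with the given
    prominence, in temporal order."""
    from scipy.signal import find_peaks

    hi, _ = find_peaks(x, prominence=prominence)
    lo, _ = find_peaks(-x, prominence=prominence)
    idx = np.sort(np.concatenate([hi, lo]))
    return x[idx]


def bout_amplitude(series: KinematicSeries, bout: Bout) -> float:
    """Tail-beat amplitude of a bout, as a fraction of tail length.

    Mean peak-to-trough half-amplitude of the tip deflection over the
    bout's oscillation cycles; bouts with fewer than two extrema (single
    sustained deflections) fall back to max |tip deflection|.
    """
    x = series.tip_position[bout.start_frame : bout.end_frame]
    x = x[np.isfinite(x)]
    if x.size == 0:
        return 0.0
    span = float(x.max() - x.min())
    if span <= 0:
        return 0.0
    prom = max(0.02, 0.1 * span / 2.0)
    ext = _alternating_extrema(x, prominence=prom)
    if ext.size < 2:
        return float(np.max(np.abs(x)))
    return float(np.mean(np.abs(np.diff(ext)) / 2.0))
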