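"""Tail digitization from high-speed video frames.

Reimplements the ridge-following midline tracker: starting from a
user-supplied base point, the tracker repeatedly predicts where the next
tail midpoint should be (linear extrapolation of the last segment),
samples an intensity slice perpendicular to the predicted direction,
smooths it, correlates it with a tail-like (Gaussian ridge) kernel, and
takes the maximum as the midpoint. The end of the tail is detected with
a threshold on the luminance change across the slice. Width and contrast
of the tail are characterized on the first frame and refine tracking for
the rest of the video.

Tracked frames are resampled to a fixed number of points (default 40)
uniform in arc length so downstream features have fixed dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .core import TailTrace, arc_lengths, resample_points
from .exceptions import CalibrationError, VideoQualityError

#: default spacing between successive midpoints, pixels
DEFAULT_STEP_PX = 5.0

#: end-of-tail test: stop when the slice's ridge contrast falls below
#: this fraction of the calibrated tail contrast
END_CONTRAST_FRACTION = 0.3


@dataclass
class TrackerCalibration:
    """First-frame tail characterization used to refine tracking.

    tail_width_px ~ 2 sigma of the stroke's Gaussian cross-section;
    kernel is the unit-normalized symmetric ridge template the slices are
    correlated with; luminance_change_threshold is the absolute contrast
    below which a slice is judged to have run off the tail.
    """

    tail_width_px: float
    tail_contrast: float
    step_px: float
    kernel: np.ndarray
    luminance_change_threshold: float
    background: float


def _sample(frame: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear samples of ``frame`` at (x, y) positions, shape (n, 2)."""
    return map_coordinates(
        frame.astype(float), [xy[:, 1], xy[:, 0]], order=1, mode="nearest"
    )


def _gaussian_kernel(sigma: float) -> np.ndarray:
    half = max(2, int(np.ceil(3 * sigma)))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def calibrate(
    first_frame: np.ndarray,
    base_point: tuple[float, float],
    step_px: float = DEFAULT_STEP_PX,
    initial_heading: tuple[float, float] = (0.0, 1.0),
) -> TrackerCalibration:
    """Characterize tail width and contrast at the base point.

    The width is the second-moment width of the background-subtracted
    intensity profile perpendicular to the initial heading; contrast is
    the profile peak minus the frame's median background. Fails if the
    base point is not on a bright structure.
    """
    frame = np.asarray(first_frame, dtype=float)
    background = float(np.median(frame))
    noise = 1.4826 * float(np.median(np.abs(frame - background)))
    bx, by = base_point
    heading = np.asarray(initial_heading, dtype=float)
    heading = heading / np.linalg.norm(heading)
    perp = np.array([-heading[1], heading[0]])
    offsets = np.linspace(-10.0, 10.0, 41)
    xy = np.array([bx, by])[None] + offsets[:, None] * perp[None]
    profile = _sample(frame, xy) - background
    peak = float(profile.max())
    if peak < max(5.0 * noise, 10.0):
        raise CalibrationError(
            "base point does not sit on a bright tail (no contrast above background)"
        )
    w = profile.clip(min=0.0)
    mu = float(np.sum(offsets * w) / np.sum(w))
    sigma = float(np.sqrt(np.sum((offsets - mu) ** 2 * w) / np.sum(w)))
    # the profile includes a noise pedestal; keep sigma in a sane range
    sigma = float(np.clip(sigma, 0.5, 10.0))
    width = 2.0 * sigma
    return TrackerCalibration(
        tail_width_px=width,
        tail_contrast=peak,
        step_px=step_px,
        kernel=_gaussian_kernel(sigma),
        luminance_change_threshold=END_CONTRAST_FRACTION * peak,
        background=background,
    )


def _slice_midpoint(
    frame: np.ndarray,
    predicted: np.ndarray,
    direction: np.ndarray,
    cal: TrackerCalibration,
) -> tuple[np.ndarray | None, float]:
    """Locate the tail midpoint on the slice through ``predicted``.

    Returns (midpoint, ridge_contrast); midpoint is None when the slice's
    ridge contrast falls below the end-of-tail threshold.
    """
    half = 2.0 * cal.tail_width_px
    n = int(2 * np.ceil(half)) + 1
    offsets = np.linspace(-half, half, n)
    perp = np.array([-direction[1], direction[0]])
    xy = predicted[None] + offsets[:, None] * perp[None]
    raw = _sample(frame, xy)
    smoothed = gaussian_filter1d(raw, sigma=cal.tail_width_px / 2.0, mode="nearest")
    resp = np.convolve(smoothed, cal.kernel, mode="same")
    contrast = float(smoothed.max() - cal.background)
    if contrast < cal.luminance_change_threshold:
        return None, contrast
    # argmax with ties broken toward the predicted midpoint (slice center)
    m = resp.max()
    ties = np.flatnonzero(resp >= m - 1e-9)
    center = (n - 1) / 2.0
    i = int(ties[np.argmin(np.abs(ties - center))])
    # parabolic sub-pixel refinement
    off = offsets[i]
    if 0 < i < n - 1:
        denom = resp[i - 1] - 2 * resp[i] + resp[i + 1]
        if denom < 0:
            off += 0.5 * (resp[i - 1] - resp[i + 1]) / denom * (offsets[1] - offsets[0])
    return predicted + off * perp, contrast


def _refine_tip(
    frame: np.ndarray,
    last: np.ndarray,
    direction: np.ndarray,
    cal: TrackerCalibration,
) -> np.ndarray:
    """March past the last accepted midpoint to locate the tail tip.

    The rendered/imaged stroke fades past the tip with the tail's own
    Gaussian cross-section, so the point where the on-ridge intensity
    drops to half contrast lies ~1.18 sigma beyond the tip; that bias is
    subtracted using the calibrated width.
    """
    sigma = cal.tail_width_px / 2.0
    ts = np.arange(0.0, 3.0 * cal.step_px, 0.25)
    xy = last[None] + ts[:, None] * direction[None]
    vals = _sample(frame, xy) - cal.background
    half_level = 0.5 * cal.tail_contrast
    below = np.flatnonzero(vals < half_level)
    if below.size == 0 or below[0] == 0:
        return last
    i = below[0]
    # linear interpolation of the crossing position
    t_cross = np.interp(half_level, [vals[i], vals[i - 1]], [ts[i], ts[i - 1]])
    t_tip = max(0.0, t_cross - np.sqrt(2.0 * np.log(2.0)) * sigma)
    return last + t_tip * direction


def track_frame(
    frame: np.ndarray,
    base_point: tuple[float, float],
    calibration: TrackerCalibration,
    initial_heading: tuple[float, float] = (0.0, 1.0),
    max_points: int = 80,
) -> np.ndarray | None:
    """Track one frame from base to tail tip.

    Returns an (n, 2) ordered point array, or None when fewer than 10
    points are found (the frame is flagged, not fatal).
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    heading = np.asarray(initial_heading, dtype=float)
    heading = heading / np.linalg.norm(heading)
    # re-center the base point itself on the ridge
    p0, _ = _slice_midpoint(frame, np.asarray(base_point, dtype=float), heading, calibration)
    if p0 is None:
        p0 = np.asarray(base_point, dtype=float)
    points = [p0]
    direction = heading
    for _ in range(max_points - 1):
        predicted = points[-1] + calibration.step_px * direction
        if not (0 <= predicted[0] <= w - 1 and 0 <= predicted[1] <= h - 1):
            break
        nxt, _ = _slice_midpoint(frame, predicted, direction, calibration)
        if nxt is not None:
            # a midpoint past the tail tip still produces a ridge response
            # from the tip blob behind it; reject it by the on-point
            # luminance, which drops sharply past the end of the tail
            v = float(_sample(frame, nxt[None])[0]) - calibration.background
            if v < 0.7 * calibration.tail_contrast:
                nxt = None
        if nxt is None:
            points[-1] = _refine_tip(frame, points[-1], direction, calibration)
            break
        points.append(nxt)
        step_vec = points[-1] - points[-2]
        norm = np.linalg.norm(step_vec)
        if norm > 0:
            direction = step_vec / norm
    if len(points) < 10:
        return None
    return np.asarray(points)


def track_video(
    frames: np.ndarray,
    base_point: tuple[float, float],
    n_points: int = 40,
    step_px: float = DEFAULT_STEP_PX,
    initial_heading: tuple[float, float] = (0.0, 1.0),
    fail_tolerance: float = 0.10,
    frame_rate: float = 300.0,
) -> TailTrace:
    """Digitize a whole video into a :class:`TailTrace`.

    Calibrates on the first frame, tracks every frame, and resamples each
    frame's points to ``n_points`` uniform in arc length. Frames that fail
    tracking are carried as NaN; if more than ``fail_tolerance`` of frames
    fail, a :class:`VideoQualityError` is raised.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("frames must be a (T, H, W) stack with T >= 1")
    cal = calibrate(frames[0], base_point, step_px=step_px, initial_heading=initial_heading)
    T = frames.shape[0]
    out = np.full((T, n_points, 2), np.nan)
    failed = 0
    for t in range(T):
        pts = track_frame(frames[t], base_point, cal, initial_heading=initial_heading)
        if pts is None:
            failed += 1
            continue
        out[t] = resample_points(pts, n_points)
    if failed > fail_tolerance * T:
        raise VideoQualityError(
            f"{failed}/{T} frames failed tracking (tolerance {fail_tolerance:.0%})"
        )
    if failed:
        warnings.warn(f"{failed}/{T} frames failed tracking; carried as NaN")
    first_ok = next(t for t in range(T) if np.isfinite(out[t]).all())
    tail_length = float(arc_lengths(out[first_ok])[-1])
    return TailTrace(points=out, frame_rate=frame_rate, tail_length_px=tail_length)
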