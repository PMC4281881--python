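"""Synthetic ground-truth generator for larval-zebrafish hunting behavior.

The module produces three kinds of artifact, each with exact ground truth
attached, so every downstream stage of the pipeline can be validated
without any recorded data:

* tail-midline kinematics for the three behavior classes
  (``prey_forward`` low-amplitude oscillatory swims, ``j_turn`` sustained
  unilateral bends, ``spontaneous`` high-amplitude routine swims),
* rendered high-speed video of those midlines (bright tail on a dark,
  noisy background, 300 × 300 px by default), and
* fluorescence movies (128 × 128 px by default) with ROI-localized,
  stimulus-tuned ΔF/F responses.

Tail geometry model
-------------------
The tail is an inextensible curve of arc length L whose local tangent
angle at normalized arc position ``s`` is ``phi(s, t) = theta(t) * r(s)``,
where ``r`` is a monotone bend profile with ``r(0) = 0`` and ``r(1) = 1``
and ``theta(t)`` is the bend-angle waveform. Beat-type swims concentrate
the bend near the base (``r`` saturates at ``s0 = 0.15``), so the distal
tail sweeps side to side nearly rigidly; j-turns spread the bend over the
proximal half, producing the characteristic J shape. The nominal
``tip_amplitude`` (peak horizontal tip deflection as a fraction of tail
length) is converted to a peak bend angle by numerically inverting the
tip-deflection integral, so the generator's amplitude parameter is exact
ground truth for the amplitude statistics measured downstream.

Class defaults encode the published kinematic contrasts: prey-capture
forward swims at 17% of tail length, spontaneous swims at 48%, and
spontaneous beat frequency calibrated so that the longest tail bend
exceeding 20° most often lasts ~27 ms at 300 frames/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .core import TailTrace, arc_lengths
from .exceptions import InvalidLayoutError, InvalidParameterError, OutOfBoundsError

BEHAVIOR_CLASSES = ("prey_forward", "j_turn", "spontaneous")

#: arc fraction over which the bend is distributed, per class
BEND_EXTENT = {"prey_forward": 0.15, "spontaneous": 0.15, "j_turn": 0.5}

#: small oscillation superimposed on the j-turn hold so the bend is not
#: perfectly static (real holds show tremor; it also keeps the tail-angle
#: derivative informative throughout the hold)
JTURN_WOBBLE_DEG = 4.5
JTURN_WOBBLE_HZ = 10.0

#: default rendering geometry: base near the top of a 300x300 frame,
#: tail hanging down, leaving lateral room for a 0.6 L deflection
DEFAULT_BASE = (150.0, 50.0)
DEFAULT_TAIL_LENGTH_PX = 180.0


@dataclass(frozen=True)
class KinematicsParams:
    """Ground-truth kinematic parameters for one bout.

    tip_amplitude is the peak horizontal tip deflection as a fraction of
    tail length; hold_* apply only to j-turns; noise_sd is per-point
    coordinate jitter as a fraction of tail length.
    """

    behavior_class: str
    tip_amplitude: float
    beat_frequency: float  # Hz
    bout_duration: float  # ms
    hold_duration: float = 0.0  # ms
    hold_angle: float = 0.0  # degrees (tangent angle at the tip during hold)
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.behavior_class not in BEHAVIOR_CLASSES:
            raise InvalidParameterError(
                f"unknown behavior_class {self.behavior_class!r}"
            )
        if not 0.0 <= self.tip_amplitude <= 1.0:
            raise InvalidParameterError("tip_amplitude must be in [0, 1]")
        if self.bout_duration <= 0:
            raise InvalidParameterError("bout_duration must be positive")
        if self.beat_frequency <= 0:
            raise InvalidParameterError("beat_frequency must be positive")
        if self.hold_duration > 0 and self.behavior_class != "j_turn":
            raise InvalidParameterError(
                "hold_duration > 0 is only valid for j_turn bouts"
            )
        if self.behavior_class == "j_turn":
            if self.hold_duration <= 0:
                raise InvalidParameterError("j_turn requires hold_duration > 0")
            if self.hold_duration >= self.bout_duration:
                raise InvalidParameterError(
                    "bout_duration must exceed hold_duration (ramp + release)"
                )
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")


#: Class defaults. Amplitudes are the published class statistics (17% and
#: 48% of tail length). The spontaneous beat frequency is a calibration
#: choice (no published value exists): 9.2 Hz puts the longest >20° bend
#: at ~8 frames (26.7 ms) at 300 f/s given the 48% amplitude and the
#: basal bend profile. Prey-forward swims beat faster at low amplitude.
_CLASS_DEFAULTS = {
    "prey_forward": dict(
        tip_amplitude=0.17, beat_frequency=16.0, bout_duration=180.0
    ),
    "spontaneous": dict(
        tip_amplitude=0.48, beat_frequency=9.2, bout_duration=280.0
    ),
    "j_turn": dict(
        tip_amplitude=0.54,  # implied by the 45 deg hold over the j profile
        beat_frequency=10.0,
        bout_duration=460.0,
        hold_duration=300.0,
        hold_angle=45.0,
    ),
}


def class_defaults(behavior_class: str) -> KinematicsParams:
    """Default ground-truth parameters for one behavior class."""
    if behavior_class not in _CLASS_DEFAULTS:
        raise InvalidParameterError(f"unknown behavior_class {behavior_class!r}")
    return KinematicsParams(behavior_class=behavior_class, **_CLASS_DEFAULTS[behavior_class])


def sample_params(
    behavior_class: str,
    rng: np.random.Generator,
    amplitude_jitter: float = 0.06,
    frequency_jitter: float = 0.05,
    hold_range_ms: tuple[float, float] = (100.0, 600.0),
) -> KinematicsParams:
    """Draw per-bout parameters around the class defaults.

    Relative amplitude/frequency jitter is Gaussian with mean 1, clipped to
    [0.8, 1.2] (symmetric, so the class mean amplitude is preserved).
    J-turn hold durations are uniform over ``hold_range_ms``.
    """
    base = class_defaults(behavior_class)
    a = float(np.clip(rng.normal(1.0, amplitude_jitter), 0.8, 1.2))
    f = float(np.clip(rng.normal(1.0, frequency_jitter), 0.8, 1.2))
    kw: dict = dict(
        tip_amplitude=base.tip_amplitude * a,
        beat_frequency=base.beat_frequency * f,
    )
    if behavior_class == "j_turn":
        hold = float(rng.uniform(*hold_range_ms))
        kw["hold_duration"] = hold
        kw["bout_duration"] = hold + (base.bout_duration - base.hold_duration)
        kw["hold_angle"] = base.hold_angle * a
        kw["tip_amplitude"] = base.tip_amplitude  # informational for j_turn
    return replace(base, **kw)


@dataclass
class SyntheticTrial:
    """A generated trial: trace plus exact bout ground truth."""

    trace: TailTrace
    bout_truth: list[tuple[int, int, str]]
    frame_rate: float
    seed: int


@dataclass
class RenderedVideo:
    """Rendered grayscale frames with the generating trace attached."""

    frames: np.ndarray  # (T, H, W) float32, intensity units
    ground_truth: TailTrace
    tail_width_px: float
    contrast: float
    background: float
    background_noise_sd: float


@dataclass
class SyntheticFluorescenceMovie:
    """Fluorescence frames with ROI masks and ΔF/F time courses attached."""

    frames: np.ndarray  # (T, H, W) float32
    roi_truth: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (mask, dff)
    baseline_level: float
    noise_sd: float


# ---------------------------------------------------------------------------
# tail geometry


def _bend_profile(s: np.ndarray, extent: float) -> np.ndarray:
    """Cumulative tangent-angle fraction r(s): linear rise to 1 at ``extent``."""
    return np.clip(s / extent, 0.0, 1.0)


def tail_shape(
    theta: float,
    extent: float,
    n_points: int,
    tail_length: float = 1.0,
    base: tuple[float, float] = (0.0, 0.0),
    n_fine: int = 400,
) -> np.ndarray:
    """Midline points for bend angle ``theta`` (radians, + = rightward).

    The curve starts at ``base`` heading down-image (+y) and its tangent
    angle grows as ``theta * r(s)``; returns (n_points, 2) xy coordinates
    uniform in arc length.
    """
    s_fine = np.linspace(0.0, 1.0, n_fine)
    phi = theta * _bend_profile(s_fine, extent)
    # tangent: rest axis +y; positive phi rotates toward +x
    dx = np.sin(phi)
    dy = np.cos(phi)
    ds = 1.0 / (n_fine - 1)
    x = np.concatenate(([0.0], np.cumsum((dx[1:] + dx[:-1]) * 0.5 * ds)))
    y = np.concatenate(([0.0], np.cumsum((dy[1:] + dy[:-1]) * 0.5 * ds)))
    s_out = np.linspace(0.0, 1.0, n_points)
    px = base[0] + tail_length * np.interp(s_out, s_fine, x)
    py = base[1] + tail_length * np.interp(s_out, s_fine, y)
    return np.column_stack([px, py])


def tip_deflection(theta: float, extent: float) -> float:
    """Horizontal tip deflection (fraction of tail length) at bend ``theta``."""
    pts = tail_shape(theta, extent, n_points=2, tail_length=1.0)
    return float(pts[-1, 0])


def bend_angle_for_amplitude(amplitude: float, extent: float) -> float:
    """Invert :func:`tip_deflection`: bend angle giving the tip deflection."""
    if amplitude == 0.0:
        return 0.0
    if not 0.0 < amplitude <= 1.0:
        raise InvalidParameterError("amplitude must be in (0, 1]")
    # deflection is non-monotone once the tail curls past ~90 deg, so
    # bracket the smallest bend angle reaching the requested amplitude
    grid = np.linspace(0.0, np.pi, 200)
    defl = np.array([tip_deflection(th, extent) for th in grid])
    above = np.flatnonzero(defl >= amplitude)
    if above.size == 0:
        raise InvalidParameterError(f"amplitude {amplitude} is unreachable")
    i = above[0]
    if i == 0:
        return float(grid[0])
    return float(
        brentq(lambda th: tip_deflection(th, extent) - amplitude, grid[i - 1], grid[i])
    )


def _apply_jitter(
    pts: np.ndarray, rng: np.random.Generator, sd: float
) -> np.ndarray:
    """Add lateral (perpendicular-to-midline) jitter to a (T, P, 2) stack.

    The jitter models shape uncertainty of an inextensible tail, so it
    displaces points perpendicular to the local tangent only (along-arc
    displacement would be unobservable in an image of the tail). It is
    smoothed along the point axis (sigma = 2 points, unit variance
    restored) because a real midline is smooth at the scale of adjacent
    midpoints, and it ramps up from zero at the base, which is embedded
    and therefore static.
    """
    from scipy.ndimage import gaussian_filter1d

    T, P, _ = pts.shape
    white = rng.standard_normal((T, P))
    lat = gaussian_filter1d(white, sigma=2.0, axis=1, mode="nearest")
    gain = float(np.sqrt(np.mean(lat**2)))
    lat = sd * lat / (gain if gain > 0 else 1.0)
    lat *= np.clip(np.arange(P) / 6.0, 0.0, 1.0)[None]
    # unit normals from the local tangent of the noiseless midline
    tang = np.gradient(pts, axis=1)
    norm = np.linalg.norm(tang, axis=2, keepdims=True)
    tang = tang / np.where(norm > 0, norm, 1.0)
    normal = np.stack([-tang[..., 1], tang[..., 0]], axis=-1)
    return pts + lat[..., None] * normal


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def bend_waveform(params: KinematicsParams, frame_rate: float) -> np.ndarray:
    """Per-frame bend angle theta(t) in radians for one bout.

    Beat classes: a constant-amplitude sinusoid truncated at an integer
    number of half-cycles, so every oscillation peak realizes the nominal
    amplitude and the per-bout mean amplitude equals ``tip_amplitude``.
    J-turns: smoothstep ramp, hold with a small tremor, smoothstep release.
    """
    extent = BEND_EXTENT[params.behavior_class]
    if params.behavior_class == "j_turn":
        theta_hold = np.deg2rad(params.hold_angle)
        ramp = (params.bout_duration - params.hold_duration) / 2.0  # ms
        n = max(2, int(round(params.bout_duration / 1000.0 * frame_rate)))
        t = np.arange(n) / frame_rate * 1000.0  # ms
        up = _smoothstep(t / ramp)
        down = _smoothstep((params.bout_duration - t) / ramp)
        theta = theta_hold * np.minimum(up, down)
        in_hold = (t >= ramp) & (t <= ramp + params.hold_duration)
        wob = np.deg2rad(JTURN_WOBBLE_DEG) * np.sin(
            2 * np.pi * JTURN_WOBBLE_HZ * (t - ramp) / 1000.0
        )
        theta = theta + np.where(in_hold, wob, 0.0)
        return theta
    theta_peak = bend_angle_for_amplitude(params.tip_amplitude, extent)
    f = params.beat_frequency
    dur_s = params.bout_duration / 1000.0
    n_half = max(1, int(round(2.0 * f * dur_s)))
    n = max(2, int(round(n_half / (2.0 * f) * frame_rate)))
    t = np.arange(n) / frame_rate
    return theta_peak * np.sin(2 * np.pi * f * t)


def generate_bout(
    params: KinematicsParams,
    frame_rate: float = 300.0,
    tail_points: int = 40,
    seed: int = 0,
    base: tuple[float, float] = DEFAULT_BASE,
    tail_length_px: float = DEFAULT_TAIL_LENGTH_PX,
) -> TailTrace:
    """Generate one bout as a :class:`TailTrace` (deterministic under seed)."""
    if tail_points < 10:
        raise InvalidParameterError("tail_points must be >= 10")
    if frame_rate <= 0:
        raise InvalidParameterError("frame_rate must be positive")
    theta = bend_waveform(params, frame_rate)
    extent = BEND_EXTENT[params.behavior_class]
    pts = np.stack(
        [tail_shape(th, extent, tail_points, tail_length_px, base) for th in theta]
    )
    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        pts = _apply_jitter(pts, rng, params.noise_sd * tail_length_px)
    return TailTrace(points=pts, frame_rate=frame_rate, tail_length_px=tail_length_px)


def generate_trial(
    class_sequence: list[KinematicsParams],
    rest_durations: list[float],
    frame_rate: float = 300.0,
    seed: int = 0,
    tail_points: int = 40,
    base: tuple[float, float] = DEFAULT_BASE,
    tail_length_px: float = DEFAULT_TAIL_LENGTH_PX,
    rest_noise_sd: float = 0.005,
) -> SyntheticTrial:
    """Interleave rest segments and bouts into one trial with bout truth.

    ``rest_durations`` (ms) must have ``len(class_sequence) + 1`` entries:
    rest, bout, rest, ..., bout, rest. An empty ``class_sequence`` with a
    single rest duration yields an all-rest trial with empty truth.
    """
    if len(rest_durations) != len(class_sequence) + 1:
        raise InvalidParameterError(
            "rest_durations must have len(class_sequence) + 1 entries"
        )
    if not rest_durations and not class_sequence:
        raise InvalidParameterError("trial would be empty")
    rng = np.random.default_rng(seed)
    segments: list[np.ndarray] = []
    bout_truth: list[tuple[int, int, str]] = []
    straight = tail_shape(0.0, 0.15, tail_points, tail_length_px, base)
    cursor = 0

    def rest_segment(dur_ms: float) -> np.ndarray:
        n = int(round(dur_ms / 1000.0 * frame_rate))
        seg = np.repeat(straight[None], n, axis=0)
        if rest_noise_sd > 0 and n:
            seg = _apply_jitter(seg, rng, rest_noise_sd * tail_length_px)
        return seg

    for i, params in enumerate(class_sequence):
        seg = rest_segment(rest_durations[i])
        segments.append(seg)
        cursor += seg.shape[0]
        bout = generate_bout(
            params,
            frame_rate,
            tail_points,
            seed=int(rng.integers(0, 2**31 - 1)),
            base=base,
            tail_length_px=tail_length_px,
        )
        segments.append(bout.points)
        bout_truth.append(
            (cursor, cursor + bout.n_frames, params.behavior_class)
        )
        cursor += bout.n_frames
    segments.append(rest_segment(rest_durations[-1]))
    pts = np.concatenate(segments, axis=0)
    if pts.shape[0] == 0:
        raise InvalidParameterError("trial has zero frames")
    trace = TailTrace(points=pts, frame_rate=frame_rate, tail_length_px=tail_length_px)
    return SyntheticTrial(trace=trace, bout_truth=bout_truth, frame_rate=frame_rate, seed=seed)


# ---------------------------------------------------------------------------
# video rendering


def render_video(
    trace: TailTrace,
    tail_width_px: float = 5.0,
    contrast: float = 180.0,
    background: float = 10.0,
    background_noise_sd: float = 5.0,
    seed: int = 0,
    shape: tuple[int, int] = (300, 300),
    margin: float = 2.0,
) -> RenderedVideo:
    """Render a trace as grayscale frames: bright tail stroke on dark noise.

    The stroke's cross-section is Gaussian with sigma = tail_width_px / 2,
    so the intensity ridge coincides with the midline exactly.
    """
    h, w = shape
    pts = trace.points
    bad = (
        (pts[..., 0] < margin)
        | (pts[..., 0] > w - 1 - margin)
        | (pts[..., 1] < margin)
        | (pts[..., 1] > h - 1 - margin)
    )
    if bad.any():
        frame = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise OutOfBoundsError(
            f"trace leaves the {h}x{w} frame (first offending frame: {frame})"
        )
    sigma = tail_width_px / 2.0
    pad = int(np.ceil(3.0 * sigma)) + 1
    rng = np.random.default_rng(seed)
    frames = np.empty((trace.n_frames, h, w), dtype=np.float32)
    for i in range(trace.n_frames):
        img = np.full((h, w), background, dtype=np.float32)
        p = pts[i]
        # dense resample so a nearest-sample distance approximates the
        # distance to the continuous midline
        s = arc_lengths(p)
        n_dense = max(2, int(np.ceil(s[-1] / 0.25)))
        t = np.linspace(0, s[-1], n_dense)
        dense = np.column_stack(
            [np.interp(t, s, p[:, 0]), np.interp(t, s, p[:, 1])]
        )
        # evaluate the stroke only on a band of pixels within `pad` of the
        # curve (everything further is indistinguishable from background)
        cx = np.round(dense[:, 0]).astype(int)
        cy = np.round(dense[:, 1]).astype(int)
        off = np.arange(-pad, pad + 1)
        bx = (cx[:, None] + off[None]).ravel()
        by = np.repeat(cy, off.size)
        band = np.unique(
            np.clip(by, 0, h - 1) * w + np.clip(bx, 0, w - 1)
        )
        # widen vertically too
        band = np.unique(
            (band[:, None] + (off * w)[None]).ravel()
        )
        band = band[(band >= 0) & (band < h * w)]
        qy, qx = np.divmod(band, w)
        q = np.column_stack([qx, qy]).astype(float)
        d, _ = cKDTree(dense).query(q, k=1)
        img.ravel()[band] += (
            contrast * np.exp(-0.5 * (d / sigma) ** 2)
        ).astype(np.float32)
        frames[i] = img
    if background_noise_sd > 0:
        frames += rng.normal(0.0, background_noise_sd, frames.shape).astype(
            np.float32
        )
    np.clip(frames, 0.0, 255.0, out=frames)
    return RenderedVideo(
        frames=frames,
        ground_truth=trace,
        tail_width_px=tail_width_px,
        contrast=contrast,
        background=background,
        background_noise_sd=background_noise_sd,
    )


# ---------------------------------------------------------------------------
# fluorescence movies


def generate_fluorescence_movie(
    roi_layout: dict[str, np.ndarray],
    responses: dict[str, np.ndarray],
    n_frames: int,
    baseline_level: float = 100.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
) -> SyntheticFluorescenceMovie:
    """Synthesize a movie where each ROI follows its ΔF/F time course.

    Pixel model: baseline * (1 + dff(t)) inside an ROI, baseline outside,
    plus additive Gaussian noise everywhere.
    """
    if n_frames <= 25:
        raise InvalidParameterError("n_frames must exceed 25")
    occupancy = np.zeros(shape, dtype=int)
    for name, mask in roi_layout.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise InvalidLayoutError(f"mask {name!r} has shape {mask.shape}, want {shape}")
        occupancy += mask
    if (occupancy > 1).any():
        raise InvalidLayoutError("ROI masks overlap")
    frames = np.full((n_frames,) + shape, baseline_level, dtype=np.float32)
    roi_truth: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, mask in roi_layout.items():
        mask = np.asarray(mask, dtype=bool)
        dff = np.asarray(responses.get(name, np.zeros(n_frames)), dtype=float)
        if dff.shape != (n_frames,):
            raise InvalidParameterError(
                f"response for {name!r} must have length n_frames"
            )
        frames[:, mask] += (baseline_level * dff[:, None]).astype(np.float32)
        roi_truth[name] = (mask, dff)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)
    return SyntheticFluorescenceMovie(
        frames=frames,
        roi_truth=roi_truth,
        baseline_level=baseline_level,
        noise_sd=noise_sd,
    )


def default_roi_layout(shape: tuple[int, int] = (128, 128)) -> dict[str, np.ndarray]:
    """Two disjoint square ROIs mimicking a prey-tuned and a large-stimulus
    arborization field in one imaging plane."""
    prey = np.zeros(shape, dtype=bool)
    prey[28:40, 28:40] = True
    large = np.zeros(shape, dtype=bool)
    large[80:92, 80:92] = True
    return {"prey_tuned": prey, "large_stimulus": large}


def size_tuning(size_deg: float, kind: str = "prey") -> float:
    """Relative response (0..1) of an ROI to a dot of the given diameter.

    ``prey``: log-Gaussian bump peaking at 2.5°, nearly silent above ~6°
    (the prey-selective profile). ``large``: sigmoid in log size that turns
    on above ~6° (the large-stimulus profile).
    """
    ls = np.log2(size_deg)
    if kind == "prey":
        return float(np.exp(-0.5 * ((ls - np.log2(2.5)) / 0.55) ** 2))
    if kind == "large":
        return float(1.0 / (1.0 + np.exp(-(ls - 3.0) / 0.5)))
    raise InvalidParameterError(f"unknown tuning kind {kind!r}")


def speed_tuning(speed_deg_s: float) -> float:
    """Prey-stimulus speed tuning: log-Gaussian bump peaking at 90°/s."""
    ls = np.log2(speed_deg_s / 90.0)
    return float(np.exp(-0.5 * (ls / 1.2) ** 2))


def calcium_response(
    n_frames: int,
    onset_frame: int,
    peak: float,
    stimulus_frames: int = 4,
    decay_frames: float = 6.0,
) -> np.ndarray:
    """Stimulus-locked ΔF/F time course: plateau then exponential decay."""
    t = np.arange(n_frames, dtype=float)
    dff = np.zeros(n_frames)
    on = (t >= onset_frame) & (t < onset_frame + stimulus_frames)
    dff[on] = peak
    after = t >= onset_frame + stimulus_frames
    dff[after] = peak * np.exp(
        -(t[after] - onset_frame - stimulus_frames + 1) / decay_frames
    )
    return dff
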