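"""Shared data containers: tail traces and swim bouts.

Coordinates are 0-based pixels, origin at the image top-left, x rightward,
y downward. A resting tail points down the image (+y), so lateral tail
deflection is horizontal (x) displacement — the convention used by the
head-embedded preparation the tracker is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TailTrace:
    """Per-frame ordered tail midpoints, base to tip.

    Parameters
    ----------
    points : ndarray, shape (n_frames, n_points, 2)
        (x, y) pixel coordinates for every midpoint in every frame.
        NaN rows mark frames where tracking failed.
    frame_rate : float
        Acquisition rate in frames per second.
    tail_length_px : float
        Base-to-tip arc length of the tail in the first frame, in pixels.
    """

    points: np.ndarray
    frame_rate: float
    tail_length_px: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must have shape (n_frames, n_points, 2)")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    @property
    def base(self) -> np.ndarray:
        """Base point of the first frame, shape (2,)."""
        return self.points[0, 0]

    def tip_x(self) -> np.ndarray:
        """Horizontal position of the tail tip in every frame."""
        return self.points[:, -1, 0]


@dataclass(frozen=True)
class Bout:
    """A half-open frame interval [start_frame, end_frame) of tail movement."""

    start_frame: int
    end_frame: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError(
                f"start_frame ({self.start_frame}) must precede end_frame "
                f"({self.end_frame})"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def duration_ms(self, frame_rate: float) -> float:
        return 1000.0 * self.n_frames / frame_rate


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along one frame's point list, starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate(([0.0], np.cumsum(seg)))


def resample_points(points: np.ndarray, n_out: int) -> np.ndarray:
    """Resample an ordered point list to ``n_out`` points uniform in arc length."""
    s = arc_lengths(points)
    if s[-1] <= 0:
        return np.repeat(points[:1], n_out, axis=0)
    target = np.linspace(0.0, s[-1], n_out)
    x = np.interp(target, s, points[:, 0])
    y = np.interp(target, s, points[:, 1])
    return np.column_stack([x, y])
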