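"""Shared fixtures: generated trials and rendered videos are expensive,
so the ones several test modules need are session scoped."""

from __future__ import annotations

import numpy as np
import pytest

from preycap.core import Bout, TailTrace
from preycap.kinematics import KinematicSeries
from preycap.synthetic import (
    class_defaults,
    generate_trial,
    render_video,
    sample_params,
)


@pytest.fixture(scope="session")
def spont_trial():
    """One spontaneous-swim trial (rest-bout-rest) with default kinematics."""
    return generate_trial([class_defaults("spontaneous")], [100.0, 100.0], seed=11)


@pytest.fixture(scope="session")
def spont_video(spont_trial):
    return render_video(spont_trial.trace, seed=12)


@pytest.fixture(scope="session")
def rest_video():
    """Rendered 100-frame all-rest trial, with its ground truth attached."""
    trial = generate_trial([], [100 / 300 * 1000.0], seed=21)
    return render_video(trial.trace, seed=22)


def make_series(
    tail_angle=None,
    tip_position=None,
    frame_rate: float = 300.0,
    n: int | None = None,
) -> KinematicSeries:
    """Hand-built series for oracle tests on single signals."""
    if tail_angle is None and tip_position is None:
        raise ValueError("give at least one signal")
    if tail_angle is None:
        tail_angle = np.zeros_like(np.asarray(tip_position, dtype=float))
    tail_angle = np.asarray(tail_angle, dtype=float)
    n = len(tail_angle)
    if tip_position is None:
        tip_position = np.zeros(n)
    tip_position = np.asarray(tip_position, dtype=float)
    z = np.zeros(n)
    return KinematicSeries(
        tail_angle=tail_angle,
        tip_angle=z.copy(),
        tip_position=tip_position,
        tip_region_position=tip_position.copy(),
        tail_position_12plus=tip_position.copy(),
        curvature=z.copy(),
        frame_rate=frame_rate,
        tail_length=180.0,
    )
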