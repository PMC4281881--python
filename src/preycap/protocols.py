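"""Reproduction workflows for the study's headline quantities.

Each function regenerates its synthetic inputs from a seed, runs the
relevant pipeline stages, and returns the measured quantity:

* :func:`classifier_cv_accuracy` — pooled fivefold stratified CV accuracy
  of the RBF-SVM on the first five bout parameters, with the study's
  class sizes (248 prey-capture vs 121 spontaneous bouts).
* :func:`amplitude_recovery` — class-mean tail-beat amplitude through the
  full video pipeline (render → track → segment → amplitude).
* :func:`bend_duration_mode` — modal longest->20°-bend duration of
  spontaneous bouts in one-frame (3.33 ms) bins.
"""

from __future__ import annotations

import numpy as np

from .classifier import cross_validate
from .core import Bout
from .datasets import labeled_bout_set
from .features import VIRTUAL_PREY_FEATURES
from .kinematics import (
    bout_amplitude,
    compute_series,
    longest_bend_duration,
    segment_bouts,
)
from .synthetic import generate_trial, render_video, sample_params
from .tracking import track_video


def classifier_cv_accuracy(
    seed: int = 0,
    n_prey: int = 248,
    n_spontaneous: int = 121,
    folds: int = 5,
) -> float:
    """Pooled CV accuracy (fraction) on parameters 1-5, default class sizes."""
    data = labeled_bout_set(n_prey=n_prey, n_spontaneous=n_spontaneous, seed=seed)
    report = cross_validate(data, VIRTUAL_PREY_FEATURES, folds=folds, seed=seed)
    return report.pooled_accuracy


def amplitude_recovery(
    behavior_class: str,
    n_bouts: int = 100,
    seed: int = 0,
    rest_ms: float = 100.0,
) -> float:
    """Mean per-bout amplitude (fraction of tail length) via the full
    render → track → segment → amplitude pipeline."""
    rng = np.random.default_rng(seed)
    amps = []
    for _ in range(n_bouts):
        params = sample_params(behavior_class, rng)
        trial = generate_trial(
            [params], [rest_ms, rest_ms], seed=int(rng.integers(0, 2**31 - 1))
        )
        video = render_video(trial.trace, seed=int(rng.integers(0, 2**31 - 1)))
        trace = track_video(video.frames, tuple(trial.trace.points[0, 0]))
        series = compute_series(trace)
        bouts = segment_bouts(series)
        if not bouts:
            continue
        bout = max(bouts, key=lambda b: b.n_frames)
        amps.append(bout_amplitude(series, bout))
    return float(np.mean(amps))


def bend_duration_mode(
    n_bouts: int = 200,
    seed: int = 0,
    frame_rate: float = 300.0,
    angle_threshold: float = 20.0,
) -> float:
    """Modal longest-bend duration (ms) over spontaneous bouts.

    Durations are multiples of one frame, so the histogram uses one-frame
    (1000/frame_rate ms) bins centered on those multiples; returns the
    modal bin center.
    """
    rng = np.random.default_rng(seed)
    durations = []
    for _ in range(n_bouts):
        params = sample_params("spontaneous", rng)
        trial = generate_trial(
            [params], [100.0, 100.0], seed=int(rng.integers(0, 2**31 - 1))
        )
        series = compute_series(trial.trace)
        start, end, _ = trial.bout_truth[0]
        durations.append(
            longest_bend_duration(series, Bout(start, end), angle_threshold)
        )
    frames = np.round(np.asarray(durations) * frame_rate / 1000.0).astype(int)
    mode_frames = np.bincount(frames).argmax()
    return float(mode_frames * 1000.0 / frame_rate)
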