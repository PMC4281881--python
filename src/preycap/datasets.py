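"""Assembly of labeled synthetic bout sets for classifier experiments.

Emulates the study design of the published classifier: an expert-labeled
set of prey-capture bouts (forward swims plus j-turns) and spontaneous
swims, each bout generated with per-bout parameter jitter around the
class defaults, turned into kinematic series and the 16-parameter
feature vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import LabeledBoutSet
from .core import Bout
from .features import FEATURE_NAMES, extract_features
from .kinematics import compute_series
from .synthetic import generate_trial, sample_params

#: fraction of prey-capture bouts generated as j-turns (the remainder are
#: forward swims); prey-capture behavior comprises both maneuver types
JTURN_FRACTION = 0.3


def _single_bout_trial(behavior_class: str, rng: np.random.Generator, frame_rate: float):
    params = sample_params(behavior_class, rng)
    rest = (100.0, 100.0)
    trial = generate_trial(
        [params], list(rest), frame_rate=frame_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return trial, params


def labeled_bout_set(
    n_prey: int = 248,
    n_spontaneous: int = 121,
    seed: int = 0,
    frame_rate: float = 300.0,
    j_turn_fraction: float = JTURN_FRACTION,
) -> LabeledBoutSet:
    """Generate a labeled training set with the study's class sizes.

    Each bout is generated as its own short trial (rest–bout–rest),
    features are extracted on the ground-truth bout interval, and the
    bout is labeled 'prey_capture' or 'spontaneous'.
    """
    rng = np.random.default_rng(seed)
    rows, labels, prov = [], [], []
    n_jturn = int(round(j_turn_fraction * n_prey))
    plan = (
        [("j_turn", "prey_capture")] * n_jturn
        + [("prey_forward", "prey_capture")] * (n_prey - n_jturn)
        + [("spontaneous", "spontaneous")] * n_spontaneous
    )
    for i, (behavior_class, label) in enumerate(plan):
        trial, params = _single_bout_trial(behavior_class, rng, frame_rate)
        series = compute_series(trial.trace)
        start, end, _ = trial.bout_truth[0]
        rows.append(extract_features(series, Bout(start, end)))
        labels.append(label)
        prov.append({"trial_id": i, "bout_id": 0, "behavior_class": behavior_class})
    features = pd.DataFrame(rows, columns=FEATURE_NAMES)
    return LabeledBoutSet(
        features=features,
        labels=np.asarray(labels, dtype=object),
        provenance=pd.DataFrame(prov),
    )
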