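# preycap

Quantitative analysis of prey-capture behavior in larval zebrafish, from
high-speed video to classified swim bouts, plus the matching
calcium-imaging response statistics.

Head-embedded zebrafish larvae respond to prey (paramecia, or small
moving dots) with a distinctive motor program: low-amplitude forward
swims and sustained unilateral j-turns, quite unlike their high-amplitude
spontaneous swims. `preycap` implements the full measurement chain used
to quantify this behavior:

1. **Tail tracking** — digitize each 300 f/s video frame into ~40 ordered
   midline points by iterative ridge following (predict, slice, smooth,
   correlate with a tail-like kernel, take the maximum).
2. **Kinematics** — per-frame tail angle θ(t) (center-of-mass deflection),
   tip angle, tip deflection and curvature; swim bouts segmented by
   thresholding the normalized, smoothed derivative dθ/dt.
3. **Features** — 16 per-bout parameters (max curvature, peak counts,
   mean tip angle, spectral band powers, ...).
4. **Classification** — an RBF-kernel SVM separating prey-capture from
   spontaneous bouts with fivefold stratified cross-validation, greedy
   parameter-count selection, per-trial prey-capture scores
   (% of trial time in prey-capture bouts) and stimulus tuning curves.
5. **Imaging** — pixelwise ΔF/F with a sliding-percentile baseline
   (8th percentile over 25 frames), before/after condition-ratio maps,
   ROI tuning curves, and normality-gated two-group statistics
   (Jarque–Bera → t-test or Wilcoxon rank sum, with Levene's test).

No raw recordings are distributed with the original analysis, so the
package includes a synthetic generator (`preycap.synthetic`) that
produces tail traces, rendered videos and fluorescence movies with exact
ground truth; its defaults encode the published class statistics
(prey-capture amplitude 17% of tail length vs 48% for spontaneous swims;
spontaneous longest->20°-bend mode at ~27 ms). See `docs/methods.md` for
the model and every numerical convention.

## Worked example

```python
import numpy as np
from preycap import (
    class_defaults, sample_params, generate_trial, render_video,
    compute_series, segment_bouts, bout_amplitude,
)
from preycap.tracking import track_video

rng = np.random.default_rng(0)
trial = generate_trial(
    [sample_params("prey_forward", rng), sample_params("spontaneous", rng)],
    rest_durations=[300.0, 300.0, 300.0],  # ms
    seed=1,
)
video = render_video(trial.trace, seed=2)            # 300x300 px, 300 f/s
trace = track_video(video.frames, base_point=(150.0, 50.0))
series = compute_series(trace)
for bout, (start, end, cls) in zip(segment_bouts(series), trial.bout_truth):
    amp = bout_amplitude(series, bout)
    print(f"{cls:>13}: frames {bout.start_frame:3d}-{bout.end_frame:3d} "
          f"(truth {start}-{end}), amplitude {100*amp:.1f}% of tail length")
```

Output:

```
 prey_forward: frames  89-150 (truth 90-147), amplitude 17.6% of tail length
  spontaneous: frames 236-321 (truth 237-318), amplitude 49.9% of tail length
```

The detected bouts match the generator's ground-truth intervals to within
a couple of frames, and the recovered tail-beat amplitudes show the
class contrast the classifier exploits: the prey-capture forward swim
moves the tail about a third as far as the spontaneous swim.

Training and validating the bout classifier on a synthetic labeled set
with the study's class sizes:

```python
from preycap.classifier import cross_validate
from preycap.datasets import labeled_bout_set
from preycap.features import VIRTUAL_PREY_FEATURES

data = labeled_bout_set(n_prey=248, n_spontaneous=121, seed=42)
report = cross_validate(data, VIRTUAL_PREY_FEATURES, folds=5, seed=0)
print(f"pooled CV accuracy: {report.pooled_accuracy:.1%}")
```

```
pooled CV accuracy: 100.0%
```

A command-line interface mirrors the pipeline (`preycap synth`, `track`,
`segment`, `features`, `train`, `cv`, `select-params`, `classify`,
`score`, `dff`, `tuning`, `demo`); `preycap demo --out run/` executes the
whole behavioral chain on synthetic data and writes every intermediate
artifact plus a manifest with the config hash and seeds.

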