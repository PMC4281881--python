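# Methods

`preycap` reimplements a quantitative pipeline for classifying hunting
behavior in head-embedded larval zebrafish from high-speed video, together
with the accompanying calcium-imaging response analysis. Because no raw
recordings accompany the published analysis, the package ships a synthetic
generator whose defaults encode the published kinematic statistics; every
downstream stage is validated against that generator's exact ground truth.

## Synthetic behavior generator

**Tail geometry.** The tail is modelled as an inextensible planar curve of
arc length L (180 px by default, hanging down-image from a fixed base at
(150, 50) in a 300 × 300 px frame). Its local tangent angle at normalized
arc position `s` is `phi(s, t) = theta(t) · r(s)` with a monotone bend
profile `r` (0 at the base, 1 at the tip). Beat-type swims concentrate the
bend near the base (`r` saturates at s = 0.15), so the distal tail sweeps
nearly rigidly; j-turns spread the bend over the proximal half of the
tail, producing the characteristic J posture. Positions are obtained by
integrating the tangent on a fine grid and resampling 40 points uniform in
arc length.

**Amplitude as ground truth.** The class parameter `tip_amplitude` is the
peak horizontal tip deflection as a fraction of tail length; it is
converted to a peak bend angle by numerically inverting the tip-deflection
integral. The beat waveform is a constant-amplitude sinusoid truncated at
an integer number of half-cycles rather than a decaying oscillation: the
per-bout amplitude statistic downstream is the mean peak-to-trough
half-amplitude over cycles, and with a constant envelope that mean equals
the nominal amplitude exactly, so the generator parameter *is* the ground
truth the pipeline is checked against. Defaults: prey-capture forward
swims 0.17 and spontaneous swims 0.48 of tail length — the published
class statistics.

**Beat frequency (calibration).** No tail-beat frequency is published for
either class; frequencies here are calibration choices, not reported
values. The spontaneous default (9.2 Hz) was chosen, together with the
48% amplitude and the basal bend profile, so that the longest continuous
tail bend exceeding 20° most often lasts 8 frames ≈ 27 ms at 300
frames/s, reproducing the published bend-duration mode. Prey-forward
swims default to 16 Hz, a faster low-amplitude beat.

**J-turns.** A smoothstep ramp to a sustained bend (tangent hold angle
45°, hold 100–600 ms) and a smoothstep release. A 4.5° tremor at 10 Hz is
superimposed on the hold: real holds are not perfectly static, and the
tremor keeps the tail-angle derivative informative so threshold-based
segmentation sees the hold as part of one continuous bout.

**Noise.** Per-point jitter (sd 0.5% of tail length) is applied
perpendicular to the midline, smoothed along the point axis (sigma = 2
points), and ramped to zero at the base. Lateral-only jitter is the
physically meaningful shape noise for an inextensible tail with an
embedded base; an along-arc component would be invisible in the rendered
image and would only corrupt the ground truth it is supposed to define.
Per-bout variation: amplitude and frequency multipliers ~ N(1, 0.06) and
N(1, 0.05), clipped to [0.8, 1.2] (symmetric, so class means are
preserved).

**Rendering.** Each frame draws the midline as a bright stroke with a
Gaussian cross-section (sigma = width/2, default width 5 px, contrast 180
over background 10) on a noisy background (sd 5), evaluated from exact
point-to-curve distances on a band around the curve. The intensity ridge
therefore coincides with the ground-truth midline, which the rendering
tests verify by per-row argmax.

**Fluorescence movies.** 128 × 128 px stacks in which each named,
disjoint ROI follows a prescribed ΔF/F time course on a constant baseline
(pixel = baseline × (1 + ΔF/F) + Gaussian noise). Stimulus tuning helpers
provide a prey-tuned profile (log-Gaussian over dot diameter, peak 2.5°,
nearly silent above ~6°), a large-stimulus profile (sigmoid turning on
above ~6°), and a speed profile peaking at 90°/s. Shot noise,
photobleaching and motion are deliberately not modelled — the movies
exercise percentile baselining and ROI statistics, not registration.

## Tail tracking

Calibration on the first frame measures the tail's width (second-moment
width of the background-subtracted profile perpendicular to the initial
heading) and contrast (profile peak minus median background); both refine
the rest of the tracking. Tracking iterates from the user-supplied base
point: the next midpoint is predicted by linear extrapolation of the last
segment at a 5 px step, an intensity slice of length 4 × width is sampled
perpendicular to the prediction (bilinear interpolation), smoothed
(Gaussian, sd = width/2), correlated with a Gaussian ridge kernel matched
to the calibrated width, and the maximum — ties broken toward the
prediction, refined to sub-pixel by a parabola — becomes the midpoint.

The end of the tail fires on a luminance-change test: the slice's ridge
contrast falling below 30% of the calibrated contrast. Two guards keep
the tip honest: a candidate midpoint whose on-point luminance is below
70% of the calibrated contrast is rejected (a slice placed past the tip
still sees ridge response from the tip blob behind it), and the final tip
is located by marching along the ridge to the half-contrast crossing and
subtracting the sqrt(2 ln 2)·sigma offset that the stroke's own Gaussian
falloff imposes. Each frame is resampled to exactly 40 points uniform in
arc length; frames with fewer than 10 found points are carried as
missing, and a video with more than 10% such frames is rejected.

## Kinematic series and segmentation

Signals per frame: tail angle (deflection of the midline's center of mass
from the rest axis, degrees, rightward positive), tip angle (principal
direction of the last eight points), tip deflection (last point,
fraction of tail length) plus the last-8-centroid and point-12-to-end
deflections used by the positional features, and the maximum absolute
three-point circumscribed-circle curvature in 1/tail-length units. The
rest axis defaults to the modal base-to-tip direction (densest 1°
histogram bin, median-refined), which stays anchored to rest posture even
in trials dominated by long holds; an explicit override is accepted. The
center-of-mass angle uses the trace-wide median base point, since the
base is embedded and static.

Bout segmentation thresholds the first derivative of the tail angle after
moving-average smoothing (5 frames) and normalization by a robust scale.
The scale is the 25th percentile of absolute deviations divided by 0.3186
(the Gaussian-consistent constant): a low quantile rather than the median
because the classical MAD loses robustness exactly in bout-heavy trials.
Frames above 3.0 scale units are active; active runs closed over gaps
shorter than 15 frames and runs shorter than 10 frames dropped. The same
operation serves optomotor swim counting. The estimator presumes trials
are rest-dominated (at least roughly half resting frames), which matches
the sparse-swim recordings it is designed for; segmentation of clips that
are mostly continuous movement would need an explicit scale.

Per-bout statistics: the longest bend is the longest run of frames with
|tail angle| above 20° (ms); the bout amplitude is the mean peak-to-trough
half-amplitude of the tip deflection over the bout's oscillation cycles
(alternating extrema with an adaptive prominence floor), falling back to
max |deflection| for single-deflection bouts such as j-turns.

## The 16 bout parameters

As enumerated for the classifier: max/mean tail curvature, number of
peaks in the (rectified) tail angle, mean |tip angle|, max |tail angle|,
mean tip-region deflection, mean inter-peak interval (missing for bouts
with fewer than two peaks; imputed with the training-set median before
classification), medium- and low-band spectral power of the tail angle
(5–30 Hz and 0.5–5 Hz by default; mean squared one-sided DFT magnitude
after mean removal), signed mean and at-max differences between the tail
and tip-center-of-mass deflection angles, tail-angle variance, |mean tip
angle|, mean point-12+ deflection, mean difference between curvature and
|tail angle| (radians), and max |tip deflection|. Positional and angular
aggregates are rectified so that all features except the two signed
tail-vs-tip comparisons are mirror invariant, which the property suite
asserts on generated bouts. Peaks require 2° prominence; both choices are
config-exposed.

## Classification

An RBF-kernel SVM (scikit-learn, C = 1, gamma = 'scale' by default) on
features centered and scaled by training statistics. Cross-validation is
fivefold and stratified; within each class, rows are sorted by the first
feature and dealt to folds in a serpentine pattern, which balances both
fold sizes (within one) and fold means of the leading feature, and makes
fold assignment a function of data content — permuting rows cannot change
the pooled accuracy. Both pooled accuracy (all held-out predictions
combined) and per-fold accuracies are reported, since published accuracy
figures can follow either convention. Parameter-count selection
cross-validates nested prefixes of a candidate ordering (default: ranked
by single-feature CV accuracy) and picks the smallest count within 0.5
percentage points of the curve maximum.

The default labeled set mirrors the study design: 248 prey-capture bouts
(70% forward swims, 30% j-turns) versus 121 spontaneous swims, features
extracted on ground-truth bout intervals. The prey-capture score of a
trial is 100 × (frames in prey-capture-labeled bouts)/(trial frames);
tuning curves express each larva's scores as percent of that larva's
maximum and report mean ± SEM across larvae, excluding all-zero larvae.

## Imaging analysis

ΔF/F is computed pixelwise as (F − F0)/F0 with F0 the 8th percentile of
the pixel's fluorescence over a sliding 25-frame window — centered, with
truncated windows at the movie's edges, and linear interpolation between
order statistics (the same convention as the test oracle, which sorts and
ranks each window independently). Pixels with non-positive baseline are
masked and counted. Percentile baselining is intentionally conservative:
in noisy data it sits slightly below the mean resting level, giving ΔF/F
a small positive offset — the ROI-recovery test therefore isolates the
response statistics with a known baseline. Condition-ratio maps divide
temporal-max projections of two ΔF/F segments (after vs before prey
delivery), masking pixels whose pre-segment max is below 0.05 to avoid
dividing by noise. ROI responses are spatial means over masks with
their per-trial peaks; tuning across larvae normalizes per-larva to the
maximum (assumed positive) response. Movies are assumed registered; a
phase-correlation drift detector warns when any frame has shifted more
than 2 px against the first.

Two-group comparisons follow the gated recipe: Jarque–Bera normality on
each sample at alpha = 0.05; both normal → two-sample t-test, otherwise
the Wilcoxon rank-sum test (exact enumeration when both samples are small
and tie-free, otherwise the normal approximation without continuity
correction so that identical samples give p = 1); Levene's variance test
is reported alongside. Samples under n = 3 are rejected.

## Problem sizes and determinism

The reproduction workflows in `preycap.protocols` use the study's own
sizes: 248 + 121 bouts for classifier validation, 100 rendered bouts per
class for amplitude recovery, 200 bouts for the bend-duration histogram;
the property suites use 100 seeded trials (segmentation) and 200 movies
(ROI recovery). Every generator consumes an explicit seed and regenerates
bit-identical output; the pipeline runner derives per-stage substreams
from one master seed by hashing, and its manifest records the config hash.

## Limitations

The generator is a kinematic emulation, not a biomechanical fish: it
encodes the published class statistics (amplitudes, bend-duration mode,
class sizes) but invents waveforms, beat frequencies and noise structure
where none are published. Passing tests therefore demonstrate that the
pipeline recovers the statistics a data set is built on — not performance
on real video, where eye/yolk structures, illumination gradients,
paramecia and motion blur would stress the tracker. Prey-forward bouts
under the defaults never exceed the 20° bend threshold, so the secondary
published observation that prey-capture bouts share the 27 ms bend mode
is not reproduced by the defaults. Free-swimming fish, eye tracking,
registration, spike inference and anatomical segmentation are out of
scope.
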