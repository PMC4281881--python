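"""Generator-level checks: determinism, class-separating kinematics,
rendering fidelity, and fluorescence-movie ground truth."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from preycap.core import Bout, arc_lengths
from preycap.exceptions import (
    InvalidLayoutError,
    InvalidParameterError,
    OutOfBoundsError,
)
from preycap.kinematics import bout_amplitude, compute_series, longest_bend_duration
from preycap.synthetic import (
    KinematicsParams,
    calcium_response,
    class_defaults,
    default_roi_layout,
    generate_bout,
    generate_fluorescence_movie,
    generate_trial,
    render_video,
    sample_params,
    size_tuning,
)


class TestGenerateBout:
    def test_zero_amplitude_no_noise_gives_straight_tail(self):
        p = KinematicsParams("prey_forward", 0.0, 16.0, 180.0, noise_sd=0.0)
        trace = generate_bout(p, seed=0)
        x = trace.points[..., 0]
        assert np.allclose(x, x[0, 0])

    def test_peak_tip_deflection_matches_amplitude(self):
        # oracle: direct max over generated tip coordinates
        p = KinematicsParams("prey_forward", 0.17, 16.0, 180.0, noise_sd=0.0)
        trace = generate_bout(p, seed=1)
        defl = np.abs(trace.points[:, -1, 0] - trace.points[:, 0, 0])
        assert np.max(defl) / trace.tail_length_px == pytest.approx(0.17, rel=0.01)

    def test_jturn_hold_sustains_bend_over_20_degrees(self):
        p = class_defaults("j_turn")  # hold_duration 300 ms
        trial = generate_trial([p], [100.0, 100.0], seed=3)
        series = compute_series(trial.trace)
        start, end, _ = trial.bout_truth[0]
        assert longest_bend_duration(series, Bout(start, end)) >= 300.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            KinematicsParams("prey_forward", 0.17, 16.0, bout_duration=-1.0)
        with pytest.raises(InvalidParameterError):
            KinematicsParams("prey_forward", 1.5, 16.0, 180.0)
        with pytest.raises(InvalidParameterError):
            KinematicsParams("spontaneous", 0.48, 9.2, 280.0, hold_duration=100.0)

    def test_deterministic_under_seed(self):
        p = class_defaults("spontaneous")
        a = generate_bout(p, seed=7)
        b = generate_bout(p, seed=7)
        assert np.array_equal(a.points, b.points)


class TestGenerateTrial:
    def test_zero_bouts_is_all_rest(self):
        trial = generate_trial([], [500.0], seed=0)
        assert trial.bout_truth == []
        x = trial.trace.points[..., 0]
        assert np.all(np.abs(x - 150.0) < 6.0)  # straight tail + small jitter

    def test_bout_truth_frame_counts(self):
        # oracle: hand count; beat bouts snap to integer half-cycles, so
        # a 250 ms bout at 10 Hz stays exactly 250 ms = 75 frames
        p = KinematicsParams("spontaneous", 0.4, 10.0, 250.0)
        trial = generate_trial([p, p, p], [100.0] * 4, seed=5)
        assert len(trial.bout_truth) == 3
        for start, end, cls in trial.bout_truth:
            assert cls == "spontaneous"
            assert end - start == 75
        # rests are 30 frames each
        assert trial.bout_truth[0][0] == 30

    def test_truth_intervals_disjoint_and_ordered(self):
        rng = np.random.default_rng(0)
        params = [sample_params(c, rng) for c in ("prey_forward", "j_turn", "spontaneous")]
        trial = generate_trial(params, [200.0] * 4, seed=9)
        prev_end = 0
        for start, end, _ in trial.bout_truth:
            assert prev_end <= start < end <= trial.trace.n_frames
            prev_end = end

    def test_rest_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_trial([class_defaults("spontaneous")], [100.0], seed=0)

    def test_class_separation_amplitude(self):
        # prey-capture forward swims must be visibly weaker than
        # spontaneous swims before any downstream stage runs
        rng = np.random.default_rng(2)
        amps = {}
        for cls in ("prey_forward", "spontaneous"):
            vals = []
            for _ in range(20):
                trial = generate_trial(
                    [sample_params(cls, rng)], [100.0, 100.0],
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                s = compute_series(trial.trace)
                start, end, _ = trial.bout_truth[0]
                vals.append(bout_amplitude(s, Bout(start, end)))
            amps[cls] = np.mean(vals)
        assert amps["prey_forward"] < amps["spontaneous"]


class TestRenderVideo:
    def test_noiseless_straight_tail_ridge_at_tail_column(self):
        trial = generate_trial([], [50.0], seed=0, rest_noise_sd=0.0)
        video = render_video(trial.trace, background_noise_sd=0.0, seed=0)
        frame = video.frames[0]
        ys = np.arange(60, 220)
        assert np.all(np.argmax(frame[ys], axis=1) == 150)

    def test_ridge_reextraction_matches_ground_truth(self, spont_video):
        # oracle: per-row argmax of the rendered frame vs the generating
        # midline, within half the stroke width
        video = spont_video
        truth = video.ground_truth.points
        for f in (0, 50):
            frame = video.frames[f]
            pts = truth[f]
            dense_t = np.linspace(0, 1, 400)
            s = arc_lengths(pts)
            dense = np.column_stack([
                np.interp(dense_t * s[-1], s, pts[:, 0]),
                np.interp(dense_t * s[-1], s, pts[:, 1]),
            ])
            tree = cKDTree(dense)
            rows = np.arange(70, 200)
            ridge_x = np.argmax(frame[rows], axis=1)
            d, _ = tree.query(np.column_stack([ridge_x, rows]))
            assert np.max(d) <= video.tail_width_px

    def test_out_of_frame_points_rejected_with_frame_number(self):
        p = class_defaults("spontaneous")
        trial = generate_trial([p], [50.0, 50.0], seed=1)
        with pytest.raises(OutOfBoundsError, match="frame"):
            render_video(trial.trace, shape=(120, 120))

    def test_default_geometry_is_300px(self, spont_video):
        assert spont_video.frames.shape[1:] == (300, 300)

    def test_deterministic_under_seed(self):
        trial = generate_trial([], [30.0], seed=3)
        a = render_video(trial.trace, seed=5)
        b = render_video(trial.trace, seed=5)
        assert np.array_equal(a.frames, b.frames)


class TestFluorescenceMovie:
    def test_zero_response_is_baseline_plus_noise(self):
        layout = default_roi_layout()
        m = generate_fluorescence_movie(layout, {}, n_frames=40, noise_sd=1.0, seed=0)
        assert m.frames.shape == (40, 128, 128)
        assert np.abs(m.frames.mean() - m.baseline_level) < 0.1

    def test_single_pixel_boxcar_recovered_exactly_without_noise(self):
        mask = np.zeros((128, 128), dtype=bool)
        mask[5, 5] = True
        dff = np.zeros(40)
        dff[10:20] = 1.0
        m = generate_fluorescence_movie(
            {"px": mask}, {"px": dff}, n_frames=40, noise_sd=0.0, seed=0
        )
        trace = m.frames[:, 5, 5]
        assert trace[15] == pytest.approx(2 * m.baseline_level)
        assert trace[0] == pytest.approx(m.baseline_level)

    def test_overlapping_masks_rejected(self):
        a = np.zeros((128, 128), dtype=bool)
        a[:10, :10] = True
        with pytest.raises(InvalidLayoutError):
            generate_fluorescence_movie({"a": a, "b": a}, {}, n_frames=30)

    def test_too_short_movie_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_fluorescence_movie(default_roi_layout(), {}, n_frames=20)

    def test_prey_tuning_peaks_at_small_sizes(self):
        sizes = [0.5, 1, 2, 3, 6, 10, 30]
        resp = {s: size_tuning(s, "prey") for s in sizes}
        best = max(resp, key=resp.get)
        assert best in (2, 3)
        assert resp[10] < 0.1 * max(resp.values())
        # the large-stimulus profile is the opposite
        large = {s: size_tuning(s, "large") for s in sizes}
        assert large[30] > 0.9 and large[2] < 0.1

    def test_calcium_response_shape(self):
        dff = calcium_response(60, onset_frame=20, peak=0.8)
        assert dff[:20].max() == 0.0
        assert dff.max() == pytest.approx(0.8)
        assert dff[40] < 0.3  # decayed
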