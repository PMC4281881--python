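"""ΔF/F and response-statistics checks against brute-force and
enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from preycap.exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidWindowError,
)
from preycap.imaging import (
    compare_groups,
    compute_dff,
    condition_ratio_map,
    rank_sum,
    response_tuning,
    roi_response,
    sliding_percentile_baseline,
)
from preycap.synthetic import (
    calcium_response,
    default_roi_layout,
    generate_fluorescence_movie,
)


def brute_force_baseline(trace, window=25, percentile=8.0):
    """Independent oracle: sort each truncated centered window and take
    the linearly interpolated rank."""
    T = len(trace)
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    out = np.empty(T)
    for t in range(T):
        vals = np.sort(trace[max(0, t - half_lo) : min(T, t + half_hi + 1)])
        rank = percentile / 100.0 * (len(vals) - 1)
        lo = int(np.floor(rank))
        hi = int(np.ceil(rank))
        out[t] = vals[lo] + (rank - lo) * (vals[hi] - vals[lo])
    return out


class TestSlidingPercentileBaseline:
    def test_constant_pixel_baseline_constant(self):
        movie = np.full((40, 2, 2), 100.0)
        base = sliding_percentile_baseline(movie)
        assert np.allclose(base, 100.0)

    def test_matches_sort_rank_oracle_on_ramp(self):
        trace = np.arange(1.0, 26.0)
        movie = trace[:, None, None]
        base = sliding_percentile_baseline(np.vstack([movie, movie]), window=25)
        oracle = brute_force_baseline(np.concatenate([trace, trace]), window=25)
        assert np.allclose(base[:, 0, 0], oracle)

    def test_matches_oracle_on_random_traces(self):
        rng = np.random.default_rng(0)
        movie = rng.normal(100.0, 10.0, (60, 8, 4))
        base = sliding_percentile_baseline(movie, window=25, percentile=8.0)
        for (i, j) in [(0, 0), (3, 2), (7, 3)]:
            assert np.allclose(base[:, i, j], brute_force_baseline(movie[:, i, j]))

    def test_window_too_long_rejected(self):
        with pytest.raises(InvalidWindowError):
            sliding_percentile_baseline(np.zeros((20, 2, 2)), window=25)

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(float, (30, 2), elements=st.floats(0.0, 1000.0)),
        st.integers(0, 29),
        st.integers(0, 1),
    )
    def test_monotonicity(self, movie, t, px):
        # raising any raw value never lowers any baseline value
        movie3 = movie[:, :, None]
        base = sliding_percentile_baseline(movie3, window=7)
        bumped = movie3.copy()
        bumped[t, px, 0] += 50.0
        base2 = sliding_percentile_baseline(bumped, window=7)
        assert np.all(base2 >= base - 1e-9)


class TestComputeDff:
    def test_raw_equals_baseline_gives_zero(self):
        movie = np.full((30, 3, 3), 50.0)
        dff = compute_dff(movie, movie)
        assert np.allclose(dff.values, 0.0)

    def test_boxcar_doubling_gives_dff_one(self):
        base = np.full((30, 2, 2), 80.0)
        movie = base.copy()
        movie[10:15] *= 2.0
        dff = compute_dff(movie, base)
        assert np.allclose(dff.values[10:15], 1.0)
        assert np.allclose(dff.values[:10], 0.0)

    def test_nonpositive_baseline_masked_and_warned(self):
        base = np.full((30, 2, 2), 10.0)
        base[5, 0, 0] = 0.0
        movie = np.full((30, 2, 2), 20.0)
        with pytest.warns(UserWarning, match="masked"):
            dff = compute_dff(movie, base)
        assert np.isnan(dff.values[:, 0, 0]).all()
        assert np.isfinite(dff.values[:, 1, 1]).all()

    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(1)
        movie = rng.uniform(50, 150, (40, 4, 4))
        base = sliding_percentile_baseline(movie, window=11)
        dff = compute_dff(movie, base)
        recon = base * (1.0 + dff.values)
        assert np.allclose(recon, movie)


class TestConditionRatioMap:
    def test_identical_segments_ratio_one(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.2, 1.0, (20, 5, 5))
        dff = compute_dff(vals + 1.0, np.ones_like(vals))
        ratio = condition_ratio_map(dff, dff)
        assert np.allclose(ratio[np.isfinite(ratio)], 1.0)

    def test_post_only_response_shows_high_ratio(self):
        # generator-truth oracle: ROI responds only after prey appear
        layout = default_roi_layout()
        pre = generate_fluorescence_movie(
            layout, {"prey_tuned": np.full(40, 0.1)}, 40, noise_sd=0.0, seed=0
        )
        post = generate_fluorescence_movie(
            layout, {"prey_tuned": np.full(40, 0.8)}, 40, noise_sd=0.0, seed=1
        )
        base = np.full(pre.frames.shape, 100.0)
        dpre = compute_dff(pre.frames, base)
        dpost = compute_dff(post.frames, base)
        ratio = condition_ratio_map(dpre, dpost)
        roi = layout["prey_tuned"]
        assert np.nanmedian(ratio[roi]) == pytest.approx(8.0, rel=0.05)
        assert np.isnan(ratio[~roi]).all()  # pre-max below the floor -> masked

    def test_swap_and_invert_symmetry(self):
        rng = np.random.default_rng(3)
        a = compute_dff(rng.uniform(80, 120, (20, 6, 6)), np.full((20, 6, 6), 80.0))
        b = compute_dff(rng.uniform(80, 120, (20, 6, 6)), np.full((20, 6, 6), 80.0))
        r_ab = condition_ratio_map(a, b, mask_floor=0.0)
        r_ba = condition_ratio_map(b, a, mask_floor=0.0)
        ok = np.isfinite(r_ab) & np.isfinite(r_ba)
        assert np.allclose(r_ab[ok] * r_ba[ok], 1.0)


class TestRoiResponse:
    def test_zero_dff_gives_zero_time_course(self):
        dff = compute_dff(np.full((30, 4, 4), 10.0), np.full((30, 4, 4), 10.0))
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        resp = roi_response(dff, mask)
        assert np.allclose(resp.time_course, 0.0)
        assert resp.peak == 0.0

    def test_single_pixel_mask_equals_pixel_trace(self):
        rng = np.random.default_rng(4)
        movie = rng.uniform(90, 110, (30, 4, 4))
        dff = compute_dff(movie, np.full((30, 4, 4), 100.0))
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 3] = True
        resp = roi_response(dff, mask)
        assert np.allclose(resp.time_course, dff.values[:, 2, 3])

    def test_empty_mask_rejected(self):
        dff = compute_dff(np.full((30, 4, 4), 10.0), np.full((30, 4, 4), 10.0))
        with pytest.raises(InvalidParameterError):
            roi_response(dff, np.zeros((4, 4), dtype=bool))

    def test_synthetic_peak_recovered_within_noise(self):
        layout = default_roi_layout()
        tc = calcium_response(60, onset_frame=30, peak=0.8)
        m = generate_fluorescence_movie(layout, {"prey_tuned": tc}, 60, noise_sd=2.0, seed=5)
        base = sliding_percentile_baseline(m.frames, window=25)
        dff = compute_dff(m.frames, base)
        resp = roi_response(dff, layout["prey_tuned"])
        assert resp.peak == pytest.approx(0.8, abs=0.1)


class TestResponseTuning:
    def test_best_condition_reads_100(self):
        responses = pd.DataFrame({"2deg": [0.8], "10deg": [0.2]})
        out = response_tuning(responses)
        assert out.loc["2deg", "mean"] == pytest.approx(100.0)

    def test_scale_invariance_across_larvae(self):
        base = np.array([0.2, 0.8, 0.1])
        responses = pd.DataFrame([base, 5 * base], columns=["a", "b", "c"])
        out = response_tuning(responses)
        assert np.allclose(out["sem"], 0.0)

    def test_prey_tuned_roi_prefers_small_dots(self):
        # end-to-end: movies per stimulus size, peak response normalized
        from preycap.synthetic import size_tuning

        layout = default_roi_layout()
        sizes = [1.0, 2.0, 3.0, 6.0, 10.0]
        peaks = {}
        for k, size in enumerate(sizes):
            tc = calcium_response(60, 30, 0.9 * size_tuning(size, "prey"))
            m = generate_fluorescence_movie(
                layout, {"prey_tuned": tc}, 60, noise_sd=1.0, seed=10 + k
            )
            base = sliding_percentile_baseline(m.frames, window=25)
            resp = roi_response(compute_dff(m.frames, base), layout["prey_tuned"])
            peaks[f"{size}deg"] = resp.peak
        out = response_tuning(pd.DataFrame([peaks]))
        best = out["mean"].idxmax()
        assert best in ("2.0deg", "3.0deg")
        assert out.loc["10.0deg", "mean"] < 30.0


class TestCompareGroups:
    def test_exact_rank_sum_enumeration_oracle(self):
        # all 20 assignments of {1..6} to two groups of 3: only 2 are as
        # extreme as {1,2,3} vs {4,5,6}, so the exact two-sided p is 0.1
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        obs = sum(a)
        pool = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        count = 0
        for combo in itertools.combinations(pool, 3):
            s = sum(combo)
            if abs(s - 10.5) >= abs(obs - 10.5):
                count += 1
        p_enum = count / 20.0
        assert p_enum == pytest.approx(0.1)
        assert rank_sum(a, b).pvalue == pytest.approx(p_enum)

    def test_identical_samples_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert rank_sum(a, a).pvalue == pytest.approx(1.0)

    def test_normal_data_routes_to_t_test(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 40)
        rep = compare_groups(a, b)
        assert rep.test_name == "t-test"
        assert rep.p_value < 0.01
        assert rep.levene_p > 0.01

    def test_heavy_tailed_data_routes_to_rank_sum(self):
        rng = np.random.default_rng(7)
        a = rng.standard_cauchy(60)
        b = rng.standard_cauchy(60) + 5.0
        rep = compare_groups(a, b)
        assert rep.test_name == "wilcoxon_rank_sum"
        assert rep.p_value < 0.01

    def test_small_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0, 2.0], [3.0, 4.0, 5.0])
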