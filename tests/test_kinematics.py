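"""Displacement curves, tap segmentation and movement features."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

import tapddk as td
from tapddk.kinematics import _TAP_TEST_LABELS  # noqa: F401  (labels exist)

from conftest import local_maxima_oracle, sinusoid_curve


def make_landmarks(index, thumb, fs=30.0):
    n = len(index)
    t = np.arange(n) / fs
    return td.LandmarkStream(t, np.asarray(index, float),
                             np.asarray(thumb, float), fps=fs)


class TestDisplacement:
    def test_345_triangle(self):
        s = make_landmarks([(3, 4), (3, 4)], [(0, 0), (0, 0)])
        curve = td.displacement_from_landmarks(s)
        assert curve.values == pytest.approx([5.0, 5.0])
        assert not curve.normalized

    def test_coincident_points_zero_curve(self):
        pts = [(2.0, 7.0)] * 5
        curve = td.displacement_from_landmarks(make_landmarks(pts, pts))
        assert np.all(curve.values == 0.0)

    def test_three_frame_toy_against_loop(self):
        index = [(0, 0), (1, 1), (2, 0)]
        thumb = [(0, 0), (0, 0), (0, 0)]
        curve = td.displacement_from_landmarks(make_landmarks(index, thumb))
        # independent per-frame distance loop
        expected = [np.sqrt((ix - tx) ** 2 + (iy - ty) ** 2)
                    for (ix, iy), (tx, ty) in zip(index, thumb)]
        assert curve.values == pytest.approx(expected)
        assert curve.values == pytest.approx([0.0, np.sqrt(2), 2.0])

    def test_sensor_1223_quadruple(self):
        t = np.arange(2) / 60
        s = td.SensorStream(t, np.array([[1.0, 2, 2]] * 2),
                            np.zeros((2, 3)))
        assert td.displacement_from_sensors(s).values == pytest.approx([3.0, 3.0])

    def test_sensor_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        s = td.SensorStream(np.arange(4) / 60, a, b)
        curve = td.displacement_from_sensors(s)
        for i in range(4):
            expected = np.sqrt(sum((a[i, j] - b[i, j]) ** 2 for j in range(3)))
            assert abs(curve.values[i] - expected) < 1e-12

    def test_mismatched_lengths_named_in_error(self):
        with pytest.raises(td.StreamValidationError, match="thumb_xy"):
            td.LandmarkStream(np.arange(3) / 30, np.zeros((3, 2)),
                              np.zeros((2, 2)))

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 100), dx=st.floats(-500, 500),
           dy=st.floats(-500, 500))
    def test_translation_invariance_and_scale_equivariance(self, scale, dx, dy):
        rng = np.random.default_rng(7)
        index = rng.uniform(0, 100, (20, 2))
        thumb = rng.uniform(0, 100, (20, 2))
        base = td.displacement_from_landmarks(make_landmarks(index, thumb))
        shift = np.array([dx, dy])
        moved = td.displacement_from_landmarks(
            make_landmarks(scale * index + shift, scale * thumb + shift))
        assert moved.values == pytest.approx(scale * base.values, rel=1e-9,
                                             abs=1e-9 * scale)

    def test_swap_index_thumb_symmetry(self):
        rng = np.random.default_rng(8)
        index = rng.uniform(0, 100, (15, 2))
        thumb = rng.uniform(0, 100, (15, 2))
        c1 = td.displacement_from_landmarks(make_landmarks(index, thumb))
        c2 = td.displacement_from_landmarks(make_landmarks(thumb, index))
        assert np.array_equal(c1.values, c2.values)


class TestNormalize:
    def test_simple_minmax(self):
        c = td.DisplacementCurve(np.arange(3.0), np.array([2.0, 4.0, 6.0]))
        out = td.normalize_curve(c)
        assert out.values == pytest.approx([0.0, 0.5, 1.0])
        assert out.normalized

    def test_constant_curve_is_degenerate(self):
        c = td.DisplacementCurve(np.arange(3.0), np.array([5.0, 5.0, 5.0]))
        with pytest.raises(td.DegenerateSignalError):
            td.normalize_curve(c)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1000), min_size=2, max_size=50, unique=True))
    def test_output_spans_unit_interval(self, vals):
        assume(max(vals) - min(vals) > 1e-9)  # non-degenerate by contract
        c = td.DisplacementCurve(np.arange(len(vals), dtype=float),
                                 np.array(vals))
        out = td.normalize_curve(c)
        assert out.values.min() == pytest.approx(0.0)
        assert out.values.max() == pytest.approx(1.0)


class TestSegmentTaps:
    def test_clean_2hz_sinusoid(self):
        curve = td.normalize_curve(sinusoid_curve(2.0, 10.0, 30.0))
        events = td.segment_taps(curve)
        # oracle: exhaustive local-maximum scan on the same samples
        oracle_peaks = local_maxima_oracle(curve.values)
        assert events.n_events == len(oracle_peaks) == 20
        assert np.all(np.abs(events.intervals - 0.5) <= 1.0 / 30.0 + 1e-9)

    def test_flat_curve_zero_events(self):
        t = np.arange(30) / 30
        curve = td.DisplacementCurve(t, np.full(30, 0.5), normalized=True)
        events = td.segment_taps(curve)
        assert events.n_events == 0

    def test_noisy_2hz_sinusoid(self):
        curve = td.normalize_curve(
            sinusoid_curve(2.0, 10.0, 30.0, noise_sd=0.05, seed=11))
        events = td.segment_taps(curve)
        assert abs(events.n_events - 20) <= 1

    def test_min_separation_enforced(self):
        curve = td.normalize_curve(sinusoid_curve(4.0, 10.0, 60.0))
        events = td.segment_taps(curve, min_separation=0.5)
        assert np.all(events.intervals >= 0.5 - 1e-9)


class TestFeatures:
    def test_perfectly_periodic(self):
        t = np.arange(0, 10.5, 0.5)
        ev = td.EventSeries(t, np.ones_like(t), 10.0)
        fs = td.features_from_events(ev)
        assert fs.mean_frequency == pytest.approx(2.0)
        assert fs.cov_frequency == pytest.approx(0.0)
        assert fs.iiv == pytest.approx(0.0)
        assert fs.decrement_on_speed == pytest.approx(0.0, abs=1e-9)

    def test_three_event_hand_arithmetic(self):
        ev = td.EventSeries(np.array([0.0, 0.4, 0.9]), np.ones(3), 1.0)
        fs = td.features_from_events(ev)
        d = np.array([0.4, 0.5])
        f = 1.0 / d
        # independent statistics routine (numpy) on the hand-derived arrays
        assert fs.iiv == pytest.approx(np.var(d, ddof=1)) == pytest.approx(0.005)
        assert fs.cov_frequency == pytest.approx(np.std(f, ddof=1) / f.mean())
        assert fs.mean_frequency == pytest.approx(2 / 0.9)

    def test_chirp_decrement_on_speed(self):
        # instantaneous frequency falls 3.0 -> 2.0 Hz over 10 s
        times = [0.0]
        while True:
            f_now = 3.0 - 0.1 * times[-1]
            nxt = times[-1] + 1.0 / f_now
            if nxt > 10.0:
                break
            times.append(nxt)
        ev = td.EventSeries(np.array(times), np.ones(len(times)), 10.0)
        fs = td.features_from_events(ev)
        # independent least-squares oracle on the same event times
        t_arr = np.array(times)
        mid = (t_arr[:-1] + t_arr[1:]) / 2
        f_inst = 1.0 / np.diff(t_arr)
        A = np.vstack([mid, np.ones_like(mid)]).T
        slope_oracle = np.linalg.lstsq(A, f_inst, rcond=None)[0][0]
        assert fs.decrement_on_speed == pytest.approx(slope_oracle, abs=1e-9)
        assert fs.decrement_on_speed == pytest.approx(-0.10, abs=0.02)

    def test_half_difference_mode_tracks_slope(self):
        times = np.cumsum(np.concatenate([[0], 1 / np.linspace(3, 2, 25)]))
        ev = td.EventSeries(times, np.ones(len(times)), times[-1])
        fs = td.features_from_events(ev, dos_method="half_difference")
        assert fs.decrement_on_speed == pytest.approx(-0.1, abs=0.03)

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_undefined_below_three_events(self, n):
        ev = td.EventSeries(np.arange(n, dtype=float),
                            np.ones(n), 10.0)
        fs = td.features_from_events(ev)
        assert not fs.defined
        assert fs.n_events == n
        assert np.isnan(fs.mean_frequency) and np.isnan(fs.iiv)


class TestAnalyzeTapping:
    def test_paired_streams_recover_latent_rate(self, config):
        p = td.TapSimParams(base_frequency=2.5, interval_jitter_cv=0.02, seed=5)
        video, sensor, _ = td.simulate_tap_pair(p)
        fv = td.analyze_tapping(video, config)
        fs = td.analyze_tapping(sensor, config)
        assert fv.source == "video" and fs.source == "sensor"
        assert abs(fv.mean_frequency - 2.5) < 0.15
        assert abs(fs.mean_frequency - 2.5) < 0.15

    def test_degenerate_stream_names_normalize_stage(self):
        t = np.arange(60) / 30
        pts = np.tile([5.0, 5.0], (60, 1))
        stream = td.LandmarkStream(t, pts + 3.0, pts)
        with pytest.raises(td.DegenerateSignalError, match="normalize"):
            td.analyze_tapping(stream)

    def test_deterministic(self, config):
        video, _, _ = td.simulate_tap_pair(td.TapSimParams(seed=9))
        f1 = td.analyze_tapping(video, config)
        f2 = td.analyze_tapping(video, config)
        assert f1 == f2

    def test_normalized_features_scale_translation_invariant(self, config):
        video, _, _ = td.simulate_tap_pair(td.TapSimParams(seed=10))
        moved = td.LandmarkStream(video.timestamps,
                                  3.0 * video.index_xy + 17.0,
                                  3.0 * video.thumb_xy + 17.0,
                                  fps=video.fps, test_label=video.test_label)
        f1 = td.analyze_tapping(video, config)
        f2 = td.analyze_tapping(moved, config)
        assert f1.mean_frequency == pytest.approx(f2.mean_frequency)
        assert f1.cov_frequency == pytest.approx(f2.cov_frequency)
        assert f1.iiv == pytest.approx(f2.iiv)
        assert f1.decrement_on_speed == pytest.approx(f2.decrement_on_speed)

    def test_downsampled_sensor_consistent(self, config):
        """60 Hz vs 30 Hz observation of the same process: M-TF within one
        quantization step (cross-rate consistency)."""
        p = td.TapSimParams(base_frequency=2.5, interval_jitter_cv=0.05,
                            position_noise_sd_sensor=0.0, seed=12)
        _, sensor, _ = td.simulate_tap_pair(p)
        f60 = td.analyze_tapping(sensor, config)
        half = td.SensorStream(sensor.timestamps[::2],
                               sensor.sensor_a_xyz[::2],
                               sensor.sensor_b_xyz[::2], sample_rate=30.0)
        f30 = td.analyze_tapping(half, config)
        # one quantization step of the slower stream
        assert abs(f60.mean_frequency - f30.mean_frequency) <= 1 / 30 + 1e-9


class TestParameterRecovery:
    @pytest.mark.parametrize("jitter", [0.05, 0.15])
    def test_cov_recovers_interval_jitter(self, jitter, config):
        """Median recovered COV-TF across seeded simulations tracks the true
        interval jitter CV within 25% relative error (spec sweep scaled down
        from 200 to 40 runs to stay inside the suite's time budget)."""
        covs = []
        for seed in range(40):
            p = td.TapSimParams(base_frequency=2.5, interval_jitter_cv=jitter,
                                position_noise_sd_video=0.005, seed=seed)
            video, _, _ = td.simulate_tap_pair(p)
            fs = td.analyze_tapping(video, config)
            if fs.defined:
                covs.append(fs.cov_frequency)
        med = float(np.median(covs))
        assert abs(med - jitter) / jitter < 0.25

    @pytest.mark.parametrize("f0", [1.0, 2.0, 3.5, 5.0])
    def test_noise_free_frequency_recovery(self, f0, config):
        p = td.TapSimParams(base_frequency=f0, interval_jitter_cv=0.0,
                            position_noise_sd_video=0.0,
                            position_noise_sd_sensor=0.0, seed=0)
        video, _, truth = td.simulate_tap_pair(p)
        fs = td.analyze_tapping(video, config)
        tol = 1.0 / p.duration + 1.0 / p.video_fps
        assert abs(fs.mean_frequency - f0) <= tol
        assert fs.cov_frequency <= 0.05
        assert abs(fs.decrement_on_speed) <= 0.02
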