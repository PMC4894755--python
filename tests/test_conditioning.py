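"""Signal conditioning: rectification, smoothing against convolution
oracles, crosstalk subtraction, per-step normalization, event detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import turncycle as tc
from turncycle.core import SampledTrace


def trace(values, fs=100.0):
    return SampledTrace(np.asarray(values, dtype=float), fs)


class TestRectify:
    def test_matches_elementwise_abs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        np.testing.assert_array_equal(tc.rectify(trace(x)).values, np.abs(x))

    def test_idempotent(self):
        x = np.array([-2.0, 0.0, 3.0])
        once = tc.rectify(trace(x))
        np.testing.assert_array_equal(once.values, [2.0, 0.0, 3.0])
        np.testing.assert_array_equal(tc.rectify(once).values, once.values)


class TestSmoothBoxcar:
    def test_constant_is_fixed_point_including_edges(self):
        out = tc.smooth_boxcar(trace(np.full(50, 3.7)), T=0.05)
        np.testing.assert_allclose(out.values, 3.7)

    def test_unit_impulse_spreads_to_uniform_plateau(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = tc.smooth_boxcar(trace(x, fs=100.0), T=0.05)
        # [t-T, t+T] at 100 Hz holds 11 samples
        np.testing.assert_allclose(out.values[45:56], 1 / 11)
        assert np.all(out.values[:45] == 0) and np.all(out.values[56:] == 0)

    def test_zero_window_is_identity(self):
        x = np.random.default_rng(1).normal(size=40)
        np.testing.assert_array_equal(tc.smooth_boxcar(trace(x), T=0.0).values, x)

    def test_interior_matches_convolution_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        out = tc.smooth_boxcar(trace(x), T=0.05).values
        k = np.ones(11) / 11
        oracle = np.convolve(x, k, mode="valid")  # interior samples only
        np.testing.assert_allclose(out[5:-5], oracle, rtol=1e-9)

    def test_mean_preserved_for_interior_supported_signal(self):
        # mean preservation of the renormalized smoother holds when the
        # signal stays a half-window clear of both edges
        rng = np.random.default_rng(3)
        x = np.zeros(300)
        x[20:-20] = rng.normal(size=260)
        out = tc.smooth_boxcar(trace(x), T=0.05).values
        np.testing.assert_allclose(out.mean(), x.mean(), rtol=1e-9, atol=1e-12)

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            tc.smooth_boxcar(trace([1.0, 2.0]), T=-0.1)


class TestSmoothGaussian:
    def test_constant_is_fixed_point(self):
        out = tc.smooth_gaussian(trace(np.full(80, -1.5)), width=0.1)
        np.testing.assert_allclose(out.values, -1.5)

    def test_interior_impulse_mass_and_peak(self):
        x = np.zeros(201)
        x[100] = 1.0
        out = tc.smooth_gaussian(trace(x, fs=100.0), width=0.1).values
        # renormalized kernel: unit mass, and the peak carries the kernel's
        # centre weight
        half = 5
        t = np.arange(-half, half + 1) / 100.0
        kernel = np.exp(-0.5 * (t / 0.025) ** 2)
        kernel /= kernel.sum()
        np.testing.assert_allclose(out.sum(), 1.0, rtol=1e-9)
        np.testing.assert_allclose(out[100], kernel[half], rtol=1e-9)

    def test_interior_matches_convolution_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        out = tc.smooth_gaussian(trace(x), width=0.1).values
        half = 5
        t = np.arange(-half, half + 1) / 100.0
        kernel = np.exp(-0.5 * (t / 0.025) ** 2)
        kernel /= kernel.sum()
        oracle = np.convolve(x, kernel, mode="valid")
        np.testing.assert_allclose(out[half:-half], oracle, rtol=1e-9)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            tc.smooth_gaussian(trace([1.0, 2.0]), width=0.0)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=60),
       st.sampled_from([0.01, 0.03, 0.05]))
def test_smoothers_are_linear(values, T):
    """Smoothing is linear: f(a x + b y) = a f(x) + b f(y)."""
    x = np.asarray(values)
    y = x[::-1].copy()
    fx = tc.smooth_boxcar(trace(x), T).values
    fy = tc.smooth_boxcar(trace(y), T).values
    combo = tc.smooth_boxcar(trace(2 * x - 3 * y), T).values
    np.testing.assert_allclose(combo, 2 * fx - 3 * fy, rtol=1e-9, atol=1e-6)


class TestRemoveCrosstalk:
    def test_pointwise_arithmetic_example(self):
        agonist = trace([0.0, 1.0, 0.4])
        antagonist = trace([0.0, 0.5, 1.0])  # rescales to [0, .25, .5]
        out = tc.remove_crosstalk(agonist, antagonist, cap=0.5)
        np.testing.assert_allclose(out.values, [0.0, 0.75, 0.0])

    def test_constant_antagonist_leaves_agonist(self):
        agonist = trace([0.0, 2.0, 1.0, 0.0])
        out = tc.remove_crosstalk(agonist, trace([3.0, 3.0, 3.0, 3.0]))
        np.testing.assert_allclose(out.values, [0.0, 1.0, 0.5, 0.0])

    def test_silent_agonist_stays_silent(self):
        out = tc.remove_crosstalk(trace(np.zeros(5)), trace(np.arange(5.0)))
        np.testing.assert_array_equal(out.values, np.zeros(5))

    def test_misaligned_traces_rejected(self):
        with pytest.raises(ValueError):
            tc.remove_crosstalk(trace(np.zeros(5)), trace(np.zeros(6)))

    def test_restores_truth_envelope_on_generated_emg(self, fl_inside):
        gait = tc.make_steps(fl_inside, 100, seed=11)
        emg = tc.make_emg(gait, fl_inside.replace(crosstalk_coeff=0.3), seed=12)
        env_a = tc.smooth_boxcar(tc.rectify(emg.agonist), 0.05)
        env_b = tc.smooth_boxcar(tc.rectify(emg.antagonist), 0.05)
        cleaned = tc.remove_crosstalk(env_a, env_b)
        r = np.corrcoef(cleaned.values, emg.true_env_agonist.values)[0, 1]
        assert r >= 0.95


class TestNormalizePerStep:
    def test_affine_map_to_unit_interval(self):
        step = tc.StepCycle("FL", "inside", 0.0, 0.02, 0.03)
        tr = trace([2.0, 4.0, 6.0, 99.0], fs=100.0)
        out = tc.normalize_per_step(tr, step)
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])

    def test_constant_segment_maps_to_zero(self):
        step = tc.StepCycle("FL", "inside", 0.0, 0.02, 0.03)
        out = tc.normalize_per_step(trace([5.0, 5.0, 5.0, 1.0], fs=100.0), step)
        np.testing.assert_array_equal(out.values, np.zeros(3))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=30))
    def test_output_spans_unit_interval(self, values):
        x = np.asarray(values)
        fs = 100.0
        step = tc.StepCycle("FL", "inside", 0.0,
                            (len(x) - 1) / fs / 2, (len(x) - 1) / fs)
        out = tc.normalize_per_step(trace(x, fs), step).values
        if np.ptp(out) > 0:
            assert out.min() == 0.0 and out.max() == 1.0
        else:
            assert np.all(out == 0.0)


class TestDetectContactEvents:
    def test_interpolated_crossing_of_linear_ramp(self):
        # ramp 0 -> 1 between samples 10 and 14: threshold 0.5 is crossed
        # exactly midway through the ramp
        v = np.concatenate([np.zeros(10), np.linspace(0, 1, 5), np.ones(10),
                            np.linspace(1, 0, 5), np.zeros(10)])
        tr = trace(v, fs=100.0)
        tds, los = tc.detect_contact_events(tr, td_threshold=0.5)
        assert len(tds) == 1
        np.testing.assert_allclose(tds.times[0], 0.12, atol=1e-12)

    def test_flat_trace_yields_empty_series(self):
        tds, los = tc.detect_contact_events(trace(np.zeros(50)), 0.5)
        assert len(tds) == 0 and len(los) == 0

    def test_tied_steepest_slope_takes_earliest_sample(self):
        # linear release ramp: every fall step is equally steep; the
        # earliest one defines the lift-off
        v = np.concatenate([np.zeros(5), np.ones(10), [0.75, 0.5, 0.25],
                            np.zeros(10)])
        tds, los = tc.detect_contact_events(trace(v, fs=100.0), 0.5)
        assert len(los) == 1
        np.testing.assert_allclose(los.times[0], 14 / 100.0)

    def test_recovers_generator_touchdowns_within_one_sample(self, fl_inside):
        gait = tc.make_steps(fl_inside, 150, seed=13)
        contact = tc.make_contact_trace(gait, fs=2000.0)
        tds, _ = tc.detect_contact_events(contact, 0.5)
        assert len(tds) == len(gait.touchdowns)
        err = np.abs(tds.times - gait.touchdowns.times)
        assert err.max() <= 1.0 / 2000.0


class TestDetectSpikes:
    def test_two_separated_transients(self):
        v = np.zeros(100)
        v[20:23] = [1.5, 2.0, 1.5]
        v[70:73] = [1.5, 2.0, 1.5]
        spikes = tc.detect_spikes(trace(v), threshold=1.0)
        np.testing.assert_allclose(spikes.times, [0.21, 0.71])

    def test_subthreshold_trace_is_empty(self):
        spikes = tc.detect_spikes(trace(np.full(50, 0.2)), threshold=1.0)
        assert len(spikes) == 0

    def test_double_crossing_within_dead_time_merges(self):
        v = np.zeros(100)
        v[30:37] = [1.5, 2.0, 0.5, 0.5, 0.5, 1.8, 1.2]  # dip below threshold
        spikes = tc.detect_spikes(trace(v, fs=1000.0), threshold=1.0,
                                  dead_time=0.005)
        assert len(spikes) == 1
        np.testing.assert_allclose(spikes.times, [0.031])
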