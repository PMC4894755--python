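"""Load-stimulus response quantification: PSTH, response magnitude,
Michelson contrast and three-way classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import turncycle as tc
from turncycle.core import EventSeries, SampledTrace


def ev(times, kind="spike"):
    return EventSeries(np.asarray(times, dtype=float), kind)


class TestPsth:
    def test_single_event_lands_in_first_post_bin(self):
        h = tc.psth(ev([1.005]), ev([1.0], "stim_onset"),
                    pre=0.05, post=0.05, bin=0.01)
        assert h.counts.sum() == 1
        i = np.flatnonzero(h.counts)[0]
        assert h.edges[i] == pytest.approx(0.0)

    def test_empty_events_all_zero(self):
        h = tc.psth(ev([]), ev([1.0, 2.0], "stim_onset"),
                    pre=0.1, post=0.1, bin=0.02)
        assert h.counts.sum() == 0 and h.n_stimuli == 2

    def test_poisson_rate_recovered_per_bin(self):
        rng = np.random.default_rng(3)
        lam = 200.0
        dur = 60.0
        spikes = np.sort(rng.uniform(0, dur, rng.poisson(lam * dur)))
        stims = np.arange(1.0, dur - 1.0, 1.0)
        h = tc.psth(ev(spikes), ev(stims, "stim_onset"),
                    pre=0.1, post=0.1, bin=0.02)
        expected = lam * 0.02 * len(stims)
        assert np.all(np.abs(h.counts - expected) < 3 * np.sqrt(expected))

    def test_count_conservation(self):
        rng = np.random.default_rng(5)
        spikes = np.sort(rng.uniform(0, 10, 500))
        stims = np.array([3.0, 7.0])
        h = tc.psth(ev(spikes), ev(stims, "stim_onset"),
                    pre=0.5, post=0.5, bin=0.1)
        manual = sum(((spikes >= s - 0.5) & (spikes < s + 0.5)).sum()
                     for s in stims)
        assert h.counts.sum() == manual

    def test_no_stimuli_is_error(self):
        with pytest.raises(ValueError):
            tc.psth(ev([1.0]), ev([], "stim_onset"), pre=0.1, post=0.1, bin=0.01)


class TestResponseMagnitude:
    def make_env(self, post_level):
        v = np.full(1000, 0.5)
        v[500:650] = post_level
        return SampledTrace(v, fs=1000.0)

    def test_control_level_gives_unity(self):
        env = self.make_env(2.0)
        assert tc.response_magnitude(env, 0.5, control_max_mean=2.0) == 1.0

    def test_silent_window_gives_zero(self):
        env = SampledTrace(np.zeros(1000), fs=1000.0)
        assert tc.response_magnitude(env, 0.5, control_max_mean=1.0) == 0.0

    def test_scales_linearly_with_envelope(self):
        env = self.make_env(2.0)
        doubled = env.with_values(env.values * 2)
        m1 = tc.response_magnitude(env, 0.5, 2.0)
        m2 = tc.response_magnitude(doubled, 0.5, 2.0)
        assert m2 == pytest.approx(2 * m1)

    def test_window_past_trace_end_is_error(self):
        env = self.make_env(2.0)
        with pytest.raises(ValueError):
            tc.response_magnitude(env, 0.95, 2.0)


class TestMichelsonContrast:
    def env(self, pre_level, post_level, fs=30.0):
        v = np.concatenate([np.full(3, pre_level), [0.0],
                            np.full(3, post_level)])
        return SampledTrace(v, fs=fs)

    def test_equal_windows_give_zero(self):
        assert tc.michelson_contrast(self.env(2.0, 2.0), 0.1, w=0.1) == 0.0

    def test_silent_pre_gives_plus_one(self):
        assert tc.michelson_contrast(self.env(0.0, 1.5), 0.1, w=0.1) == 1.0

    def test_hand_computed_three_point_window(self):
        # pre mean 3, post mean 1 -> (1-3)/(1+3) = -0.5
        assert tc.michelson_contrast(self.env(3.0, 1.0), 0.1, w=0.1) == \
            pytest.approx(-0.5)

    def test_both_silent_defined_as_zero(self):
        assert tc.michelson_contrast(self.env(0.0, 0.0), 0.1, w=0.1) == 0.0

    def test_negative_envelope_rejected(self):
        with pytest.raises(ValueError):
            tc.michelson_contrast(self.env(-1.0, 1.0), 0.1, w=0.1)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(0, 1e6), min_size=3, max_size=3),
           st.lists(st.floats(0, 1e6), min_size=3, max_size=3))
    def test_bounded_and_antisymmetric(self, pre_vals, post_vals):
        v = np.concatenate([pre_vals, [0.0], post_vals])
        c = tc.michelson_contrast(SampledTrace(v, 30.0), 0.1, w=0.1)
        c_swapped = tc.michelson_contrast(SampledTrace(v[::-1].copy(), 30.0),
                                          0.1, w=0.1)
        assert -1.0 <= c <= 1.0
        assert c_swapped == pytest.approx(-c, abs=1e-12)

    def test_fuzz_bound_on_random_traces(self):
        # |contrast| <= 1 across 10^4 random rectified traces
        rng = np.random.default_rng(11)
        for _ in range(10_000):
            v = rng.exponential(1.0, 7) * rng.integers(0, 2, 7)
            c = tc.michelson_contrast(SampledTrace(v, 30.0), 0.1, w=0.1)
            assert -1.0 <= c <= 1.0


class TestClassifyResponse:
    def step_pair(self, ret_post, pro_post, base=0.5):
        n = 2000
        pro = np.full(n, base)
        ret = np.full(n, base)
        ret[1000:1150] = ret_post
        pro[1000:1150] = pro_post
        mk = lambda v, lab: SampledTrace(v, 1000.0, 0.0, lab)
        return mk(pro, "pro"), mk(ret, "ret")

    def test_retractor_step_up_is_ret_act(self):
        pro, ret = self.step_pair(ret_post=5.0, pro_post=0.5)
        assert tc.classify_response(pro, ret, 1.0) == "RET_ACT"

    def test_retractor_down_protractor_up_is_pro_act(self):
        pro, ret = self.step_pair(ret_post=0.0, pro_post=5.0)
        assert tc.classify_response(pro, ret, 1.0) == "PRO_ACT"

    def test_flat_traces_are_none(self):
        pro, ret = self.step_pair(ret_post=0.5, pro_post=0.5)
        assert tc.classify_response(pro, ret, 1.0) == "NONE"

    def test_recovers_ground_truth_at_low_noise(self, fl_inside):
        preset = tc.get_preset("load-inside").replace(noise_sd=1e-4)
        gait = tc.make_steps(preset, 201, seed=41)
        trial = tc.make_load_trial(gait, preset, seed=42, n_stim=100)
        pro = tc.condition_envelope(trial.protractor)
        ret = tc.condition_envelope(trial.retractor)
        pred = [tc.classify_response(pro, ret, t) for t in trial.stimuli.times]
        agreement = np.mean(np.asarray(pred) == trial.true_class)
        assert agreement >= 0.95

    def test_none_fraction_recovered_on_full_session(self, load_inside_session):
        preset, gait, trial, cycles = load_inside_session
        pro = tc.condition_envelope(trial.protractor)
        ret = tc.condition_envelope(trial.retractor)
        responses = tc.classify_all(pro, ret, trial.stimuli, cycles)
        frac = np.mean([r.klass == "NONE" for r in responses])
        se = np.sqrt(0.188 * (1 - 0.188) / len(responses))
        assert abs(frac - 0.188) < 3 * se


class TestResponseVsPhase:
    def test_degenerate_phase_cluster(self, load_inside_session):
        responses = [tc.StimulusResponse(float(t), 0.89, 1.0, 0.0, 0.0, "NONE")
                     for t in np.arange(10.0)]
        _, cs = tc.response_vs_phase(responses, [], klass="NONE")
        assert cs.mean_fraction == pytest.approx(0.89)
        assert cs.R == pytest.approx(1.0)

    def test_none_phase_preference_recovered(self, load_inside_session):
        preset, gait, trial, cycles = load_inside_session
        pro = tc.condition_envelope(trial.protractor)
        ret = tc.condition_envelope(trial.retractor)
        responses = tc.classify_all(pro, ret, trial.stimuli, cycles)
        _, cs = tc.response_vs_phase(responses, cycles, klass="NONE")
        assert cs is not None
        assert abs(cs.mean_fraction - preset.none_phase_mu) < 0.03
        assert cs.p_rayleigh < 0.05

    def test_too_few_responses_yield_no_test(self):
        responses = [tc.StimulusResponse(1.0, 0.5, 1.0, 0.0, 0.0, "NONE")]
        _, cs = tc.response_vs_phase(responses, [], klass="NONE")
        assert cs is None

    def test_ret_act_magnitude_phase_independent(self, load_inside_session):
        # generated RET_ACT magnitudes carry no phase information; a
        # permutation null on the circular-linear association confirms it
        preset, gait, trial, cycles = load_inside_session
        ret = tc.condition_envelope(trial.retractor)
        pro = tc.condition_envelope(trial.protractor)
        responses = tc.classify_all(pro, ret, trial.stimuli, cycles)
        sel = [r for r in responses if r.klass == "RET_ACT"
               and not np.isnan(r.phase)]
        phases = np.array([r.phase for r in sel])
        mags = np.array([r.magnitude for r in sel])

        def circ_lin_stat(ph, m):
            # correlation of magnitude with the (cos, sin) phase embedding
            c = np.corrcoef(m, np.cos(2 * np.pi * ph))[0, 1]
            s = np.corrcoef(m, np.sin(2 * np.pi * ph))[0, 1]
            return np.hypot(c, s)

        obs = circ_lin_stat(phases, mags)
        rng = np.random.default_rng(53)
        null = np.array([circ_lin_stat(phases, rng.permutation(mags))
                         for _ in range(1000)])
        assert obs < np.quantile(null, 0.99)


def test_select_control_stimuli_excludes_step_adjacent():
    stims = ev([1.0, 5.0, 9.0], "stim_onset")
    tds = ev([4.8, 5.5], "touchdown")
    controls = tc.select_control_stimuli(stims, tds, mean_period=1.0)
    np.testing.assert_allclose(controls.times, [1.0, 9.0])
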