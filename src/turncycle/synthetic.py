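"""Synthetic gait, nerve, EMG, load-stimulus and slow-rhythm generators.

Every downstream analysis stage in this package is exercised against data
produced here, with known ground truth: step trains with Gaussian periods,
pro-/retractor spike trains phase-locked to the step cycle (von Mises
phase tuning), tonic retractor-biased activity for the outside turning
side, slow alternating pilocarpine-like burst rhythms that speed up during
stepping, stochastic load-stimulus responses with side-specific class
mixtures, and EMG envelope pairs with known antagonist crosstalk.

All generators are deterministic for a given (preset, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0 as _bessel_i0

from .core import EventSeries, SampledTrace
from .presets import GeneratorPreset

__all__ = [
    "GaitEvents",
    "LoadTrial",
    "EmgPair",
    "make_steps",
    "make_nerve_activity",
    "make_pilocarpine_rhythm",
    "make_load_trial",
    "make_emg",
    "make_contact_trace",
]

RESPONSE_CLASSES = ("RET_ACT", "PRO_ACT", "NONE")


@dataclass(frozen=True)
class GaitEvents:
    """Touchdown and lift-off series of one leg."""

    touchdowns: EventSeries
    liftoffs: EventSeries

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.touchdowns.times)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.touchdowns.times[0]), float(self.touchdowns.times[-1])


def make_steps(preset: GeneratorPreset, n_steps: int, seed: int,
               t_start: float = 0.0, source: str = "") -> GaitEvents:
    """Generate a train of step cycles with Gaussian-distributed periods.

    Periods are drawn from Normal(mean_period, sd_period) truncated below
    at 0.1*mean_period; lift-off follows each touchdown after
    duty_fraction of that cycle's period.  Returns ``n_steps`` complete
    cycles, i.e. ``n_steps + 1`` touchdowns.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    lo = 0.1 * preset.mean_period
    periods = np.empty(n_steps)
    filled = 0
    while filled < n_steps:  # rejection sampling of the truncated Normal
        draw = rng.normal(preset.mean_period, preset.sd_period, n_steps - filled)
        ok = draw[draw >= lo]
        periods[filled:filled + len(ok)] = ok
        filled += len(ok)
    touchdowns = t_start + np.concatenate(([0.0], np.cumsum(periods)))
    liftoffs = touchdowns[:-1] + preset.duty_fraction * periods
    return GaitEvents(
        EventSeries(touchdowns, "touchdown", source),
        EventSeries(liftoffs, "liftoff", source),
    )


def _phase_of(times: np.ndarray, touchdowns: np.ndarray) -> np.ndarray:
    """Cycle fraction of each time within the contiguous cycle train."""
    idx = np.searchsorted(touchdowns, times, side="right") - 1
    idx = np.clip(idx, 0, len(touchdowns) - 2)
    td = touchdowns[idx]
    period = touchdowns[idx + 1] - td
    return (times - td) / period


def make_nerve_activity(steps: GaitEvents, mode: str, preset: GeneratorPreset,
                        seed: int) -> tuple[EventSeries, EventSeries]:
    """Protractor and retractor spike trains for one turning side.

    ``mode="inside"``: inhomogeneous Poisson trains whose rate follows a
    von Mises profile of step-cycle phase (protractor peaking at
    ``pro_peak_deg``, retractor at ``ret_peak_deg``, concentration
    ``kappa``), generated by thinning; the phase marginal of the spikes is
    then exactly von Mises and the time-averaged rate is ``base_rate``.

    ``mode="outside"``: homogeneous Poisson trains, tonically biased
    toward the retractor (rate ratio 3:1), with no phase tuning.
    """
    if len(steps.touchdowns) < 2:
        raise ValueError("steps must contain at least one complete cycle")
    if mode not in ("inside", "outside"):
        raise ValueError(f"unknown mode {mode!r}; use 'inside' or 'outside'")
    rng = np.random.default_rng(seed)
    t0, t1 = steps.span
    duration = t1 - t0
    tds = steps.touchdowns.times

    trains = []
    if mode == "inside":
        for peak_deg in (preset.pro_peak_deg, preset.ret_peak_deg):
            mu = np.deg2rad(peak_deg)
            kap = preset.kappa
            # rate(t) = base_rate * exp(kappa*cos(theta-mu)) / I0(kappa);
            # phase-average is base_rate, peak is base_rate*e^kappa/I0.
            rate_max = preset.base_rate * np.exp(kap) / _bessel_i0(kap)
            n_cand = rng.poisson(rate_max * duration)
            cand = np.sort(t0 + rng.uniform(0.0, duration, n_cand))
            theta = 2 * np.pi * _phase_of(cand, tds)
            accept_p = np.exp(kap * (np.cos(theta - mu) - 1.0))
            keep = rng.uniform(size=n_cand) < accept_p
            trains.append(np.unique(cand[keep]))
    else:
        pro_rate = preset.base_rate / 2.0
        ret_rate = 3.0 * pro_rate
        for rate in (pro_rate, ret_rate):
            n = rng.poisson(rate * duration)
            trains.append(np.unique(np.sort(t0 + rng.uniform(0.0, duration, n))))

    pro, ret = trains
    return (EventSeries(pro, "spike", "protractor"),
            EventSeries(ret, "spike", "retractor"))


def _check_intervals(intervals, duration: float) -> list[tuple[float, float]]:
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    for a, b in ivs:
        if not (0.0 <= a < b <= duration):
            raise ValueError(f"interval ({a}, {b}) not within [0, {duration}]")
    for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise ValueError("stepping intervals overlap")
    return ivs


def _in_any(t: float, intervals) -> bool:
    return any(a <= t < b for a, b in intervals)


def make_pilocarpine_rhythm(duration: float, stepping_intervals,
                            preset: GeneratorPreset, seed: int,
                            burst_rate: float = 80.0,
                            burst_duty: float = 0.35,
                            period_cv: float = 0.05,
                            ) -> tuple[EventSeries, EventSeries]:
    """Slow alternating pro-/retractor burst rhythm with stepping speed-up.

    Burst cycles run at ``rhythm_freq_quiet`` outside the given stepping
    intervals and at ``rhythm_freq_step`` inside them; protractor bursts
    occupy the first part of each cycle and retractor bursts the
    anti-phase half.  Spikes within a burst are Poisson at ``burst_rate``.
    The rhythm resets at every interval boundary (the speed-up with
    stepping onset, and the relaxation after it, are prompt): a cycle
    straddling a boundary is truncated there and a fresh cycle starts at
    the new frequency.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    ivs = _check_intervals(stepping_intervals, duration)
    rng = np.random.default_rng(seed)
    boundaries = sorted({duration, *(e for iv in ivs for e in iv)})

    pro_spikes: list[np.ndarray] = []
    ret_spikes: list[np.ndarray] = []
    t = 0.0
    while t < duration:
        freq = preset.rhythm_freq_step if _in_any(t, ivs) else preset.rhythm_freq_quiet
        period = max(0.2 / freq, (1.0 / freq) * (1.0 + period_cv * rng.normal()))
        t_next = next(b for b in boundaries if b > t + 1e-12)
        cut = min(t + period, t_next)
        for offset, sink in ((0.0, pro_spikes), (0.5, ret_spikes)):
            b0 = t + offset * period
            b1 = min(b0 + burst_duty * period, cut)
            if b1 - b0 < 0.02:
                continue
            n = max(3, rng.poisson(burst_rate * (b1 - b0)))
            sink.append(np.sort(b0 + rng.uniform(0.0, b1 - b0, n)))
        t = cut

    def _series(chunks, source):
        times = np.unique(np.concatenate(chunks)) if chunks else np.empty(0)
        return EventSeries(times, "spike", source)

    return _series(pro_spikes, "protractor"), _series(ret_spikes, "retractor")


@dataclass(frozen=True)
class LoadTrial:
    """One synthetic load-stimulation session with ground truth.

    ``true_class[i]`` is the generated response class of stimulus ``i``
    (RET_ACT / PRO_ACT / NONE); the traces are pro-/retractor activity
    envelopes containing the corresponding 150 ms rate transients.
    """

    stimuli: EventSeries
    protractor: SampledTrace
    retractor: SampledTrace
    true_class: np.ndarray
    ramp_duration: float = 0.5  # command ramp plateau stored with the onsets


def make_load_trial(steps: GaitEvents, preset: GeneratorPreset, stim_rate: float = 0.5,
                    seed: int = 0, n_stim: int | None = None,
                    baseline: float = 0.2, transient_amp: float = 2.0,
                    transient_dur: float = 0.150) -> LoadTrial:
    """Load stimuli with class-dependent motor transients and ground truth.

    Each stimulus is assigned RET_ACT / PRO_ACT / NONE with the preset's
    probabilities.  NONE stimuli are placed at step-cycle phases drawn
    from von Mises(none_phase_mu, none_kappa); the other classes at
    uniform phases.  Stimuli occupy every other step cycle so adjacent
    transients and analysis windows never overlap.

    RET_ACT: retractor envelope steps up by ``transient_amp`` for
    ``transient_dur``; PRO_ACT: retractor suppressed to zero while the
    protractor steps up; NONE: no change.
    """
    if len(steps.touchdowns) < 2:
        raise ValueError("steps must contain at least one complete cycle")
    if stim_rate <= 0:
        raise ValueError("stim_rate must be positive")
    rng = np.random.default_rng(seed)
    tds = steps.touchdowns.times
    n_cycles = len(tds) - 1
    if n_stim is None:
        t0, t1 = steps.span
        n_stim = max(1, int(round(stim_rate * (t1 - t0))))
    stride = max(2, n_cycles // n_stim)
    # skip cycle 0 so the earliest stimulus keeps a full pre-stimulus window
    cycle_idx = np.arange(1, n_cycles, stride)[:n_stim]
    if len(cycle_idx) < n_stim:
        raise ValueError(
            f"need >= {2 * n_stim + 1} step cycles for {n_stim} stimuli, got {n_cycles}")

    classes = rng.choice(RESPONSE_CLASSES, size=n_stim,
                         p=[preset.p_ret_act, preset.p_pro_act, preset.p_none])
    phases = rng.uniform(0.0, 1.0, n_stim)
    none_mask = classes == "NONE"
    if none_mask.any():
        vm = rng.vonmises(2 * np.pi * preset.none_phase_mu, preset.none_kappa,
                          none_mask.sum())
        phases[none_mask] = (vm / (2 * np.pi)) % 1.0

    td = tds[cycle_idx]
    periods = tds[cycle_idx + 1] - td
    stim_times = np.sort(td + phases * periods)

    fs = preset.fs
    n_samp = int(np.ceil((tds[-1] + 1.0) * fs))
    t_axis = np.arange(n_samp) / fs
    pro = np.full(n_samp, baseline)
    ret = np.full(n_samp, baseline)
    for st, cls in zip(stim_times, classes):
        i0 = int(np.ceil(st * fs))
        i1 = min(n_samp, int(np.ceil((st + transient_dur) * fs)))
        if cls == "RET_ACT":
            ret[i0:i1] += transient_amp
        elif cls == "PRO_ACT":
            pro[i0:i1] += transient_amp
            ret[i0:i1] = 0.0
    if preset.noise_sd > 0:
        pro = pro + rng.normal(0.0, preset.noise_sd, n_samp)
        ret = ret + rng.normal(0.0, preset.noise_sd, n_samp)
    pro = np.clip(pro, 0.0, None)
    ret = np.clip(ret, 0.0, None)
    del t_axis

    return LoadTrial(
        stimuli=EventSeries(stim_times, "stim_onset", "CS"),
        protractor=SampledTrace(pro, fs, 0.0, "protractor", "a.u."),
        retractor=SampledTrace(ret, fs, 0.0, "retractor", "a.u."),
        true_class=classes,
    )


@dataclass(frozen=True)
class EmgPair:
    """Recorded agonist/antagonist EMG traces plus their true envelopes."""

    agonist: SampledTrace
    antagonist: SampledTrace
    true_env_agonist: SampledTrace
    true_env_antagonist: SampledTrace


def make_emg(steps: GaitEvents, preset: GeneratorPreset, seed: int,
             env_kappa: float = 6.0) -> EmgPair:
    """EMG pair with phase-locked bursts and known antagonist crosstalk.

    Each muscle's true envelope is a von Mises bump of step-cycle phase
    (agonist = protractor peak, antagonist = retractor peak, concentration
    ``env_kappa`` so the antagonists barely overlap).  The recorded trace
    is its own envelope multiplying a white-noise interference carrier,
    plus ``crosstalk_coeff`` times the antagonist's raw trace, plus sensor
    noise of SD ``noise_sd``.
    """
    if preset.fs < 1000:
        raise ValueError("EMG generation requires fs >= 1000 Hz")
    rng = np.random.default_rng(seed)
    t0, t1 = steps.span
    fs = preset.fs
    n = int(np.ceil((t1 - t0) * fs))
    times = t0 + np.arange(n) / fs
    theta = 2 * np.pi * _phase_of(times, steps.touchdowns.times)

    def bump(peak_deg):
        mu = np.deg2rad(peak_deg)
        e = np.exp(env_kappa * (np.cos(theta - mu) - 1.0))
        return e  # peak 1, near-zero in the antagonist's half-cycle

    env_a = bump(preset.pro_peak_deg)
    env_b = bump(preset.ret_peak_deg)
    raw_a = env_a * rng.normal(size=n)
    raw_b = env_b * rng.normal(size=n)
    rec_a = raw_a + preset.crosstalk_coeff * raw_b + rng.normal(0, preset.noise_sd, n)
    rec_b = raw_b + preset.crosstalk_coeff * raw_a + rng.normal(0, preset.noise_sd, n)

    mk = lambda v, lab: SampledTrace(v, fs, t0, lab, "a.u.")
    return EmgPair(mk(rec_a, "agonist"), mk(rec_b, "antagonist"),
                   mk(env_a, "agonist_env"), mk(env_b, "antagonist_env"))


def make_contact_trace(steps: GaitEvents, fs: float = 2000.0,
                       ramp: float = 0.010, noise_sd: float = 0.0,
                       seed: int = 0) -> SampledTrace:
    """Tarsal-contact voltage emulating the electrical touchdown monitor.

    High during stance, low during swing, with raised-cosine edges of
    total duration ``ramp`` centred on the true touchdown / lift-off, so a
    0.5 threshold crossing falls at the touchdown and the steepest slope
    at the lift-off.
    """
    tds = steps.touchdowns.times
    los = steps.liftoffs.times
    t0 = tds[0] - 5 * ramp
    t1 = tds[-1] + 5 * ramp
    n = int(np.ceil((t1 - t0) * fs))
    t = t0 + np.arange(n) / fs
    v = np.zeros(n)

    def edge(center, rising):
        x = np.clip((t - (center - ramp / 2)) / ramp, 0.0, 1.0)
        s = 0.5 * (1 - np.cos(np.pi * x))
        return s if rising else -s

    for td, lo in zip(tds[:-1], los):
        v += edge(td, True) + edge(lo, False)
    # last touchdown opens a final (unterminated) stance epoch
    v += edge(tds[-1], True)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0, noise_sd, n)
    return SampledTrace(v, fs, t0, "tarsal_contact", "V")
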