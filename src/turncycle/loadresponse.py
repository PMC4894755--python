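"""Quantification and classification of motor responses to leg-load
(campaniform sensilla) stimuli.

Per stimulus: a peristimulus time histogram of motoneuron spikes, the
maximum retractor activation in a 150 ms post-stimulus window normalized
to control stimulations, a pre/post Michelson contrast of envelope
activity, and a three-way classification into retractor activation
(RET_ACT), retractor termination with protractor activation (PRO_ACT),
or no response (NONE).  The NONE class's step-cycle phases can then be
tested for a phase preference with circular statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circstats import CircularSummary, mean_vector
from .core import EventSeries, SampledTrace
from .stepcycle import StepCycle, phase_at

__all__ = [
    "StimulusResponse",
    "PSTH",
    "psth",
    "response_magnitude",
    "michelson_contrast",
    "classify_response",
    "classify_all",
    "response_vs_phase",
    "select_control_stimuli",
]

RESPONSE_WINDOW = 0.150      # s, post-stimulus window for the max activation
CONTRAST_WINDOW = 0.100      # s, pre/post windows of the Michelson contrast
ACT_THRESHOLD = 0.5          # contrast >= this: activation
TERM_THRESHOLD = -0.5        # contrast <= this: termination
MIN_CLASS_N = 8              # minimum responses for a circular phase test


@dataclass(frozen=True)
class StimulusResponse:
    """One load stimulus with its phase, magnitude, contrasts and class."""

    stim_time: float
    phase: float                 # cycle fraction, NaN if outside any cycle
    magnitude: float             # max 150 ms activation / control mean max
    contrast_ret: float
    contrast_pro: float
    klass: str                   # RET_ACT | PRO_ACT | NONE

    def __post_init__(self) -> None:
        if self.magnitude < 0 or not np.isnan(self.contrast_ret) and abs(self.contrast_ret) > 1 + 1e-9:
            raise ValueError("invalid response statistics")


@dataclass(frozen=True)
class PSTH:
    """Peristimulus time histogram summed over stimuli."""

    edges: np.ndarray            # bin edges in seconds relative to stimulus
    counts: np.ndarray           # summed event counts per bin
    n_stimuli: int


def psth(events: EventSeries, stim_times: EventSeries, pre: float, post: float,
         bin: float) -> PSTH:
    """Event counts binned by lag from each stimulus, summed over stimuli.

    Bins span [-pre, +post) with one bin edge exactly at lag 0.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be non-negative")
    if len(stim_times) == 0:
        raise ValueError("no stimuli")
    n_pre = int(np.ceil(pre / bin - 1e-9))
    n_post = int(np.ceil(post / bin - 1e-9))
    edges = np.arange(-n_pre, n_post + 1) * bin
    counts = np.zeros(n_pre + n_post, dtype=int)
    for st in stim_times.times:
        lags = events.times - st
        counts += np.histogram(lags, bins=edges)[0]
    return PSTH(edges=edges, counts=counts, n_stimuli=len(stim_times))


def response_magnitude(retractor_env: SampledTrace, stim_time: float,
                       control_max_mean: float,
                       window: float = RESPONSE_WINDOW) -> float:
    """Maximum activation within ``window`` after the stimulus, normalized.

    The envelope should be rectified and Gaussian-smoothed (100 ms width)
    beforehand; ``control_max_mean`` is the mean of the same maxima over
    control stimulations and must be positive.
    """
    if control_max_mean <= 0:
        raise ValueError("control_max_mean must be positive")
    i0 = retractor_env.index_at(stim_time)
    i1 = retractor_env.index_at(stim_time + window)
    if i0 < 0 or i1 >= len(retractor_env) or stim_time < retractor_env.t0:
        raise ValueError("response window exceeds the trace")
    return float(retractor_env.values[i0:i1 + 1].max() / control_max_mean)


def michelson_contrast(env: SampledTrace, stim_time: float,
                       w: float = CONTRAST_WINDOW) -> float:
    """(post - pre)/(post + pre) contrast of mean envelope activity.

    ``pre`` is the mean over [stim - w, stim), ``post`` over
    (stim, stim + w].  Positive values indicate an increase after the
    stimulus.  Both windows must lie within the trace and the envelope
    must be non-negative (rectified); 0/0 is defined as 0 (a silent trace
    shows no response).
    """
    nw = int(round(w * env.fs))
    i_stim = env.index_at(stim_time)
    if i_stim - nw < 0 or i_stim + 1 + nw > len(env):
        raise ValueError("contrast windows exceed the trace")
    pre = env.values[i_stim - nw:i_stim]
    post = env.values[i_stim + 1:i_stim + 1 + nw]
    if (pre < 0).any() or (post < 0).any():
        raise ValueError("envelope has negative values; rectify first")
    m_pre, m_post = pre.mean(), post.mean()
    if m_pre + m_post == 0:
        return 0.0
    return float((m_post - m_pre) / (m_post + m_pre))


def classify_response(pro_env: SampledTrace, ret_env: SampledTrace,
                      stim_time: float,
                      act_threshold: float = ACT_THRESHOLD,
                      term_threshold: float = TERM_THRESHOLD,
                      w: float = CONTRAST_WINDOW) -> str:
    """Three-way response class from the two muscles' contrasts.

    RET_ACT if the retractor contrast reaches ``act_threshold``; PRO_ACT
    if the protractor contrast reaches ``act_threshold`` while the
    retractor contrast falls to ``term_threshold``; NONE otherwise.
    """
    c_ret = michelson_contrast(ret_env, stim_time, w)
    c_pro = michelson_contrast(pro_env, stim_time, w)
    if c_ret >= act_threshold:
        return "RET_ACT"
    if c_pro >= act_threshold and c_ret <= term_threshold:
        return "PRO_ACT"
    return "NONE"


def classify_all(pro_env: SampledTrace, ret_env: SampledTrace,
                 stimuli: EventSeries, steps: list[StepCycle] | None = None,
                 act_threshold: float = ACT_THRESHOLD,
                 term_threshold: float = TERM_THRESHOLD,
                 w: float = CONTRAST_WINDOW) -> list[StimulusResponse]:
    """Classify every stimulus and attach phases and contrasts.

    Magnitude is normalized to the mean post-stimulus retractor maximum
    over all stimuli (a within-session reference); phases come from
    ``phase_at`` when ``steps`` is given.
    """
    maxima = []
    for st in stimuli.times:
        i0 = ret_env.index_at(st)
        i1 = min(len(ret_env) - 1, ret_env.index_at(st + RESPONSE_WINDOW))
        maxima.append(ret_env.values[i0:i1 + 1].max())
    control = float(np.mean(maxima)) if maxima else 1.0
    control = control if control > 0 else 1.0

    out = []
    for st in stimuli.times:
        c_ret = michelson_contrast(ret_env, st, w)
        c_pro = michelson_contrast(pro_env, st, w)
        if c_ret >= act_threshold:
            klass = "RET_ACT"
        elif c_pro >= act_threshold and c_ret <= term_threshold:
            klass = "PRO_ACT"
        else:
            klass = "NONE"
        phase = phase_at(st, steps) if steps else float("nan")
        out.append(StimulusResponse(
            stim_time=float(st), phase=float(phase),
            magnitude=response_magnitude(ret_env, st, control),
            contrast_ret=c_ret, contrast_pro=c_pro, klass=klass))
    return out


def response_vs_phase(responses: list[StimulusResponse],
                      steps: list[StepCycle], klass: str = "NONE",
                      ) -> tuple[list[StimulusResponse], CircularSummary | None]:
    """Attach step-cycle phases and test the selected class for a phase
    preference.

    Returns the phase-annotated responses and the circular summary (mean
    phase, R, Rayleigh p) of the selected class, or None when fewer than
    8 phased responses of that class exist (too few for the test).
    """
    annotated = []
    for r in responses:
        phase = r.phase if not np.isnan(r.phase) else phase_at(r.stim_time, steps)
        annotated.append(StimulusResponse(r.stim_time, float(phase), r.magnitude,
                                          r.contrast_ret, r.contrast_pro, r.klass))
    phases = np.array([r.phase for r in annotated
                       if r.klass == klass and not np.isnan(r.phase)])
    if len(phases) < MIN_CLASS_N:
        return annotated, None
    return annotated, mean_vector(phases, unit="fraction")


def select_control_stimuli(stimuli: EventSeries, touchdowns: EventSeries,
                           mean_period: float) -> EventSeries:
    """Stimuli delivered in the quiescent animal.

    A stimulus counts as a control when no step touchdown occurs within
    one mean period on either side of it.
    """
    tds = touchdowns.times
    keep = []
    for st in stimuli.times:
        i = np.searchsorted(tds, st)
        near = []
        if i > 0:
            near.append(st - tds[i - 1])
        if i < len(tds):
            near.append(tds[i] - st)
        if not near or min(near) > mean_period:
            keep.append(st)
    return EventSeries(np.asarray(keep), "stim_onset", stimuli.source)
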