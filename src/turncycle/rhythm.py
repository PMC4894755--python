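"""Burst detection, CPG cycle-frequency estimation, antagonist
cross-correlation and quiet-vs-stepping frequency comparison.

The slow alternating pro-/retractor rhythm of the pharmacologically
activated, deafferented ganglion is quantified by grouping spikes into
bursts (inter-spike-interval criterion), taking cycle frequency as the
inverse mean inter-onset interval — robust with fewer than ten cycles —
and characterising alternation by the lag-wise Pearson cross-correlation
of the two envelopes (dip at lag 0, peaks near half a cycle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import EventSeries, SampledTrace, _check_aligned
from .stepcycle import TestResult

__all__ = [
    "BurstTrain",
    "CrossCorrelation",
    "detect_bursts",
    "rhythm_frequency",
    "compare_frequencies",
    "cross_correlate",
]

MAX_ISI = 0.2     # s, default intra-burst inter-spike-interval bound
MIN_SPIKES = 3    # default minimum spikes per burst


@dataclass(frozen=True)
class BurstTrain:
    """Burst onsets/offsets of one nerve; onset_k < offset_k < onset_{k+1}."""

    onsets: np.ndarray
    offsets: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        on = np.asarray(self.onsets, dtype=float)
        off = np.asarray(self.offsets, dtype=float)
        if len(on) != len(off):
            raise ValueError("onsets and offsets differ in length")
        if len(on) and (np.any(off < on) or np.any(on[1:] <= off[:-1])):
            raise ValueError("bursts must be ordered and non-overlapping")
        object.__setattr__(self, "onsets", on)
        object.__setattr__(self, "offsets", off)

    def __len__(self) -> int:
        return len(self.onsets)


def detect_bursts(spikes: EventSeries, max_isi: float = MAX_ISI,
                  min_spikes: int = MIN_SPIKES) -> BurstTrain:
    """Group spikes into bursts by an inter-spike-interval criterion.

    A burst is a maximal run of spikes whose consecutive intervals are
    all <= ``max_isi`` and which contains at least ``min_spikes`` spikes;
    onset/offset are the first/last spike of the run.
    """
    t = spikes.times
    if len(t) == 0:
        return BurstTrain(np.empty(0), np.empty(0), spikes.source)
    breaks = np.flatnonzero(np.diff(t) > max_isi)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [len(t) - 1]))
    keep = (stops - starts + 1) >= min_spikes
    return BurstTrain(t[starts[keep]], t[stops[keep]], spikes.source)


def rhythm_frequency(bursts: BurstTrain, interval: tuple[float, float] | None = None,
                     ) -> float:
    """Cycle frequency as the inverse mean inter-onset interval (Hz).

    Only burst onsets within ``interval`` (if given) are used; with
    fewer than two onsets the frequency is undefined and NaN is
    returned.
    """
    onsets = bursts.onsets
    if interval is not None:
        a, b = interval
        onsets = onsets[(onsets >= a) & (onsets <= b)]
    if len(onsets) < 2:
        return float("nan")
    return float(1.0 / np.mean(np.diff(onsets)))


def compare_frequencies(quiet, stepping, paired: bool = True) -> TestResult:
    """Compare quiescent vs stepping cycle frequencies across animals.

    Paired t-test by default (each animal contributes one quiet and one
    stepping frequency); Welch's unequal-variance t-test otherwise.
    """
    q = np.asarray(quiet, dtype=float)
    s = np.asarray(stepping, dtype=float)
    if len(q) < 2 or len(s) < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if len(q) != len(s):
            raise ValueError("paired comparison needs equal group sizes")
        d = s - q
        if np.allclose(d, 0):
            return TestResult(0.0, float(len(d) - 1), 1.0)
        t, p = sps.ttest_rel(q, s)
        return TestResult(float(t), float(len(q) - 1), float(p))
    if q.var(ddof=1) == 0 and s.var(ddof=1) == 0 and q.mean() == s.mean():
        return TestResult(0.0, float(len(q) + len(s) - 2), 1.0)
    t, p = sps.ttest_ind(q, s, equal_var=False)
    return TestResult(float(t), None, float(p))


@dataclass(frozen=True)
class CrossCorrelation:
    """Lag-wise Pearson correlation; positive lag means B follows A."""

    lags: np.ndarray
    r: np.ndarray

    @property
    def peak_lag(self) -> float:
        return float(self.lags[int(np.argmax(self.r))])


def cross_correlate(env_a: SampledTrace, env_b: SampledTrace,
                    max_lag: float) -> CrossCorrelation:
    """Normalized cross-correlation over the full record.

    At each lag the overlapping segments are correlated (Pearson), so
    values are in [-1, 1] and scale-free; r(lag) = corr(A(t), B(t+lag)),
    hence the argmax sits at +delta when B is A delayed by delta.
    Antagonistic alternation shows as a minimum at lag 0 and maxima near
    +/- half the cycle period.
    """
    _check_aligned(env_a, env_b)
    a = env_a.values
    b = env_b.values
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    max_k = int(round(max_lag * env_a.fs))
    if max_k >= len(a):
        raise ValueError("max_lag must be shorter than the trace")
    lags = np.arange(-max_k, max_k + 1) / env_a.fs
    r = np.empty(len(lags))
    for j, k in enumerate(range(-max_k, max_k + 1)):
        if k >= 0:
            x, y = a[:len(a) - k], b[k:]
        else:
            x, y = a[-k:], b[:len(b) + k]
        sx, sy = x.std(), y.std()
        r[j] = 0.0 if sx == 0 or sy == 0 else float(
            np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return CrossCorrelation(lags=lags, r=r)
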