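"""Stance-anchored step cycles: segmentation, period statistics, cycle
phases, first-spike latencies and step-triggered average profiles.

A step cycle runs from one touchdown (stance onset, the anterior extreme
position) to the next; phase 0 of the cycle is anchored at the touchdown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .conditioning import normalize_per_step
from .core import EventSeries, SampledTrace

__all__ = [
    "StepCycle",
    "PeriodStats",
    "TestResult",
    "segment_steps",
    "period_stats",
    "compare_periods",
    "phase_at",
    "first_spike_latency",
    "step_triggered_average",
]

log = logging.getLogger(__name__)

PAUSE_SD_FACTOR = 5.0  # periods beyond mean + 5 SD are treated as pauses


@dataclass(frozen=True)
class StepCycle:
    """One stance-anchored gait cycle of one leg."""

    leg: str                 # "FL" or "ML"
    side: str                # "inside" or "outside"
    touchdown: float
    liftoff: float
    next_touchdown: float

    def __post_init__(self) -> None:
        if not self.touchdown < self.liftoff < self.next_touchdown:
            raise ValueError("require touchdown < liftoff < next_touchdown")

    @property
    def period(self) -> float:
        return self.next_touchdown - self.touchdown

    @property
    def stance(self) -> float:
        return self.liftoff - self.touchdown

    @property
    def swing(self) -> float:
        return self.next_touchdown - self.liftoff


def segment_steps(touchdowns: EventSeries, liftoffs: EventSeries,
                  leg: str = "FL", side: str = "inside",
                  drop_pauses: bool = True) -> list[StepCycle]:
    """Pair touchdowns with the unique lift-off before the next touchdown.

    Cycles with zero or more than one intervening lift-off are rejected
    (and logged); unpaired leading/trailing events are dropped.  With
    ``drop_pauses`` (default), cycles whose period exceeds
    mean + 5 SD of the accepted periods are flagged as walking pauses and
    excluded, since the analysis targets continuous stepping sequences.
    """
    tds = touchdowns.times
    los = liftoffs.times
    cycles: list[StepCycle] = []
    rejected = 0
    for td, nxt in zip(tds[:-1], tds[1:]):
        inside = los[(los > td) & (los < nxt)]
        if len(inside) != 1:
            rejected += 1
            log.info("rejected cycle at t=%.3f: %d lift-offs", td, len(inside))
            continue
        cycles.append(StepCycle(leg, side, float(td), float(inside[0]), float(nxt)))
    if rejected:
        log.info("segment_steps: %d of %d cycles rejected", rejected, len(tds) - 1)
    if drop_pauses and len(cycles) >= 3:
        periods = np.array([c.period for c in cycles])
        cutoff = periods.mean() + PAUSE_SD_FACTOR * periods.std(ddof=1)
        kept = [c for c in cycles if c.period <= cutoff]
        if len(kept) < len(cycles):
            log.info("segment_steps: %d pause cycles excluded", len(cycles) - len(kept))
        cycles = kept
    return cycles


@dataclass(frozen=True)
class PeriodStats:
    mean: float
    sd: float
    n: int


def period_stats(steps: list[StepCycle]) -> PeriodStats:
    """Arithmetic mean and sample SD of the step periods."""
    if not steps:
        raise ValueError("need at least one step cycle")
    periods = np.array([c.period for c in steps])
    sd = float(periods.std(ddof=1)) if len(periods) > 1 else 0.0
    return PeriodStats(mean=float(periods.mean()), sd=sd, n=len(periods))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p: float


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        return float(len(a) + len(b) - 2)
    return float((va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)))


def compare_periods(group_a, group_b, method: str = "welch") -> TestResult:
    """Two-sided comparison of per-sequence mean periods.

    ``method="welch"`` (default) is Welch's unequal-variance t-test;
    ``method="ranksum"`` is the Wilcoxon rank-sum alternative.  Inputs
    are arrays of per-sequence mean periods (one value per stepping
    sequence), the comparison unit used for between-condition contrasts.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2 sequences")
    if method == "welch":
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            return TestResult(0.0, _welch_df(a, b), 1.0)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(float(t), _welch_df(a, b), float(p))
    if method == "ranksum":
        s, p = sps.ranksums(a, b)
        return TestResult(float(s), None, float(p))
    raise ValueError(f"unknown method {method!r}")


def phase_at(t, steps: list[StepCycle]):
    """Step-cycle phase (cycle fraction in [0, 1)) of time ``t``.

    Returns NaN for times outside every cycle (e.g. between stepping
    sequences).  Accepts a scalar or an array of times.
    """
    tds = np.array([c.touchdown for c in steps])
    nxt = np.array([c.next_touchdown for c in steps])
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(tds, tt, side="right") - 1
    phase = np.full(len(tt), np.nan)
    ok = idx >= 0
    i = np.clip(idx, 0, None)
    within = ok & (tt < nxt[i])
    phase[within] = (tt[within] - tds[i[within]]) / (nxt[i[within]] - tds[i[within]])
    return float(phase[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else phase


def first_spike_latency(spikes: EventSeries, anchor: str,
                        steps: list[StepCycle]) -> np.ndarray:
    """Normalized latency of the first spike after the anchor, per cycle.

    ``anchor`` is "touchdown" or "liftoff".  The latency (first spike at
    or after the anchor, minus the anchor time) is divided by the cycle's
    period; cycles whose anchor-to-cycle-end window holds no spike are
    returned as NaN and should be excluded from averages.
    """
    if anchor not in ("touchdown", "liftoff"):
        raise ValueError("anchor must be 'touchdown' or 'liftoff'")
    times = spikes.times
    out = np.full(len(steps), np.nan)
    for k, c in enumerate(steps):
        t_anchor = c.touchdown if anchor == "touchdown" else c.liftoff
        i = np.searchsorted(times, t_anchor)
        if i < len(times) and times[i] < c.next_touchdown:
            out[k] = (times[i] - t_anchor) / c.period
    return out


def step_triggered_average(trace: SampledTrace, steps: list[StepCycle],
                           n_bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean normalized activity profile over the step cycle.

    Each step's trace segment is min-max normalized to [0, 1], resampled
    by linear interpolation onto ``n_bins`` phase-bin centres, and
    averaged across steps.  Returns (bin_centres, mean, sd); steps
    falling outside the trace span are skipped (and logged).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    centres = (np.arange(n_bins) + 0.5) / n_bins
    profiles = []
    t_end = trace.t0 + len(trace) / trace.fs
    for c in steps:
        if c.touchdown < trace.t0 or c.next_touchdown > t_end:
            log.info("step at t=%.3f outside trace span, skipped", c.touchdown)
            continue
        seg = normalize_per_step(trace, c)
        seg_phase = (seg.times - c.touchdown) / c.period
        if len(seg) < 2:
            continue
        profiles.append(np.interp(centres, seg_phase, seg.values))
    if not profiles:
        raise ValueError("no step overlaps the trace span")
    arr = np.vstack(profiles)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(n_bins)
    return centres, arr.mean(axis=0), sd
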