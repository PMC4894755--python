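"""Trace-level preprocessing: rectification, smoothing, per-step
normalization, antagonist-crosstalk subtraction, and event detection
from tarsal-contact and nerve signals.

Smoothing uses truncated, renormalized windows at the edges (no padding),
so constant traces are fixed points of every smoother.
"""

from __future__ import annotations

import numpy as np

from .core import EventSeries, SampledTrace, _check_aligned

__all__ = [
    "rectify",
    "smooth_boxcar",
    "smooth_gaussian",
    "remove_crosstalk",
    "normalize_per_step",
    "condition_envelope",
    "detect_contact_events",
    "detect_spikes",
]


def rectify(trace: SampledTrace) -> SampledTrace:
    """Full-wave rectification (elementwise absolute value)."""
    return trace.with_values(np.abs(trace.values))


def _smooth_with_kernel(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # Truncated windows at the edges, renormalized by the weight actually
    # inside the trace, so a constant input is returned unchanged.
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def smooth_boxcar(trace: SampledTrace, T: float = 0.05) -> SampledTrace:
    """Centered moving average over the window [t-T, t+T]."""
    if T < 0:
        raise ValueError("T must be non-negative")
    half = int(round(T * trace.fs))
    if half == 0:
        return trace.with_values(trace.values.copy())
    kernel = np.ones(2 * half + 1)
    return trace.with_values(_smooth_with_kernel(trace.values, kernel))


def smooth_gaussian(trace: SampledTrace, width: float = 0.1) -> SampledTrace:
    """Running Gaussian average of total support ``width`` seconds.

    The kernel has sigma = width/4 and is truncated at +/- width/2
    (i.e. +/- 2 sigma) and renormalized.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    sigma = width / 4.0
    half = int(round(width / 2.0 * trace.fs))
    if half == 0:
        return trace.with_values(trace.values.copy())
    t = np.arange(-half, half + 1) / trace.fs
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    return trace.with_values(_smooth_with_kernel(trace.values, kernel))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def remove_crosstalk(agonist: SampledTrace, antagonist: SampledTrace,
                     cap: float = 0.5) -> SampledTrace:
    """Subtract rescaled antagonist activity from the agonist envelope.

    Both inputs should already be rectified and smoothed.  The agonist is
    min-max normalized to [0, 1]; the antagonist is rescaled so its
    minimum is 0 and its maximum ``cap`` (default 0.5, reflecting the
    smaller size of the antagonist's bleed-through in the agonist
    channel), then subtracted pointwise.  Negative residuals are clipped
    to 0 since rectified envelopes are non-negative by definition.  A
    constant antagonist rescales to all-zero and leaves the agonist
    unchanged.
    """
    _check_aligned(agonist, antagonist)
    ago = _minmax(agonist.values)
    anta = _minmax(antagonist.values) * cap
    return agonist.with_values(np.clip(ago - anta, 0.0, None))


def normalize_per_step(trace: SampledTrace, step) -> SampledTrace:
    """Min-max normalize the trace segment of one step cycle to [0, 1].

    A constant segment maps to all zeros.  ``step`` is any object with
    ``touchdown`` and ``next_touchdown`` attributes (seconds).
    """
    seg = trace.slice(step.touchdown, step.next_touchdown)
    return seg.with_values(_minmax(seg.values))


def condition_envelope(trace: SampledTrace, width: float = 0.1) -> SampledTrace:
    """Standard envelope pipeline: rectify then Gaussian-smooth."""
    return smooth_gaussian(rectify(trace), width)


def detect_contact_events(contact: SampledTrace, td_threshold: float,
                          ) -> tuple[EventSeries, EventSeries]:
    """Touchdowns and lift-offs from a tarsal-contact voltage trace.

    Touchdown is the upward crossing of ``td_threshold`` (sub-sample time
    by linear interpolation across the crossing samples).  Lift-off is
    the time of steepest descending slope within the release transition
    of each contact epoch (ties resolved to the earliest sample).
    Alternation touchdown, lift-off, touchdown, ... is enforced; a trace
    with no crossings yields empty series.
    """
    v = contact.values
    fs = contact.fs
    above = v >= td_threshold
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1    # first sample above
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1  # first sample below
    if len(up) == 0:
        return (EventSeries(np.empty(0), "touchdown", contact.label),
                EventSeries(np.empty(0), "liftoff", contact.label))
    down = down[down > up[0]]  # drop a release preceding the first contact

    touchdowns = []
    for i in up:
        frac = (td_threshold - v[i - 1]) / (v[i] - v[i - 1])
        touchdowns.append(contact.t0 + (i - 1 + frac) / fs)

    liftoffs = []
    diffs = np.diff(v)
    for k, i_dn in enumerate(down):
        i_up = up[np.searchsorted(up, i_dn) - 1]       # contact onset of epoch
        i_mid = (i_up + i_dn) // 2
        i_end = up[k + 1] if k + 1 < len(up) else len(v) - 1
        seg = diffs[i_mid:i_end]
        if len(seg) == 0:
            continue
        j = i_mid + int(np.argmin(seg))                # steepest fall, earliest tie
        liftoffs.append(contact.t0 + j / fs)

    return (EventSeries(np.asarray(touchdowns), "touchdown", contact.label),
            EventSeries(np.asarray(liftoffs), "liftoff", contact.label))


def detect_spikes(trace: SampledTrace, threshold: float,
                  dead_time: float = 0.001) -> EventSeries:
    """One spike per supra-threshold excursion of a rectified trace.

    Each excursion is timestamped at its local maximum; excursions whose
    gaps are shorter than ``dead_time`` are merged into one spike.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = trace.values
    above = v > threshold
    if not above.any():
        return EventSeries(np.empty(0), "spike", trace.label)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        stops = np.concatenate((stops, [len(v)]))

    gap = int(round(dead_time * trace.fs))
    merged: list[list[int]] = [[starts[0], stops[0]]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    peaks = [s + int(np.argmax(v[s:e])) for s, e in merged]
    times = trace.t0 + np.asarray(peaks, dtype=float) / trace.fs
    return EventSeries(times, "spike", trace.label)
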