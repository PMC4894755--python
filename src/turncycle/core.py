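"""Core containers: uniformly sampled traces and time-stamped event series.

These two types are the substrate of every stage of the pipeline: traces
carry EMG / nerve / tarsal-contact signals with their sampling rate, event
series carry touchdowns, lift-offs, stimulus onsets and spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SampledTrace", "EventSeries"]

EVENT_KINDS = ("touchdown", "liftoff", "stim_onset", "spike")


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array-like
        Sample amplitudes. Must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    label : str
        Free-form channel label (e.g. ``"retractor"``).
    units : str
        Physical units of the samples.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""
    units: str = "a.u."

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            raise ValueError("trace values must be finite")
        if not self.fs > 0:
            raise ValueError("sampling rate fs must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    def index_at(self, t: float) -> int:
        """Index of the sample closest to time ``t``."""
        return int(round((t - self.t0) * self.fs))

    def with_values(self, values: np.ndarray, label: str | None = None) -> "SampledTrace":
        """New trace with the same clock but different samples."""
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)

    def slice(self, t_start: float, t_stop: float) -> "SampledTrace":
        """Samples with t_start <= t < t_stop, keeping the clock."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.fs - 1e-9)))
        i1 = min(len(self.values), int(np.ceil((t_stop - self.t0) * self.fs - 1e-9)))
        if i1 <= i0:
            raise ValueError("empty trace slice")
        return replace(self, values=self.values[i0:i1], t0=self.t0 + i0 / self.fs)


def _check_aligned(a: SampledTrace, b: SampledTrace) -> None:
    if a.fs != b.fs or len(a) != len(b) or abs(a.t0 - b.t0) > 1e-12:
        raise ValueError("traces are not aligned (fs, t0 and length must match)")


@dataclass(frozen=True)
class EventSeries:
    """Sorted time stamps of one kind of event from one source.

    ``kind`` is one of touchdown / liftoff / stim_onset / spike; ``source``
    names the leg or nerve the events belong to.
    """

    times: np.ndarray
    kind: str
    source: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("event times must be one-dimensional")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        if len(t) and t[0] < 0:
            raise ValueError("event times must be non-negative")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)

    def between(self, t_start: float, t_stop: float) -> "EventSeries":
        m = (self.times >= t_start) & (self.times < t_stop)
        return EventSeries(self.times[m], self.kind, self.source)
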