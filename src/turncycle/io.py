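"""Delimited-text I/O for event tables, sampled traces and presets.

Event tables are CSV with columns (time_s, kind, source); traces are CSV
with a commented header carrying fs, t0 and units and a single value
column.  Presets serialize to YAML.  Every writer accepts optional
provenance lines (seed, config hash) that are prepended as comments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EventSeries, SampledTrace
from .presets import GeneratorPreset

__all__ = [
    "write_events", "read_events",
    "write_trace", "read_trace",
    "write_preset", "read_preset",
]


def _write_with_header(path, df: pd.DataFrame, header: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def _read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    return meta


def write_events(path, series: EventSeries | list[EventSeries],
                 provenance: dict | None = None) -> None:
    items = [series] if isinstance(series, EventSeries) else list(series)
    df = pd.concat([
        pd.DataFrame({"time_s": s.times, "kind": s.kind, "source": s.source})
        for s in items
    ]).sort_values("time_s", kind="stable")
    _write_with_header(path, df, provenance)


def read_events(path, kind: str | None = None,
                source: str | None = None) -> list[EventSeries]:
    """Read an event table back into one EventSeries per (kind, source)."""
    df = pd.read_csv(path, comment="#")
    df["source"] = df["source"].fillna("")
    if kind is not None:
        df = df[df["kind"] == kind]
    if source is not None:
        df = df[df["source"] == source]
    out = []
    for (k, src), grp in df.groupby(["kind", "source"], sort=False):
        out.append(EventSeries(np.sort(grp["time_s"].to_numpy()), k, src))
    return out


def write_trace(path, trace: SampledTrace, provenance: dict | None = None) -> None:
    header = {"fs": trace.fs, "t0": trace.t0, "units": trace.units,
              "label": trace.label, **(provenance or {})}
    _write_with_header(path, pd.DataFrame({"value": trace.values}), header)


def read_trace(path) -> SampledTrace:
    meta = _read_header(path)
    df = pd.read_csv(path, comment="#")
    return SampledTrace(df["value"].to_numpy(), fs=float(meta["fs"]),
                        t0=float(meta.get("t0", 0.0)),
                        label=meta.get("label", ""), units=meta.get("units", "a.u."))


def write_preset(path, preset: GeneratorPreset) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(preset.to_dict(), fh, sort_keys=False)


def read_preset(path) -> GeneratorPreset:
    with open(path) as fh:
        return GeneratorPreset(**yaml.safe_load(fh))
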