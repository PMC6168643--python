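"""File formats: flat little-endian float32 traces with JSON sidecars,
spike-time and sweep CSVs, and per-unit metric tables.

Layout of a session directory::

    session/
      trace.bin        float32 little-endian raw trace (optional)
      session.json     fs, stim_times, metadata, generator config echo, seed
      spikes.csv       ground-truth or detected spike times (unit_id, time_s)

Sweep sets are stored as ``sweeps.csv`` (one column per sweep) plus
``sweeps.json`` (fs, pulse_times, mode, holding).  Times are written in
seconds with 6 decimals; CSVs are UTF-8, comma-separated with a header
row and '.' decimal marks.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import GroundTruth, RecordingSession, SessionMetadata, SweepSet

__all__ = [
    "write_session",
    "read_session",
    "write_sweep_set",
    "read_sweep_set",
    "read_spike_csv",
    "write_spike_csv",
]


def write_session(path: str | Path, session: RecordingSession,
                  truth: Optional[GroundTruth] = None) -> Path:
    """Write a session directory (trace.bin + session.json [+ spikes.csv])."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "fs": session.fs,
        "stim_times": [round(float(t), 6) for t in session.stim_times],
        "metadata": {
            "state": session.metadata.state,
            "pathway": session.metadata.pathway,
            "epoch": session.metadata.epoch,
        },
        "has_trace": session.trace is not None,
    }
    if truth is not None:
        sidecar["config"] = truth.params
        sidecar["seed"] = truth.seed
    if session.trace is not None:
        session.trace.astype("<f4").tofile(path / "trace.bin")
    (path / "session.json").write_text(json.dumps(sidecar, indent=1))
    if truth is not None and truth.spike_times:
        write_spike_csv(path / "spikes.csv", truth.spike_times)
    return path


def read_session(path: str | Path) -> tuple[RecordingSession, Optional[dict]]:
    """Read a session directory; returns the session and the spike-time
    dict from ``spikes.csv`` when present."""
    path = Path(path)
    sidecar = json.loads((path / "session.json").read_text())
    trace = None
    if sidecar.get("has_trace") and (path / "trace.bin").exists():
        trace = np.fromfile(path / "trace.bin", dtype="<f4")
    meta = SessionMetadata(**sidecar.get("metadata", {}))
    session = RecordingSession(
        trace=trace, fs=sidecar["fs"],
        stim_times=np.asarray(sidecar["stim_times"], dtype=float),
        metadata=meta,
    )
    spikes = None
    if (path / "spikes.csv").exists():
        spikes = read_spike_csv(path / "spikes.csv")
    return session, spikes


def write_spike_csv(path: str | Path, spike_times: dict) -> None:
    rows = []
    for uid, times in spike_times.items():
        for t in np.asarray(times, dtype=float):
            rows.append((uid, round(float(t), 6)))
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def read_spike_csv(path: str | Path) -> dict:
    """Read a (unit_id, time_s) CSV into a dict of sorted time arrays.

    Unsorted times are sorted on read with a warning.
    """
    df = pd.read_csv(path)
    out = {}
    for uid, grp in df.groupby("unit_id", sort=False):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            warnings.warn(f"unsorted spike times for unit {uid!r}; sorting",
                          UserWarning)
            t = np.sort(t)
        out[uid] = t
    return out


def write_sweep_set(path: str | Path, sweeps: SweepSet) -> Path:
    """Write a sweep-set directory (sweeps.csv + sweeps.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(sweeps.sweeps.T,
                      columns=[f"sweep_{i}" for i in range(sweeps.n_sweeps)])
    df.to_csv(path / "sweeps.csv", index=False, float_format="%.6f")
    sidecar = {
        "fs": sweeps.fs,
        "pulse_times": [round(float(t), 6) for t in sweeps.pulse_times],
        "mode": sweeps.mode,
        "holding": sweeps.holding,
    }
    (path / "sweeps.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_sweep_set(path: str | Path) -> SweepSet:
    path = Path(path)
    sidecar = json.loads((path / "sweeps.json").read_text())
    df = pd.read_csv(path / "sweeps.csv")
    return SweepSet(
        sweeps=df.to_numpy(dtype=float).T,
        fs=sidecar["fs"],
        pulse_times=np.asarray(sidecar["pulse_times"], dtype=float),
        mode=sidecar.get("mode", "current_clamp"),
        holding=sidecar.get("holding", -60.0),
    )
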