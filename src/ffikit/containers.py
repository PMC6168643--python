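"""Shared data containers for extracellular sessions and intracellular sweep sets.

Conventions used throughout the package:

* event/stimulus/pulse times are in **seconds**; stimulus-relative lags in
  seconds; bins are half-open ``[edge_i, edge_{i+1})``
* spike-waveform widths and PSP kinetics are reported in **milliseconds**
* voltages in mV, currents in pA, rates in spikes/s
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

__all__ = ["RecordingSession", "SessionMetadata", "SweepSet", "GroundTruth"]

_STATES = ("rest", "run", "iso")
_PATHWAYS = ("CLA", "BLA", "MD", "control")
_EPOCHS = ("baseline", "post_CNO")


@dataclass
class SessionMetadata:
    """Behavioral / experimental context of an extracellular recording."""

    state: str = "rest"
    pathway: str = "CLA"
    epoch: str = "baseline"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}, got {self.state!r}")
        if self.pathway not in _PATHWAYS:
            raise ValueError(f"pathway must be one of {_PATHWAYS}, got {self.pathway!r}")
        if self.epoch not in _EPOCHS:
            raise ValueError(f"epoch must be one of {_EPOCHS}, got {self.epoch!r}")


@dataclass
class RecordingSession:
    """A continuous extracellular voltage trace with stimulus times.

    ``trace`` may be ``None`` for spike-time-only sessions (pre-extracted
    event lists), in which case detection steps are skipped downstream.
    """

    trace: Optional[np.ndarray]
    fs: float
    stim_times: np.ndarray
    metadata: SessionMetadata = field(default_factory=SessionMetadata)

    def __post_init__(self) -> None:
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.stim_times.size and np.any(np.diff(self.stim_times) <= 0):
            raise ValueError("stim_times must be strictly increasing")
        if self.trace is not None:
            self.trace = np.asarray(self.trace, dtype=np.float32)
            dur = self.trace.size / self.fs
            if self.stim_times.size and (
                self.stim_times[0] < 0 or self.stim_times[-1] > dur
            ):
                raise ValueError("stim_times must lie within the trace duration")

    @property
    def duration(self) -> Optional[float]:
        if self.trace is None:
            return None
        return self.trace.size / self.fs


@dataclass
class SweepSet:
    """Stimulus-aligned intracellular sweeps (one row per trial)."""

    sweeps: np.ndarray  # (n_sweeps, n_samples), mV or pA
    fs: float
    pulse_times: np.ndarray  # s, within sweep
    mode: str = "current_clamp"
    holding: float = -60.0  # mV

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown recording mode {self.mode!r}")
        dur = self.sweeps.shape[1] / self.fs
        if self.pulse_times.size and (
            self.pulse_times.min() < 0 or self.pulse_times.max() >= dur
        ):
            raise ValueError("pulse_times must lie within the sweep")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def duration(self) -> float:
        return self.sweeps.shape[1] / self.fs


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every synthetic recording.

    ``spike_times`` maps unit id -> planted spike times (s); ``clean`` is the
    noise-free rendered trace or sweep matrix; ``params`` echoes the full
    generator configuration so the recording regenerates deterministically
    from ``(params, seed)``.
    """

    spike_times: dict[Any, np.ndarray] = field(default_factory=dict)
    clean: Optional[np.ndarray] = None
    params: dict[str, Any] = field(default_factory=dict)
    seed: Optional[int] = None
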