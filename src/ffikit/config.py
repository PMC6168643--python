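"""Pipeline configuration: every threshold and window used by the
analysis modules, with the published defaults, loadable from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # filtering / detection
    filter_low_hz: float = 300.0
    filter_high_hz: float = 5000.0
    snr_threshold: float = 4.0
    dead_time_ms: float = 1.0
    # unit isolation / typing
    isi_threshold_ms: float = 2.0
    isi_fraction: float = 0.001
    width_threshold_ms: float = 0.4
    # modulation index
    pre_window_s: float = 1.0
    post_window_s: float = 0.1
    # excitation criterion
    excitation_binsize_s: float = 0.005
    excitation_window_s: float = 0.03
    excitation_sd: float = 4.0
    # inhibition duration rule
    duration_binsize_s: float = 0.01
    duration_smooth_bins: int = 3
    duration_sustain_bins: int = 2
    # intracellular
    min_latency_amplitude: float = 10.0
    ipsp_rise_boundary_ms: float = (5.6 + 22.3) / 2.0
    ipsp_halfwidth_boundary_ms: float = (46.3 + 118.6) / 2.0
    connection_z: float = 3.0
    kinetics_smooth_ms: float = 0.0
    # simulation / bookkeeping
    seed: int = 0
    n_trials: int = 200
    stim_period_s: float = 5.0
    fs: float = 25_000.0
    noise_sd: float = 1.0
    in_dir: Optional[str] = None
    out_dir: str = "results"
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.filter_low_hz < self.filter_high_hz):
            raise ValueError("require 0 < filter_low_hz < filter_high_hz")
        if self.filter_high_hz >= self.fs / 2:
            raise ValueError("filter_high_hz must be below fs / 2")
        for name in ("snr_threshold", "pre_window_s", "post_window_s",
                     "excitation_binsize_s", "duration_binsize_s",
                     "stim_period_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.isi_fraction < 1):
            raise ValueError("isi_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def echo(self) -> dict:
        return asdict(self)
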