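"""Analysis configuration.

Defaults follow the physiological/processing choices used throughout the
package: blood density 1060 kg/m3, ten RK4 substeps per reconstructed frame
interval, 15% exclusion thresholds for non-physiological flow and for the
inflow/outflow discrepancy, and a 0.05 significance level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class AnalysisConfig:
    rho: float = 1060.0               # blood density, kg/m^3
    rk4_substeps_per_frame: int = 10  # pathline integrator substeps per frame interval
    np_exclusion_threshold: float = 15.0   # % non-physiological pathlines
    io_discrepancy_threshold: float = 15.0  # % inflow vs outflow mismatch
    alpha: float = 0.05               # significance level
    median_filter: bool = True        # 3x3x3 spatial median filter on TKE
    check_np_transits: bool = True    # flag multi-transit pathlines as NP
    a_wave_fallback_fraction: float = 0.30  # tail fraction of diastole for merged A-wave
    gaussian_weight_sampling: bool = True   # verbatim distance-weight scheme vs trilinear
    seed: int = 0                     # RNG seed for any stochastic stage

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ConfigError(f"rho must be > 0, got {self.rho}")
        if self.rk4_substeps_per_frame < 1:
            raise ConfigError("rk4_substeps_per_frame must be >= 1")
        for name in ("np_exclusion_threshold", "io_discrepancy_threshold"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ConfigError(f"{name} must be in (0, 100), got {v}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.a_wave_fallback_fraction < 1:
            raise ConfigError("a_wave_fallback_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
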