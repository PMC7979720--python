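"""Pipeline configuration.

Every tunable of the analysis chain lives here with the shipped defaults:
0.1 kHz 3rd-order high-pass on sound, 2 kHz 3rd-order low-pass on pressures
and flow, 2 ms bins sliding by 1 ms, YIN gating thresholds, the phonation
threshold rule and the control-space grid resolution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError


@dataclass
class F0Config:
    """Gating and search settings for per-bin fundamental-frequency extraction.

    Attributes
    ----------
    aperiodicity_max : float
        Reporting gate on the cumulative-mean-normalised difference value at
        the selected lag; f_o is withheld above it.  Sensible range 0.05-0.2.
    power_min : float
        Reporting gate on the analysis-window RMS sound pressure in Pa
        (0.25e-3 to 5.0e-3 is the usual tuning range).
    f_lo, f_hi : float
        Fundamental-frequency search band, Hz.
    window_s : float
        Length of the centered analysis window.  Must hold at least two
        periods of ``f_lo``.
    cmnd_threshold : float
        Dip-selection threshold of the normalised difference function,
        distinct from the reporting gate ``aperiodicity_max``.
    """

    aperiodicity_max: float = 0.15
    power_min: float = 0.5e-3
    f_lo: float = 150.0
    f_hi: float = 8000.0
    window_s: float = 0.015
    cmnd_threshold: float = 0.15

    def validate(self) -> "F0Config":
        if not 0.0 < self.aperiodicity_max < 1.0:
            raise ConfigError("aperiodicity_max must lie in (0, 1)")
        if self.power_min <= 0:
            raise ConfigError("power_min must be positive")
        if not 0.0 < self.f_lo < self.f_hi:
            raise ConfigError("need 0 < f_lo < f_hi")
        if self.window_s <= 0 or self.cmnd_threshold <= 0:
            raise ConfigError("window_s and cmnd_threshold must be positive")
        return self


@dataclass
class PipelineConfig:
    """All analysis tunables, loadable from a YAML/JSON mapping."""

    # channel conditioning (Hz / filter order)
    sound_highpass_hz: float = 100.0
    sound_highpass_order: int = 3
    slow_lowpass_hz: float = 2000.0
    slow_lowpass_order: int = 3

    # sliding-bin grid (s)
    bin_width: float = 0.002
    hop: float = 0.001

    f0: F0Config = field(default_factory=F0Config)

    # Wiener entropy
    we_fft_size: int = 2048
    we_band_hi_hz: float = 10000.0

    # phonation-threshold rule: max(noise_floor_multiple * pre-ramp median
    # RMS sound, absolute_floor)
    ptp_noise_multiple: float = 6.0
    ptp_absolute_floor: float = 0.25e-3
    # settle interval eroded around phonation on/offsets before computing
    # extreme-value and mean summaries (s)
    onset_guard_s: float = 0.015

    # ramp segmentation
    pb_on_kpa: float = 0.02
    picas_tolerance_kpa: float = 0.05
    min_ramp_s: float = 0.2

    # efficiency
    flow_floor: float = 1e-7
    solid_angle_factor: float = 4.0

    # control-space grid (kPa)
    pb_step: float = 0.1
    picas_step: float = 0.25

    # piecewise f_o fit (kPa)
    breakpoint: float = 0.75
    pt_upper: float = 2.0

    seed: int = 0

    def __post_init__(self):
        if isinstance(self.f0, dict):
            self.f0 = F0Config(**self.f0)
        self.validate()

    def validate(self) -> "PipelineConfig":
        if self.bin_width < self.hop or self.hop <= 0:
            raise ConfigError("need bin_width >= hop > 0")
        for name in ("sound_highpass_hz", "slow_lowpass_hz", "ptp_noise_multiple",
                     "ptp_absolute_floor", "pb_step", "picas_step",
                     "breakpoint", "pt_upper"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.sound_highpass_order < 1 or self.slow_lowpass_order < 1:
            raise ConfigError("filter order must be >= 1")
        if not 0 < self.breakpoint < self.pt_upper:
            raise ConfigError("need 0 < breakpoint < pt_upper")
        self.f0.validate()
        return self

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                              encoding="utf-8")

    def digest(self) -> str:
        """Stable hash of the configuration, used in provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
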