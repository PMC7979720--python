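"""Calibrated multichannel recording I/O.

A recording is stored as a 4-channel 32-bit-float WAV (sound, bronchial
pressure, air-sac pressure, flow) plus a JSON sidecar that names each
channel and declares its unit, the acquisition metadata and the microphone
calibration.  Units are fixed by convention — sound in Pa, pressures in kPa,
flow in m^3/s — and are written verbatim to, and checked verbatim against,
the sidecar: nothing is rescaled on the way in or out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .exceptions import FormatError, IntegrityError

#: fixed channel order in the WAV, declared (not assumed) in the sidecar
CHANNELS = ("sound", "p_b", "p_icas", "flow")
CHANNEL_UNITS = {"sound": "Pa", "p_b": "kPa", "p_icas": "kPa", "flow": "m3/s"}

#: column order of the exported per-bin feature table
FEATURE_COLUMNS = (
    "bin_center_t", "rms_sound", "rms_pb", "rms_picas", "rms_flow",
    "p_t", "f_o", "aperiodicity", "SL", "WE", "ME",
)


@dataclass
class RecordingMeta:
    """Acquisition and calibration metadata for one hemi-syrinx run.

    ``mic_distance_r`` is the microphone distance in m used to normalise
    source level to 1 m; ``ref_pressure_P0`` the 20 µPa reference;
    ``air_density_rho`` and ``sound_speed_v`` enter the radiated acoustic
    power.
    """

    subject_id: str = "unknown"
    side: str = "left"
    sex: str = "unknown"
    age_dph: int | None = None
    mic_distance_r: float = 0.15
    ref_pressure_P0: float = 20e-6
    air_density_rho: float = 1.2
    sound_speed_v: float = 344.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise IntegrityError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.sex not in ("male", "female", "unknown"):
            raise IntegrityError(f"sex must be male/female/unknown, got {self.sex!r}")
        for name in ("mic_distance_r", "ref_pressure_P0", "air_density_rho",
                     "sound_speed_v"):
            if getattr(self, name) <= 0:
                raise IntegrityError(f"{name} must be positive")


@dataclass
class MultichannelRecording:
    """Synchronised calibrated channels of one pressure-ramp run.

    Channels: ``sound`` (Pa), ``p_b`` and ``p_icas`` (kPa), ``flow``
    (m^3/s), all sampled at ``sample_rate`` Hz and of identical length.
    """

    sample_rate: float
    sound: np.ndarray
    p_b: np.ndarray
    p_icas: np.ndarray
    flow: np.ndarray
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise IntegrityError("sample_rate must be positive")
        lengths = {len(self.sound), len(self.p_b), len(self.p_icas), len(self.flow)}
        if lengths == {0}:
            raise IntegrityError("channels must hold at least one sample")
        if len(lengths) != 1:
            raise IntegrityError(f"channel lengths differ: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(self.sound)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise FormatError(f"no channel named {name!r}")
        return getattr(self, name if name != "sound" else "sound")


def write_recording(rec: MultichannelRecording, path) -> Path:
    """Write ``rec`` as ``<path>.wav`` (float32) plus ``<path>.json`` sidecar.

    ``path`` may carry the ``.wav`` suffix or none.  Returns the WAV path.
    """
    path = Path(path)
    wav_path = path if path.suffix == ".wav" else path.with_suffix(".wav")
    data = np.column_stack([
        np.asarray(getattr(rec, ch), dtype=np.float32) for ch in CHANNELS
    ])
    wavfile.write(wav_path, int(round(rec.sample_rate)), data)
    sidecar = {
        "channels": list(CHANNELS),
        "units": dict(CHANNEL_UNITS),
        "sample_rate": rec.sample_rate,
        "meta": asdict(rec.meta),
    }
    wav_path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2), encoding="utf-8")
    return wav_path


def read_recording(path) -> MultichannelRecording:
    """Read a WAV + JSON sidecar pair written by :func:`write_recording`.

    The sidecar is mandatory: channel order and units come from it, never
    from position alone, and there are no silent unit defaults.
    """
    path = Path(path)
    wav_path = path if path.suffix == ".wav" else path.with_suffix(".wav")
    sidecar_path = wav_path.with_suffix(".json")
    if not wav_path.exists():
        raise FormatError(f"waveform file not found: {wav_path}")
    if not sidecar_path.exists():
        raise FormatError(f"metadata sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    for key in ("channels", "units", "sample_rate"):
        if key not in sidecar:
            raise FormatError(f"sidecar missing required key {key!r}")
    channels = sidecar["channels"]
    missing = [ch for ch in CHANNELS if ch not in channels]
    if missing:
        raise FormatError(f"sidecar lacks channel(s): {missing}")
    for ch in CHANNELS:
        declared = sidecar["units"].get(ch)
        if declared != CHANNEL_UNITS[ch]:
            raise IntegrityError(
                f"channel {ch!r} declared in {declared!r}, expected "
                f"{CHANNEL_UNITS[ch]!r}; refusing to guess a conversion")

    rate, data = wavfile.read(wav_path)
    if data.ndim != 2 or data.shape[1] != len(channels):
        found = 1 if data.ndim == 1 else data.shape[1]
        raise IntegrityError(
            f"waveform holds {found} channel(s) but sidecar declares "
            f"{len(channels)}")
    if float(sidecar["sample_rate"]) != float(rate):
        raise IntegrityError(
            f"sample rate mismatch: WAV {rate}, sidecar {sidecar['sample_rate']}")
    cols = {ch: data[:, channels.index(ch)].astype(np.float64) for ch in CHANNELS}
    meta = RecordingMeta(**sidecar.get("meta", {}))
    return MultichannelRecording(
        sample_rate=float(sidecar["sample_rate"]),
        sound=cols["sound"], p_b=cols["p_b"], p_icas=cols["p_icas"],
        flow=cols["flow"], meta=meta)


def write_features(features, path) -> Path:
    """Export a :class:`~pysyrinx.preprocess.BinnedFeatureSeries` as CSV.

    One row per bin, comma-delimited UTF-8 with a mandatory header, columns
    in the order of :data:`FEATURE_COLUMNS`.  Missing values (ungated f_o,
    undefined WE/ME) are written as empty fields, never as 0.  Finite values
    keep at least 10 significant digits.
    """
    path = Path(path)
    frame = features.to_frame()
    frame = frame[list(FEATURE_COLUMNS)]
    frame.to_csv(path, index=False, float_format="%.10g", na_rep="")
    return path


def read_features(path):
    """Read a feature table written by :func:`write_features`."""
    import pandas as pd

    frame = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"feature table lacks column(s): {sorted(missing)}")
    return frame
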