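"""Channel conditioning and sliding-bin feature extraction.

The raw channels are zero-phase Butterworth filtered (high-pass for sound,
low-pass for the slow pressure/flow channels) and then summarised on a
shared sliding-bin grid: 2 ms windows advancing by 1 ms.  Sound is
summarised by its RMS; the non-negative slow channels by their per-bin mean
(for signals that move on ~100 ms scales the two coincide to high order,
and a difference of means keeps the transmural pressure p_t = p_b - p_icas
well defined).  Both conventions are recorded in the series metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, filtfilt

from .config import PipelineConfig
from .exceptions import PysyrinxError
from .io import MultichannelRecording

log = logging.getLogger(__name__)


def zero_phase_filter(x, sample_rate, kind, cutoff, order=3):
    """Forward-backward Butterworth filter (zero phase shift).

    Parameters
    ----------
    x : array-like
        Input series.
    sample_rate : float
        Sampling rate, Hz.
    kind : {"highpass", "lowpass"}
    cutoff : float
        Cutoff frequency, Hz; must lie inside (0, Nyquist).
    order : int
        Butterworth order of each pass; applied twice the effective
        magnitude response is |H(f)|^2.

    The input is padded by odd reflection over 3*(order+1) samples per pass
    before filtering; inputs shorter than that raise instead of being
    silently truncated.
    """
    x = np.asarray(x, dtype=np.float64)
    if kind not in ("highpass", "lowpass"):
        raise ValueError(f"kind must be highpass/lowpass, got {kind!r}")
    if not 0 < cutoff < sample_rate / 2:
        raise ValueError("cutoff must lie strictly inside (0, Nyquist)")
    if order < 1:
        raise ValueError("order must be >= 1")
    padlen = 3 * (order + 1)
    if x.size <= padlen:
        raise PysyrinxError(
            f"input of {x.size} samples is too short for stable "
            f"forward-backward filtering (needs > {padlen})")
    b, a = butter(order, cutoff, btype=kind, fs=sample_rate)
    return filtfilt(b, a, x, padtype="odd", padlen=padlen)


def n_bins(n_samples: int, win: int, hop: int) -> int:
    """Number of full sliding windows of ``win`` samples advancing by ``hop``."""
    if n_samples < win:
        return 0
    return (n_samples - win) // hop + 1


def _windows(x, win, hop):
    view = sliding_window_view(np.asarray(x, dtype=np.float64), win)
    return view[::hop]


def bin_rms(x, sample_rate, bin_width=0.002, hop=0.001):
    """Per-bin root-mean-square of ``x`` on the sliding-bin grid.

    Bin k covers samples ``[k*H, k*H + W)`` with W, H the window and hop in
    samples.  A recording shorter than one bin yields an empty series (with
    a warning), matching the bin-count formula ``floor((N-W)/H) + 1``.
    """
    if not (bin_width >= hop > 0):
        raise ValueError("need bin_width >= hop > 0")
    x = np.asarray(x, dtype=np.float64)
    win = int(round(bin_width * sample_rate))
    hop_n = int(round(hop * sample_rate))
    if x.size < win:
        log.warning("recording of %d samples is shorter than one %d-sample bin",
                    x.size, win)
        return np.empty(0)
    return np.sqrt(np.mean(_windows(x, win, hop_n) ** 2, axis=1))


def bin_mean(x, sample_rate, bin_width=0.002, hop=0.001):
    """Per-bin arithmetic mean on the same grid as :func:`bin_rms`."""
    x = np.asarray(x, dtype=np.float64)
    win = int(round(bin_width * sample_rate))
    hop_n = int(round(hop * sample_rate))
    if x.size < win:
        return np.empty(0)
    return np.mean(_windows(x, win, hop_n), axis=1)


@dataclass
class BinnedFeatureSeries:
    """Per-bin features of one run on a shared time grid.

    ``bin_center_t`` advances by ``hop``; every column refers to the same
    sample window.  f_o and aperiodicity may be NaN where gated; WE/ME are
    NaN where undefined.  Units: rms_sound Pa, pressures kPa, flow m^3/s,
    SL dB re 20 µPa at 1 m, WE log10 units (<= 0), ME dB.
    """

    bin_center_t: np.ndarray
    rms_sound: np.ndarray
    rms_pb: np.ndarray
    rms_picas: np.ndarray
    rms_flow: np.ndarray
    p_t: np.ndarray
    f_o: np.ndarray
    aperiodicity: np.ndarray
    SL: np.ndarray
    WE: np.ndarray
    ME: np.ndarray
    bin_width: float
    hop: float
    sample_rate: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bin_center_t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_t": self.bin_center_t,
            "rms_sound": self.rms_sound,
            "rms_pb": self.rms_pb,
            "rms_picas": self.rms_picas,
            "rms_flow": self.rms_flow,
            "p_t": self.p_t,
            "f_o": self.f_o,
            "aperiodicity": self.aperiodicity,
            "SL": self.SL,
            "WE": self.WE,
            "ME": self.ME,
        })

    def column(self, name: str) -> np.ndarray:
        if name == "bin_center_t" or not hasattr(self, name):
            raise KeyError(name)
        return getattr(self, name)


def assemble_features(rec: MultichannelRecording,
                      cfg: PipelineConfig | None = None) -> BinnedFeatureSeries:
    """Run the conditioning + binning + per-bin feature chain on a recording.

    Sound is high-passed, pressures and flow low-passed (both zero-phase),
    then all channels are binned on one grid; p_t is the per-bin difference
    of the pressure means, and the acoustic (f_o, SL, WE) and efficiency
    (ME) features are delegated to their modules.
    """
    from . import features as _feat
    from . import power as _pow

    cfg = cfg or PipelineConfig()
    fs = rec.sample_rate

    sound = zero_phase_filter(rec.sound, fs, "highpass",
                              cfg.sound_highpass_hz, cfg.sound_highpass_order)
    slow = {}
    for name in ("p_b", "p_icas", "flow"):
        slow[name] = zero_phase_filter(getattr(rec, name), fs, "lowpass",
                                       cfg.slow_lowpass_hz, cfg.slow_lowpass_order)

    win = int(round(cfg.bin_width * fs))
    hop_n = int(round(cfg.hop * fs))
    nb = n_bins(rec.n_samples, win, hop_n)
    starts = np.arange(nb) * hop_n
    centers = (starts + win / 2.0) / fs

    rms_sound = bin_rms(sound, fs, cfg.bin_width, cfg.hop)
    rms_pb = bin_mean(slow["p_b"], fs, cfg.bin_width, cfg.hop)
    rms_picas = bin_mean(slow["p_icas"], fs, cfg.bin_width, cfg.hop)
    rms_flow = bin_mean(slow["flow"], fs, cfg.bin_width, cfg.hop)
    p_t = rms_pb - rms_picas

    f_o, aperiodicity = _feat.yin_track(sound, fs, centers, cfg.f0)
    SL = _feat.source_level_series(rms_sound, rec.meta.mic_distance_r,
                                   rec.meta.ref_pressure_P0)
    WE = _feat.wiener_entropy_track(sound, fs, starts, win,
                                    fft_size=cfg.we_fft_size,
                                    band_hi=min(cfg.we_band_hi_hz, fs / 2))
    ME = _pow.mechanical_efficiency_series(
        rms_sound, rms_pb, rms_flow, rec.meta,
        flow_floor=cfg.flow_floor, solid_angle_factor=cfg.solid_angle_factor)

    return BinnedFeatureSeries(
        bin_center_t=centers, rms_sound=rms_sound, rms_pb=rms_pb,
        rms_picas=rms_picas, rms_flow=rms_flow, p_t=p_t, f_o=f_o,
        aperiodicity=aperiodicity, SL=SL, WE=WE, ME=ME,
        bin_width=cfg.bin_width, hop=cfg.hop, sample_rate=fs,
        meta={
            "sound_summary": "rms",
            "slow_channel_summary": "mean",
            "config_digest": cfg.digest(),
        })
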