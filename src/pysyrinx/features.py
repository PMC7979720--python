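"""Per-bin acoustic features: YIN fundamental frequency, source level,
Wiener entropy, and harmonic-based f_o refinement.

The YIN estimator follows the classic recipe: squared difference function,
cumulative-mean-normalised difference (CMND), first local CMND minimum
below a dip threshold (falling back to the global minimum), and parabolic
interpolation of the selected lag.  The CMND value at that lag doubles as
the aperiodicity measure; f_o is reported only where the frame is both
periodic enough (aperiodicity <= gate) and loud enough (window RMS >= power
gate), mirroring how such recordings are screened in practice.

A 2 ms analysis bin is far too short for fundamentals of a few hundred Hz,
so f_o for a bin is computed on a longer window (default 15 ms) centered on
the bin and reported at that bin.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft
from scipy.signal import welch

from .config import F0Config
from .exceptions import PysyrinxError

__all__ = [
    "yin_f0", "yin_track", "source_level", "source_level_series",
    "wiener_entropy", "wiener_entropy_track", "f0_from_harmonic",
]


# ---------------------------------------------------------------------------
# YIN
# ---------------------------------------------------------------------------

def _yin_cmnd_batch(frames: np.ndarray, tau_max: int) -> np.ndarray:
    """CMND d'(tau) for a batch of frames, tau = 0..tau_max.

    The difference function d(tau) = sum_{j<W} (x_j - x_{j+tau})^2 with
    W = frame_len - tau_max is evaluated with an FFT cross-correlation plus
    running energy terms; the normalisation d'(tau) = d(tau) * tau /
    sum_{k<=tau} d(k) is exact, with d'(0) = 1.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    n, length = frames.shape
    w = length - tau_max
    if w < 2:
        raise PysyrinxError("frame too short for the requested lag range")

    nfft = sp_fft.next_fast_len(length)
    spec_full = sp_fft.rfft(frames, nfft, axis=1)
    head = np.zeros_like(frames)
    head[:, :w] = frames[:, :w]
    spec_head = sp_fft.rfft(head, nfft, axis=1)
    corr = sp_fft.irfft(np.conj(spec_head) * spec_full, nfft, axis=1)[:, :tau_max + 1]

    sq = frames ** 2
    csum = np.cumsum(sq, axis=1)
    e0 = csum[:, w - 1][:, None]
    # energy of x[tau : tau+w] for each tau
    padded = np.concatenate([np.zeros((n, 1)), csum], axis=1)
    taus = np.arange(tau_max + 1)
    e_tau = padded[:, taus + w] - padded[:, taus]

    d = np.maximum(e0 + e_tau - 2.0 * corr, 0.0)
    denom = np.cumsum(d[:, 1:], axis=1)
    cmnd = np.ones_like(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        cmnd[:, 1:] = d[:, 1:] * taus[1:] / denom
    cmnd[:, 1:][denom <= 0] = 1.0
    return cmnd


def _select_lags(cmnd, tau_min, tau_max, dip_threshold):
    """Pick per-frame the first local CMND minimum below the dip threshold
    inside [tau_min, tau_max] (global minimum if none), with parabolic
    interpolation.  Returns (lag_float, aperiodicity)."""
    n = cmnd.shape[0]
    # pad so the boundary lags have a neighbour to compare against
    padded = np.pad(cmnd, ((0, 0), (0, 1)), constant_values=np.inf)
    band = padded[:, tau_min:tau_max + 1]
    prev = padded[:, tau_min - 1:tau_max]
    nxt = padded[:, tau_min + 1:tau_max + 2]
    local_min = (band <= prev) & (band <= nxt)
    below = band < dip_threshold
    candidate = local_min & below

    has_dip = candidate.any(axis=1)
    first_dip = np.argmax(candidate, axis=1)
    global_min = np.argmin(band, axis=1)
    sel = np.where(has_dip, first_dip, global_min) + tau_min

    ap = cmnd[np.arange(n), sel]

    # parabolic refinement of the lag (guard the array ends)
    sel_c = np.clip(sel, 1, cmnd.shape[1] - 2)
    ym = cmnd[np.arange(n), sel_c - 1]
    y0 = cmnd[np.arange(n), sel_c]
    yp = cmnd[np.arange(n), sel_c + 1]
    denom = ym - 2.0 * y0 + yp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (ym - yp) / denom
    delta = np.where(np.isfinite(delta), np.clip(delta, -1.0, 1.0), 0.0)
    lag = sel_c + delta
    # frames where the selection sat on a guard boundary keep the raw lag
    lag = np.where(sel == sel_c, lag, sel.astype(float))
    return lag, ap


def yin_f0(frame, sample_rate, cfg: F0Config | None = None):
    """YIN f_o estimate of a single frame.

    Returns ``(f_o, aperiodicity)`` where ``f_o`` is NaN when gated out
    (aperiodicity above ``cfg.aperiodicity_max`` or frame RMS below
    ``cfg.power_min``).  An all-zero frame reports aperiodicity 1.  Raises
    if the frame cannot hold two periods of the lowest search frequency.
    """
    cfg = (cfg or F0Config()).validate()
    frame = np.asarray(frame, dtype=np.float64)
    tau_max = int(np.ceil(sample_rate / cfg.f_lo))
    tau_min = max(2, int(np.floor(sample_rate / cfg.f_hi)))
    if frame.size < 2 * tau_max:
        raise PysyrinxError(
            f"frame of {frame.size} samples cannot hold two periods of "
            f"{cfg.f_lo} Hz at {sample_rate} Hz (needs >= {2 * tau_max})")
    if not np.any(frame):
        return float("nan"), 1.0
    cmnd = _yin_cmnd_batch(frame[None, :], tau_max)
    lag, ap = _select_lags(cmnd, tau_min, tau_max, cfg.cmnd_threshold)
    f = float(sample_rate / lag[0])
    ap = float(ap[0])
    rms = float(np.sqrt(np.mean(frame ** 2)))
    if ap > cfg.aperiodicity_max or rms < cfg.power_min:
        return float("nan"), ap
    return f, ap


def yin_track(sound, sample_rate, centers, cfg: F0Config | None = None,
              chunk=4096):
    """Vectorised per-bin YIN track.

    For every bin center (s) a window of ``cfg.window_s`` centered on it is
    analysed; windows are shifted inward at the recording edges so that all
    frames are full length.  Returns ``(f_o, aperiodicity)`` arrays with
    NaN f_o where gated.
    """
    cfg = (cfg or F0Config()).validate()
    sound = np.asarray(sound, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    tau_max = int(np.ceil(sample_rate / cfg.f_lo))
    tau_min = max(2, int(np.floor(sample_rate / cfg.f_hi)))
    win = int(round(cfg.window_s * sample_rate))
    if win < 2 * tau_max:
        raise PysyrinxError(
            f"YIN window of {win} samples cannot hold two periods of "
            f"{cfg.f_lo} Hz (needs >= {2 * tau_max})")
    starts = np.clip(np.round(centers * sample_rate).astype(int) - win // 2,
                     0, max(0, sound.size - win))

    n = centers.size
    f_o = np.full(n, np.nan)
    ap_out = np.ones(n)
    offs = np.arange(win)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        frames = sound[starts[lo:hi, None] + offs]
        rms = np.sqrt(np.mean(frames ** 2, axis=1))
        nonzero = rms > 0
        if not nonzero.any():
            continue
        cmnd = _yin_cmnd_batch(frames[nonzero], tau_max)
        lag, ap = _select_lags(cmnd, tau_min, tau_max, cfg.cmnd_threshold)
        f = sample_rate / lag
        keep = (ap <= cfg.aperiodicity_max) & (rms[nonzero] >= cfg.power_min)
        block_f = np.full(hi - lo, np.nan)
        block_ap = np.ones(hi - lo)
        block_ap[nonzero] = ap
        fvals = np.where(keep, f, np.nan)
        block_f[nonzero] = fvals
        f_o[lo:hi] = block_f
        ap_out[lo:hi] = block_ap
    return f_o, ap_out


# ---------------------------------------------------------------------------
# Source level
# ---------------------------------------------------------------------------

def source_level(p_rms, r=0.15, P0=20e-6):
    """Source level in dB re ``P0`` normalised to 1 m.

    SL = 20 log10(p_rms / P0) + 20 log10(r).  ``p_rms = 0`` maps to -inf
    (treated as missing downstream); negative pressure is a domain error.
    """
    if r <= 0 or P0 <= 0:
        raise ValueError("r and P0 must be positive")
    p_rms = float(p_rms)
    if p_rms < 0:
        raise ValueError("p_rms must be non-negative")
    if p_rms == 0:
        return float("-inf")
    return 20.0 * np.log10(p_rms / P0) + 20.0 * np.log10(r)


def source_level_series(p_rms, r=0.15, P0=20e-6):
    """Vectorised :func:`source_level`; non-positive values become NaN."""
    p_rms = np.asarray(p_rms, dtype=np.float64)
    out = np.full(p_rms.shape, np.nan)
    ok = p_rms > 0
    out[ok] = 20.0 * np.log10(p_rms[ok] / P0) + 20.0 * np.log10(r)
    return out


# ---------------------------------------------------------------------------
# Wiener entropy
# ---------------------------------------------------------------------------

def _we_from_amplitude(px: np.ndarray, axis=-1) -> np.ndarray:
    """log10(geometric mean / arithmetic mean) of an amplitude spectrum.

    Zeros are floored at machine epsilon times the spectral maximum so the
    geometric mean stays defined; the result is <= 0 with equality only for
    a flat spectrum.
    """
    px = np.asarray(px, dtype=np.float64)
    peak = px.max(axis=axis, keepdims=True)
    floor = np.finfo(np.float64).eps * peak
    pxf = np.maximum(px, floor)
    gm = np.exp(np.mean(np.log(pxf), axis=axis))
    am = np.mean(pxf, axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        we = np.log10(gm / am)
    we = np.where(peak.squeeze(axis) > 0, we, np.nan)
    return np.minimum(we, 0.0)


def wiener_entropy(frame, sample_rate=None, fft_size=2048, overlap=1024,
                   band_hi=10000.0):
    """Wiener entropy of one frame, in log10 units (<= 0).

    The amplitude spectrum is the square root of a Hann-tapered
    periodogram (the taper keeps boxcar sidelobe leakage from flooring the
    inter-harmonic valleys that this measure grades); frames shorter than
    ``fft_size`` are zero-padded to it, longer frames are Welch-averaged
    with the given segment overlap.  The spectrum is
    restricted to [0, band_hi] Hz when the sample rate is known (the
    acquisition anti-alias band).  An all-zero frame is undefined (NaN).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("frame must be non-empty")
    if not np.any(frame):
        return float("nan")
    fs = sample_rate if sample_rate else 1.0
    if frame.size <= fft_size:
        spec = np.abs(sp_fft.rfft(frame * np.hanning(frame.size), fft_size))
        freqs = sp_fft.rfftfreq(fft_size, 1.0 / fs)
    else:
        freqs, pxx = welch(frame, fs=fs, window="hann", nperseg=fft_size,
                           noverlap=overlap, detrend=False)
        spec = np.sqrt(pxx)
    if sample_rate:
        spec = spec[freqs <= band_hi]
    return float(_we_from_amplitude(spec))


def wiener_entropy_track(sound, sample_rate, starts, win, fft_size=2048,
                         band_hi=10000.0, chunk=4096):
    """Per-bin Wiener entropy reported on the sliding-bin grid.

    Each bin's spectrum is a boxcar periodogram over ``fft_size`` samples
    centered on the bin (shifted inward at the recording edges): the 2 ms
    bin itself is far too short to resolve the harmonic structure that
    Wiener entropy is meant to grade, so — like the pitch track — the
    spectral window is longer than the bin it is reported at.
    """
    sound = np.asarray(sound, dtype=np.float64)
    starts = np.asarray(starts, dtype=int)
    n = starts.size
    out = np.full(n, np.nan)
    keep = sp_fft.rfftfreq(fft_size, 1.0 / sample_rate) <= band_hi
    centers = starts + win // 2
    wstarts = np.clip(centers - fft_size // 2, 0,
                      max(0, sound.size - fft_size))
    offs = np.arange(min(fft_size, sound.size))
    taper = np.hanning(offs.size)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        frames = sound[wstarts[lo:hi, None] + offs]
        live = frames.any(axis=1)
        if not live.any():
            continue
        spec = np.abs(sp_fft.rfft(frames[live] * taper, fft_size, axis=1))[:, keep]
        block = np.full(hi - lo, np.nan)
        block[live] = _we_from_amplitude(spec, axis=1)
        out[lo:hi] = block
    return out


# ---------------------------------------------------------------------------
# Harmonic-based f_o
# ---------------------------------------------------------------------------

def f0_from_harmonic(f_n, n):
    """Fundamental inferred from the frequency of the n-th harmonic.

    Measuring an upper harmonic (typically the 3rd-5th) and dividing by its
    order multiplies the frequency resolution of the readout by n.
    """
    if int(n) != n or n < 1:
        raise ValueError("harmonic order n must be a positive integer")
    if f_n <= 0:
        raise ValueError("harmonic frequency must be positive")
    return f_n / n
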