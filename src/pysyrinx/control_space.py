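"""Ramp segmentation, phonation-threshold detection and pressure
control-space summaries.

A run consists of repeated bronchial-pressure ramps, each at a constant
air-sac pressure setpoint, separated by pauses with both pressures at
baseline.  Per ramp, the phonation threshold pressures are the pressures at
the first bin whose RMS sound crosses the detection threshold; per run, the
thresholds (minimum over ramps), the minimal f_o (mean of the per-ramp
onset f_o), the minimal source level and the control-space means of Wiener
entropy and mechanical efficiency are summarised.  Any binned feature can
additionally be gridded into a p_b x p_icas map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import SegmentationError
from .preprocess import BinnedFeatureSeries

log = logging.getLogger(__name__)


@dataclass
class RampSegment:
    """One bronchial-pressure ramp: a bin interval at a fixed p_icas setpoint."""

    start_bin: int
    end_bin: int  # exclusive
    picas_setpoint: float
    ramp_rate_est: float

    def __post_init__(self):
        if self.start_bin >= self.end_bin:
            raise ValueError("start_bin must precede end_bin")

    def slice(self):
        return slice(self.start_bin, self.end_bin)


@dataclass
class PTPResult:
    """Phonation onset of one ramp.

    ``ptp_t = ptp_b - ptp_icas`` holds exactly by construction; all
    pressures are NaN when the ramp never crossed the sound threshold.
    """

    phonated: bool
    ptp_b: float
    ptp_icas: float
    ptp_t: float
    onset_bin: int
    onset_f0: float


@dataclass
class RunSummary:
    """Per-run scalar summaries over all ramps.

    ``minimal_f0`` is the mean of the per-ramp onset f_o; ``minimal_SL``
    the lowest source level across settled phonating bins; ``mean_WE`` /
    ``mean_ME`` are means over the same bins ("the entire control space");
    the PTP fields are minima over phonating ramps.  All values are NaN
    when no ramp phonated.
    """

    minimal_f0: float
    minimal_SL: float
    mean_WE: float
    mean_ME: float
    ptp_b_first: float
    ptp_icas_min: float
    ptp_t_min: float
    n_phonating_ramps: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ControlSpaceMap:
    """Per-cell mean/sd/count of one feature over the p_b x p_icas plane.

    Cells without data hold NaN mean/sd (never zero); sd needs >= 2 points.
    """

    feature: str
    pb_edges: np.ndarray
    picas_edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray


def segment_ramps(features: BinnedFeatureSeries, protocol_hint=None,
                  pb_on=0.02, picas_tolerance=0.05, min_ramp_s=0.2):
    """Split a run into maximal p_b-rise intervals at constant p_icas.

    Ramps are the contiguous stretches where p_b sits above the ``pb_on``
    baseline (kPa); inter-ramp pauses (both pressures ~ 0) separate them.
    With a ``protocol_hint`` (anything exposing ``picas_levels``) the
    segment count must match the protocol's ramp count, otherwise a
    :class:`SegmentationError` listing the candidates is raised.
    """
    pb = np.asarray(features.rms_pb)
    picas = np.asarray(features.rms_picas)
    above = pb > pb_on
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(np.flatnonzero(above[1:] & ~above[:-1]) + 1)
    if above[0]:
        starts.insert(0, 0)
    ends = list(np.flatnonzero(~above[1:] & above[:-1]) + 1)
    if above[-1]:
        ends.append(len(pb))
    del edges

    min_bins = max(2, int(round(min_ramp_s / features.hop)))
    segments = []
    for s, e in zip(starts, ends):
        if e - s < min_bins:
            continue
        seg_picas = picas[s:e]
        setpoint = float(np.median(seg_picas))
        spread = float(np.percentile(np.abs(seg_picas - setpoint), 95))
        if spread > picas_tolerance:
            log.warning("segment [%d, %d): p_icas spread %.3f kPa exceeds "
                        "tolerance %.3f around setpoint %.3f",
                        s, e, spread, picas_tolerance, setpoint)
        t = features.bin_center_t[s:e]
        rate = float(np.polyfit(t - t[0], pb[s:e], 1)[0])
        segments.append(RampSegment(int(s), int(e), setpoint, rate))

    if protocol_hint is not None:
        expected = len(protocol_hint.picas_levels)
        if len(segments) != expected:
            raise SegmentationError(
                f"found {len(segments)} ramp segments but the protocol "
                f"specifies {expected}", candidates=segments)
    return segments


def resolve_threshold(features: BinnedFeatureSeries, segments,
                      noise_multiple=6.0, absolute_floor=0.25e-3):
    """Sound-power threshold for phonation detection (Pa RMS).

    max(noise_multiple x median pre-ramp RMS sound, absolute_floor): robust
    to the preparation's noise floor yet anchored to an absolute magnitude
    at the low end of the usual power-gating range.
    """
    first = segments[0].start_bin if segments else len(features)
    noise = features.rms_sound[:first]
    noise_med = float(np.median(noise)) if noise.size else 0.0
    return max(noise_multiple * noise_med, absolute_floor)


def detect_ptp(segment: RampSegment, features: BinnedFeatureSeries,
               threshold: float, f0_guard_s=0.015) -> PTPResult:
    """Phonation onset of one ramp: first bin with RMS sound >= threshold.

    The onset pressures are read from the crossing bin itself (no
    interpolation).  The onset f_o is the crossing bin's f_o; if that bin's
    estimate is gated out (the centered pitch window straddles the onset),
    the first valid f_o within ``f0_guard_s`` after the crossing is used.
    """
    sl = segment.slice()
    rms = features.rms_sound[sl]
    hits = np.flatnonzero(rms >= threshold)
    if hits.size == 0:
        nan = float("nan")
        return PTPResult(False, nan, nan, nan, -1, nan)
    k = segment.start_bin + int(hits[0])
    ptp_b = float(features.rms_pb[k])
    ptp_icas = float(features.rms_picas[k])
    onset_f0 = float(features.f_o[k])
    if np.isnan(onset_f0) and f0_guard_s > 0:
        guard_bins = int(round(f0_guard_s / features.hop))
        stop = min(k + guard_bins + 1, segment.end_bin)
        ahead = features.f_o[k:stop]
        valid = np.flatnonzero(~np.isnan(ahead))
        if valid.size:
            onset_f0 = float(ahead[valid[0]])
    return PTPResult(True, ptp_b, ptp_icas, ptp_b - ptp_icas, k, onset_f0)


def phonating_mask(features: BinnedFeatureSeries, segments, threshold,
                   guard_s=0.0) -> np.ndarray:
    """Boolean mask of phonating bins (RMS sound >= threshold inside ramps).

    With ``guard_s > 0`` the mask is eroded by that many seconds at every
    on/offset so that bins whose window straddles an amplitude transition
    (and therefore mixes silence into the RMS and spectral estimates) do not
    contaminate extreme-value and mean summaries.
    """
    mask = np.zeros(len(features), dtype=bool)
    for seg in segments:
        sl = seg.slice()
        mask[sl] = features.rms_sound[sl] >= threshold
    if guard_s > 0 and mask.any():
        g = int(round(guard_s / features.hop))
        if g > 0:
            m = mask.astype(np.int8)
            edges = np.flatnonzero(np.diff(m) != 0) + 1
            eroded = mask.copy()
            for e in edges:
                eroded[max(0, e - g):min(len(mask), e + g)] = False
            mask = eroded & mask
    return mask


def summarize_run(ptps, features: BinnedFeatureSeries, segments,
                  threshold=None, guard_s=0.015, noise_multiple=6.0,
                  absolute_floor=0.25e-3) -> RunSummary:
    """Scalar run summary from per-ramp onsets and the settled phonating bins."""
    if not segments:
        raise ValueError("summarize_run needs at least one segment")
    if threshold is None:
        threshold = resolve_threshold(features, segments, noise_multiple,
                                      absolute_floor)
    phon = [p for p in ptps if p.phonated]
    n_ph = len(phon)
    if n_ph == 0:
        log.warning("no phonating ramps; run summary is all-missing")
        nan = float("nan")
        return RunSummary(nan, nan, nan, nan, nan, nan, nan, 0)

    onset_f0 = np.array([p.onset_f0 for p in phon])
    minimal_f0 = float(np.nanmean(onset_f0)) if np.any(~np.isnan(onset_f0)) \
        else float("nan")

    mask = phonating_mask(features, segments, threshold, guard_s)
    sl = features.SL[mask]
    minimal_sl = float(np.nanmin(sl)) if sl.size and np.any(~np.isnan(sl)) \
        else float("nan")
    we = features.WE[mask]
    mean_we = float(np.nanmean(we)) if we.size and np.any(~np.isnan(we)) \
        else float("nan")
    me = features.ME[mask]
    mean_me = float(np.nanmean(me)) if me.size and np.any(~np.isnan(me)) \
        else float("nan")

    return RunSummary(
        minimal_f0=minimal_f0,
        minimal_SL=minimal_sl,
        mean_WE=mean_we,
        mean_ME=mean_me,
        ptp_b_first=float(np.min([p.ptp_b for p in phon])),
        ptp_icas_min=float(np.min([p.ptp_icas for p in phon])),
        ptp_t_min=float(np.min([p.ptp_t for p in phon])),
        n_phonating_ramps=n_ph,
    )


def build_map(features: BinnedFeatureSeries, segments, feature_name,
              pb_step=0.1, picas_step=0.25, threshold=None, guard_s=0.015,
              noise_multiple=6.0, absolute_floor=0.25e-3) -> ControlSpaceMap:
    """Grid one feature over the p_b x p_icas plane (phonating bins only)."""
    if pb_step <= 0 or picas_step <= 0:
        raise ValueError("grid steps must be positive")
    values = features.column(feature_name)
    if threshold is None:
        threshold = resolve_threshold(features, segments, noise_multiple,
                                      absolute_floor)
    mask = phonating_mask(features, segments, threshold, guard_s)
    mask = mask & ~np.isnan(values)
    pb = features.rms_pb[mask]
    picas = features.rms_picas[mask]
    vals = values[mask]

    pb_max = max(pb.max() if pb.size else pb_step, pb_step)
    pi_max = max(picas.max() if picas.size else picas_step, picas_step)
    pb_edges = np.arange(0.0, pb_max + pb_step, pb_step)
    picas_edges = np.arange(0.0, pi_max + picas_step, picas_step)
    # half-open cells; make the digitize of the top edge land in the last cell
    nb_pb, nb_pi = len(pb_edges) - 1, len(picas_edges) - 1
    i = np.clip(np.digitize(pb, pb_edges) - 1, 0, nb_pb - 1)
    j = np.clip(np.digitize(picas, picas_edges) - 1, 0, nb_pi - 1)

    flat = i * nb_pi + j
    count = np.bincount(flat, minlength=nb_pb * nb_pi).astype(int)
    sums = np.bincount(flat, weights=vals, minlength=nb_pb * nb_pi)
    sqs = np.bincount(flat, weights=vals ** 2, minlength=nb_pb * nb_pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(count > 0, sums / np.maximum(count, 1), np.nan)
        var = np.where(count > 1,
                       (sqs - sums ** 2 / np.maximum(count, 1))
                       / np.maximum(count - 1, 1), np.nan)
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[count <= 1] = np.nan
    mean[count == 0] = np.nan
    shape = (nb_pb, nb_pi)
    return ControlSpaceMap(feature_name, pb_edges, picas_edges,
                           mean.reshape(shape), sd.reshape(shape),
                           count.reshape(shape))
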