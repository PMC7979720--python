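"""Run-level model and results objects.

`SyrinxRunModel` bundles the whole analysis of one recording the way a
statistical model class bundles data and options: construct it from a
recording (or file) plus a `PipelineConfig`, call :meth:`fit`, and read
everything — binned features, ramp segments, per-ramp phonation onsets,
the run summary, the piecewise f_o-p_t and linear SL-p_b fits, and the
ΔBIC driving-pressure comparisons — off the returned
:class:`SyrinxRunResults`, whose :meth:`~SyrinxRunResults.summary` prints
a compact report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .config import PipelineConfig
from .control_space import (build_map, detect_ptp, phonating_mask,
                            resolve_threshold, segment_ramps, summarize_run)
from .fits import delta_bic, fit_linear, fit_piecewise
from .io import MultichannelRecording, read_recording
from .preprocess import assemble_features


class SyrinxRunModel:
    """Analysis model for one hemi-syrinx pressure-ramp run."""

    def __init__(self, recording: MultichannelRecording,
                 config: PipelineConfig | None = None, protocol_hint=None):
        self.recording = recording
        self.config = config or PipelineConfig()
        self.protocol_hint = protocol_hint

    @classmethod
    def from_file(cls, path, config: PipelineConfig | None = None,
                  protocol_hint=None) -> "SyrinxRunModel":
        return cls(read_recording(path), config, protocol_hint)

    def fit(self) -> "SyrinxRunResults":
        cfg = self.config
        features = assemble_features(self.recording, cfg)
        segments = segment_ramps(
            features, self.protocol_hint, pb_on=cfg.pb_on_kpa,
            picas_tolerance=cfg.picas_tolerance_kpa, min_ramp_s=cfg.min_ramp_s)
        threshold = resolve_threshold(features, segments,
                                      cfg.ptp_noise_multiple,
                                      cfg.ptp_absolute_floor)
        ptps = [detect_ptp(seg, features, threshold,
                           f0_guard_s=cfg.onset_guard_s) for seg in segments]
        if segments:
            summary = summarize_run(ptps, features, segments, threshold,
                                    guard_s=cfg.onset_guard_s)
        else:
            nan = float("nan")
            from .control_space import RunSummary
            summary = RunSummary(nan, nan, nan, nan, nan, nan, nan, 0)

        mask = phonating_mask(features, segments, threshold,
                              cfg.onset_guard_s)
        f0_fit = sl_fit = f0_bic = sl_bic = None
        sel = mask & ~np.isnan(features.f_o)
        if sel.sum() >= 10:
            try:
                f0_fit = fit_piecewise(features.p_t[sel], features.f_o[sel],
                                       cfg.breakpoint, cfg.pt_upper)
            except ValueError:
                f0_fit = None
            preds = {"p_t": features.p_t[sel], "p_b": features.rms_pb[sel],
                     "p_icas": features.rms_picas[sel]}
            f0_bic = delta_bic(features.f_o[sel], preds)
        sel_sl = mask & ~np.isnan(features.SL)
        if sel_sl.sum() >= 10:
            sl_fit = fit_linear(features.rms_pb[sel_sl], features.SL[sel_sl])
            preds = {"p_t": features.p_t[sel_sl],
                     "p_b": features.rms_pb[sel_sl],
                     "p_icas": features.rms_picas[sel_sl]}
            sl_bic = delta_bic(features.SL[sel_sl], preds)

        return SyrinxRunResults(
            model=self, features=features, segments=segments, ptps=ptps,
            threshold=threshold, run_summary=summary, phonating=mask,
            f0_fit=f0_fit, sl_fit=sl_fit, f0_bic=f0_bic, sl_bic=sl_bic)


@dataclass
class SyrinxRunResults:
    """Fitted results of a :class:`SyrinxRunModel`."""

    model: SyrinxRunModel
    features: object
    segments: list
    ptps: list
    threshold: float
    run_summary: object
    phonating: np.ndarray
    f0_fit: object = None
    sl_fit: object = None
    f0_bic: object = None
    sl_bic: object = None
    provenance: dict = field(init=False)

    def __post_init__(self):
        self.provenance = {
            "package_version": _pkg_version,
            "config_digest": self.model.config.digest(),
            "seed": self.model.config.seed,
            "threshold_pa": self.threshold,
        }

    def control_space_map(self, feature="f_o"):
        cfg = self.model.config
        return build_map(self.features, self.segments, feature,
                         pb_step=cfg.pb_step, picas_step=cfg.picas_step,
                         threshold=self.threshold,
                         guard_s=cfg.onset_guard_s)

    def plot_map(self, feature="f_o", ax=None):
        """Quick-look pcolormesh of one feature over the pressure plane."""
        import matplotlib.pyplot as plt

        cmap = self.control_space_map(feature)
        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(cmap.picas_edges, cmap.pb_edges, cmap.mean,
                             shading="auto")
        ax.set_xlabel("p_icas (kPa)")
        ax.set_ylabel("p_b (kPa)")
        ax.figure.colorbar(mesh, ax=ax, label=feature)
        return ax

    def summary(self) -> str:
        s = self.run_summary
        meta = self.model.recording.meta
        lines = [
            "Syringeal pressure-control run summary",
            "=" * 46,
            f"subject {meta.subject_id}  side {meta.side}  sex {meta.sex}",
            f"ramps: {len(self.segments)}  phonating: {s.n_phonating_ramps}"
            f"  threshold: {self.threshold * 1e3:.3g} mPa",
            "-" * 46,
            f"PTP_b     {s.ptp_b_first:8.3f} kPa",
            f"PTP_icas  {s.ptp_icas_min:8.3f} kPa",
            f"PTP_t     {s.ptp_t_min:8.3f} kPa",
            f"min f_o   {s.minimal_f0:8.1f} Hz",
            f"min SL    {s.minimal_SL:8.1f} dB re 20 uPa at 1 m",
            f"mean WE   {s.mean_WE:8.2f}",
            f"mean ME   {s.mean_ME:8.1f} dB",
        ]
        if self.f0_fit is not None:
            f = self.f0_fit
            lines.append(
                f"f_o~p_t   S1 {f.s1_slope:7.1f} Hz/kPa (n={f.n1}, r2={f.r2_1:.3f})"
                f"  S2 {f.s2_slope:6.1f} Hz/kPa (n={f.n2}, r2={f.r2_2:.3f})")
        if self.sl_fit is not None:
            lines.append(f"SL~p_b    slope {self.sl_fit.slope:6.2f} dB/kPa "
                         f"(r2={self.sl_fit.r2:.3f})")
        if self.f0_bic is not None:
            d = ", ".join(f"{k}={v:.0f}" for k, v in self.f0_bic.delta_bic.items())
            lines.append(f"dBIC f_o  best={self.f0_bic.best}  ({d})")
        if self.sl_bic is not None:
            d = ", ".join(f"{k}={v:.0f}" for k, v in self.sl_bic.delta_bic.items())
            lines.append(f"dBIC SL   best={self.sl_bic.best}  ({d})")
        return "\n".join(lines)
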