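import numpy as np
import pytest

import pysyrinx as ps
from pysyrinx.control_space import phonating_mask, resolve_threshold
from pysyrinx.exceptions import SegmentationError

from conftest import make_features


def ramp_features(n=3000, onset=1500, level=0.02, setpoint=1.0, hop=0.001):
    """Single synthetic ramp: p_b rises 1 kPa/s, sound switches on at
    ``onset`` bins with RMS ``level``."""
    pb = np.arange(n) * hop * 1.0
    sound = np.full(n, 1e-5)
    sound[onset:] = level
    f_o = np.full(n, np.nan)
    f_o[onset:] = 500.0 + 100.0 * (pb[onset:] - pb[onset])
    return make_features(rms_sound=sound, rms_pb=pb,
                         rms_picas=np.full(n, setpoint), f_o=f_o,
                         SL=np.where(sound > 1e-4, 45.0 + 4 * pb, np.nan))


class TestSegmentRamps:
    def test_full_protocol_yields_13_segments_with_matching_setpoints(
            self, full_run, fast_protocol):
        _, res = full_run
        assert len(res.segments) == len(fast_protocol.picas_levels) == 13
        found = [s.picas_setpoint for s in res.segments]
        np.testing.assert_allclose(found, fast_protocol.picas_levels, atol=0.03)

    def test_ramp_rate_estimated_near_protocol_rate(self, full_run,
                                                    fast_protocol):
        _, res = full_run
        rates = [s.ramp_rate_est for s in res.segments]
        np.testing.assert_allclose(rates, fast_protocol.ramp_rate, rtol=0.1)

    def test_all_silence_yields_empty_list(self):
        feats = make_features(rms_sound=np.full(500, 1e-6))
        assert ps.segment_ramps(feats) == []

    def test_single_ramp_without_pause_spans_the_rise(self):
        feats = ramp_features()
        segs = ps.segment_ramps(feats)
        assert len(segs) == 1
        assert segs[0].start_bin <= 30 and segs[0].end_bin == len(feats)

    def test_protocol_hint_count_mismatch_raises_with_candidates(self):
        feats = ramp_features()
        proto = ps.make_protocol({"picas_levels": [0.0, 1.0]}, seed=0)
        with pytest.raises(SegmentationError) as err:
            ps.segment_ramps(feats, protocol_hint=proto)
        assert len(err.value.candidates) == 1


class TestDetectPTP:
    def test_onset_pressures_read_from_crossing_bin(self):
        feats = ramp_features(onset=1500, setpoint=1.0)
        seg = ps.segment_ramps(feats)[0]
        ptp = ps.detect_ptp(seg, feats, threshold=1e-3)
        assert ptp.phonated
        assert ptp.ptp_b == pytest.approx(1.5, abs=0.002)
        assert ptp.ptp_icas == pytest.approx(1.0)
        assert ptp.ptp_t == ptp.ptp_b - ptp.ptp_icas  # exact identity
        assert ptp.onset_f0 == pytest.approx(500.0)

    def test_subthreshold_ramp_reports_not_phonated(self):
        feats = ramp_features(level=1e-4)
        seg = ps.segment_ramps(feats)[0]
        ptp = ps.detect_ptp(seg, feats, threshold=1e-3)
        assert not ptp.phonated and np.isnan(ptp.ptp_b)

    def test_onset_at_first_bin_uses_the_setpoint(self):
        feats = ramp_features(onset=0, setpoint=0.8)
        seg = ps.segment_ramps(feats)[0]
        ptp = ps.detect_ptp(seg, feats, threshold=1e-3)
        assert ptp.onset_bin == seg.start_bin
        assert ptp.ptp_icas == pytest.approx(0.8)

    def test_onset_bin_is_nondecreasing_in_threshold(self):
        feats = ramp_features()
        seg = ps.segment_ramps(feats)[0]
        onsets = []
        for thr in [1e-4, 5e-4, 1e-3, 0.019, 0.05]:
            p = ps.detect_ptp(seg, feats, thr)
            onsets.append(p.onset_bin if p.phonated else np.inf)
        assert all(a <= b for a, b in zip(onsets, onsets[1:]))

    def test_noiseless_simulator_onset_recovered_at_bin_resolution(self):
        import dataclasses
        pre = dataclasses.replace(
            ps.PRESETS["adult-male-left"], ptp_b=1.0, noise_rms=0.0,
            pressure_noise=0.0, flow_noise=0.0, breath_fraction=0.0)
        proto = ps.make_protocol({"picas_levels": [0.5], "pause_s": 1.0},
                                 seed=0, fast=True)
        rec = ps.simulate_run(pre, proto, seed=0)
        feats = ps.assemble_features(rec)
        segs = ps.segment_ramps(feats)
        thr = resolve_threshold(feats, segs)
        ptp = ps.detect_ptp(segs[0], feats, thr)
        assert ptp.ptp_b == pytest.approx(1.0, abs=0.01)


class TestSummarizeRun:
    def test_minimal_f0_is_mean_of_onset_f0(self):
        feats = ramp_features()
        seg = ps.segment_ramps(feats)[0]
        ptps = [ps.PTPResult(True, 1.0, 0.5, 0.5, 10, 480.0),
                ps.PTPResult(True, 1.2, 0.5, 0.7, 20, 520.0)]
        s = ps.summarize_run(ptps, feats, [seg], threshold=1e-3)
        assert s.minimal_f0 == pytest.approx(500.0)
        assert s.n_phonating_ramps == 2
        assert s.ptp_b_first == pytest.approx(1.0)

    def test_single_ramp_summary_equals_its_onset(self):
        feats = ramp_features()
        seg = ps.segment_ramps(feats)[0]
        ptp = ps.detect_ptp(seg, feats, 1e-3)
        s = ps.summarize_run([ptp], feats, [seg], threshold=1e-3)
        assert s.minimal_f0 == ptp.onset_f0
        assert s.ptp_t_min == ptp.ptp_t

    def test_zero_phonating_ramps_yield_missing_summaries(self):
        feats = ramp_features(level=1e-4)
        seg = ps.segment_ramps(feats)[0]
        ptp = ps.detect_ptp(seg, feats, 1e-3)
        s = ps.summarize_run([ptp], feats, [seg], threshold=1e-3)
        assert s.n_phonating_ramps == 0
        assert np.isnan(s.minimal_f0) and np.isnan(s.minimal_SL)

    def test_simulator_summary_recovers_preset_minimal_f0(
            self, full_run, aml_preset, fast_protocol):
        _, res = full_run
        gt, _ = ps.ground_truth(aml_preset, fast_protocol)
        assert res.run_summary.minimal_f0 == pytest.approx(gt.minimal_f0,
                                                           abs=10.0)


class TestControlSpaceMap:
    def test_single_giant_cell_equals_global_phonating_mean(self, full_run):
        _, res = full_run
        cmap = ps.build_map(res.features, res.segments, "f_o",
                            pb_step=10.0, picas_step=10.0,
                            threshold=res.threshold)
        mask = phonating_mask(res.features, res.segments, res.threshold,
                              guard_s=0.015)
        vals = res.features.f_o[mask]
        assert cmap.mean.shape == (1, 1)
        assert cmap.mean[0, 0] == pytest.approx(np.nanmean(vals), rel=1e-9)

    def test_cell_counts_sum_to_phonating_bin_count(self, full_run):
        _, res = full_run
        cmap = res.control_space_map("f_o")
        mask = phonating_mask(res.features, res.segments, res.threshold,
                              guard_s=0.015)
        assert cmap.count.sum() == np.sum(mask & ~np.isnan(res.features.f_o))

    def test_f0_rises_toward_lower_picas_at_fixed_pb(self, full_run):
        # at fixed p_b, lowering p_icas raises p_t and hence f_o
        _, res = full_run
        cmap = res.control_space_map("f_o")
        pb_centers = (cmap.pb_edges[:-1] + cmap.pb_edges[1:]) / 2
        row = np.argmin(np.abs(pb_centers - 2.0))
        vals = cmap.mean[row]
        ok = ~np.isnan(vals)
        assert ok.sum() >= 3
        diffs = np.diff(vals[ok])
        assert np.all(diffs < 1.0)  # non-increasing with p_icas (tolerance 1 Hz)

    def test_empty_cells_are_nan_not_zero(self, full_run):
        _, res = full_run
        cmap = res.control_space_map("f_o")
        empty = cmap.count == 0
        assert empty.any()
        assert np.all(np.isnan(cmap.mean[empty]))

    def test_nonpositive_step_is_domain_error(self, full_run):
        _, res = full_run
        with pytest.raises(ValueError):
            ps.build_map(res.features, res.segments, "f_o", pb_step=0.0)
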