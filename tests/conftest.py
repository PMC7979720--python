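import numpy as np
import pytest

import pysyrinx as ps


@pytest.fixture(scope="session")
def aml_preset():
    """Adult-male-left preset: the default ground-truth parameter set."""
    return ps.PRESETS["adult-male-left"]


@pytest.fixture(scope="session")
def fast_protocol():
    """Default 13-level protocol at the 20 kHz reduced-cost profile."""
    return ps.make_protocol(seed=1, fast=True)


@pytest.fixture(scope="session")
def full_run(aml_preset, fast_protocol):
    """One complete simulated run (seed 1) plus its fitted results."""
    rec = ps.simulate_run(aml_preset, fast_protocol, seed=1)
    res = ps.SyrinxRunModel(rec, protocol_hint=fast_protocol).fit()
    return rec, res


@pytest.fixture(scope="session")
def short_recording(aml_preset):
    """Cheap single-ramp recording for I/O and plumbing tests."""
    proto = ps.make_protocol({"picas_levels": [1.0], "pause_s": 1.0},
                             seed=3, fast=True)
    return ps.simulate_run(aml_preset, proto, seed=3), proto


def make_features(rms_sound, rms_pb=None, rms_picas=None, f_o=None,
                  SL=None, WE=None, ME=None, hop=0.001, bin_width=0.002):
    """Hand-built BinnedFeatureSeries for unit tests of the control-space
    logic, bypassing the signal chain."""
    n = len(rms_sound)
    z = np.zeros(n)
    nanarr = np.full(n, np.nan)
    rms_pb = z if rms_pb is None else np.asarray(rms_pb, float)
    rms_picas = z if rms_picas is None else np.asarray(rms_picas, float)
    return ps.BinnedFeatureSeries(
        bin_center_t=np.arange(n) * hop + bin_width / 2,
        rms_sound=np.asarray(rms_sound, float),
        rms_pb=rms_pb, rms_picas=rms_picas, rms_flow=z.copy(),
        p_t=rms_pb - rms_picas,
        f_o=nanarr.copy() if f_o is None else np.asarray(f_o, float),
        aperiodicity=np.ones(n),
        SL=nanarr.copy() if SL is None else np.asarray(SL, float),
        WE=nanarr.copy() if WE is None else np.asarray(WE, float),
        ME=nanarr.copy() if ME is None else np.asarray(ME, float),
        bin_width=bin_width, hop=hop)
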