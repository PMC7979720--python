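import numpy as np
import pytest

import pysyrinx as ps
from pysyrinx.exceptions import PysyrinxError
from pysyrinx.features import _we_from_amplitude


def harmonic_frame(f0, fs, dur=0.05, n_harm=8, rolloff_db=6.0, rms=1e-3,
                   seed=None):
    t = np.arange(int(fs * dur)) / fs
    amps = 10 ** (-rolloff_db * np.arange(n_harm) / 20.0)
    x = sum(a * np.sin(2 * np.pi * (k + 1) * f0 * t)
            for k, a in enumerate(amps))
    x *= rms / np.sqrt(np.mean(x ** 2))
    if seed is not None:
        x = x + np.random.default_rng(seed).normal(0, rms * 1e-3, x.size)
    return x


def autocorr_f0(frame, fs, f_lo=150.0, f_hi=8000.0):
    """Brute-force oracle: parabolic-refined argmax of the normalised
    autocorrelation over the lag range."""
    frame = np.asarray(frame, float)
    tau_max = int(np.ceil(fs / f_lo))
    tau_min = max(2, int(np.floor(fs / f_hi)))
    w = frame.size - tau_max
    e0 = np.sum(frame[:w] ** 2)
    r = np.empty(tau_max + 1)
    norm = np.empty(tau_max + 1)
    for tau in range(tau_max + 1):
        seg = frame[tau:tau + w]
        r[tau] = np.dot(frame[:w], seg)
        norm[tau] = np.sqrt(e0 * np.sum(seg ** 2))
    rho = r / np.maximum(norm, 1e-300)
    # a periodic frame peaks equally at every multiple of the (possibly
    # non-integer) period: interpolate each local maximum's true height,
    # then break the tie toward the smallest lag
    peaks = []
    for k in range(max(tau_min, 1), tau_max):
        ym, y0, yp = rho[k - 1], rho[k], rho[k + 1]
        if y0 >= ym and y0 >= yp:
            denom = ym - 2 * y0 + yp
            delta = 0.5 * (ym - yp) / denom if denom != 0 else 0.0
            height = y0 - 0.25 * (ym - yp) * delta
            peaks.append((k + delta, height))
    assert peaks, "no autocorrelation peak in the lag range"
    best = max(h for _, h in peaks)
    lag, height = next(p for p in peaks if p[1] >= best - 1e-3)
    return fs / lag, 1.0 - height


class TestYin:
    def test_pure_tone_recovered_within_1_hz(self):
        fs = 50000
        t = np.arange(int(0.025 * fs)) / fs
        frame = 1e-3 * np.sqrt(2) * np.sin(2 * np.pi * 500 * t)
        f, ap = ps.yin_f0(frame, fs)
        assert f == pytest.approx(500.0, abs=1.0)
        assert ap < 0.05

    def test_harmonic_stack_recovered_within_1_hz(self):
        fs = 50000
        frame = harmonic_frame(600.0, fs, dur=0.025)
        f, _ = ps.yin_f0(frame, fs)
        assert f == pytest.approx(600.0, abs=1.0)

    @pytest.mark.parametrize("f0", [220.0, 313.0, 500.0, 641.0, 987.0, 2200.0])
    def test_agrees_with_autocorrelation_oracle_on_periodic_frames(self, f0):
        fs = 50000
        frame = harmonic_frame(f0, fs, dur=0.03, seed=int(f0))
        f_yin, _ = ps.yin_f0(frame, fs)
        f_ref, ap_ref = autocorr_f0(frame, fs)
        assert ap_ref < 0.05
        assert abs(f_yin - f_ref) <= 2.0

    def test_white_noise_is_gated_out(self):
        rng = np.random.default_rng(5)
        frame = rng.normal(0, 1e-3, 1500)
        f, ap = ps.yin_f0(frame, 50000)
        assert np.isnan(f)
        assert ap > 0.15

    def test_quiet_tone_fails_power_gate_but_reports_aperiodicity(self):
        fs = 50000
        t = np.arange(1500) / fs
        frame = 1e-5 * np.sin(2 * np.pi * 500 * t)  # below 0.5 mPa RMS
        f, ap = ps.yin_f0(frame, fs)
        assert np.isnan(f)
        assert ap < 0.05

    def test_all_zero_frame(self):
        f, ap = ps.yin_f0(np.zeros(1500), 50000)
        assert np.isnan(f) and ap == 1.0

    def test_frame_too_short_raises(self):
        with pytest.raises(PysyrinxError, match="two periods"):
            ps.yin_f0(np.ones(100), 50000)


class TestSourceLevel:
    @pytest.mark.parametrize("p,r,expected,atol", [
        (20e-6, 1.0, 0.0, 1e-9),
        (0.2, 1.0, 80.0, 1e-9),
        (0.0237, 0.15, 45.0, 0.05),
    ])
    def test_reference_values(self, p, r, expected, atol):
        assert ps.source_level(p, r=r) == pytest.approx(expected, abs=atol)

    @pytest.mark.parametrize("k", [0.1, 2.0, 31.6])
    def test_pressure_scaling_adds_20log10k(self, k):
        base = ps.source_level(0.01)
        assert ps.source_level(0.01 * k) == pytest.approx(
            base + 20 * np.log10(k), abs=1e-9)

    def test_zero_pressure_is_minus_infinity(self):
        assert ps.source_level(0.0) == float("-inf")

    def test_negative_pressure_is_domain_error(self):
        with pytest.raises(ValueError):
            ps.source_level(-0.1)


class TestWienerEntropy:
    def test_flat_spectrum_limit_is_zero(self):
        frame = np.zeros(512)
        frame[256] = 1.0  # impulse: flat amplitude spectrum
        assert abs(ps.wiener_entropy(frame, 20000)) < 0.05

    def test_hand_computed_amplitude_spectrum(self):
        # direct formula check bypassing the FFT
        we = _we_from_amplitude(np.array([1.0, 1.0, 1.0, 8.0]))
        assert we == pytest.approx(np.log10(8 ** 0.25 / 2.75), abs=1e-3)
        assert we == pytest.approx(-0.213, abs=1e-3)

    def test_tonal_limit_is_strongly_negative(self):
        fs = 20000
        t = np.arange(2048) / fs
        tone = np.sin(2 * np.pi * (40 * fs / 2048) * t)
        assert ps.wiener_entropy(tone, fs) < -3.0

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(2)
        frame = rng.normal(size=1024)
        a = ps.wiener_entropy(frame, 20000)
        b = ps.wiener_entropy(250.0 * frame, 20000)
        assert a == pytest.approx(b, abs=1e-9)
        assert a <= 0.0

    def test_all_zero_frame_is_missing(self):
        assert np.isnan(ps.wiener_entropy(np.zeros(256), 20000))


class TestHarmonicF0:
    @pytest.mark.parametrize("f_n,n,expected", [
        (1500.0, 3, 500.0), (432.0, 1, 432.0), (2995.0, 5, 599.0)])
    def test_division_by_harmonic_order(self, f_n, n, expected):
        assert ps.f0_from_harmonic(f_n, n) == pytest.approx(expected)

    def test_zero_order_is_domain_error(self):
        with pytest.raises(ValueError):
            ps.f0_from_harmonic(1000.0, 0)
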