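"""Forward hemi-syrinx simulator.

Generates protocol-conformant multichannel recordings (sound, bronchial
pressure, air-sac pressure, flow) with fully known ground truth, emulating
the ramp paradigm used on isolated preparations: bronchial pressure ramps
0 -> 3 kPa at 1 kPa/s against 13 equidistant air-sac pressure setpoints
between 0 and 3 kPa in seeded-random order, with 2 s pauses.

The sound model is phenomenological, not biomechanical: phonation is
active inside an AND-box of the three threshold pressures (p_b >= PTP_b,
p_icas >= PTP_icas, PTP_t <= p_t <= pt_max); while active the fundamental
follows a piecewise-linear function of transmural pressure (slope s1 below
the 0.75 kPa breakpoint, s2 above, continuous at the break), the waveform
is a constant-rolloff harmonic stack with continuous phase and 5 ms
raised-cosine on/offsets, its RMS realises a linear source-level law
SL(p_b), and flow is proportional to bronchial pressure while the
generator oscillates.  Gaussian sensor noise is added to every channel.

The f_o line's offset is chosen analytically (see :func:`f0_offset`) so
that the mean of f_o over the per-ramp phonation onsets — the operational
definition of "minimal f_o" in the analysis — equals the preset's
``f_min``.  With threshold pressures that differ per ramp in which
constraint binds first, anchoring instead at f_o(PTP_t) = f_min would make
the recovered minimal f_o systematically exceed its target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .control_space import RunSummary
from .exceptions import ConfigError
from .fits import PiecewiseSlopeFit
from .io import MultichannelRecording, RecordingMeta

#: partials at or above this frequency are dropped (acquisition anti-alias band)
PARTIAL_CAP_HZ = 10000.0

#: sample rate of the reduced-cost profile
FAST_SAMPLE_RATE = 20000.0


@dataclass
class SyrinxPreset:
    """Ground-truth parameter set of one synthetic hemi-syrinx.

    Pressure thresholds and acoustic laws default to the adult cohort
    means: PTP_b 1.01 kPa, PTP_icas 0.45 kPa, PTP_t 0.15 kPa, minimal f_o
    511 Hz, S1/S2 slopes 189/55 Hz/kPa with the 0.75 kPa breakpoint,
    minimal SL 45 dB re 20 µPa at 1 m with 4 dB/kPa (left side).
    ``flow_conductance`` defaults to 1.19e-6 m^3 s^-1 kPa^-1, which places
    the mechanical efficiency at phonation onset at -35 dB;
    ``breath_fraction`` (aspiration noise co-modulated with the voiced
    source, as a fraction of its RMS) is calibrated so the pipeline's mean
    Wiener entropy lands near -1.8; ``harmonic_rolloff`` sets the spectral
    slope of the stack in dB per harmonic step.
    """

    ptp_b: float = 1.01
    ptp_icas: float = 0.45
    ptp_t: float = 0.15
    f_min: float = 511.0
    s1: float = 189.0
    s2: float = 55.0
    breakpoint: float = 0.75
    sl_min: float = 45.0
    sl_slope: float = 4.0
    harmonic_count: int = 8
    harmonic_rolloff: float = 6.0
    flow_conductance: float = 1.19e-6
    noise_rms: float = 1e-5
    breath_fraction: float = 0.0012
    pt_max: float = 2.0
    pressure_noise: float = 0.002
    flow_noise: float = 2e-9
    leak_fraction: float = 0.02
    attack_s: float = 0.005
    side: str = "left"
    sex: str = "male"
    age_dph: int | None = 100

    def __post_init__(self):
        if self.f_min <= 0:
            raise ConfigError("f_min must be positive")
        if not self.ptp_b > self.ptp_t >= 0:
            raise ConfigError("need ptp_b > ptp_t >= 0")
        for name in ("s1", "s2", "sl_slope", "flow_conductance"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")


#: named presets with the cohort-mean acoustic laws per side and sex
PRESETS = {
    "adult-male-left": SyrinxPreset(),
    "adult-male-right": SyrinxPreset(f_min=513.0, sl_slope=5.0, side="right"),
    "adult-female-left": SyrinxPreset(f_min=529.0, sl_slope=4.0,
                                      side="left", sex="female"),
    "adult-female-right": SyrinxPreset(f_min=568.0, sl_slope=5.0,
                                       side="right", sex="female"),
}


@dataclass
class RampProtocol:
    """Pressure-ramp protocol: levels, rates, pauses and acquisition rate."""

    ramp_rate: float = 1.0
    pb_max: float = 3.0
    picas_levels: list = field(
        default_factory=lambda: list(np.linspace(0.0, 3.0, 13)))
    pause_s: float = 2.0
    order_seed: int = 0
    sample_rate: float = 50000.0

    def __post_init__(self):
        if not self.picas_levels:
            raise ConfigError("picas_levels must be non-empty")
        if any(lv < 0 for lv in self.picas_levels):
            raise ConfigError("picas_levels must be >= 0")
        if self.ramp_rate <= 0 or self.pb_max <= 0 or self.sample_rate <= 0:
            raise ConfigError("ramp_rate, pb_max and sample_rate must be positive")

    @property
    def ramp_duration(self) -> float:
        return self.pb_max / self.ramp_rate


def make_protocol(overrides=None, seed=0, fast=False) -> RampProtocol:
    """Build a protocol with the level order as a seeded permutation.

    ``overrides`` maps RampProtocol field names (plus the convenience key
    ``picas_spacing`` to regenerate 13 levels at a given kPa spacing) to
    values.  ``fast=True`` selects the 20 kHz reduced-cost profile.  The
    same seed always yields the same level order.
    """
    overrides = dict(overrides or {})
    spacing = overrides.pop("picas_spacing", None)
    if spacing is not None:
        overrides["picas_levels"] = [i * float(spacing) for i in range(13)]
    if fast and "sample_rate" not in overrides:
        overrides["sample_rate"] = FAST_SAMPLE_RATE
    known = {f.name for f in dataclasses.fields(RampProtocol)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown protocol overrides: {sorted(unknown)}")
    proto = RampProtocol(order_seed=seed, **overrides)
    order = np.random.default_rng(seed).permutation(len(proto.picas_levels))
    proto.picas_levels = [float(proto.picas_levels[i]) for i in order]
    return proto


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _onsets(preset: SyrinxPreset, protocol: RampProtocol):
    """Per-level analytic phonation onsets: (level, onset p_b, onset p_t)."""
    out = []
    for lv in protocol.picas_levels:
        if lv < preset.ptp_icas:
            continue
        pb_on = max(preset.ptp_b, lv + preset.ptp_t)
        if pb_on > protocol.pb_max or pb_on - lv > preset.pt_max:
            continue
        out.append((lv, pb_on, pb_on - lv))
    return out


def _f0_shape(pt, preset: SyrinxPreset):
    pt = np.asarray(pt, dtype=np.float64)
    return (preset.s1 * np.minimum(pt, preset.breakpoint)
            + preset.s2 * np.maximum(0.0, pt - preset.breakpoint))


def f0_offset(preset: SyrinxPreset, protocol: RampProtocol) -> float:
    """Offset C of the f_o(p_t) law, f_o = C + s1-piecewise-s2 shape.

    Chosen so the mean of f_o over the per-ramp onset transmural pressures
    equals ``preset.f_min``; with no phonating ramp it falls back to
    anchoring f_o(PTP_t) = f_min.
    """
    onsets = _onsets(preset, protocol)
    if onsets:
        anchor = float(np.mean(_f0_shape([pt for _, _, pt in onsets], preset)))
    else:
        anchor = float(_f0_shape(preset.ptp_t, preset))
    return preset.f_min - anchor


def ground_truth(preset: SyrinxPreset, protocol: RampProtocol,
                 meta: RecordingMeta | None = None):
    """Analytic expectations the pipeline should recover from a clean run.

    Returns ``(RunSummary, PiecewiseSlopeFit)``.  The mean mechanical
    efficiency is integrated numerically over the protocol's phonating
    pressure trajectory; the mean Wiener entropy has no closed form for the
    leaky short-window spectra and is reported as NaN.
    """
    meta = meta or RecordingMeta()
    onsets = _onsets(preset, protocol)
    offset = f0_offset(preset, protocol)
    nan = float("nan")
    if not onsets:
        summary = RunSummary(nan, nan, nan, nan, nan, nan, nan, 0)
    else:
        pb_first = min(pb for _, pb, _ in onsets)
        me_vals = []
        for lv, pb_on, _ in onsets:
            pb_end = min(protocol.pb_max, lv + preset.pt_max)
            pb_grid = np.linspace(pb_on, pb_end, 200)
            sl = preset.sl_min + preset.sl_slope * (pb_grid - preset.ptp_b)
            p_rms = meta.ref_pressure_P0 * 10.0 ** (
                (sl - 20.0 * np.log10(meta.mic_distance_r)) / 20.0)
            p_ac = (4.0 * np.pi * meta.mic_distance_r ** 2 * p_rms ** 2
                    / (meta.air_density_rho * meta.sound_speed_v))
            p_aero = pb_grid * 1000.0 * preset.flow_conductance * pb_grid
            me_vals.append(10.0 * np.log10(p_ac / p_aero))
        summary = RunSummary(
            minimal_f0=preset.f_min,
            minimal_SL=preset.sl_min + preset.sl_slope * (pb_first - preset.ptp_b),
            mean_WE=nan,
            mean_ME=float(np.mean(np.concatenate(me_vals))),
            ptp_b_first=pb_first,
            ptp_icas_min=min(lv for lv, _, _ in onsets),
            ptp_t_min=min(pt for _, _, pt in onsets),
            n_phonating_ramps=len(onsets),
        )
    fit = PiecewiseSlopeFit(
        s1_slope=preset.s1, s2_slope=preset.s2,
        s1_intercept=offset,
        s2_intercept=offset + (preset.s1 - preset.s2) * preset.breakpoint,
        breakpoint=preset.breakpoint, upper_limit=preset.pt_max,
        n1=0, n2=0, r2_1=nan, r2_2=nan)
    return summary, fit


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _command_pressures(protocol: RampProtocol):
    """Sample-level commanded (p_b, p_icas) over the whole run timeline."""
    fs = protocol.sample_rate
    n_pause = int(round(protocol.pause_s * fs))
    n_ramp = int(round(protocol.ramp_duration * fs))
    ramp = np.arange(n_ramp) / fs * protocol.ramp_rate
    pb_parts, pi_parts = [], []
    zeros = np.zeros(n_pause)
    for lv in protocol.picas_levels:
        pb_parts += [zeros, ramp]
        pi_parts += [zeros, np.full(n_ramp, lv)]
    pb_parts.append(zeros)
    pi_parts.append(zeros)
    return np.concatenate(pb_parts), np.concatenate(pi_parts)


def _envelope(active: np.ndarray, fs: float, attack_s: float) -> np.ndarray:
    """0/1 mask softened with raised-cosine on/offsets inside each stretch."""
    env = active.astype(np.float64)
    n_att = int(round(attack_s * fs))
    if n_att < 2:
        return env
    edges = np.flatnonzero(np.diff(active.astype(np.int8)))
    half = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_att) / n_att))
    for e in edges:
        if active[e + 1]:  # onset at e+1
            seg = slice(e + 1, min(e + 1 + n_att, env.size))
            env[seg] = np.minimum(env[seg], half[:seg.stop - seg.start])
        else:  # offset after e
            seg = slice(max(0, e + 1 - n_att), e + 1)
            env[seg] = np.minimum(env[seg], half[::-1][n_att - (seg.stop - seg.start):])
    return env


def simulate_run(preset: SyrinxPreset, protocol: RampProtocol | None = None,
                 seed: int = 0, meta: RecordingMeta | None = None
                 ) -> MultichannelRecording:
    """Generate one complete synthetic run; identical seed, identical output."""
    protocol = protocol or make_protocol()
    fs = protocol.sample_rate
    meta = meta or RecordingMeta(subject_id=f"sim-{seed}", side=preset.side,
                                 sex=preset.sex, age_dph=preset.age_dph)
    rng = np.random.default_rng(seed)

    pb, picas = _command_pressures(protocol)
    pt = pb - picas
    active = ((pb >= preset.ptp_b) & (picas >= preset.ptp_icas)
              & (pt >= preset.ptp_t) & (pt <= preset.pt_max))

    # instantaneous fundamental and continuous phase
    offset = f0_offset(preset, protocol)
    f_inst = offset + _f0_shape(np.clip(pt, preset.ptp_t, preset.pt_max), preset)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
    phase += rng.uniform(0.0, 2.0 * np.pi)

    # harmonic stack, partials capped below the anti-alias band
    f_max = float(f_inst[active].max()) if active.any() else preset.f_min
    amps = []
    for k in range(1, preset.harmonic_count + 1):
        if k * f_max >= min(PARTIAL_CAP_HZ, 0.95 * fs / 2):
            break
        amps.append(10.0 ** (-preset.harmonic_rolloff * (k - 1) / 20.0))
    amps = np.array(amps) if amps else np.array([1.0])
    stack = np.zeros_like(pb)
    for k, a in enumerate(amps, start=1):
        stack += a * np.sin(k * phase)
    norm = np.sqrt(np.sum(amps ** 2) / 2.0)

    # target RMS sound pressure at the microphone from the SL(p_b) law
    sl = preset.sl_min + preset.sl_slope * (pb - preset.ptp_b)
    target_rms = meta.ref_pressure_P0 * 10.0 ** (
        (sl - 20.0 * np.log10(meta.mic_distance_r)) / 20.0)
    env = _envelope(active, fs, preset.attack_s)
    sound = env * target_rms / norm * stack
    if preset.breath_fraction > 0:
        # aspiration noise co-modulated with the voiced source; sets the
        # inter-harmonic floor and hence the Wiener entropy of the output
        sound = sound + (env * target_rms * preset.breath_fraction
                         * rng.normal(0.0, 1.0, sound.size))
    if preset.noise_rms > 0:
        sound = sound + rng.normal(0.0, preset.noise_rms, sound.size)

    flow = preset.flow_conductance * pb * np.where(
        active, 1.0, preset.leak_fraction)
    if preset.flow_noise > 0:
        flow = flow + rng.normal(0.0, preset.flow_noise, flow.size)
    if preset.pressure_noise > 0:
        pb = pb + rng.normal(0.0, preset.pressure_noise, pb.size)
        picas = picas + rng.normal(0.0, preset.pressure_noise, picas.size)

    return MultichannelRecording(sample_rate=fs, sound=sound, p_b=pb,
                                 p_icas=picas, flow=flow, meta=meta)
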