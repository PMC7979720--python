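"""Acoustic power, aerodynamic power and mechanical efficiency.

Radiated acoustic power is computed from the calibrated RMS sound pressure
assuming spherical spreading, P = c * pi * r^2 * p_rms^2 / (rho * v) with
the solid-angle factor c = 4 by default (the printed formula; c = 2 is the
literal half-sphere and is available but not silently substituted).
Aerodynamic power is the product of bronchial pressure (Pa) and volumetric
flow (m^3/s); mechanical efficiency is their ratio in dB.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

#: kPa -> Pa, applied explicitly at this module's boundary
KPA_TO_PA = 1000.0


def acoustic_power(p_rms, r=0.15, rho=1.2, v=344.0, solid_angle_factor=4.0):
    """Radiated acoustic power in W from RMS sound pressure at distance r."""
    if r <= 0 or rho <= 0 or v <= 0 or solid_angle_factor <= 0:
        raise ValueError("r, rho, v and solid_angle_factor must be positive")
    if np.any(np.asarray(p_rms) < 0):
        raise ValueError("p_rms must be non-negative")
    return solid_angle_factor * np.pi * r ** 2 * np.asarray(p_rms) ** 2 / (rho * v)


def aerodynamic_power(p_b_pa, flow):
    """Aerodynamic power p_b * V in W; p_b in Pa (convert kPa upstream!),
    flow in m^3/s.  Negative flow (back-flow) is a domain error — such bins
    are excluded before this point."""
    if np.any(np.asarray(flow) < 0):
        raise ValueError("negative flow: back-flow bins must be excluded upstream")
    if np.any(np.asarray(p_b_pa) < 0):
        raise ValueError("p_b must be non-negative")
    return np.asarray(p_b_pa) * np.asarray(flow)


def mechanical_efficiency(p_acoustic, p_aerodynamic):
    """Mechanical efficiency 10 log10(P_acoustic / P_aerodynamic) in dB.

    Zero acoustic power or non-positive aerodynamic power yields NaN
    (missing) rather than an exception, because both occur routinely in
    silent bins.
    """
    pa = float(p_acoustic)
    pd = float(p_aerodynamic)
    if pa < 0:
        raise ValueError("acoustic power must be non-negative")
    if pd <= 0 or pa == 0:
        if pd <= 0:
            log.debug("non-positive aerodynamic power (%g); ME missing", pd)
        return float("nan")
    return 10.0 * np.log10(pa / pd)


def mechanical_efficiency_series(rms_sound, pb_kpa, flow, meta,
                                 flow_floor=1e-7, solid_angle_factor=4.0):
    """Per-bin ME (dB) from binned features; kPa -> Pa happens here.

    Bins with flow below ``flow_floor`` (noise floor, m^3/s) or with
    non-positive sound or bronchial pressure are NaN to avoid division
    blow-ups on silent or leak-only bins.
    """
    rms_sound = np.asarray(rms_sound, dtype=np.float64)
    pb_pa = np.asarray(pb_kpa, dtype=np.float64) * KPA_TO_PA
    flow = np.asarray(flow, dtype=np.float64)
    p_ac = acoustic_power(np.maximum(rms_sound, 0.0), meta.mic_distance_r,
                          meta.air_density_rho, meta.sound_speed_v,
                          solid_angle_factor)
    ok = (flow >= flow_floor) & (pb_pa > 0) & (p_ac > 0)
    out = np.full(rms_sound.shape, np.nan)
    p_aero = pb_pa[ok] * flow[ok]
    out[ok] = 10.0 * np.log10(p_ac[ok] / p_aero)
    return out
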