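# Methods

## Scope and model

The package quantifies pressure control of voiced sound in an isolated
hemi-syrinx driven by two independently set respiratory pressures: the
bronchial pressure *p*_b upstream of the sound generator and the air-sac
(chamber) pressure *p*_icas surrounding it. The transmural pressure
*p*_t = *p*_b − *p*_icas is the net outward load on the medial vibratory
mass, the vocal-fold analog. The working model, embodied both in the
analysis and in the forward simulator, is:

- phonation requires all of *p*_b, *p*_icas and *p*_t to exceed their
  thresholds (PTP_b, PTP_icas, PTP_t), and *p*_t to stay below a working
  ceiling (2 kPa) — an AND-box in the pressure plane;
- while phonating, f_o is a continuous piecewise-linear function of
  *p*_t with a steep low-pressure slope (S1, below 0.75 kPa) and a
  shallower high-pressure slope (S2, 0.75–2 kPa);
- source level rises linearly with *p*_b;
- Wiener entropy and mechanical efficiency have no systematic pressure
  dependence and are summarised as control-space means.

## Signal chain

All channels are filtered with zero-phase (forward–backward) Butterworth
filters: sound 0.1 kHz 3rd-order high-pass, pressures and flow 2 kHz
3rd-order low-pass (a 0.3 kHz high-pass variant for noisier in-vivo style
recordings is a config switch). Forward–backward filtering applies the
squared magnitude response |H(f)|²; edges are padded by odd reflection
over 3·(order+1) samples, and inputs shorter than the padding raise
rather than being silently truncated.

Features live on a shared sliding-bin grid: 2 ms windows advancing by
1 ms, bin k covering samples [k·H, k·H+W), `n_bins = floor((N−W)/H)+1`,
bins anchored at t = 0 with centers at start + width/2. Sound is
summarised by RMS; the non-negative slow channels by the per-bin mean (for
signals moving on ~100 ms scales the two coincide to high order, and a
difference of means keeps *p*_t = *p*_b − *p*_icas exactly consistent
per bin; a difference of RMS values would be ill-defined for signed
signals). Both conventions are recorded in the series metadata.

### Per-bin analysis windows

A 2 ms bin holds at most one period of a ~500 Hz fundamental, so the two
spectral estimators use longer windows centered on each bin and report at
that bin:

- **YIN** uses a 15 ms window (default) — the shortest length holding two
  periods of the 150 Hz search floor. The estimator is the classic
  difference function / cumulative-mean-normalised difference (CMND)
  recipe; the dip threshold is 0.15, parabolic interpolation refines the
  lag, and the CMND value at the selected lag is the aperiodicity.
  f_o is reported only where aperiodicity ≤ 0.15 and window RMS ≥ 0.5 mPa
  (both per-recording tunables, nominal ranges 0.05–0.2 and 0.25–5 mPa);
  aperiodicity is always reported.
- **Wiener entropy** uses a 2048-sample Hann-tapered boxcar periodogram
  restricted to the 0–10 kHz acquisition band. The Hann taper matters:
  with a rectangular window the sidelobes of the voiced harmonics floor
  the inter-harmonic valleys near −1.3 log units, saturating WE
  regardless of how tonal the source actually is. (Frames passed directly
  to `wiener_entropy()` that are shorter than the FFT are zero-padded;
  the per-bin track always uses full windows.) Zeros in the spectrum are
  floored at machine epsilon times the spectral peak so the geometric
  mean stays defined.

Mechanical efficiency converts kPa→Pa explicitly at the power-module
boundary. The radiated-power formula uses the printed solid-angle factor
4 (4πr²p²/ρv); a literal half-sphere factor 2 is available but never
substituted silently. Bins with flow below 10⁻⁷ m³ s⁻¹ get missing ME to
avoid division blow-ups on leak-only bins.

## Phonation detection and summaries

The detection threshold on RMS sound is
`max(6 × median pre-ramp RMS, 0.25 mPa)` — robust to each preparation's
noise floor yet anchored to an absolute magnitude at the low end of the
usual power-gating range. Per-ramp onsets are read from the first
crossing bin without interpolation ("the first pressure value"), so
PTP_t = PTP_b − PTP_icas holds exactly per ramp.

Extreme-value and mean summaries (minimal SL, mean WE/ME, the maps) use a
*settled* phonating-bin mask: bins within 15 ms (config `onset_guard_s`)
of a threshold crossing are eroded, because windows straddling an
amplitude transition mix silence into the RMS and would, e.g., collapse
the minimal SL to the detection threshold itself rather than the level
the preparation actually produces at onset. Similarly, if the crossing
bin's f_o is gated out (its centered pitch window straddles the onset),
the onset f_o falls back to the first valid estimate within the guard;
at a 1 kPa/s ramp this biases onset readings by at most a few
thousandths of a kPa and ~1–3 Hz.

Minimal f_o is the mean of per-ramp onset f_o; the run-level PTPs are
minima over phonating ramps (the threshold of the preparation). Maps
default to 0.1 × 0.25 kPa cells, the p_icas step aligning with the
protocol's 13 equidistant levels over 0–3 kPa.

## Regression and model selection

S1/S2 are independent OLS lines on the phonating bins pooled across ramps
of one run; regions are half-open with the 0.75 kPa boundary assigned to
S2 (configurable). ΔBIC uses the Gaussian profiled-likelihood form
`BIC = n·ln(RSS/n) + k·ln(n)` with k counting mean parameters plus the
variance; the additive `n·ln(2π)+n` term is identical across models and
cancels in every ΔBIC, so it is omitted (tests verify agreement with the
full-likelihood computation). Candidates tied within 1e-9 resolve by the
fixed precedence p_t > p_b > p_icas > null. Cohort-level statistics
(mixed models, t-tests) are deliberately not re-implemented; the `report`
command exports tidy tables for standard external tooling.

## The simulator: what it emulates, and what it does not

`simulate_run` reproduces the experimental paradigm — *p*_b ramps 0→3 kPa
at 1 kPa/s against 13 equidistant *p*_icas setpoints (0–3 kPa, seeded
random order, 2 s pauses, 50 kHz; a 20 kHz profile for cheap runs) — with
a phenomenological source: a continuous-phase harmonic stack (8 partials,
6 dB/harmonic rolloff, partials capped below the 10 kHz anti-alias band),
5 ms raised-cosine on/offsets, aspiration noise co-modulated with the
voiced source, linear SL(*p*_b) realised exactly through the inverse
source-level formula, flow proportional to *p*_b through a conductance
while oscillating (2 % leak otherwise), and Gaussian sensor noise on
every channel. It is **not** a biomechanical (two-mass / MEAD) model: no
tissue dynamics, no hysteresis between onset and offset, no bilateral
coupling, no vocal tract. Passing recovery tests therefore demonstrates
that the *analysis* is correct and unbiased under realistic signal
conditions, not that the biological system behaves this way.

Default preset values are the adult cohort means (PTP_b 1.01 kPa,
PTP_icas 0.45 kPa, PTP_t 0.15 kPa, minimal f_o 511 Hz, S1 189 Hz/kPa,
S2 55 Hz/kPa, minimal SL 45 dB at 4 dB/kPa on the left side; right and
female variants ship as named presets). Two derived defaults:

- **flow conductance** 1.19×10⁻⁶ m³ s⁻¹ kPa⁻¹ places the mechanical
  efficiency at phonation onset at −35 dB analytically
  (ME then drifts ≤ 2 dB over the working range, mean ≈ −36.7 dB);
- **breath fraction** 0.0012 of the voiced RMS sets the inter-harmonic
  noise floor so the pipeline's mean Wiener entropy lands near −1.8. The
  harmonic rolloff alone cannot set WE: with clean spectra WE saturates
  near −4 to −5 for any plausible rolloff, because WE of this signal
  class is governed by the broadband floor between harmonics.

A subtlety of the onset geometry: with an AND-box boundary built from the
cohort-mean thresholds, the binding constraint at onset differs per ramp
(*p*_b binds at low setpoints, *p*_t at high ones), so onset *p*_t varies
between 0.15 and ~0.5 kPa. The f_o line is therefore anchored so that the
*mean* of f_o over the per-ramp onsets equals the preset's minimal f_o —
matching the operational definition the analysis uses — rather than
anchoring f_o(PTP_t) = f_min, which would make the recovered minimal f_o
systematically high by ~9 Hz. `ground_truth()` computes these anchors and
all expected summaries analytically for use in recovery assertions.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use five seeded runs of the
default 13-ramp protocol at the 20 kHz profile (~65 s of 4-channel signal
per run, ~65 000 bins; identical tolerances apply at 50 kHz). The
simulator is bit-reproducible under a fixed seed; all randomness flows
from `numpy.random.default_rng(seed)`. Degenerate inputs are handled
explicitly: all-zero pitch frames report aperiodicity 1, empty map cells
are missing (never zero), zero phonating ramps give an all-missing
summary, constant ΔBIC predictors are skipped with a warning.

## Known limitations

- The phonation boundary is sharp; real preparations show gradual onset
  and offset hysteresis, which the onset-guard logic only approximates.
- WE depends on the spectral window choice; values are comparable within
  one configuration, not across different FFT sizes.
- Per-bin f_o and WE use windows much longer than the 2 ms bin, so sharp
  acoustic transients are smoothed over ±8–50 ms.
- The ΔBIC comparison fits single-predictor linear models only, by
  design; it will not detect non-linear or joint-pressure control.
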