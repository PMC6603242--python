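# Methods

`startlekit` is a hardware-free implementation of an acoustic-startle-reflex
(ASR) measurement stack for rodent behavioral audiometry: pre-pulse
inhibition (PPI) threshold estimation and gap-pre-pulse inhibition of the
acoustic startle (GPIAS) tinnitus screening. This note records the models,
the numerical choices, and what the synthetic data generator does and does
not emulate.

## The measurement model

A trial ends with a loud, sudden startle stimulus (a 20 ms broadband noise
burst at 115 dB SPL). The animal's whole-body twitch is picked up by a
3-axis accelerometer on a spring-mounted platform. The ASR amplitude is

    A = max_{0 ≤ t ≤ 150 ms} a(t),
    a(t) = sqrt((c_x a_x(t))² + (c_y a_y(t))² + (c_z a_z(t))²),

with t = 0 at the rising edge of a TTL trigger locked to startle onset, and
c_x, c_y, c_z per-axis calibration factors chosen so the same force gives
the same reading on every axis. Each axis is low-pass filtered at 40 Hz
(4th-order Butterworth, forward–backward, hence zero-phase) *before* the
vector magnitude is formed. Filtering axes first preserves sign information
through the filter; filtering the magnitude instead would rectify before
smoothing. Either reading of "RMS of the three channels, pre-processed with
a low-pass filter" is defensible; we chose per-axis filtering and expose
`lowpass_hz=None` to disable filtering entirely. The window endpoint is
inclusive and ties resolve to the earliest sample.

A perceptible pre-stimulus — a 40 ms pure tone, or a 50 ms silent gap in
ongoing band noise, either one ending/beginning 100 ms before startle
onset — inhibits the reflex. The inhibition statistic is

    PPI (or GPIAS) = 1 − median( A_pre[i] / A_base[j] over all pairs ),

the full combinatorial of pairwise ratios between pre-stimulus-trial and
baseline-trial amplitudes. Startle amplitudes are well described as
log-normal, so the ratios are log-normal too and the log-ratios Gaussian;
the median of ratios is the natural robust effect measure. The standard
error is the standard deviation of the full-combinatorial medians over
bootstrap resamples, resampling the two *amplitude* groups independently
with replacement (not the ratios — resampling ratios would break the
two-sample dependence structure). The canonical replicate count is 100,000;
tests and the acceptance script use reduced counts (500–10,000) since the
SE estimate is already stable there.

PPI as a function of pre-stimulus level follows a hard sigmoid,

    f(x) = clip(m·(x − θ), 0, s),

with the lower asymptote fixed at zero: an inaudible pre-stimulus cannot
inhibit. The fitted breakpoint θ is the estimated hearing threshold at the
probe frequency. Group differences between per-animal statistics use the
two-sided Mann–Whitney U test.

## Stimulus conventions

* **Levels.** dB SPL maps to digital amplitude via a calibration reference:
  a unit-RMS signal is defined to play at `ref_dbspl` (default 100 dB SPL).
  Levels above the reference then exceed digital full scale (the 115 dB
  startle burst has RMS ≈ 5.62); in hardware the amplifier gain absorbs
  this, so synthesis preserves the requested RMS exactly and reports
  full-scale excursions with a warning rather than rejecting them. 16-bit
  PCM export, which genuinely cannot represent them, refuses.
* **Gap.** 50 ms measured between the half-amplitude points of the 20 ms
  sin² down/up ramps, so the printed gap length survives ramping; the fully
  silent plateau is 30 ms. The gap's half-amplitude end precedes startle
  onset by the 100 ms lead interval, mirroring the tone paradigm (the
  original interval is not printed; it is configurable).
* **Tone.** Lead interval is onset-to-onset; plateau RMS (not the
  ramp-diluted average) carries the nominal level.
* **Band noise.** Frequency-domain brick-wall synthesis: uniform magnitude
  and independent uniform phases inside [f_c·2^−w, f_c·2^w], zero outside.
  Band edges are exact and testable; out-of-band power is at numerical
  zero.
* **Trigger.** Rectangular, amplitude 1, 10 ms, rising edge at startle
  onset. Trial timeline defaults: 1.0 s trial, startle onset at 0.7 s.

## Protocols

Every session opens with five startle-only habituation trials, excluded
from all statistics. The data block is a seeded Fisher–Yates permutation
(PCG64, integer seed — stable across platforms and sessions, so a cohort
can share one pseudo-random order) of the balanced condition multiset:
equal gap/no-gap counts per center frequency, or equal tone/no-tone totals
with the no-tone trials pooled as the common baseline for all conditions of
the session. Center frequencies interleave within one permutation by
default; a flag switches to per-frequency blocks.

## Equalizer calibration

The playback chain (loudspeaker–enclosure–microphone system, LEMS) is
identified as an FIR filter by NLMS adaptation against a broadband
excitation (seeded Gaussian noise at RMS 0.5, or a ±1 maximum-length
sequence). Defaults: 2048 taps, step size µ = 0.5, regularization
δ = 1e−6, 2 passes — stable for desk-scale recordings; tests use µ = 1 and
shorter filters for speed. The minimum-phase component is extracted with
the real cepstrum (log-magnitude floor −100 dB, FFT grid ≥ 8× the filter
length to keep cepstral aliasing below the 0.01 dB magnitude-preservation
tolerance). Its Tikhonov-regularized inverse G = H*/(|H|² + ε|H|²_max),
ε = 1e−4, is applied inside the 2–20 kHz band only, with unity gain
outside and raised-cosine transitions of 1/6 octave; taps come from the
inverse FFT, shifted by n_taps/4 to absorb the slight non-causal smear the
regularization and band mask introduce, and Tukey-windowed. Truncation is
the dominant error source: ~2048 taps at 48 kHz keep the cascade ripple of
an already-flat chain below 0.03 dB, and a ±6 dB-colored synthetic LEMS
equalizes to within ±1 dB across the band.

Inter-channel latency is measured from simultaneously played TTL pulses;
the rising edge is the first crossing of 50 % of the per-channel maximum.

## Hard-sigmoid fitting

Nonlinear least squares with a multi-start strategy: coarse threshold
starts across the level range, trust-region refinement of (θ, m, s) with
bounds m > 0, 0 < s ≤ 1, then a 0.1 dB local grid around the winner —
finer than the 2 dB level spacing, and robust against the flat directions
of the piecewise-linear objective. Inverse-variance weights are used when
per-level SEs are supplied. Noiseless data are recovered to ≤ 1e−6; with
saturation never reached inside the level range, s is unidentifiable but θ
and m still recover exactly. All-zero PPI yields an explicit `no_response`
flag instead of a fabricated threshold. The exact Mann–Whitney null is
enumerated for combined n ≤ 12; beyond that the tie-corrected normal
approximation (scipy) is used.

## The synthetic generator

`simulate` stands in for animal, sensor and room, with ground truth known:

* **Amplitudes** are log-normal (default µ = 0, σ = 0.4 — dimensionless
  sensor units, spread comparable to in-vivo startle variability) times a
  multiplicative inhibition factor (1 − I): I = `gpias_true` on gap trials,
  the hard sigmoid of the tone level on tone trials (defaults θ = 10 dB
  SPL, m = 0.05/dB, s = 0.8), zero otherwise. Multiplicative inhibition
  matches the ratio statistic and keeps amplitudes log-normal under
  inhibition.
* **The platform** is one damped second-order mode per axis (15 Hz,
  ζ = 0.25 — a soft spring suspension resonating below the 40 Hz analysis
  filter), excited 20 ms after trigger onset, with per-axis gains and a
  Gaussian sensor-noise floor (default RMS 0.02, i.e. 2 % of the median
  baseline amplitude — a clean MEMS accelerometer after low-pass
  filtering). The per-axis template is numerically normalized through the
  exact extraction pipeline, so a noiseless rendered trial returns the
  drawn amplitude to machine precision; the 2 % round-trip tolerance is
  consumed entirely by sensor noise.
* **The LEMS** is a sum of random smooth log-frequency Gaussian bumps,
  rescaled to the requested in-band swing and realized minimum-phase via
  the cepstrum.

All randomness flows from explicit integer seeds (PCG64 /
`SeedSequence`); identical seeds reproduce sessions bit-identically.

What the generator does **not** emulate: habituation or sensitization
trends across trials, movement artifacts, non-stationary sensor noise,
multi-modal platform mechanics, loudspeaker nonlinearity, or inter-animal
variance structure. Passing closure tests therefore demonstrate that the
analysis recovers what this statistical model plants — they validate the
pipeline's internal consistency, not its robustness to every failure mode
of real recordings.

## Problem sizes and seeds in tests

The suite's problem sizes are chosen for single-CPU runs: accelerometer
rate 2 kHz (the sensor-side rate is independent of the 96 kHz audio rate),
1 s trials, 48 kHz equalizer fixtures with 256-tap systems and 2 s of
excitation. The GPIAS closure uses 500 end-to-end sessions of 15 gap/15
no-gap trials with a 500-replicate bootstrap; coverage of the ±3 SE
interval sits at the 99 % criterion almost exactly — 3·SE intervals for a
median-based statistic at n = 15/15 are not guaranteed Gaussian-calibrated,
and ~1 % misses are inherent, not a seed artifact (the rate is unchanged at
2000 replicates). Threshold closure uses 50 replicates at 15 repeats per
level (the canonical protocol uses 50 repeats; 15 suffices for ~1 dB median
recovery error). The bootstrap-SE check compares the *mean* bootstrap SE
over 50 independent datasets with the Monte-Carlo sampling SD over 1000
datasets: a single dataset's bootstrap SE is itself random (±30 % at
n = 15), while the estimator's true bias is ≈ +6 %.

## Known limitations

* No physical units: amplitudes are arbitrary-but-consistent sensor units,
  levels assume a calibrated reference rather than a measured microphone
  chain.
* The equalizer assumes a linear, time-invariant playback chain.
* `compare_groups` implements exactly one test (two-sided rank-sum); no
  correction across frequencies is applied, by design.
* The statsmodels-style model objects (`InhibitionModel`,
  `HardSigmoidModel`, `LogNormalModel`) wrap the statistics layer only;
  stimulus/equalizer/simulation remain plain functions and dataclasses —
  a deliberate split, since only the statistics layer is genuinely a
  model-fitting problem.
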