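# Methods

This note documents the models implemented in `cgc`, the defaults and units
of their parameters, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dynamic random chord stimuli

A DRC is a sequence of chords of `n_freqs = 25` pure tones on a geometric
frequency grid from 1 to 64 kHz in quarter-octave steps (endpoints
inclusive). Each chord lasts 25 ms; each tone's level (dB SPL) is drawn
independently per chord from a continuous uniform distribution with mean
40 dB SPL and full width 20 dB (low contrast) or 40 dB (high contrast).
The closed-form level SD is `range/sqrt(12)`: 5.77 dB (low) and 11.55 dB
(high); `measure_contrast` reports the empirical SD, which converges to
these values.

Rendering: each tone is a fixed-frequency sinusoid whose amplitude follows
a trapezoidal envelope with 5-ms linear ramps. Envelopes are overlap-added
at 25-ms intervals so consecutive chords cross-fade while the chord period
stays 25 ms; the trailing ramp is truncated at the nominal stimulus end so
`duration = n_chords × 0.025 s` holds exactly. Tone phases are drawn once
from a stream derived from the stimulus seed and recorded on the stimulus
object. The dB→amplitude calibration is configurable; the default maps
94 dB SPL to unit amplitude. Only relative levels matter downstream.

Noise bursts replace whole chords (a 50-ms burst 500 ms into a 1-s DRC
replaces chords 20 and 21) with frozen Gaussian noise at the RMS of a
mean-level chord; the same burst seed reproduces the waveform exactly.

Alternating-contrast sequences draw one pattern of uniform deviates and
map it affinely into each condition's level distribution. The map is
mean-preserving and monotone, so per-chord rank order is identical in
every segment and the shared 40-dB midpoint is a fixed point. The first
(low-contrast) segment is flagged for exclusion to avoid
silence-to-stimulus onset responses.

Two contrast summaries are reported because the quantity σ_P/μ_P admits
several readings. `c` is the SD/mean of the Hilbert-envelope magnitude of
the full synthesized waveform; random-phase interference between 25 tones
dominates this envelope, so it separates the two conditions only weakly
(Monte-Carlo reference values 0.525 / 0.541, frozen in
`stimgen.REFERENCE_ENVELOPE_CONTRAST`). `c_level` is the coefficient of
variation of the per-tone sound pressures in linear units, ≈ 0.64 for a
20-dB range and ≈ 1.14 for a 40-dB range around a fixed mean — this is the
measure that tracks the nominal contrast of the conditions.

## Extracellular signals

Analog MUA: band-pass 300–6,000 Hz (4th-order Butterworth by default; the
filter family for this stage is a configuration choice), full-wave
rectification, low-pass below 6 kHz, polyphase anti-aliased resampling to
12 kHz. All filtering is zero-phase (forward-backward) so latency metrics
do not inherit filter delay. The rectified signal retains within-band
ripple; envelope-recovery accuracy should therefore be assessed at the
analysis resolution (25-ms frames), where a 10-Hz amplitude modulation of
a spike-band carrier is recovered with CC > 0.95.

LFP: 8th-order Chebyshev Type I low-pass at 300 Hz, 0.05 dB passband
ripple (note forward-backward filtering applies the ripple twice).

PSTHs use 25-ms bins; when a light onset is given, the two bins at and
after it are masked (photoelectric artifacts). The peak noise response is
the largest unmasked bin within 150 ms of noise onset; a unit is
noise-responsive iff that peak is at least double the mean of the
pre-stimulus (t < 0) unmasked bins — the doubling criterion is inclusive.
Optogenetic effects are percent changes in the peak between light
conditions; the baseline is checked separately from the pre-stimulus bins.

## Separable STRF estimation

The STRF is constrained to rank 1: `k_fh = outer(k_f, k_h)` with one
history weight per 25-ms lag (default 8 lags = 200 ms; tuning metrics only
use the first 100 ms). The design matrix holds lagged stimulus levels
(frequency-major column order); the response is averaged within each chord
frame; the first `n_lags − 1` chords are dropped.

Fitting is alternating least squares: solve for `k_f` (with bias) by linear
regression holding `k_h` fixed, then for `k_h` holding `k_f` fixed, to
convergence (relative loss change < 1e-8 or 200 iterations). This is block
coordinate descent on a quadratic, so the loss history is non-increasing —
asserted on every fit via `fit_meta`. Each subproblem carries a Tikhonov
floor of `ridge × mean(diag(AᵀA))` with `ridge = 1e-4` by default, which
also guards singular subproblems. Note that because the level design is
strongly correlated (a large common-level component), even this small
relative ridge visibly shrinks prediction variance; analyses that need
unbiased gain estimates from kernel amplitudes (e.g. the cross-condition
scale factor) should fit with `ridge = 0` on the clean simulated fixtures,
and the parameter-recovery tests do so.

Identifiability: the rank-1 factorization is unique only up to scale and
sign, so the convention `‖k_h‖₂ = 1` with the largest-magnitude element of
`k_f` positive is applied at exit; fits from different initializations
agree to < 1e-6 in Frobenius norm on noiseless rank-1 data. The default
initialization is a unit impulse at lag 1 (deterministic).

Evaluation: Pearson CC between prediction and held-out response; the final
contiguous 10% of each stimulus sequence is held out (avoids temporal
leakage); units with CC < 0.04 are excluded from further analysis.
Held-out segments are concatenated before computing CC. Metrics: BF is the
argmax of `k_f`; bandwidth is the contiguous half-amplitude width around
BF in octaves on the log2 frequency axis, with crossings located by linear
interpolation between bins; the temporal window is the analogous width
around the history-kernel peak within the first 100 ms. Cross-condition
transfer fits a single scale factor and offset to the light-off
prediction by closed-form least squares.

## Nonparametric gain statistics

`R_min` and `R_max` are the 5th and 95th percentiles of a response trace
(linear-interpolation percentiles; the percentile method is a choice),
`S = R_max − R_min`, and `G_relative` is the ratio of low/high contrast
gain ratios between light-on and light-off. `R_offset` normalizes the
light-induced baseline shift by the **light-off** range — the formula's
condition subscripts are a convention, and the control dynamic range is
the natural normalizer; the reference range is an explicit argument.

G_relative is invariant to common rescaling of the four S values, and on
LN populations where light multiplies gain equally at both contrasts the
median G_relative stays at 1 while the within-contrast gain ratios move
with the light effect — the dissociation the statistic is designed to
expose, tested end-to-end on 50-unit populations.

Population tests are standard procedures (Wilcoxon signed-rank, paired t,
Kruskal–Wallis) from scipy.stats, two-sided except where the hypothesis is
directional: photo-tagging requires a significant *increase* under light,
so a one-sided paired t-test is used, combined with a strict spike-width
criterion (< 0.25 ms).

## Whole-cell analysis

Units: voltages mV, currents pA, resistances MΩ, conductances nS, time
constants ms; `mV = pA × MΩ / 1000` and `G(nS) = 1000 / R(MΩ)`.

**Up states** are detected by threshold crossing at the mean V_m computed
across all sweeps (the midpoint of a bimodal up/down distribution), with a
minimum dwell of 50 ms so EPSPs and noise excursions do not count. An
optional precondition checks bimodality first, using Sarle's bimodality
coefficient (> 5/9), since the mean-threshold rule is meaningless for
unimodal data; a dedicated dip statistic would serve the same purpose but
the coefficient is adequate for plateau-shaped up states. Sweeps (or pulse
cycles) containing up states are excluded from pulse averaging.

**Access-resistance model.** The response to injected current is the sum
of a fast electrode component (R_access, τ_access ≲ 1 ms) and a slow
membrane component (R_input, τ_input ≈ tens of ms). The pulse protocol is
a 20-cycle, 20-Hz, 40-pA square train; at 20 Hz the 25-ms half-period is
comparable to τ_input, so cycle-folded mean responses are in periodic
steady state and the single-step form `R(1 − e^(−t/τ))` misattributes
amplitude. The fit therefore evaluates the same two-component model in its
periodic steady-state solution for the square-wave history (closed form
per component), plus a free offset absorbing the baseline convention of
the folded average. Estimation is a coarse grid over (τ_access, τ_input) —
each grid point needs only a linear solve for the two resistances — with
the MSE surface retained as a diagnostic, followed by bounded nonlinear
least-squares refinement of all four parameters. A boundary grid minimum
is flagged. Model times are evaluated at `(n+1)·dt` to match zero-order-
hold acquisition; on noiseless simulated sweeps all four parameters are
recovered to well within 5%.

**Compensation** subtracts `R_access × I(t)` low-passed with τ_access
(first-order filter, the electrode model) from every sweep using the full
per-trial current waveform, so pulse transitions and stimulus-epoch
holding currents are both handled. Validation follows the spike-threshold
criterion: spike threshold should not depend on injected current, so the
slope of mean spike threshold vs I_inj (mV/pA → MΩ) measures residual
uncompensated R_access; on simulated cells compensation reduces it by over
90%.

**Spike detection** uses a threshold of mean + 7 SD of the subthreshold
trace. The mean and SD are computed after despiking: a 3-ms median filter
tracks the subthreshold baseline, samples deviating from it by more than 5
robust SDs are replaced by the baseline, and the plain mean/SD of the
cleaned trace are used. This removes spike-waveform inflation of the
threshold without attenuating genuine subthreshold variability. Crossings
within 2 ms are merged. The spike threshold (voltage at spike onset) is
the maximum of the second derivative of a lightly smoothed (0.2-ms
Gaussian) trace within 1 ms before the crossing; a window with no positive
curvature (e.g. a pure exponential rise) is flagged as degenerate.

**Conductance estimation.** At each timepoint, ordinary least squares of
V_m on I_inj across all trials (pooling repetitions at each current level
rather than using level means — all data contribute) gives a slope
R_input(t) and offset; `G(t) = 1000/R(t)` nS. Reconstruction r² predicts
every trial's V_m from (slope, offset, I) over all trials and timepoints.
Because the membrane integrates with τ_eff = C/g_tot, the per-timepoint
estimate tracks conductance changes with that time constant: step changes
are recovered quantitatively once the plateau exceeds a few τ_eff, and
single-timepoint estimates carry trial-noise jitter of order
`noise_SD / (SD(I)·√n_trials)`; recovery is therefore assessed on
quasi-steady plateau averages.

**PSP metrics.** Amplitude is the peak of the trial-mean V_m in a 5–100 ms
post-onset window minus the mean of the 50 ms before onset;
`amplitude_sd` is the SD of per-trial (peak − baseline); `sigma_vm` is the
across-trial SD of V_m averaged over time. **Power law:**
`rate = k_c (V_m − V_rest)₊^p` fitted jointly over both contrast
conditions by bounded nonlinear least squares with a shared exponent p and
per-condition gains; V̄_m/rate pairs are formed per 25-ms frame averaged
across trials (the binning is a choice). The gain change is k_high/k_low.

## Synthetic data: what it emulates, what it does not

The LN simulator produces per-chord responses
`rate = bias + light_offset·light + gain·f(kf ⊗ kh * levels) + noise`,
floored at zero, with gain determined by the stimulus contrast condition
(`gain_low = 2, gain_high = 1` by default encodes contrast gain control:
the level-SD doubling from low to high contrast is met by a gain halving)
and multiplied by `light_gain_factor` under light. The nonlinearity is
half-wave rectified linear by default ('logistic' available); a 'linear'
option exists because exactness tests (prediction CC = 1 at zero noise)
require the simulated response to lie in the fitted model class. Random
units (`make_ln_params`) have Gaussian frequency bumps (width 1–2.5 bins)
and a decaying history kernel peaking at one 25-ms lag, scaled so the
drive has roughly unit SD at low contrast — rates stay far from the zero
floor at the default bias of 10.

The whole-cell simulator integrates a single passive compartment
(exponential Euler, default 20 kHz, exact for piecewise-constant inputs
and unconditionally stable) with conductance drive toward a 0-mV reversal,
and adds: the electrode component (first-order filter of I·R_access —
exactly the model the compensation inverts), rectangular up-state
plateaus with jittered amplitude (Poisson event times), stereotyped
inserted spike waveforms on threshold crossing (spikes are treated only as
events to detect, not biophysically), and white trial noise. Defaults:
R_input 100 MΩ, τ_input 20 ms, R_access 20 MΩ, τ_access 0.5 ms, E_rest
−60 mV, current levels (−80, −40, 0, +40) pA.

Passing recovery tests on these fixtures shows the estimators are correct
for data obeying their assumptions. Real recordings additionally contain
correlated (non-white) noise, electrode drift and nonlinear electrode
behavior, conductance-dependent driving-force changes, active dendritic
events, and spike-rate nonstationarity — none of which the generators
emulate, so test performance bounds, rather than predicts, real-data
performance.

## Problem sizes and orchestration

The extracellular pipeline follows the recording protocol: per contrast,
4 DRC sequences × 3 presentations × 40 s = 480 s per condition, per light
state; STRFs are fitted on light-off data with the final 10% of each
sequence held out. The intracellular pipeline uses 11 alternating 1-s
segments (first excluded → 5 analyzed per contrast) with a frozen 50-ms
burst 500 ms into each, at 4 current levels × 3 trials by default. The
population recovery checks use 50–100 seeded units/cells; these sizes make
the full test suite and the acceptance script run in seconds while keeping
Monte-Carlo error well inside the asserted tolerances. Every pipeline
report embeds its config hash, package version, and seeds; identical
configs reproduce identical reports.

## Known limitations

- The separable (rank-1) STRF cannot represent frequency-dependent
  temporal dynamics; the full-rank model exists here only as a test
  oracle.
- The periodic-steady-state access fit assumes the pulse train has run
  long enough to forget the initial condition (the first cycles are
  skipped when folding).
- G(t) is a low-passed view of the true conductance (time constant
  τ_eff); fast synaptic transients are underestimated.
- The half-wave-rectified LN response is fitted with a linear model;
  kernel amplitudes are therefore attenuated relative to ground truth at
  strong rectification, although BF and gain *ratios* are preserved (the
  ledger is built on ratios for this reason).
- `classify_putative_pvi` refuses fewer than 3 trial pairs rather than
  returning an unstable test result.
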