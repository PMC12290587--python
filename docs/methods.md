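# Methods

## Estimators

All estimators operate on 1-D sequences of instantaneous phases in radians;
angles are wrapped to (−π, π] on entry, and circular differences are wrapped
before any squaring or sign operation.

**Circular mean direction.** μ = arg Σ e^{iα_k}; the mean resultant length
R̄ = |Σ e^{iα_k}|/n measures concentration. When R̄ falls below 1e−12 the
direction is flagged undefined and set to 0 by convention. This convention
matters for the classical circular correlation only: the estimator is still
computed (with a warning flag on the result) rather than raising, because
its behaviour on exactly such data is the package's subject matter.

**Standard circular correlation** (`ccorr_standard`) is the sine-deviation
correlation ρ_c = Σ sin(α−μ) sin(β−ν) / √(Σ sin²(α−μ) Σ sin²(β−ν)). It
assumes well-defined mean directions. Zero sine deviation in either margin
(all angles identical) raises a degenerate-input error.

**Adjusted circular correlation** (`ccorr_adjusted`) replaces the numerator
by (R_{α−β} − R_{α+β})/2 with R_{α±β} = |Σ e^{i(α±β)}|, the form appropriate
for marginals with arbitrary or undefined mean directions. The denominator
keeps the sine-deviation normalisation computed from the sample means; for
near-uniform marginals Σ sin²(α−μ) ≈ n/2 for any μ, so this choice is
numerically immaterial, and it matches the downstream reference
implementations (pingouin's `circ_corrcc(..., correction_uniform=True)`,
against which the test suite cross-checks to 1e−12). The placement of the
factor 2 in the denominator is fixed by the requirement that a perfectly
in-phase pair with uniform marginals yield exactly +1 (then R_{α−β} = n,
R_{α+β} = 0, and each sine sum is n/2). An alternative normalisation that
chooses association-maximising means instead of sample means exists in the
circular-statistics literature; it is not implemented, because the sample
mean variant is what the field's toolboxes compute.

**Temporal PLV** is |n^{-1} Σ e^{i(α_k−β_k)}| within one epoch — the
resultant length of the phase differences. Intertrial PLV is out of scope.

**Hodges–Ajne test.** The statistic m is the minimum over all half-planes
of the number of observations strictly inside. The count as a function of
the half-plane boundary direction is piecewise constant, changing only when
the boundary crosses a data angle or its antipode; the implementation
evaluates the count at the midpoints between consecutive such events via a
sorted-angle sweep, which is exact (a fixed-grid scan, used as the test
oracle, can miss narrow minimising arcs). P-values use the exact formula
2^{1−n}(n−2m)C(n,m) for n ≤ 50 and the large-sample approximation
A = π√n/(2(n−2m)), p = √(2π)/A · exp(−π²/(8A²)) otherwise. Both formulas
degenerate for perfectly balanced data (m = n/2); p is then set to 1, which
keeps p ∈ (0, 1] and makes evenly spaced samples a clean failure to reject.

## Signal pipeline

Band-pass filtering uses a two-pass (forward–backward, hence zero-phase)
4th-order Butterworth design — `scipy.signal.butter(4, band)`, the same
convention as MATLAB's `butter(4, ...)`, i.e. an 8-pole band-pass — realised
as second-order sections. The transfer-function (b, a) realisation of this
narrow design has a numerical roundoff floor around 1e−5 that would mask
the true stop-band attenuation; sections keep the floor near machine
precision while being algebraically the same filter. Before filtering, the
signal is extended by 256 samples (1 s at the 256-Hz reference rate) of odd
(reflective) padding on each side, then trimmed; the padding length is a
parameter. Published pipelines rarely state their padding; this choice is
documented as this package's own, and results reported here are insensitive
to it (padding 24 vs 256 changes the simulation summaries by less than
their seed-to-seed spread).

Instantaneous phase and envelope come from the analytic signal
(`scipy.signal.hilbert`). Filtering and the Hilbert transform run once per
whole trial, and epochs are sliced from the trial-level phase series —
except in the epoch-length sweep, where phases are re-estimated per epoch
(see below). Two practical cautions, both visible in the tests: the
filter's lightly damped passband ringing decays at roughly 5 s^{-1}, so
even the centre of a 3-s tone still ripples ~2%; and FFT-based envelope
measurements of strongly attenuated tones are leakage-limited, so the
stop-band test uses a quadrature (lock-in) projection instead.

Epoch windows are half-open 0-based sample intervals [onset, onset+length).
The one-sample onset-shift iterator emits onsets 0 … T−L−1 (512 shifts for
a 3-s trial with 1-s epochs at 256 Hz) and the extension iterator lengths
L … T−1 (512 extensions), matching the reference counts.

Phase RMS error is the root mean square of the pointwise circular
difference wrapped to (−π, π]; it is symmetric, shift-invariant, and equals
π/√3 ≈ 1.814 for independent uniform phases.

## Generators

**Linear mixing model.** Each trial: a common white Gaussian source s(t)
with standard deviation `mix_std` and independent white Gaussian channel
noises with standard deviation `absnoise_std`; channel A = s + η_A,
channel B = s (optionally delayed by whole samples) + η_B. The reference
conditions are `absnoise_std = 0.2` with coupling levels
`mix_std ∈ {0, 0.4, 0.8}` (no/medium/strong), 100 trials of 3 s (20 s for
the epoch-length sweep) at fs = 256 Hz, no delay. The raw-channel Pearson
correlation is mix²/(mix² + absnoise²) (≈ 0.94 at strong coupling), which
the generator tests verify. The generators implement this model directly
with white Gaussian components; no attempt is made to match any particular
toolbox's RNG stream, since the model, not the bytes, defines the
conditions.

**Oscillation plus noise.** clean(t) = A·sin(2π·10·t + φ) with a uniform
random trial phase, plus white Gaussian noise; the noise-free component is
stored per trial so phase-estimation error can be measured exactly. "Noise
amplitude 1" is interpreted as a standard deviation of 1, making
SNR = A / noise_std; the scanned amplitudes 0.25–5 (step 0.05, 96 levels)
then span SNR 0.25–5, which brackets the observed stabilisation of phase
error around SNR ≈ 0.5.

**Bursts.** The common source of the linear-mix model multiplied by a 0/1
gate: bursts of a given duration recurring at period duration/duty_cycle,
onsets jittered uniformly within ±jitter_s (defaults 1 s, 0.5, 0.25 s —
free parameters of this package, as no reference values exist). Duty 1
reproduces the sustained simulation bit for bit; duty 0 removes the
coupling entirely.

Reproducibility: every trial draws from its own substream spawned from the
master seed (`numpy.random.SeedSequence`), so trial i is bit-identical
regardless of the number of trials requested, and all harnesses are
bit-reproducible from (config, seed).

**What the generators do not emulate:** 1/f background spectra, alpha peaks
over a broadband floor, volume conduction/leakage between channels,
non-stationarity, artifacts, or more than two channels. Passing tests
therefore demonstrate estimator properties under the stated white-noise
mixing model, not performance on real EEG.

## Experiments

**Trial-average comparison.** Per coupling level: band-pass 8–12 Hz,
Hilbert phase per trial, first 1-s epoch, both circular-correlation
variants and PLV per trial. The summary reports per-level means, the
percent surplus 100·(mean_adjusted − mean_standard)/mean_standard, and the
per-trial Pearson correlation between adjusted estimates and PLV. A caveat
the harness makes visible: at no coupling the signed per-trial standard
estimates are roughly symmetric about zero, so the surplus denominator is
near zero and the percentage is large and seed-unstable; the adjusted mean
(~0.37 for 1-s uncoupled epochs) and the correlation with PLV are the
stable summaries.

**Onset-shift / extension instability.** For each trial, both estimators
are evaluated over all 512 one-sample shifts (or extensions) and the mean
absolute consecutive change is taken per trial and method ("average
absolute change"; an RMS-of-changes variant is available behind
`use_rms=True`). The per-level ratio unadjusted/adjusted is the headline
stability factor (~10 at no coupling, ~25–30 at strong coupling in this
implementation). These sweeps are evaluated via cumulative phasor sums
(internal `_batch` module), an exact algebraic re-expression of the scalar
estimators that the tests pin to them at 1e−10.

**Epoch-length sweep.** Adjusted circular correlation and PLV on
onset-anchored epochs of 0.1–20 s (step 0.1 s) from 20-s trials, phases
re-estimated per epoch (`phase_mode="epoch"`, the default). Per-epoch
phase estimation is what produces the systematic inflation of short-epoch
estimates at every coupling level; with trial-level phases
(`phase_mode="trial"`) strongly coupled sub-second epochs instead dip
slightly below the plateau, because slicing an already-computed phase
series removes the epoch-edge phase noise that inflates short epochs. The
plateau of the fitted decay is identical either way. The trial-mean curve
against epoch length is summarised by least squares with
b1·exp(−b2·x) + b3 (x in seconds; `scipy.optimize.least_squares`,
initialised at b1 = y₀ − y_last, b2 = 0.3, b3 = y_last, b2 ≥ 0,
tolerances 1e−12). Convergence is reported honestly via a flag, and a
rank-deficient Jacobian (e.g. constant input, where b2 is unidentifiable)
sets `ill_conditioned`. The adjusted-ccorr and PLV mean curves agree
almost perfectly for epochs ≥ 0.5 s; below a few oscillation cycles the
adjusted estimator's sine-deviation denominator departs from the PLV
normalisation and the two diverge.

**SNR sweeps.** Phase error: per amplitude level, 100 trials of 3 s; both
the noisy and the clean signal are band-passed, and the RMS circular phase
difference is taken over 0.5–2.5 s of each trial (edges excluded). Relative
noise: coupling level × channel-noise std (0.1–1.0, step 0.1; 30 cells),
adjusted ccorr and PLV on the full band-passed trial; uncoupled estimates
stay flat across noise levels while coupled estimates decrease toward the
uncoupled baseline.

**Uniformity screening.** 10,000 3-s white-noise epochs (std 0.2),
band-passed 8–12 Hz, Hilbert phases, Hodges–Ajne at p < .05. Band-limited
phases wind steadily around the circle, so rejections are on the order of
0.1% or below. Epoch length, band, noise level and alpha level are
configurable; pre-computed phases can be injected for validation.

## Problem sizes and tolerances

The default test suite runs the harnesses at reduced trial counts and the
acceptance-style tests at the full reference size (100 trials, 10,000
epochs); the whole suite completes in about a minute, and
`scripts/acceptance.py` in well under two. All stochastic test thresholds
are collected in `tests/_tolerances.py`. Fixed seeds are used throughout;
the stochastic summaries move by a few percent across seeds, which the
tolerances accommodate.

## Known limitations

- The generators' white-noise model omits the real-EEG features listed
  above; conclusions about real recordings require real data.
- The percent-surplus summary is ill-conditioned at low coupling (near-zero
  denominator); prefer the per-level means.
- The adjusted estimator's denominator uses sample mean directions; the
  association-maximising variant is deliberately not implemented.
- Delays other than whole samples, more than two channels, and directed or
  lagged coupling measures (PLI and relatives) are out of scope.
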