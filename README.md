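# ibsync

Phase-based inter-brain synchronization (IBS) estimators for hyperscanning
EEG, together with the simulation experiments that characterise how those
estimators behave under the small, arbitrary analysis decisions every EEG
pipeline has to make: epoch onset, epoch length, and signal-to-noise ratio.

## The problem

Hyperscanning studies quantify the coupling between two participants'
band-limited neural signals from their instantaneous phases α, β (Hilbert
phases of the band-passed channels). The classical circular correlation

```
ρ_c(α, β) = Σ sin(α − μ) sin(β − ν) / sqrt( Σ sin²(α − μ) · Σ sin²(β − ν) )
```

relies on the sample circular mean directions μ, ν. For continuous
narrow-band signals the phase distribution within an epoch is essentially
uniform, so μ and ν are not well defined: they swing wildly when the epoch
is shifted or extended by a few samples, and ρ_c swings with them. The
adjusted circular correlation replaces the mean-dependent numerator by a
difference of resultant lengths of the phase sum and difference,

```
ρ_c_adj = (R_{α−β} − R_{α+β}) / ( 2 · sqrt( Σ sin²(α − μ) · Σ sin²(β − ν) ) ),
R_{α±β} = | Σ_k e^{i(α_k ± β_k)} |,
```

which is invariant under rotations of either input and therefore stable
against sample-level epoching decisions. The package implements both
variants, the temporal phase-locking value (PLV), the Hodges–Ajne omnibus
test of circular uniformity, the band-pass (two-pass 4th-order Butterworth)
plus Hilbert phase pipeline, seeded dual-channel signal generators, and the
experiment harnesses built on them. It is aimed at hyperscanning/EEG
methodologists who want reproducible, estimator-level control over their
IBS pipeline.

## Worked example

```python
import numpy as np
from ibsync import (MixSimConfig, simulate_linear_mix, trial_phases,
                    ccorr_standard, ccorr_adjusted, plv, exp1_trial_average)

# 100 strongly coupled 3-s dyad trials: common source (std 0.8) plus
# independent channel noise (std 0.2), fs = 256 Hz
cfg = MixSimConfig(ntrials=100, mix_std=0.8, absnoise_std=0.2, seed=42)
trials = simulate_linear_mix(cfg)
phases = trial_phases(trials)                 # band-pass 8-12 Hz + Hilbert
a, b = phases[0, 0, :256], phases[0, 1, :256]  # first 1-s epoch of trial 0
print("ccorr_standard :", round(ccorr_standard(a, b).value, 3))
print("ccorr_adjusted :", round(ccorr_adjusted(a, b).value, 3))
print("plv            :", round(plv(a, b).value, 3))

_, summary = exp1_trial_average(ntrials=100, seed=42)
print(summary[["coupling_level", "mean_standard", "mean_adjusted",
               "mean_plv", "r_adjusted_plv"]].round(3).to_string(index=False))
```

prints

```
ccorr_standard : 0.519
ccorr_adjusted : 0.859
plv            : 0.887
coupling_level  mean_standard  mean_adjusted  mean_plv  r_adjusted_plv
            no          0.091          0.382     0.397           0.998
        medium          0.351          0.743     0.758           0.998
        strong          0.536          0.880     0.891           0.992
```

Reading the table: per coupling level (common-source std 0 / 0.4 / 0.8),
the mean per-trial estimates on 1-s alpha-band epochs. The adjusted
circular correlation tracks the PLV almost perfectly (r ≥ 0.99) and sits
well above the classical estimator, whose dependence on unstable mean
directions scatters its per-trial values — at no coupling roughly
symmetrically around zero. Note the uncoupled adjusted mean of ~0.38: 1-s
epochs of 8–12 Hz signals carry only a handful of independent phase
observations, so short-epoch estimates are biased upward even without any
coupling.

## Command line

```
ibsync --seed 1 --out out/ simulate --ntrials 100 --mix-std 0.8   # trial files
ibsync --seed 1 --out out/ ibs out/trial_000.txt                  # estimators per epoch
ibsync --seed 1 --out out/ exp1            # onset-shift / extension stability
ibsync --seed 1 --out out/ exp2            # epoch-length sweep + decay fits
ibsync --seed 1 --out out/ exp3            # SNR and relative-noise sweeps
ibsync --seed 1 --out out/ uniformity      # Hodges-Ajne screening
```

Signal files are plain delimited text: a `# fs=<Hz>` header line followed by
two numeric columns (one per channel). Result CSVs keep the column orders
shown in the library docstrings (`trial, coupling_level, method,
epoch_len_s, onset, estimate` for estimate tables); every run writes a
`manifest.txt` with the seed, package version and config hash from which it
can be reproduced exactly.

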