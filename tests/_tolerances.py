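"""Centralized tolerances for the stochastic checks in the test suite.

Deterministic/algebraic checks use literal tolerances at the assertion site;
everything that depends on simulated data draws its threshold from here so
the stochastic pass criteria are auditable in one place.
"""

# term-by-term oracle agreement (pure floating-point roundoff)
ORACLE_ATOL = 1e-10

# rotation invariance of the estimators (>= 10 significant digits)
ROTATION_ATOL = 1e-10

# minimum ratio of unadjusted over adjusted instability (stability dominance)
STABILITY_DOMINANCE_FACTOR = 5.0

# adjusted-ccorr vs PLV per-trial Pearson correlation, all coupling levels
ADJ_PLV_MIN_R = 0.99

# percent-surplus reference values and half-width (percentage points)
SURPLUS_REFERENCE = {"no": 49.4, "medium": 36.6, "strong": 41.7}
SURPLUS_TOL_PP = 10.0

# onset-shift / epoch-extension instability factor references, relative tol
SHIFT_FACTOR_REFERENCE = {"no": 9.41, "strong": 29.53}
EXTENSION_FACTOR_REFERENCE = {"no": 9.70}
FACTOR_RTOL = 0.30

# exponential-decay plateau references (adjusted ccorr, 20-s trials)
PLATEAU_REFERENCE = {"strong": 0.88, "no": 0.12}
PLATEAU_ATOL = 0.05

# mean adjusted ccorr for uncoupled 1-s alpha epochs
UNCOUPLED_MEAN_ADJ = 0.30
UNCOUPLED_MEAN_ADJ_ATOL = 0.05

# Hodges-Ajne rejection fraction over band-passed noise epochs at p < .05
UNIFORMITY_MAX_REJECT = 0.01

# flatness of uncoupled estimates across noise levels (difference between
# the lowest and highest noise level)
NOISE_SWEEP_FLAT_SPREAD = 0.02
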