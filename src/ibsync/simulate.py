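"""Seeded generators for coupled dual-channel signals.

Two generative models are provided:

* a *linear mixing model*: each of the two observed channels is the sum of a
  common unobserved white Gaussian source (standard deviation ``mix_std``,
  the "coupling level") and independent white Gaussian channel noise
  (standard deviation ``absnoise_std``). The observed channels stand for one
  electrode from each of two participants, the common source for a shared
  inter-brain process.
* an *oscillation-plus-noise model*: a 10-Hz sinusoid with a random trial
  phase and amplitude ``osc_amp``, plus white Gaussian noise of standard
  deviation ``noise_amp``. The noise-free oscillation is retained per trial
  so that downstream phase-estimation error can be measured exactly; the
  ratio ``osc_amp / noise_amp`` is the trial SNR.

A burst variant gates the common source of the linear-mix model with a 0/1
window train, emulating intermittent rather than sustained coupling.

Reproducibility: each trial draws from its own substream spawned from the
master seed, so trial ``i`` is bit-identical regardless of ``ntrials``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, is_dataclass

import numpy as np

from .sigproc import ContinuousSignal

__all__ = [
    "MixSimConfig",
    "OscSimConfig",
    "BurstConfig",
    "DyadTrialSet",
    "simulate_linear_mix",
    "simulate_oscillation_noise",
    "simulate_bursts",
]


@dataclass(frozen=True)
class MixSimConfig:
    """Configuration of the linear mixing generator.

    ``mix_std`` is the standard deviation of the common source (0 = no
    coupling, 0.4 = medium, 0.8 = strong in the reference conditions);
    ``absnoise_std`` the standard deviation of the per-channel noise
    (reference value 0.2). ``delay`` shifts channel B's copy of the common
    source by whole samples (0 by default).
    """

    ntrials: int = 100
    fs: float = 256.0
    duration_s: float = 3.0
    mix_std: float = 0.0
    absnoise_std: float = 0.2
    delay: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.ntrials < 1:
            raise ValueError("ntrials must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.mix_std < 0:
            raise ValueError("mix_std must be >= 0")
        if self.absnoise_std <= 0:
            raise ValueError("absnoise_std must be > 0")
        if self.delay < 0 or int(self.delay) != self.delay:
            raise ValueError("delay must be a non-negative integer")

    @property
    def nsamples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass(frozen=True)
class OscSimConfig:
    """Configuration of the oscillation-plus-noise generator."""

    ntrials: int = 100
    fs: float = 256.0
    duration_s: float = 3.0
    osc_freq: float = 10.0
    osc_amp: float = 1.0
    noise_amp: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.ntrials < 1:
            raise ValueError("ntrials must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if not self.osc_freq < self.fs / 2:
            raise ValueError("osc_freq must be below the Nyquist frequency")
        if self.osc_amp < 0 or self.noise_amp < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def nsamples(self) -> int:
        return int(round(self.fs * self.duration_s))

    @property
    def snr(self) -> float:
        return self.osc_amp / self.noise_amp if self.noise_amp > 0 else np.inf


@dataclass(frozen=True)
class BurstConfig:
    """Parameters of the 0/1 coupling gate for burst simulations.

    Bursts of ``burst_duration_s`` recur with period duration/duty_cycle;
    each onset is jittered uniformly within +-``jitter_s``.
    """

    burst_duration_s: float = 1.0
    duty_cycle: float = 0.5
    jitter_s: float = 0.25

    def __post_init__(self):
        if self.burst_duration_s <= 0:
            raise ValueError("burst_duration_s must be > 0")
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError("duty_cycle must be in [0, 1]")
        if self.jitter_s < 0:
            raise ValueError("jitter_s must be >= 0")


@dataclass
class DyadTrialSet:
    """Per-trial paired two-channel signals from one simulation run.

    ``data`` has shape (ntrials, 2, nsamples); ``clean`` (oscillation model
    only) holds the per-trial noise-free component, ``gate`` (burst model
    only) the 0/1 coupling gate.
    """

    data: np.ndarray
    fs: float
    config: object
    clean: np.ndarray | None = None
    gate: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("data must have shape (ntrials, 2, nsamples)")

    @property
    def ntrials(self) -> int:
        return self.data.shape[0]

    @property
    def nsamples(self) -> int:
        return self.data.shape[2]

    def trial(self, i: int) -> tuple[ContinuousSignal, ContinuousSignal]:
        a, b = self.data[i]
        return (ContinuousSignal(a, self.fs), ContinuousSignal(b, self.fs))

    def config_dict(self) -> dict:
        if is_dataclass(self.config) and not isinstance(self.config, type):
            return asdict(self.config)
        return dict(self.config)


def _trial_rngs(seed: int, ntrials: int) -> list[np.random.Generator]:
    # spawn() children are prefix-stable, so trial i's stream does not depend
    # on ntrials
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(ntrials)]


def simulate_linear_mix(cfg: MixSimConfig) -> DyadTrialSet:
    """Simulate coupled dual-channel trials under the linear mixing model.

    Per trial: common white Gaussian source ``s`` with std ``mix_std`` and
    independent white Gaussian noises with std ``absnoise_std``; channel A is
    ``s + noise_A``, channel B is ``s`` delayed by ``delay`` samples plus
    ``noise_B``.
    """
    n = cfg.nsamples
    data = np.empty((cfg.ntrials, 2, n))
    for i, rng in enumerate(_trial_rngs(cfg.seed, cfg.ntrials)):
        s = cfg.mix_std * rng.standard_normal(n + cfg.delay)
        na = cfg.absnoise_std * rng.standard_normal(n)
        nb = cfg.absnoise_std * rng.standard_normal(n)
        data[i, 0] = s[cfg.delay :] + na
        data[i, 1] = s[: n] + nb
    return DyadTrialSet(data=data, fs=cfg.fs, config=cfg)


def simulate_oscillation_noise(cfg: OscSimConfig) -> DyadTrialSet:
    """Simulate oscillation-plus-noise trials, keeping the clean component.

    Both channels share the same clean oscillation (random uniform trial
    phase) and receive independent noise; phase-error studies compare the
    phase of channel A against the phase of the stored clean signal.
    """
    n = cfg.nsamples
    t = np.arange(n) / cfg.fs
    data = np.empty((cfg.ntrials, 2, n))
    clean = np.empty((cfg.ntrials, n))
    for i, rng in enumerate(_trial_rngs(cfg.seed, cfg.ntrials)):
        phi = rng.uniform(-np.pi, np.pi)
        c = cfg.osc_amp * np.sin(2.0 * np.pi * cfg.osc_freq * t + phi)
        clean[i] = c
        data[i, 0] = c + cfg.noise_amp * rng.standard_normal(n)
        data[i, 1] = c + cfg.noise_amp * rng.standard_normal(n)
    return DyadTrialSet(data=data, fs=cfg.fs, config=cfg, clean=clean)


def _burst_gate(
    rng: np.random.Generator, n: int, fs: float, burst: BurstConfig
) -> np.ndarray:
    gate = np.zeros(n)
    if burst.duty_cycle == 0.0:
        return gate
    if burst.duty_cycle == 1.0:
        gate[:] = 1.0
        return gate
    dur = int(round(burst.burst_duration_s * fs))
    period = burst.burst_duration_s / burst.duty_cycle
    k = 0
    while k * period < n / fs + burst.burst_duration_s + burst.jitter_s:
        onset_s = k * period + rng.uniform(-burst.jitter_s, burst.jitter_s)
        start = int(round(onset_s * fs))
        gate[max(start, 0) : max(start + dur, 0)] = 1.0
        k += 1
    return gate


def simulate_bursts(cfg: MixSimConfig, burst: BurstConfig) -> DyadTrialSet:
    """Linear-mix simulation with the common source gated into bursts.

    The common source and channel noises are drawn exactly as in
    :func:`simulate_linear_mix` (same seed, same draws), then the common
    source is multiplied by a 0/1 burst gate before mixing; a duty cycle of
    1 therefore reproduces the sustained-coupling simulation bit for bit.
    The gates are returned as metadata.
    """
    n = cfg.nsamples
    data = np.empty((cfg.ntrials, 2, n))
    gates = np.empty((cfg.ntrials, n + cfg.delay))
    for i, rng in enumerate(_trial_rngs(cfg.seed, cfg.ntrials)):
        s = cfg.mix_std * rng.standard_normal(n + cfg.delay)
        na = cfg.absnoise_std * rng.standard_normal(n)
        nb = cfg.absnoise_std * rng.standard_normal(n)
        g = _burst_gate(rng, n + cfg.delay, cfg.fs, burst)
        gates[i] = g
        gs = s * g
        data[i, 0] = gs[cfg.delay :] + na
        data[i, 1] = gs[: n] + nb
    return DyadTrialSet(data=data, fs=cfg.fs, config=cfg, gate=gates)
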