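"""Mossy-fiber stimulation protocols and spike-train generation.

Extrinsic mossy fibers (eMFs, vestibular afferents) encode sinusoidal head
velocity as a rectified rate modulation

    rate(t) = [r_base + slope * f * k * sign * sin(2*pi*f*t)]+

with base rate 26 Hz and modulation slope 53 Hz per Hz of modulation
frequency (per-fiber depth k in (0, 1]; sign +1 for in-phase fibers, -1
for anti-phase).  UBC firing follows its exponentiated-cosine tuning curve
evaluated at the instantaneous cycle phase.  Spike trains are generated
from the rate functions by the time-rescaling method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phase_metrics import TuningCurve, circular_normal

__all__ = [
    "EMFDrive",
    "Protocol",
    "emf_rate",
    "ubc_rate",
    "time_rescaled_spikes",
    "rate_to_times",
    "sample_ubc_population",
    "train_stim_times",
]


@dataclass(frozen=True)
class EMFDrive:
    """Rate law of one extrinsic mossy fiber under sinusoidal modulation."""

    f_mod: float
    r_base: float = 26.0
    slope: float = 53.0          # Hz of modulation per Hz of f_mod
    k_mod: float = 1.0           # per-fiber depth in (0, 1]
    phase_sign: int = 1          # +1 in phase, -1 anti-phase

    def __post_init__(self) -> None:
        if self.r_base <= 0:
            raise ValueError("r_base must be > 0")
        if not 0.0 < self.k_mod <= 1.0:
            raise ValueError("k_mod must lie in (0, 1]")
        if self.phase_sign not in (-1, 1):
            raise ValueError("phase_sign must be +1 or -1")


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol: steady firing followed by sinusoidal modulation."""

    f_mod: float = 1.0
    steady_duration_s: float = 10.0
    modulated_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.steady_duration_s <= 0 or self.modulated_duration_s <= 0:
            raise ValueError("durations must be > 0")

    @property
    def total_ms(self) -> float:
        return 1000.0 * (self.steady_duration_s + self.modulated_duration_s)

    @property
    def steady_ms(self) -> float:
        return 1000.0 * self.steady_duration_s


def emf_rate(t_ms, drive: EMFDrive):
    """Rectified sinusoidal eMF firing rate (Hz) at time(s) t (ms).

    The modulation onset is at t = 0; negative excursions are clipped.
    """
    t = np.asarray(t_ms, dtype=float)
    amp = drive.slope * drive.f_mod * drive.k_mod * drive.phase_sign
    return np.maximum(0.0, drive.r_base +
                      amp * np.sin(2.0 * np.pi * drive.f_mod * t / 1000.0))


def ubc_rate(t_ms, curve: TuningCurve, f_mod: float):
    """UBC firing rate (Hz): the tuning curve at the instantaneous phase."""
    t = np.asarray(t_ms, dtype=float)
    return circular_normal(np.mod(360.0 * f_mod * t / 1000.0, 360.0), curve)


def time_rescaled_spikes(rate_fn, duration_ms: float, rng,
                         dt: float = 0.1) -> np.ndarray:
    """Inhomogeneous-Poisson spike train by time rescaling.

    ``rate_fn`` maps a time array (ms) to rates (Hz).  Unit-rate
    exponential interarrivals are mapped back through the inverse of the
    cumulative intensity, evaluated on a grid of step ``dt``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    t = np.arange(0.0, duration_ms + dt, dt)
    rate = np.asarray(rate_fn(t), dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate function must be nonnegative")
    lam = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt / 1000.0)])
    total = lam[-1]
    n_exp = rng.poisson(total)
    targets = np.sort(rng.uniform(0.0, total, size=n_exp))
    return np.interp(targets, lam, t)


def rate_to_times(rate_fn, duration_ms: float, dt: float = 0.1,
                  phase_offset: float = 0.5) -> np.ndarray:
    """Deterministic stimulation times whose density follows the rate law.

    Emits a pulse each time the cumulative intensity crosses an integer
    (offset by ``phase_offset``), emulating a programmed slice stimulator.
    """
    t = np.arange(0.0, duration_ms + dt, dt)
    rate = np.asarray(rate_fn(t), dtype=float)
    lam = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt / 1000.0)])
    targets = np.arange(phase_offset, lam[-1], 1.0)
    return np.interp(targets, lam, t)


def train_stim_times(n_stim: int = 25, freq_hz: float = 50.0,
                     t0_ms: float = 0.0) -> np.ndarray:
    """Regular stimulation train (default 500 ms at 50 Hz)."""
    return t0_ms + np.arange(n_stim) * 1000.0 / freq_hz


def sample_ubc_population(pool, n: int, rng):
    """Sample n UBC tuning curves from a recorded-cell pool with replacement;
    a random half of the sample is phase-reversed (+180°), mirroring the
    in-phase/anti-phase split of the vestibular afferents.

    Returns (curves, reversed_flags).
    """
    if len(pool) == 0:
        raise ValueError("pool must be nonempty")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, len(pool), size=n)
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[: n // 2]] = True
    curves = []
    for i, rev in zip(idx, flags):
        c = pool[int(i)]
        if rev and np.isfinite(c.phi):
            c = c.reversed()
        curves.append(c)
    return curves, flags
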