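"""AMPAR Markov-scheme kinetics at the mossy-fiber → UBC giant synapse.

The core model is a four-state chain

    C  <->  O2  <->  O1  <->  D
       a2*x      a1*x      aD
       b2        b1        bD

with two open states (O1, O2), ligand-dependent forward rates, and a
desensitized state D entered from O1.  Because desensitization competes with
the open states at high glutamate, the steady-state open fraction is
bell-shaped in concentration: it peaks at intermediate glutamate (~25 µM
with the default constants) and relaxes to a small plateau at saturation.
That non-monotonicity is what lets slowly accumulating cleft glutamate
invert the sign of the receptor's response to rate modulation.

A three-state comparison scheme C <-> O <-> D with matched affinity and
saturating open fraction — but a monotone steady-state curve — is provided
to isolate the functional role of the bell shape.

Units: ms, µM throughout.  Occupancies are dimensionless fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from ._kernels import (
    glut_from_rate,
    glut_from_spikes,
    integrate_four_state,
    integrate_three_state,
)

__all__ = [
    "RateConstants",
    "ThreeStateRates",
    "StateOccupancy",
    "GlutamatePulse",
    "ConcentrationTrace",
    "FrequencyResponse",
    "default_rate_constants",
    "calibrate_recovery_rate",
    "steady_state",
    "dose_response",
    "integrate_states",
    "glutamate_trace",
    "frequency_response",
    "make_three_state_model",
]


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the four-state chain.

    alpha2, alpha1: ligand binding rates C->O2 and O2->O1 (per µM per ms);
    beta2, beta1: the corresponding unbinding rates (per ms);
    alphaD, betaD: desensitization on/off rates O1<->D (per ms).
    """

    alpha1: float = 0.03
    alpha2: float = 0.15
    alphaD: float = 2.0
    betaD: float = 0.05128205128205128
    beta1: float = 10.0
    beta2: float = 10.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alphaD", "betaD", "beta1", "beta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate constant {name} must be strictly positive")

    @property
    def f_sat(self) -> float:
        """Saturating (x -> inf) steady-state open fraction, betaD/(alphaD+betaD)."""
        return self.betaD / (self.alphaD + self.betaD)


@dataclass(frozen=True)
class ThreeStateRates:
    """Rate constants of the monotone comparison scheme C <-> O <-> D."""

    alpha: float
    beta: float
    alphaD: float
    betaD: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "alphaD", "betaD"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate constant {name} must be strictly positive")

    @property
    def f_sat(self) -> float:
        return self.betaD / (self.alphaD + self.betaD)


@dataclass(frozen=True)
class StateOccupancy:
    """Fractional occupancies (c, r2, r1, d); must sum to one."""

    c: float
    r2: float
    r1: float
    d: float

    def __post_init__(self) -> None:
        for name in ("c", "r2", "r1", "d"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"occupancy {name}={v} outside [0, 1]")
        if abs(self.c + self.r2 + self.r1 + self.d - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1 within 1e-9")

    @property
    def open_fraction(self) -> float:
        return self.r1 + self.r2

    @classmethod
    def rest(cls) -> "StateOccupancy":
        return cls(c=1.0, r2=0.0, r1=0.0, d=0.0)


@dataclass(frozen=True)
class GlutamatePulse:
    """Per-spike glutamate transient parameters.

    s: concentration step per spike (µM), injected into the rise variable
    (or directly into x when tau_rise == 0); tau_rise / tau_decay in ms;
    u: saturation constant (µM) of the concentration-dependent clearance
    tau_decay*(1 + x/u).
    """

    s: float
    tau_rise: float
    tau_decay: float
    u: float = 30.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("s must be > 0")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be > 0")
        if self.tau_rise < 0:
            raise ValueError("tau_rise must be >= 0")
        if self.u <= 0:
            raise ValueError("u must be > 0")

    def peak_amplitude(self) -> float:
        """Peak concentration reached by a single-spike transient (linear decay).

        With tau_rise == 0 this is simply s; otherwise the rise->decay
        cascade attenuates the step.
        """
        if self.tau_rise == 0:
            return self.s
        tr, td = self.tau_rise, self.tau_decay
        if abs(tr - td) < 1e-12:
            return self.s * np.exp(-1.0)
        t_pk = np.log(td / tr) / (1.0 / tr - 1.0 / td)
        return self.s * tr / (td - tr) * (np.exp(-t_pk / td) - np.exp(-t_pk / tr))

    def with_peak(self, peak: float) -> "GlutamatePulse":
        """Rescale the step so the single-spike transient peaks at ``peak`` µM."""
        return replace(self, s=self.s * peak / self.peak_amplitude())


@dataclass
class ConcentrationTrace:
    """Glutamate concentration (µM) on a uniform ms grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have identical shape")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("time grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentrations must be finite")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be nonnegative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class FrequencyResponse:
    """Peak-to-peak modulation amplitudes and phases across drive frequencies.

    Phases are in degrees relative to the mossy-fiber rate modulation
    (which peaks at 90° of the cycle), wrapped to [0, 360).
    """

    frequencies: np.ndarray
    glut_amplitude: np.ndarray     # µM, peak to peak
    act_amplitude: np.ndarray      # open fraction, peak to peak
    glut_phase: np.ndarray         # degrees
    act_phase: np.ndarray          # degrees

    @property
    def phase_shift(self) -> np.ndarray:
        """Activation phase minus glutamate phase, wrapped to [0, 360)."""
        return np.mod(self.act_phase - self.glut_phase, 360.0)


def calibrate_recovery_rate(alphaD: float, f_sat: float) -> float:
    """Recovery rate betaD giving a steady open fraction f_sat at saturating
    glutamate: betaD = alphaD * f_sat / (1 - f_sat)."""
    if not 0.0 < f_sat < 1.0:
        raise ValueError("f_sat must lie strictly in (0, 1)")
    if alphaD <= 0:
        raise ValueError("alphaD must be > 0")
    return alphaD * f_sat / (1.0 - f_sat)


def default_rate_constants(f_sat: float = 0.025) -> RateConstants:
    """The reference four-state constants with betaD calibrated to ``f_sat``."""
    base = RateConstants()
    return replace(base, betaD=calibrate_recovery_rate(base.alphaD, f_sat))


def steady_state(rates, x: float):
    """Exact steady state at constant glutamate x (µM).

    The scheme is a chain, so detailed balance gives the occupancy ratios in
    closed form.  Returns a StateOccupancy (four-state) or an (o, d, c)
    tuple-like occupancy for the three-state scheme.
    """
    if x < 0:
        raise ValueError("glutamate concentration must be nonnegative")
    if isinstance(rates, ThreeStateRates):
        w_o = rates.alpha * x / rates.beta
        w_d = w_o * rates.alphaD / rates.betaD
        z = 1.0 + w_o + w_d
        return np.array([1.0 / z, w_o / z, w_d / z])  # (c, o, d)
    w2 = rates.alpha2 * x / rates.beta2
    w1 = w2 * rates.alpha1 * x / rates.beta1
    wd = w1 * rates.alphaD / rates.betaD
    z = 1.0 + w2 + w1 + wd
    return StateOccupancy(c=1.0 / z, r2=w2 / z, r1=w1 / z, d=wd / z)


def steady_open_fraction(rates, x) -> np.ndarray:
    """Vectorized steady-state open fraction over a concentration array."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("glutamate concentration must be nonnegative")
    if isinstance(rates, ThreeStateRates):
        w_o = rates.alpha * x / rates.beta
        return w_o / (1.0 + w_o * (1.0 + rates.alphaD / rates.betaD))
    w2 = rates.alpha2 * x / rates.beta2
    w1 = w2 * rates.alpha1 * x / rates.beta1
    wd = w1 * rates.alphaD / rates.betaD
    return (w1 + w2) / (1.0 + w2 + w1 + wd)


def integrate_states(rates, glut: ConcentrationTrace, initial=None,
                     dt: float | None = None) -> np.ndarray:
    """Integrate the state occupancies along a glutamate trace.

    Returns an (n, 4) array of (c, r2, r1, d) for the four-state scheme, or
    (n, 3) of (c, o, d) for the three-state scheme, on the trace's grid.
    """
    if not np.all(np.isfinite(glut.values)):
        raise ValueError("glutamate trace contains non-finite values")
    step = glut.dt if len(glut.times) > 1 else (dt or 0.02)
    if dt is not None and dt > step * (1 + 1e-9):
        raise ValueError("dt must not exceed the glutamate grid step")
    x_max = float(glut.values.max(initial=0.0))
    if isinstance(rates, ThreeStateRates):
        lam = rates.alpha * x_max + rates.beta + rates.alphaD + rates.betaD
        n_sub = max(1, int(np.ceil(step * lam / 1.5)))
        o0, d0 = (0.0, 0.0) if initial is None else (initial[1], initial[2])
        od = integrate_three_state(glut.values, step, rates.alpha, rates.beta,
                                   rates.alphaD, rates.betaD, o0, d0, n_sub)
        c = 1.0 - od.sum(axis=1)
        return np.column_stack([c, od])
    init = initial or StateOccupancy.rest()
    lam = ((rates.alpha1 + rates.alpha2) * x_max
           + rates.beta1 + rates.beta2 + rates.alphaD + rates.betaD)
    n_sub = max(1, int(np.ceil(step * lam / 1.5)))
    r2r1d = integrate_four_state(
        glut.values, step,
        rates.alpha1, rates.alpha2, rates.alphaD, rates.betaD,
        rates.beta1, rates.beta2, init.r2, init.r1, init.d, n_sub)
    c = 1.0 - r2r1d.sum(axis=1)
    return np.column_stack([c, r2r1d])


def open_fraction(occ: np.ndarray) -> np.ndarray:
    """Open fraction of an occupancy time series from integrate_states."""
    if occ.shape[1] == 4:        # (c, r2, r1, d)
        return occ[:, 1] + occ[:, 2]
    return occ[:, 1]             # (c, o, d)


def dose_response(rates, grid, dt: float = 0.02, t_max: float = 500.0):
    """Peak and steady-state open-fraction curves over a concentration grid.

    The steady curve is analytic; the peak curve is the maximum open
    fraction over time after a concentration step from rest.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("concentration grid must be nonempty")
    if np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be nonnegative and sorted")
    steady = steady_open_fraction(rates, grid)
    n = int(t_max / dt) + 1
    peak = np.empty_like(grid)
    for i, x in enumerate(grid):
        trace = ConcentrationTrace(np.arange(n) * dt, np.full(n, x))
        occ = integrate_states(rates, trace)
        peak[i] = open_fraction(occ).max()
    return peak, steady


def glutamate_trace(spike_times, pulse: GlutamatePulse, duration: float,
                    dt: float = 0.02, saturating_decay: bool = True) -> ConcentrationTrace:
    """Cleft glutamate concentration driven by a presynaptic spike train."""
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if spike_times.size and (spike_times[0] < 0 or spike_times[-1] > duration):
        raise ValueError("spike times must lie within [0, duration]")
    n = int(round(duration / dt)) + 1
    steps = np.round(spike_times / dt).astype(np.int64)
    if steps.size > 1 and np.any(np.diff(steps) == 0):
        warnings.warn("duplicate spike times within dt merged into single steps")
    x = glut_from_spikes(steps, n, dt, pulse.s, pulse.tau_rise,
                         pulse.tau_decay, pulse.u, saturating_decay)
    return ConcentrationTrace(np.arange(n) * dt, x)


def _fit_sinusoid(t_ms: np.ndarray, y: np.ndarray, f_hz: float):
    """Least-squares fit y ~ m + a*sin(wt) + b*cos(wt).

    Returns (peak_to_peak, phase_deg) where phase is the cycle phase (drive
    peaks at 90°) at which the fitted sinusoid is maximal.
    """
    w = 2.0 * np.pi * f_hz * t_ms / 1000.0
    A = np.column_stack([np.ones_like(t_ms), np.sin(w), np.cos(w)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    amp = np.hypot(coef[1], coef[2])
    if amp < 1e-14:
        return 0.0, np.nan
    # y = amp*sin(wt + phi0), phi0 = atan2(b, a); maximum where wt = 90° - phi0
    phi0 = np.degrees(np.arctan2(coef[2], coef[1]))
    return 2.0 * amp, float(np.mod(90.0 - phi0, 360.0))


def frequency_response(rates, f_grid,
                       peak_per_spike: float = 2.0,
                       tau_rise: float = 15.0,
                       tau_decay: float = 600.0,
                       r_base: float = 26.0,
                       slope: float = 53.0,
                       k_mod: float = 1.0,
                       dt: float = 0.05,
                       discard_cycles: int = 5,
                       fit_cycles: int = 3) -> FrequencyResponse:
    """Frequency response of fractional activation under sinusoidal rate drive.

    The mossy-fiber rate [r_base + slope*f*k_mod*sin(2*pi*f*t)]+ drives
    glutamate deterministically (continuous source rate(t)*s, mono-
    exponential decay); per-spike transients peak at ``peak_per_spike`` µM
    with the given rise/decay times.  For each frequency the first
    ``discard_cycles`` cycles are discarded and sinusoids are fitted to the
    glutamate and open-fraction traces of the remaining cycles.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    pulse = GlutamatePulse(s=1.0, tau_rise=tau_rise, tau_decay=tau_decay)
    s_step = pulse.with_peak(peak_per_spike).s
    n_f = f_grid.size
    ga = np.zeros(n_f)
    aa = np.zeros(n_f)
    gp = np.full(n_f, np.nan)
    ap = np.full(n_f, np.nan)
    for i, f in enumerate(f_grid):
        period = 1000.0 / f
        # settle the mean level first (glutamate decay ~600 ms), then cycles
        t_settle = max(5000.0, 3.0 * tau_decay)
        duration = t_settle + (discard_cycles + fit_cycles) * period
        n = int(duration / dt) + 1
        t = np.arange(n) * dt
        rate = np.maximum(
            0.0, r_base + slope * f * k_mod * np.sin(2 * np.pi * f * (t - t_settle) / 1000.0))
        rate[t < t_settle] = r_base
        x = glut_from_rate(rate / 1000.0, dt, s_step, tau_rise, tau_decay, 30.0, False)
        trace = ConcentrationTrace(t, x)
        occ = integrate_states(rates, trace)
        act = open_fraction(occ)
        sel = t >= t_settle + discard_cycles * period
        tf = t[sel] - t_settle
        ga[i], gp[i] = _fit_sinusoid(tf, x[sel], f)
        aa[i], ap[i] = _fit_sinusoid(tf, act[sel], f)
    return FrequencyResponse(f_grid, ga, aa, gp, ap)


def make_three_state_model(reference: RateConstants) -> ThreeStateRates:
    """Monotone C<->O<->D scheme matched to the four-state reference.

    The saturating open fraction equals the reference's, and the
    concentration at which the open fraction reaches half of saturation
    matches the reference's rising-limb half-activation point.
    """
    f_sat = reference.f_sat
    target = 0.5 * f_sat

    def rising(x):
        return steady_open_fraction(reference, x) - target

    # the reference curve rises through target well below its bell peak
    x_half = brentq(rising, 1e-9, 10.0)
    ratio_d = reference.alphaD / reference.betaD       # = (1 - f_sat) / f_sat
    # half activation of kx/(1 + (1+ratio_d) k x) at (1+ratio_d) k x = 1
    k = 1.0 / ((1.0 + ratio_d) * x_half)
    beta = reference.beta1
    return ThreeStateRates(alpha=k * beta, beta=beta,
                           alphaD=reference.alphaD, betaD=reference.betaD)
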