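"""Three-pool composite EPSC simulation and trace fitting.

The compound AMPAR current at the giant mossy-fiber → UBC synapse is
modelled as the sum of three receptor pools facing different glutamate
transients:

* ``close``   — receptors facing a release site: large, instantaneous-rise,
  fast-decaying transients → the fast EPSC;
* ``intermediate`` — large, slow transients at the centre of the synaptic
  area → steady current and rebound onset;
* ``far``     — small, slowly rising transients at the periphery → the
  slow build-up and the associated offset rebound.

All pools share one set of receptor rate constants; each pool has its own
conductance g and glutamate parameters (s, tau_rise, tau_decay).  The total
current is I = Σ g_pool · (r1+r2)_pool · V_hold (nS·mV = pA, inward
negative at V_hold = −60 mV).  The 11 free parameters (g, s, tau_decay per
pool plus tau_rise for intermediate/far) are fitted to 50 Hz train
responses by bounded multi-start least squares in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .receptor_kinetics import (
    ConcentrationTrace,
    GlutamatePulse,
    RateConstants,
    default_rate_constants,
    glutamate_trace,
    integrate_states,
    open_fraction,
)
from .phase_metrics import TuningCurve, fit_tuning_binned

__all__ = [
    "PoolModel",
    "CompositeEPSCModel",
    "CurrentTrace",
    "FitOptions",
    "FitResult",
    "simulate_epsc",
    "fit_epsc",
    "predict_modulated_epsc",
    "phase_binned_current",
    "if_readout",
    "phase_histogram_correlation",
    "default_pools",
]

POOL_CLASSES = ("close", "intermediate", "far")


@dataclass(frozen=True)
class PoolModel:
    """One receptor pool: conductance (nS) and its glutamate transient."""

    pool_class: str
    g: float
    pulse: GlutamatePulse

    def __post_init__(self) -> None:
        if self.pool_class not in POOL_CLASSES:
            raise ValueError(f"unknown pool class {self.pool_class!r}")
        if self.g < 0:
            raise ValueError("conductance must be nonnegative")
        if self.pool_class == "close" and self.pulse.tau_rise != 0:
            raise ValueError("close pools have instantaneous rise (tau_rise = 0)")


def pool_from_peak(pool_class: str, g: float, peak: float,
                   tau_rise: float, tau_decay: float) -> PoolModel:
    """Build a pool whose single-spike glutamate transient peaks at ``peak`` µM."""
    pulse = GlutamatePulse(s=1.0, tau_rise=tau_rise, tau_decay=tau_decay)
    return PoolModel(pool_class, g, pulse.with_peak(peak))


def default_pools(g_close: float = 0.5, g_int: float = 1.0,
                  g_far: float = 1.0) -> dict:
    """The canonical pool geometry: glutamate (s µM, tau_rise, tau_decay ms)
    = far (4, 20, 250), intermediate (500, 1, 250), close (500, 0, 1.5).

    At 50 Hz the intermediate pool's mean glutamate (s*rate*tau_rise
    ≈ 25 µM) sits at the bell peak of the steady-state curve, so its
    clearance after the train drives the offset rebound; the far pool's
    slow low-amplitude transient builds up over the train.
    """
    return {
        "close": PoolModel("close", g_close, GlutamatePulse(500.0, 0.0, 1.5)),
        "intermediate": PoolModel("intermediate", g_int,
                                  GlutamatePulse(500.0, 1.0, 250.0)),
        "far": PoolModel("far", g_far, GlutamatePulse(4.0, 20.0, 250.0)),
    }


@dataclass(frozen=True)
class CompositeEPSCModel:
    """Three receptor pools sharing rate constants, at a holding potential."""

    pools: dict
    rates: RateConstants = field(default_factory=default_rate_constants)
    v_hold: float = -60.0

    def __post_init__(self) -> None:
        if set(self.pools) != set(POOL_CLASSES):
            raise ValueError("need exactly one pool of each class")


@dataclass
class CurrentTrace:
    """Current (pA) on a uniform ms grid with stimulation annotations."""

    times: np.ndarray
    current: np.ndarray
    stim_times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.times.shape != self.current.shape:
            raise ValueError("times and current must have identical shape")
        if self.stim_times.size and (
                self.stim_times.min() < self.times[0] - 1e-9
                or self.stim_times.max() > self.times[-1] + 1e-9):
            raise ValueError("stim_times must lie within the trace span")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def simulate_epsc(model: CompositeEPSCModel, stim_times, duration_ms: float,
                  dt: float = 0.05, t0_ms: float = 0.0,
                  saturating_decay: bool = True) -> CurrentTrace:
    """Simulate the composite AMPAR current for a stimulation pattern.

    The trace spans [t0_ms, duration_ms]; stimulation times are absolute.
    """
    stim = np.asarray(stim_times, dtype=float)
    span = duration_ms - t0_ms
    n = int(round(span / dt)) + 1
    current = np.zeros(n)
    for pool in model.pools.values():
        glut = glutamate_trace(stim - t0_ms, pool.pulse, span, dt,
                               saturating_decay=saturating_decay)
        occ = integrate_states(model.rates, glut)
        current += pool.g * open_fraction(occ) * model.v_hold
    return CurrentTrace(t0_ms + np.arange(n) * dt, current, stim)


@dataclass
class FitOptions:
    """Multi-start bounded least-squares configuration for fit_epsc."""

    n_restarts: int = 16
    seed: int = 0
    fit_dt: float = 0.1           # simulation step used inside the fit
    pre_ms: float = 50.0          # baseline span before the first stimulus
    post_ms: float = 1500.0       # span after the last stimulus (rebound)
    perturb_sd: float = 0.7       # log-space restart jitter
    s_bounds: tuple = (0.1, 2000.0)
    tau_decay_bounds: tuple = (0.5, 2000.0)
    tau_rise_bounds: tuple = (0.1, 200.0)
    g_bounds: tuple = (1e-4, 50.0)
    max_nfev: int = 60


@dataclass
class FitResult:
    """Outcome of the 11-parameter composite fit."""

    model: CompositeEPSCModel
    residual_sd: float
    converged: bool
    n_restarts_used: int
    cost: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.residual_sd) and self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")


def _pack(model: CompositeEPSCModel) -> np.ndarray:
    p = []
    for cls in POOL_CLASSES:
        pool = model.pools[cls]
        p += [pool.g, pool.pulse.s, pool.pulse.tau_decay]
        if cls != "close":
            p.append(pool.pulse.tau_rise)
    return np.log(np.asarray(p))


def _unpack(logp: np.ndarray, rates: RateConstants,
            v_hold: float) -> CompositeEPSCModel:
    p = np.exp(logp)
    pools = {
        "close": PoolModel("close", p[0], GlutamatePulse(p[1], 0.0, p[2])),
        "intermediate": PoolModel("intermediate", p[3],
                                  GlutamatePulse(p[4], p[6], p[5])),
        "far": PoolModel("far", p[7], GlutamatePulse(p[8], p[10], p[9])),
    }
    return CompositeEPSCModel(pools=pools, rates=rates, v_hold=v_hold)


def _log_bounds(opt: FitOptions):
    lo, hi = [], []
    for cls in POOL_CLASSES:
        lo += [opt.g_bounds[0], opt.s_bounds[0], opt.tau_decay_bounds[0]]
        hi += [opt.g_bounds[1], opt.s_bounds[1], opt.tau_decay_bounds[1]]
        if cls != "close":
            lo.append(opt.tau_rise_bounds[0])
            hi.append(opt.tau_rise_bounds[1])
    return np.log(np.asarray(lo)), np.log(np.asarray(hi))


def fit_epsc(trace: CurrentTrace, options: FitOptions | None = None,
             rates: RateConstants | None = None,
             init: CompositeEPSCModel | None = None) -> FitResult:
    """Fit the 11 free parameters of the composite model to a train EPSC.

    Receptor rate constants stay fixed; the best of ``n_restarts`` bounded
    least-squares fits (log-space parameters, restarts jittered around the
    canonical pool geometry) is returned together with the residual SD over
    the fitted span.
    """
    opt = options or FitOptions()
    rates = rates or default_rate_constants()
    if trace.stim_times.size < 2:
        raise ValueError("trace must contain a stimulation train")
    t, i_obs = trace.times, trace.current
    first, last = trace.stim_times[0], trace.stim_times[-1]
    sel = (t >= first - opt.pre_ms) & (t <= min(last + opt.post_ms, t[-1]))
    t_fit = t[sel]
    y = i_obs[sel]
    base = np.mean(y[t_fit < first]) if np.any(t_fit < first) else 0.0
    y = y - base
    v_hold = -60.0

    # fast path: simulate on a coarse grid, compare on a 0.5 ms comb
    dt_sim = opt.fit_dt
    n_sim = int(round((t_fit[-1] - t_fit[0]) / dt_sim)) + 1
    stim_steps = np.round((trace.stim_times - t_fit[0]) / dt_sim).astype(np.int64)
    t_sim = t_fit[0] + np.arange(n_sim) * dt_sim
    comb = np.arange(0, n_sim, max(int(round(0.5 / dt_sim)), 1))
    y_sub = np.interp(t_sim[comb], t_fit, y)
    from ._kernels import glut_from_spikes, integrate_four_state

    # stiffness is segment-local: the stiff (high-glutamate) span around the
    # train gets fine substeps, the long tail does not
    seg = min(int(stim_steps[-1] + round(250.0 / dt_sim)), n_sim - 1)
    a_sum = rates.alpha1 + rates.alpha2
    b_sum = rates.beta1 + rates.beta2 + rates.alphaD + rates.betaD

    def _n_sub(xmax):
        # corners with enormous buildup exceed the cap and go unstable;
        # the blow-up guard turns that into an off-scale residual
        return min(max(1, int(np.ceil(dt_sim * (a_sum * xmax + b_sum) / 1.5))), 24)

    def _current(logp):
        p = np.exp(logp)
        # (g, s, td) close; (g, s, td, tr) intermediate; (g, s, td, tr) far
        cur = np.zeros(n_sim)
        specs = ((p[0], p[1], p[2], 0.0),
                 (p[3], p[4], p[5], p[6]),
                 (p[7], p[8], p[9], p[10]))
        for g, s, td, tr in specs:
            x = glut_from_spikes(stim_steps, n_sim, dt_sim, s, tr, td,
                                 30.0, True)
            occ_a = integrate_four_state(
                x[: seg + 1], dt_sim, rates.alpha1, rates.alpha2,
                rates.alphaD, rates.betaD, rates.beta1, rates.beta2,
                0.0, 0.0, 0.0, _n_sub(x[: seg + 1].max()))
            occ_b = integrate_four_state(
                x[seg:], dt_sim, rates.alpha1, rates.alpha2,
                rates.alphaD, rates.betaD, rates.beta1, rates.beta2,
                occ_a[-1, 0], occ_a[-1, 1], occ_a[-1, 2],
                _n_sub(x[seg:].max()))
            open_frac = np.concatenate(
                [occ_a[:, 0] + occ_a[:, 1], occ_b[1:, 0] + occ_b[1:, 1]])
            cur += g * open_frac * v_hold
        return cur

    def residuals(logp):
        return _current(logp)[comb] - y_sub

    start = _pack(init) if init is not None else _pack(
        CompositeEPSCModel(pools=default_pools(), rates=rates))
    lo, hi = _log_bounds(opt)
    rng = np.random.default_rng(opt.seed)
    best = None
    n_used = 0
    for k in range(max(opt.n_restarts, 1)):
        x0 = start if k == 0 else np.clip(
            start + rng.normal(0.0, opt.perturb_sd, start.size), lo, hi)
        x0 = np.clip(x0, lo, hi)
        n_used += 1
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi),
                                max_nfev=opt.max_nfev, method="trf",
                                ftol=1e-6, xtol=1e-6, diff_step=1e-3)
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        dummy = _unpack(start, rates, v_hold)
        return FitResult(dummy, np.nan, False, n_used)
    model = _unpack(best.x, rates, v_hold)
    resid_sd = float(np.std(residuals(best.x)))
    return FitResult(model, resid_sd, True, n_used, cost=float(best.cost))


def phase_binned_current(trace: CurrentTrace, f_hz: float, n_bins: int = 20,
                         t_start_ms: float = 0.0,
                         skip_cycles: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Mean inward current magnitude (pA) per phase bin over cycles.

    Returns (bin_centers_deg, mean_inward_current); the first
    ``skip_cycles`` cycles are discarded as transient.
    """
    period = 1000.0 / f_hz
    t = trace.times - t_start_ms
    sel = t >= skip_cycles * period
    phases = np.mod(t[sel] / period, 1.0) * 360.0
    inward = -trace.current[sel]
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    idx = np.clip(np.digitize(phases, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=inward, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, sums / np.maximum(counts, 1)


def predict_modulated_epsc(fit: FitResult, stim_times, duration_ms: float,
                           f_hz: float = 1.0, dt: float = 0.05,
                           n_bins: int = 20):
    """Simulate the fitted model under modulated stimulation and extract the
    predicted phase tuning of the EPSC.

    Returns (CurrentTrace, TuningCurve, phase_shift_deg) where the shift is
    relative to the stimulation peak at 90°; NaN when the response is flat.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    trace = simulate_epsc(fit.model, stim_times, duration_ms, dt=dt)
    centers, hist = phase_binned_current(trace, f_hz)
    if hist.std() < 1e-12:
        return trace, TuningCurve(float(hist.mean()), float(hist.mean()),
                                  np.nan, 0.0), np.nan
    curve = fit_tuning_binned(centers, hist)
    shift = float(np.mod(curve.phi - 90.0 + 180.0, 360.0) - 180.0) \
        if np.isfinite(curve.phi) else np.nan
    return trace, curve, shift


def if_readout(trace: CurrentTrace, seed: int = 0, g_control: float = 1.0,
               sigma_N: float = 0.0):
    """Drive an integrate-and-fire neuron (granule-cell parameters) with the
    EPSC as injected current; returns spike times (ms)."""
    from .granular_network import simulate_gc
    duration = trace.times[-1] - trace.times[0]
    spikes, _, _ = simulate_gc([], duration_ms=duration, dt=trace.dt,
                               seed=seed, i_inject=g_control * trace.current,
                               sigma_N=sigma_N)
    return spikes + trace.times[0]


def phase_histogram_correlation(sim_hist, obs_hist):
    """Pearson correlation between a simulated inward-current phase
    histogram and an observed firing-rate phase histogram, with p-value."""
    sim = np.asarray(sim_hist, dtype=float)
    obs = np.asarray(obs_hist, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("histograms must have equal bin counts")
    if sim.std() < 1e-12 or obs.std() < 1e-12:
        return np.nan, np.nan
    r, p = stats.pearsonr(sim, obs)
    return float(r), float(p)
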