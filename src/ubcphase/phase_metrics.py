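"""Circular phase-tuning statistics and EPSC waveform decomposition.

Phase convention: one stimulation cycle spans [0°, 360°) and the sinusoidal
mossy-fiber rate modulation peaks at 90°.  Reported phase *shifts* are
relative to that stimulation peak; stored phases are absolute cycle phases.

The tuning model is the exponentiated cosine (von Mises) rate curve

    f(θ) = rmin + (rmax − rmin) · (exp[(k/2)·cos(θ−φ)] − exp(−k/2))
                                  / (exp(k/2) − exp(−k/2))

with f(φ) = rmax, f(φ+180°) = rmin, and concentration factor k ≥ 0
controlling how tightly spikes cluster around the preferred phase
(k → 0 recovers a raised cosine; large k gives burst-like tuning).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "TuningCurve",
    "PhaseSample",
    "EPSCDecomposition",
    "ReboundFit",
    "circular_normal",
    "fit_tuning",
    "fit_tuning_binned",
    "cv2",
    "phase_to_delay",
    "decompose_train_epsc",
    "isolate_rebound",
    "ks_uniform",
]


@dataclass(frozen=True)
class TuningCurve:
    """Exponentiated-cosine phase tuning: baseline rmin, peak rmax (Hz),
    preferred phase phi (degrees in [0, 360); NaN when undefined), and
    concentration factor k >= 0."""

    rmin: float
    rmax: float
    phi: float
    k: float

    def __post_init__(self) -> None:
        if not (self.rmax >= self.rmin >= 0.0):
            raise ValueError("require rmax >= rmin >= 0")
        if self.k < 0.0:
            raise ValueError("require k >= 0")
        if np.isfinite(self.phi):
            object.__setattr__(self, "phi", float(np.mod(self.phi, 360.0)))

    @property
    def modulation(self) -> float:
        """Peak-to-baseline firing modulation amplitude (Hz)."""
        return self.rmax - self.rmin

    def reversed(self) -> "TuningCurve":
        """The same curve with the preferred phase shifted by 180 degrees."""
        return replace(self, phi=float(np.mod(self.phi + 180.0, 360.0)))

    def __call__(self, theta_deg):
        return circular_normal(theta_deg, self)

    def cycle_mean(self, n: int = 720) -> float:
        """Cycle-averaged rate by quadrature."""
        th = np.linspace(0.0, 360.0, n, endpoint=False)
        return float(np.mean(circular_normal(th, self)))


@dataclass
class PhaseSample:
    """Phases in degrees wrapped to [0, 360) with optional weights."""

    phases: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.phases = np.mod(np.asarray(self.phases, dtype=float), 360.0)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")


def circular_normal(theta_deg, curve: TuningCurve):
    """Evaluate the exponentiated-cosine tuning curve at phase(s) in degrees.

    Numerically stable for all k >= 0 via expm1; the k -> 0 limit is the
    raised cosine rmin + (rmax-rmin)*(1+cos)/2.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float) - curve.phi)
    k = curve.k
    if k < 1e-8:
        shape = 0.5 * (1.0 + np.cos(theta))
    else:
        shape = np.expm1(0.5 * k * (np.cos(theta) + 1.0)) / np.expm1(k)
    return curve.rmin + (curve.rmax - curve.rmin) * shape


def _spike_phase_rates(spike_times_ms, f_hz: float, duration_ms: float,
                       n_bins: int, t_start_ms: float = 0.0):
    """Bin spike phases into per-cycle firing rates (Hz)."""
    spikes = np.asarray(spike_times_ms, dtype=float)
    spikes = spikes[(spikes >= t_start_ms) & (spikes < t_start_ms + duration_ms)]
    period = 1000.0 / f_hz
    n_cycles = duration_ms / period
    phases = np.mod((spikes - t_start_ms) / period, 1.0) * 360.0
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    bin_dur_s = period / n_bins / 1000.0
    rates = counts / (n_cycles * bin_dur_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rates


def fit_tuning_binned(centers_deg, rates_hz, k_max: float = 50.0,
                      flat_alpha: float = 0.002) -> TuningCurve:
    """Least-squares exponentiated-cosine fit to a binned rate profile.

    ``flat_alpha`` is the significance level of the modulation-vs-flat F
    test; it is set well below the usual 0.05 because the fitted phase is
    optimized over the same data, which inflates the naive F statistic.
    """
    centers = np.asarray(centers_deg, dtype=float)
    rates = np.asarray(rates_hz, dtype=float)
    if centers.size == 0 or rates.size == 0:
        raise ValueError("empty input")
    if rates.size != centers.size:
        raise ValueError("centers and rates must have equal length")
    mean_rate = float(rates.mean())
    if rates.std() < 1e-12 or rates.max() <= 0:
        return TuningCurve(rmin=mean_rate, rmax=mean_rate, phi=np.nan, k=0.0)

    # initial phase and concentration from circular moments of the profile
    th = np.deg2rad(centers)
    Cm = (rates * np.cos(th)).sum()
    Sm = (rates * np.sin(th)).sum()
    phi0 = float(np.mod(np.degrees(np.arctan2(Sm, Cm)), 360.0))
    rbar = min(np.hypot(Cm, Sm) / max(rates.sum(), 1e-12), 0.999)
    k0_moment = float(np.clip(2.0 * rbar * (2.0 - rbar ** 2) / (1.0 - rbar ** 2),
                              0.05, 20.0))

    def model(theta, rmin, amp, phi, k):
        return circular_normal(theta, TuningCurve(max(rmin, 0.0),
                                                  max(rmin, 0.0) + max(amp, 0.0),
                                                  phi, max(k, 0.0)))

    p0 = [max(rates.min(), 0.0), max(rates.max() - rates.min(), 1e-3), phi0, k0_moment]
    best = None
    span = max(rates.max() - rates.min(), 1e-9)
    for trial, k0 in enumerate((k0_moment, 0.3, 1.0, 4.0)):
        p0[3] = k0
        try:
            popt, _ = curve_fit(
                model, centers, rates, p0=p0,
                bounds=([0.0, 0.0, -360.0, 0.0],
                        [np.inf, np.inf, 720.0, k_max]),
                maxfev=20000)
        except RuntimeError:
            continue
        resid = float(np.sum((model(centers, *popt) - rates) ** 2))
        if best is None or resid < best[0]:
            best = (resid, popt)
        # the moment start almost always suffices; only restart on poor fits
        if trial == 0 and best is not None and \
                np.sqrt(best[0] / rates.size) < 0.15 * span:
            break
    if best is None:
        return TuningCurve(rmin=mean_rate, rmax=mean_rate, phi=np.nan, k=0.0)
    rmin, amp, phi, k = best[1]
    # guard against fitting noise: unless the tuned model explains
    # significantly more variance than a flat rate (F test), report an
    # unmodulated cell
    ss_flat = float(np.sum((rates - mean_rate) ** 2))
    ss_fit = best[0]
    dof_extra, dof_resid = 3, max(rates.size - 4, 1)
    if ss_fit > 0:
        f_stat = ((ss_flat - ss_fit) / dof_extra) / (ss_fit / dof_resid)
        p_flat = float(stats.f.sf(f_stat, dof_extra, dof_resid))
    else:
        p_flat = 0.0
    if amp < 1e-9 or p_flat > flat_alpha:
        return TuningCurve(rmin=mean_rate, rmax=mean_rate, phi=np.nan, k=0.0)
    return TuningCurve(rmin=float(rmin), rmax=float(rmin + amp),
                       phi=float(np.mod(phi, 360.0)), k=float(k))


def fit_tuning(spike_times_ms, f_hz: float, duration_ms: float,
               n_bins: int = 20, t_start_ms: float = 0.0) -> TuningCurve:
    """Fit the tuning curve to a spike train recorded under sinusoidal
    modulation at ``f_hz`` (>= 2 cycles required)."""
    if duration_ms * f_hz / 1000.0 < 2.0:
        raise ValueError("need at least 2 modulation cycles of data")
    spikes = np.asarray(spike_times_ms, dtype=float)
    if spikes.size == 0:
        return TuningCurve(rmin=0.0, rmax=0.0, phi=np.nan, k=0.0)
    centers, rates = _spike_phase_rates(spikes, f_hz, duration_ms, n_bins, t_start_ms)
    return fit_tuning_binned(centers, rates)


def cv2(isis_ms) -> float:
    """Local spike-train irregularity: mean of 2|ISI1-ISI2| / (ISI1+ISI2)
    over successive interval pairs.  0 for regular firing, ~1 for Poisson."""
    isis = np.asarray(isis_ms, dtype=float)
    if isis.size < 2:
        raise ValueError("need at least 2 inter-spike intervals")
    a, b = isis[:-1], isis[1:]
    return float(np.mean(2.0 * np.abs(a - b) / np.abs(a + b)))


def phase_to_delay(phi_deg: float, f_hz: float):
    """Convert a phase shift to a time delay at modulation frequency f.

    Returns (ms_per_degree, delay_ms); at 1 Hz one degree is 2.78 ms.
    """
    if f_hz <= 0:
        raise ValueError("modulation frequency must be > 0")
    ms_per_deg = 1000.0 / (360.0 * f_hz)
    return ms_per_deg, phi_deg * ms_per_deg


@dataclass
class ReboundFit:
    """Offset rebound isolated from the post-train decay."""

    amplitude: float          # pA, > 0 means a genuine rebound
    tau_on: float             # ms onset time constant (NaN when absent)
    charge: float             # pA*ms of the isolated residue
    decay_tau: float          # ms of the forced-origin offset decay
    ok: bool = True


@dataclass
class EPSCDecomposition:
    """Component decomposition of a 50 Hz train EPSC (magnitudes in pA)."""

    fast_peak: float
    fast_tau_decay: float
    fast_charge: float        # pA*ms = fast_peak * fast_tau_decay
    steady_amp: float
    buildup_amp: float
    buildup_tau: float
    buildup_charge: float     # pA*ms
    envelope_charge: float    # pA*ms over the train
    rebound: ReboundFit


def _inward(trace):
    """Baseline-subtracted inward deflection (positive pA) and times."""
    t = np.asarray(trace.times, dtype=float)
    i = np.asarray(trace.current, dtype=float)
    stims = np.asarray(trace.stim_times, dtype=float)
    pre = i[t < stims[0]] if stims.size else i[: max(len(i) // 20, 1)]
    base = float(np.mean(pre[-int(50.0 / (t[1] - t[0])):])) if pre.size else 0.0
    return t, -(i - base), stims


def isolate_rebound(trace, train_end_ms: float,
                    tail_fraction: float = 0.2) -> ReboundFit:
    """Isolate the offset rebound by subtracting a forced-origin exponential.

    The post-train decay tail (the last ``tail_fraction`` of the amplitude
    span, after the rebound) is fitted with an exponential forced in
    amplitude and origin to the current amplitude at stimulation offset;
    its extrapolation is subtracted from the post-train trace and the onset
    of the residue is fitted with a saturating exponential, giving the
    rebound amplitude and rise time constant tau_ON.
    """
    t, sig, _ = _inward(trace)
    dt = t[1] - t[0]
    post = t >= train_end_ms
    if t[-1] - train_end_ms < 1000.0 - 1e-6:
        raise ValueError("need at least 1 s of post-train trace")
    tp = t[post] - train_end_ms
    yp = sig[post]
    # steady amplitude at stimulation offset: the slow envelope just before
    # the train ends (a low percentile rejects the fast transients)
    pre_win = (t >= train_end_ms - 20.0) & (t < train_end_ms)
    amp0 = float(np.percentile(sig[pre_win], 10)) if pre_win.any() else float(yp[0])
    if amp0 <= 0:
        return ReboundFit(0.0, np.nan, 0.0, np.nan, ok=False)
    base_end = float(np.median(yp[-int(50.0 / dt):]))
    pk_idx = int(np.argmax(yp))
    span = yp[pk_idx] - base_end
    tail = (np.arange(yp.size) > pk_idx) & (yp <= base_end + tail_fraction * span)
    if tail.sum() < 5:
        return ReboundFit(0.0, np.nan, 0.0, np.nan, ok=False)

    def forced_exp(tt, tau):
        return amp0 * np.exp(-tt / tau)

    try:
        (tau_dec,), _ = curve_fit(forced_exp, tp[tail], yp[tail],
                                  p0=[300.0], bounds=(1.0, 1e5), maxfev=10000)
    except RuntimeError:
        return ReboundFit(0.0, np.nan, 0.0, np.nan, ok=False)
    residue = yp - forced_exp(tp, tau_dec)
    r_pk = int(np.argmax(residue))
    r_amp = float(residue[r_pk])
    charge = float(np.trapezoid(np.clip(residue, 0.0, None), tp))
    if r_amp < 0.02 * amp0 or r_pk < 3:
        # no resolvable rebound on top of the decay
        return ReboundFit(max(r_amp, 0.0), np.nan, charge, float(tau_dec))

    # onset: the residue behaves as rise x decay; dividing out an
    # exponential fitted to its falling phase linearizes the onset, which
    # is then fitted with a saturating exponential -> tau_ON.  The decay
    # constant is floored at 2 x peak time (stronger amplification would
    # mean onset and decay are not separable) and tau_ON is capped at
    # 1.5 x peak time.
    t_pk = tp[r_pk]
    try:
        dec_sel = (tp > t_pk) & (residue > 0.1 * r_amp)
        if dec_sel.sum() < 10:
            raise RuntimeError("no falling phase")
        (_, t_off), _ = curve_fit(
            lambda tt, A, tau: A * np.exp(-tt / tau),
            tp[dec_sel], residue[dec_sel],
            p0=[r_amp, max(3.0 * t_pk, 100.0)],
            bounds=([0.1 * r_amp, dt], [100.0 * r_amp, 1e6]), maxfev=20000)
        t_off = max(t_off, 2.0 * t_pk)
        rise = residue[: r_pk + 1] / np.exp(-tp[: r_pk + 1] / t_off)
        (A, tau_on), _ = curve_fit(
            lambda tt, A, tau: A * (1.0 - np.exp(-tt / tau)),
            tp[: r_pk + 1], rise,
            p0=[r_amp, max(t_pk / 3.0, dt)],
            bounds=([0.1 * r_amp, dt], [50.0 * r_amp, 1.5 * t_pk]),
            maxfev=20000)
    except RuntimeError:
        return ReboundFit(r_amp, np.nan, charge, float(tau_dec), ok=False)
    return ReboundFit(r_amp, float(tau_on), charge, float(tau_dec))


def decompose_train_epsc(trace, train_duration_ms: float = 500.0) -> EPSCDecomposition:
    """Decompose a train EPSC into fast, steady, buildup and rebound parts.

    The fast transient is quantified from an exponential-plus-base fit of
    the first EPSC decay (peak = fit amplitude, charge = amplitude x tau);
    the base of that fit is the steady amplitude; the buildup charge is the
    train envelope charge minus steady amplitude x train duration; the
    rebound is isolated from the post-train decay by ``isolate_rebound``.
    """
    t, sig, stims = _inward(trace)
    if stims.size < 10:
        raise ValueError("need a stimulation train (>= 10 stimuli)")
    dt = t[1] - t[0]
    isi = float(np.median(np.diff(stims)))
    train_end = float(stims[-1] + isi)

    # ---- first EPSC ----
    w0 = (t >= stims[0]) & (t < stims[0] + isi)
    tw, yw = t[w0], sig[w0]
    pk = int(np.argmax(yw))
    # fit only the decaying phase: stop at the valley before any slow
    # component starts rising again
    valley = pk + int(np.argmin(yw[pk:]))
    if valley > pk + 10:
        tw, yw = tw[: valley + 1], yw[: valley + 1]

    def exp_base(tt, A, tau, B):
        return A * np.exp(-tt / tau) + B

    fast_peak = fast_tau = steady0 = np.nan
    try:
        popt, _ = curve_fit(
            exp_base, tw[pk:] - tw[pk], yw[pk:],
            p0=[max(yw[pk], 1e-3), 2.0, 0.0],
            bounds=([0.0, 0.05, -np.inf], [np.inf, 1000.0, np.inf]),
            maxfev=20000)
        fast_peak, fast_tau, steady0 = popt
    except RuntimeError:
        pass

    # ---- steady amplitude and charges ----
    steady_amp = float(max(steady0, 0.0)) if np.isfinite(steady0) else 0.0
    train_sel = (t >= stims[0]) & (t < train_end)
    envelope_charge = float(np.trapezoid(sig[train_sel], t[train_sel]))

    # ---- slow (steady+buildup) envelope from inter-stimulus minima ----
    mins_t, mins_y = [], []
    for k in range(stims.size - 1):
        sel = (t >= stims[k] + 0.5 * isi) & (t < stims[k + 1])
        if sel.any():
            mins_t.append(t[sel][np.argmin(sig[sel])] - stims[0])
            mins_y.append(sig[sel].min())
    mins_t = np.asarray(mins_t)
    mins_y = np.asarray(mins_y)
    # integrate the lower envelope over the train; the fast transients ride
    # on top of it, so envelope_charge - slow_charge is the fast share
    if mins_t.size >= 2:
        env_t = np.concatenate([[0.0], mins_t, [train_end - stims[0]]])
        env_y = np.concatenate([[0.0], mins_y, [mins_y[-1]]])
        slow_charge = float(np.trapezoid(env_y, env_t))
    else:
        slow_charge = steady_amp * train_duration_ms
    buildup_charge = slow_charge - steady_amp * train_duration_ms
    buildup_amp = float(max(np.median(mins_y[-3:]) - steady_amp, 0.0)) if mins_y.size >= 3 else 0.0
    buildup_tau = np.nan
    if mins_y.size >= 5 and buildup_amp > 1e-3:
        def rise(tt, C, tau):
            return steady_amp + C * (1.0 - np.exp(-tt / tau))
        try:
            (C, btau), _ = curve_fit(rise, mins_t, mins_y,
                                     p0=[buildup_amp, 200.0],
                                     bounds=([0.0, 1.0], [np.inf, 1e5]),
                                     maxfev=10000)
            buildup_tau = float(btau)
        except RuntimeError:
            pass

    rebound = isolate_rebound(trace, train_end)
    return EPSCDecomposition(
        fast_peak=float(fast_peak), fast_tau_decay=float(fast_tau),
        fast_charge=float(fast_peak * fast_tau),
        steady_amp=steady_amp, buildup_amp=buildup_amp,
        buildup_tau=buildup_tau, buildup_charge=float(buildup_charge),
        envelope_charge=envelope_charge, rebound=rebound)


def ks_uniform(phases, rotation_minimized: bool = False,
               n_rotations: int = 720) -> float:
    """One-sample Kolmogorov-Smirnov distance of phases to the uniform
    distribution on [0°, 360°).

    With ``rotation_minimized`` the statistic is minimized over a grid of
    reference rotations, making it invariant to a global phase shift.
    """
    if isinstance(phases, PhaseSample):
        phases = phases.phases
    phases = np.mod(np.asarray(phases, dtype=float), 360.0)
    phases = phases[np.isfinite(phases)]
    if phases.size < 10:
        raise ValueError("need at least 10 phases")
    if not rotation_minimized:
        return float(stats.kstest(phases / 360.0, "uniform").statistic)
    rots = np.linspace(0.0, 360.0, n_rotations, endpoint=False)
    best = np.inf
    for r in rots:
        d = stats.kstest(np.mod(phases - r, 360.0) / 360.0, "uniform").statistic
        best = min(best, float(d))
    return best
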