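"""Rate-based Purkinje cell with climbing-fiber error-driven learning.

The Purkinje cell (PC) is a linear rate unit over the granule-cell (GC)
population, r_PC(θ) = Σ_i w_i r_i(θ), where r_i(θ) is GC i's trial-averaged
firing rate at phase θ of the stimulation cycle.  A climbing-fiber error
signal E(θ) = r_target(θ) − r_PC(θ) drives the delta rule

    dw_i/dt = η · r_i(θ(t)) · E(θ(t)),      w_i ≥ 0 (clipped),

against the target r_target(θ) = r̄ (1 + cos(θ − φ)) with mean rate
r̄ = 32 Hz.  The update is applied bin-sequentially within each cycle with
step η·Δt (Δt the bin duration in seconds), which is the stable
discretization of the continuous-time rule at the full network size.  With
clipping, learning approaches the nonnegative least-squares optimum: the
PC can reach any target phase that the GC population's phase coverage
spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "PCLearner",
    "RateMatrix",
    "pc_rate",
    "target_rate",
    "train_pc",
    "mse_vs_phase",
    "rate_matrix_from_network",
]


@dataclass
class RateMatrix:
    """Per-GC mean firing rate (Hz) per phase bin of the cycle."""

    rates: np.ndarray            # (n_gc, n_bins)
    f_hz: float = 1.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be 2-D (n_gc, n_bins)")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def bin_dt_s(self) -> float:
        return 1.0 / (self.f_hz * self.n_bins)


@dataclass
class PCLearner:
    """Purkinje weight vector and learning configuration."""

    weights: np.ndarray
    eta: float = 0.001
    r_bar: float = 32.0
    target_phi: float = 0.0
    n_cycles: int = 10000

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @classmethod
    def init(cls, n_gc: int, target_phi: float, w0: float = 0.5,
             **kw) -> "PCLearner":
        return cls(weights=np.full(n_gc, w0), target_phi=target_phi, **kw)


def pc_rate(weights, rates: RateMatrix | np.ndarray) -> np.ndarray:
    """Linear PC readout per phase bin."""
    R = rates.rates if isinstance(rates, RateMatrix) else np.asarray(rates)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != R.shape[0]:
        raise ValueError("weight/rate dimension mismatch")
    return w @ R


def target_rate(phi_deg: float, r_bar: float = 32.0,
                n_bins: int = 100) -> np.ndarray:
    """Target PC rate per phase bin: r̄(1 + cos(θ − φ)); cycle mean r̄,
    maximum 2r̄ at φ, minimum 0 opposite."""
    if r_bar <= 0:
        raise ValueError("r_bar must be > 0")
    theta = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    return r_bar * (1.0 + np.cos(np.deg2rad(theta - phi_deg)))


@njit
def _train_loop(R, target, w, step, n_cycles, rel_tol, patience):
    n_gc, n_bins = R.shape
    mse = np.empty(n_cycles)
    n_done = 0
    n_worse = 0
    diverged = False
    for c in range(n_cycles):
        err_sq = 0.0
        for b in range(n_bins):
            out = 0.0
            for i in range(n_gc):
                out += w[i] * R[i, b]
            e = target[b] - out
            err_sq += e * e
            se = step * e
            for i in range(n_gc):
                w[i] += se * R[i, b]
                if w[i] < 0.0:
                    w[i] = 0.0
        mse[c] = err_sq / n_bins
        n_done = c + 1
        if c == 0:
            best = mse[0]
        elif mse[c] < best:
            best = mse[c]
            n_worse = 0
        else:
            # genuine divergence, not the LMS noise floor around an
            # unreachable optimum
            if mse[c] > 2.0 * best and mse[c] > mse[c - 1]:
                n_worse += 1
                if n_worse >= patience:
                    diverged = True
                    break
            if c >= patience and mse[c - patience] > 0.0:
                rel = abs(mse[c] - mse[c - patience]) / mse[c - patience]
                if rel < rel_tol:
                    break
    return mse[:n_done], diverged


def train_pc(learner: PCLearner, rates: RateMatrix,
             rel_tol: float = 1e-6, patience: int = 100):
    """Train the PC weights by the clipped delta rule.

    Runs up to ``n_cycles`` cycles of bin-sequential updates with step
    η·Δt_bin, stopping early once the relative MSE change over ``patience``
    cycles falls below ``rel_tol``.  Returns (trained_learner,
    mse_history); raises FloatingPointError on sustained divergence.
    """
    R = rates.rates
    if learner.weights.shape[0] != R.shape[0]:
        raise ValueError("weight/rate dimension mismatch")
    target = target_rate(learner.target_phi, learner.r_bar, rates.n_bins)
    w = learner.weights.copy()
    step = learner.eta * rates.bin_dt_s
    # LMS stability: the per-bin loop gain is step * sum_i r_i(b)^2; cap
    # it below 1.5 (the fixed point is unchanged, only convergence speed)
    gain = step * float(np.max(np.sum(R * R, axis=0)))
    if gain > 1.5:
        step *= 1.5 / gain
    mse, diverged = _train_loop(R, target, w, step, learner.n_cycles,
                                rel_tol, patience)
    if diverged:
        raise FloatingPointError(
            f"PC training diverged (MSE rising for {patience} cycles)")
    trained = PCLearner(weights=w, eta=learner.eta, r_bar=learner.r_bar,
                        target_phi=learner.target_phi,
                        n_cycles=learner.n_cycles)
    return trained, mse


def mse_vs_phase(rates: RateMatrix, phi_grid, eta: float = 0.001,
                 r_bar: float = 32.0, n_cycles: int = 10000) -> np.ndarray:
    """Final training MSE for each target phase in ``phi_grid``."""
    out = np.empty(len(phi_grid))
    for i, phi in enumerate(phi_grid):
        learner = PCLearner.init(rates.rates.shape[0], float(phi),
                                 eta=eta, r_bar=r_bar, n_cycles=n_cycles)
        _, mse = train_pc(learner, rates)
        out[i] = mse[-1]
    return out


def rate_matrix_from_network(spike_times, f_hz: float, t_start_ms: float,
                             duration_ms: float, n_bins: int = 100,
                             smooth_bins: int = 3) -> RateMatrix:
    """Trial-averaged GC rate per phase bin from per-cell spike trains.

    ``smooth_bins`` applies a circular boxcar over neighbouring phase bins;
    with only ~10 modulation cycles per run the raw per-bin counts are
    Poisson-noisy, and the delta rule's per-update gain grows with Σ r²,
    so unsmoothed matrices sit at the edge of learning stability.  The
    smoothing stands in for the trial averaging of a longer experiment.
    """
    period = 1000.0 / f_hz
    n_cycles = duration_ms / period
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    bin_dur_s = period / n_bins / 1000.0
    R = np.zeros((len(spike_times), n_bins))
    for g, spk in enumerate(spike_times):
        spk = np.asarray(spk, dtype=float)
        spk = spk[(spk >= t_start_ms) & (spk < t_start_ms + duration_ms)]
        ph = np.mod((spk - t_start_ms) / period, 1.0) * 360.0
        counts, _ = np.histogram(ph, bins=edges)
        R[g] = counts / (n_cycles * bin_dur_s)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        R = np.apply_along_axis(
            lambda row: np.convolve(np.tile(row, 3), kernel,
                                    mode="same")[n_bins:2 * n_bins], 1, R)
    return RateMatrix(R, f_hz=f_hz)
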