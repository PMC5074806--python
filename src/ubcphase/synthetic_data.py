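"""Synthetic surrogates for the experimental recordings.

No raw recordings ship with this package; instead this module generates

* surrogate UBC tuning-curve populations whose phase, concentration-factor
  and modulation-amplitude statistics match the reported ON/OFF summary
  statistics of the recorded cells (47 cells at 1 Hz modulation);
* surrogate voltage-clamp EPSC datasets (50 Hz, 500 ms trains) with known
  composite-model ground truth and realistic additive baseline noise
  (SD ≈ 0.7 pA);
* spike-train fixtures from arbitrary tuning curves.

All generators are seed-deterministic.  Ground truth is returned alongside
— never embedded in — the surrogate traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epsc_fitting import (
    CompositeEPSCModel,
    CurrentTrace,
    PoolModel,
    simulate_epsc,
)
from .phase_metrics import TuningCurve
from .receptor_kinetics import GlutamatePulse, default_rate_constants
from .stimulus_protocols import train_stim_times, time_rescaled_spikes, ubc_rate

__all__ = [
    "UBCPopulationSpec",
    "EPSCGroundTruth",
    "make_ubc_population",
    "make_epsc_dataset",
    "make_spike_fixture",
]


@dataclass(frozen=True)
class UBCPopulationSpec:
    """Reported summary statistics of the recorded UBC population (1 Hz).

    ON cells are excited by their mossy fiber and show broadly dispersed
    preferred phases and near-sinusoidal tuning (small k); OFF cells are
    inhibited during stimulation and fire concentrated rebound-like bursts
    in a narrow band of late phases (large k, near-zero baseline).
    """

    n_on: int = 22
    n_off: int = 25
    on_phase_mean: float = 140.0     # degrees
    on_phase_sd: float = 105.0
    off_phase_mean: float = 274.0
    off_phase_sd: float = 28.0
    on_k_mean: float = 0.9
    on_k_sd: float = 1.5
    off_k_mean: float = 2.2
    off_k_sd: float = 1.2
    k_min: float = 0.05
    on_mod_mean: float = 12.0        # Hz, rmax - rmin
    on_mod_sd: float = 23.0
    off_mod_mean: float = 12.0
    off_mod_sd: float = 8.0
    mod_min: float = 0.5
    on_base_mean: float = 11.7       # Hz steady firing
    on_base_sd: float = 9.2


@dataclass
class EPSCGroundTruth:
    """Hidden truth of one surrogate EPSC recording."""

    model: CompositeEPSCModel
    noise_sd: float = 0.7
    stim_times: np.ndarray = field(default_factory=lambda: train_stim_times())

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")


def _trunc_normal(rng, mean, sd, lo, size=None):
    """Resampling-truncated normal draws (lower bound only)."""
    out = rng.normal(mean, sd, size)
    bad = out < lo
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size), out)
        bad = out < lo
    return out


def make_ubc_population(spec: UBCPopulationSpec | None = None,
                        seed: int = 0, n_scale: int = 1):
    """Sample a surrogate UBC population of tuning curves.

    Phases are drawn from wrapped normals around the class means; k and
    modulation amplitudes from truncated normals.  ON baselines follow the
    reported steady firing; OFF cells have zero baseline (they are
    silenced outside their burst phase).  ``n_scale`` multiplies both
    class counts (for large-sample statistical checks).

    Returns (curves, is_on) with ON cells first.
    """
    spec = spec or UBCPopulationSpec()
    rng = np.random.default_rng(seed)
    curves = []
    n_on = spec.n_on * n_scale
    n_off = spec.n_off * n_scale
    for n, ph_m, ph_sd, k_m, k_sd, mod_m, mod_sd, base_m, base_sd in (
            (n_on, spec.on_phase_mean, spec.on_phase_sd, spec.on_k_mean,
             spec.on_k_sd, spec.on_mod_mean, spec.on_mod_sd,
             spec.on_base_mean, spec.on_base_sd),
            (n_off, spec.off_phase_mean, spec.off_phase_sd, spec.off_k_mean,
             spec.off_k_sd, spec.off_mod_mean, spec.off_mod_sd, 0.0, 0.0)):
        phases = np.mod(rng.normal(ph_m, ph_sd, n), 360.0)
        ks = _trunc_normal(rng, k_m, k_sd, spec.k_min, n)
        mods = _trunc_normal(rng, mod_m, mod_sd, spec.mod_min, n)
        bases = _trunc_normal(rng, base_m, base_sd, 0.0, n) if base_sd > 0 \
            else np.zeros(n)
        for i in range(n):
            curves.append(TuningCurve(rmin=float(bases[i]),
                                      rmax=float(bases[i] + mods[i]),
                                      phi=float(phases[i]), k=float(ks[i])))
    is_on = np.arange(len(curves)) < n_on
    return curves, is_on


# Pool-parameter sampling centres: (glutamate step s in µM, tau_rise ms,
# tau_decay ms, conductance nS), calibrated so the emulated population
# reproduces the reported train-EPSC statistics (fast transients decaying
# in ~1 ms, steady currents of 10-20 pA, offset rebounds with onset time
# constants spanning ~25-99 ms).  At 50 Hz the intermediate pool's
# glutamate accumulates above the bell peak of the steady-state curve and
# its post-train clearance through the bell produces the rebound.
_POOL_CENTERS = {
    "far": (8.0, 40.0, 150.0, 1.2),
    "intermediate": (60.0, 20.0, 10.0, 2.0),
    "close": (400.0, 0.0, 1.2, 1.0),
}


def _sample_model(rng, v_hold=-60.0) -> CompositeEPSCModel:
    """Log-normal parameter spread (×/÷ up to 4) around the pool centres."""
    max_log = np.log(4.0)

    def jitter(v, scale):
        f = np.clip(rng.normal(0.0, scale * max_log), -max_log, max_log)
        return v * np.exp(f)

    pools = {}
    for cls, (s, tr, td, g) in _POOL_CENTERS.items():
        pulse = GlutamatePulse(
            s=jitter(s, 0.2),
            tau_rise=jitter(tr, 0.2) if cls != "close" else 0.0,
            tau_decay=jitter(td, 0.2))
        pools[cls] = PoolModel(cls, jitter(g, 0.5), pulse)
    return CompositeEPSCModel(pools=pools, rates=default_rate_constants(),
                              v_hold=v_hold)


def make_epsc_dataset(n_cells: int, seed: int = 0, noise_sd: float = 0.7,
                      dt: float = 0.05, pre_ms: float = 50.0,
                      post_ms: float = 1500.0):
    """Surrogate voltage-clamp recordings of 50 Hz / 500 ms train EPSCs.

    Each cell draws pool parameters log-normally around the canonical
    geometry, is simulated over the standard train protocol and receives
    additive Gaussian baseline noise.  Returns (traces, truths) with the
    ground truth kept separate from the traces.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    stim = train_stim_times() + pre_ms
    duration = pre_ms + 500.0 + post_ms
    traces, truths = [], []
    for _ in range(n_cells):
        model = _sample_model(rng)
        clean = simulate_epsc(model, stim, duration, dt=dt)
        noisy = clean.current + rng.normal(0.0, noise_sd, clean.current.size)
        traces.append(CurrentTrace(clean.times, noisy, stim))
        truths.append(EPSCGroundTruth(model=model, noise_sd=noise_sd,
                                      stim_times=stim))
    return traces, truths


def make_spike_fixture(curve: TuningCurve, f_hz: float = 1.0,
                       cycles: int = 10, seed: int = 0) -> np.ndarray:
    """Spike train from a tuning curve under sinusoidal modulation
    (time-rescaling draw over ``cycles`` full cycles)."""
    if cycles < 1:
        raise ValueError("need at least one cycle")
    duration = cycles * 1000.0 / f_hz
    return time_rescaled_spikes(lambda t: ubc_rate(t, curve, f_hz),
                                duration, np.random.default_rng(seed))
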