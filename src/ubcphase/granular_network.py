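"""Integrate-and-fire granular-layer network with short-term plasticity.

Granule cells (GCs) are integrate-and-fire units with a KIR-like
exponential leak toward EK, a spike plateau and afterhyperpolarization,
tonic (Golgi-replacing) inhibition, and slow Ornstein-Uhlenbeck
conductance noise:

    C dV/dt = -gL (V-EK) exp(-(V-EL)/5) - g_ahp z (V-EK)
              - gN (V-VE) - g_inh (V-ECl) - g_control * Isyn(t)

Each GC receives 4 mossy-fiber inputs — all extrinsic (eMF) in the no-UBC
network, or eMF/UBC with equal probability — through fast AMPA, slow AMPA
and NMDA receptors with Tsodyks-Markram short-term plasticity (depressing
for eMF inputs, fast-recovering for UBC inputs).  A per-cell multiplicative
scaling g_control is continuously adjusted to hold each GC's firing rate at
a common target (5 Hz), so the with/without-UBC comparison is not
confounded by excitability differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from ._kernels import gc_network_chunk, synapse_gating_batch, synapse_gating_chunk
from .phase_metrics import TuningCurve, fit_tuning, ks_uniform
from .stimulus_protocols import Protocol, emf_rate, ubc_rate, EMFDrive, \
    sample_ubc_population, time_rescaled_spikes

__all__ = [
    "GCParams",
    "SynapseParams",
    "SynapseState",
    "NetworkConfig",
    "Wiring",
    "NetworkResult",
    "SYNAPSE_TABLE",
    "nmda_gate",
    "stp_update",
    "simulate_gc",
    "rate_controller",
    "build_network",
    "run_network",
]


@dataclass(frozen=True)
class GCParams:
    """Granule-cell integrate-and-fire constants (pF, nS, mV, ms)."""

    Cm: float = 4.9
    gL: float = 1.5
    EK: float = -90.0
    EL: float = -90.0
    VT_mean: float = -50.0
    VT_sd: float = 2.5
    Vreset: float = -65.0
    V_spike: float = 40.0
    tau_dur: float = 0.6
    tau_ref: float = 2.0
    g_ahp_bar: float = 1.0
    tau_ahp: float = 3.0
    tau_ahp_x: float = 1.0
    g_inh: float = 0.9
    E_cl: float = -75.0
    sigma_N: float = 0.12
    tau_N: float = 1000.0
    V_E: float = 0.0

    def __post_init__(self) -> None:
        if self.VT_mean <= self.Vreset:
            raise ValueError("VT must exceed Vreset")
        for name in ("Cm", "gL", "g_ahp_bar", "g_inh", "sigma_N"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class SynapseParams:
    """One receptor component of a mossy-fiber -> GC synapse."""

    receptor: str                # AMPAfast | AMPAslow | NMDA
    gpeak: float                 # nS
    a: float                     # activation rate, 1/ms
    tau_rise: float              # ms
    tau_decay: float             # ms
    U: float                     # release fraction
    tau_rec: float | None = None
    tau_fac: float | None = None

    @property
    def has_stp(self) -> bool:
        return self.tau_rec is not None

    @property
    def unit_peak(self) -> float:
        """Peak of the gating variable r for a unit-efficacy spike from rest.

        gpeak is the peak conductance of a unit-efficacy EPSC (the column
        is literally named g_peak), so conductances are gpeak * r / unit_peak;
        without this normalization the rise cascade (a = 0.3/ms) would
        attenuate a mossy-fiber EPSC ~50-fold below its stated amplitude.
        """
        if not hasattr(self, "_unit_peak"):
            dt = min(self.tau_rise, self.tau_decay) / 50.0
            n = int(10.0 * (self.tau_rise + self.tau_decay) / dt)
            sv, rv, pk = 1.0, 0.0, 0.0
            for _ in range(n):
                gtot = 1.0 / self.tau_decay + self.a * sv
                rinf = self.a * sv / gtot
                rv = rinf + (rv - rinf) * np.exp(-dt * gtot)
                sv *= np.exp(-dt / self.tau_rise)
                if rv > pk:
                    pk = rv
            object.__setattr__(self, "_unit_peak", max(pk, 1e-12))
        return self._unit_peak

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError("U must lie in (0, 1]")
        for v in (self.tau_rise, self.tau_decay, self.tau_rec, self.tau_fac):
            if v is not None and v <= 0:
                raise ValueError("time constants must be > 0")


# Receptor components of the two mossy-fiber -> GC synapse types.  eMF
# synapses are slowly recovering (depressing at vestibular rates); UBC
# (intrinsic MF) synapses recover quickly.  NMDA carries no short-term
# plasticity.
SYNAPSE_TABLE: dict[tuple[str, str], SynapseParams] = {
    ("emf", "AMPAfast"): SynapseParams("AMPAfast", 0.43, 0.3, 0.8, 1.0, 0.5, 600.0, 600.0),
    ("emf", "AMPAslow"): SynapseParams("AMPAslow", 0.80, 0.3, 0.55, 6.0, 0.5, 600.0, 600.0),
    ("emf", "NMDA"): SynapseParams("NMDA", 0.96, 0.3, 5.0, 830.0, 0.05),
    ("ubc", "AMPAfast"): SynapseParams("AMPAfast", 1.63, 0.3, 0.8, 1.0, 0.5, 12.0, 12.0),
    ("ubc", "AMPAslow"): SynapseParams("AMPAslow", 3.20, 0.3, 0.55, 6.0, 0.5, 12.0, 12.0),
    ("ubc", "NMDA"): SynapseParams("NMDA", 3.84, 0.3, 5.0, 830.0, 0.05),
}

_RECEPTORS = ("AMPAfast", "AMPAslow", "NMDA")


@dataclass
class SynapseState:
    """Gating and short-term-plasticity state of one receptor component."""

    r: float = 0.0
    s: float = 0.0
    R: float = 1.0
    u: float | None = None


def nmda_gate(V):
    """Voltage dependence of the NMDA conductance, in (0, 1), increasing."""
    V = np.asarray(V, dtype=float)
    return 1.0 / (1.0 + np.exp(-(V - 84.0) / 38.0) /
                  (np.exp((V + 119.0) / 38.0) + np.exp(-(V + 45.0) / 28.0)))


def stp_update(state: SynapseState, params: SynapseParams, dt: float,
               presyn_spike: bool = False) -> SynapseState:
    """One Euler step of the synapse gating + short-term plasticity.

    Reference (pure-Python) implementation of the update used by the
    compiled batch kernel; spike order of operations: facilitate u, release
    with efficacy R*u, deplete R.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    s, r = state.s, state.r
    R = state.R
    u = params.U if state.u is None else state.u
    if presyn_spike:
        if params.has_stp:
            u = u + params.U * (1.0 - u)
            eff = R * u
            R = R - u * R
        else:
            eff = params.U
        s = s + eff
    gtot = 1.0 / params.tau_decay + params.a * s
    rinf = params.a * s / gtot
    r = rinf + (r - rinf) * np.exp(-dt * gtot)
    s = s * np.exp(-dt / params.tau_rise)
    if params.has_stp:
        R = 1.0 + (R - 1.0) * np.exp(-dt / params.tau_rec)
        u = params.U + (u - params.U) * np.exp(-dt / params.tau_fac)
    return SynapseState(r=r, s=s, R=R, u=u if params.has_stp else None)


def rate_controller(rate_est: float, observed_rate: float, gcontrol: float,
                    target: float, gain: float = 0.05,
                    window_ms: float = 5000.0, every_ms: float = 100.0):
    """One update of the multiplicative firing-rate controller.

    The rate estimate is an exponentially windowed average of the
    instantaneous rate; g_control is scaled up when the cell fires below
    target and down when above.  Returns (new_rate_est, new_gcontrol).
    """
    if target <= 0:
        raise ValueError("target rate must be > 0")
    decay = np.exp(-every_ms / window_ms)
    est = decay * rate_est + (1.0 - decay) * observed_rate
    g = gcontrol * (1.0 + gain * (target - est) / target)
    return est, float(np.clip(g, 1e-3, 1e3))


@dataclass(frozen=True)
class NetworkConfig:
    n_gc: int = 4500
    n_emf: int = 500
    n_ubc: int = 500
    inputs_per_gc: int = 4
    p_ubc_input: float = 0.5
    conductance_cv: float = 0.30
    rate_target: float = 5.0
    dt: float = 0.1
    # rate-controller schedule: fast convergence during the steady
    # burn-in (no modulation to distort), slow mean-tracking during the
    # modulated span (a fast controller there partially cancels the
    # within-cycle modulation and shifts preferred phases)
    control_gain: float = 0.2
    control_window_ms: float = 1000.0
    control_gain_mod: float = 0.15
    control_window_mod_ms: float = 5000.0
    control_every_ms: float = 100.0

    def __post_init__(self) -> None:
        if min(self.n_gc, self.n_emf, self.inputs_per_gc) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.p_ubc_input <= 1.0:
            raise ValueError("p_ubc_input must lie in [0, 1]")


@dataclass
class Wiring:
    """Connectivity and per-synapse conductances of the GC layer.

    src_type[g, j] is 0 (eMF) or 1 (UBC); src_idx indexes into the fiber
    population of that type; gpeak[g, j, k] is the scaled peak conductance
    of receptor k (AMPAfast, AMPAslow, NMDA) of input j to cell g.
    """

    src_type: np.ndarray
    src_idx: np.ndarray
    gpeak: np.ndarray


def build_network(config: NetworkConfig, rng, with_ubc: bool = True) -> Wiring:
    """Draw the wiring: 4 independent input draws per GC (eMF or UBC with
    probability p_ubc_input when UBCs are present), each receptor's peak
    conductance scaled by N(1, cv) truncated at 0.1."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    shape = (config.n_gc, config.inputs_per_gc)
    if with_ubc and config.n_ubc > 0:
        src_type = (rng.uniform(size=shape) < config.p_ubc_input).astype(np.int8)
    else:
        src_type = np.zeros(shape, dtype=np.int8)
    n_src = np.where(src_type == 1, config.n_ubc, config.n_emf)
    src_idx = rng.integers(0, n_src)
    scale = np.maximum(rng.normal(1.0, config.conductance_cv, shape + (3,)), 0.1)
    gpeak = np.empty(shape + (3,))
    for ti, pre in enumerate(("emf", "ubc")):
        for ki, rec in enumerate(_RECEPTORS):
            sel = src_type == ti
            p = SYNAPSE_TABLE[pre, rec]
            gpeak[..., ki][sel] = p.gpeak / p.unit_peak * scale[..., ki][sel]
    return Wiring(src_type=src_type, src_idx=src_idx, gpeak=gpeak)


def _fiber_spike_trains(config: NetworkConfig, protocol: Protocol,
                        ubc_curves, rng):
    """Spike trains for all eMF and UBC fibers over the full protocol."""
    total = protocol.total_ms
    steady = protocol.steady_ms
    f = protocol.f_mod
    trains = []
    for _ in range(config.n_emf):
        drive = EMFDrive(f_mod=f, k_mod=max(rng.uniform(), 1e-6),
                         phase_sign=1 if rng.uniform() < 0.5 else -1)

        def rate_fn(t, drive=drive):
            r = emf_rate(t - steady, drive)
            return np.where(t < steady, drive.r_base, r)

        trains.append(time_rescaled_spikes(rate_fn, total, rng, dt=1.0))
    for curve in ubc_curves:
        mean_rate = curve.cycle_mean()

        def rate_fn(t, curve=curve, mean_rate=mean_rate):
            r = ubc_rate(t - steady, curve, f)
            return np.where(t < steady, mean_rate, r)

        trains.append(time_rescaled_spikes(rate_fn, total, rng, dt=1.0))
    return trains


@dataclass
class NetworkResult:
    """Outcome of one granular-layer simulation."""

    spike_times: list                      # per GC, ms (full run)
    tuning: list                           # per GC TuningCurve (modulated span)
    preferred_phases: np.ndarray           # degrees, NaN where undefined
    ks_distance: float                     # raw KS of preferred phases to uniform
    mean_rates: np.ndarray                 # Hz over the analysed modulated span
    mean_rates_burnin: np.ndarray          # Hz over everything after 5 s burn-in
    g_control: np.ndarray                  # final per-cell scaling
    config: NetworkConfig = field(repr=False, default=None)


def run_network(config: NetworkConfig, protocol: Protocol, seed: int,
                with_ubc: bool = True, ubc_pool=None,
                gc: GCParams = GCParams(),
                chunk_ms: float = 1000.0,
                fit_bins: int = 20,
                skip_cycles: int = 3) -> NetworkResult:
    """Simulate the granular layer under the steady + modulated protocol.

    UBC fibers are drawn from ``ubc_pool`` (a list of TuningCurve; half of
    the draws phase-reversed); per-GC tuning is fitted on the modulated
    span and the population KS distance to uniform phase coverage is
    computed over cells with a defined preferred phase.
    """
    rng = np.random.default_rng(seed)
    dt = config.dt
    n_total = int(round(protocol.total_ms / dt))
    steady_ms = protocol.steady_ms

    # --- populations and wiring ---
    if with_ubc:
        if ubc_pool is None:
            raise ValueError("with_ubc requires a ubc_pool of tuning curves")
        ubc_curves, _ = sample_ubc_population(ubc_pool, config.n_ubc, rng)
    else:
        ubc_curves = []
    wiring = build_network(config, rng, with_ubc=with_ubc)
    trains = _fiber_spike_trains(config, protocol, ubc_curves, rng)
    n_fib = len(trains)
    spike_steps = [np.round(np.asarray(tr) / dt).astype(np.int64) for tr in trains]

    # fiber -> GC weight matrices, one per receptor
    rows = np.repeat(np.arange(config.n_gc), config.inputs_per_gc)
    cols = (wiring.src_idx + wiring.src_type.astype(np.int64) * config.n_emf).ravel()
    Ws = [sparse.csr_matrix(
        (wiring.gpeak[..., k].ravel(), (rows, cols)),
        shape=(config.n_gc, n_fib)) for k in range(3)]

    # per-(fiber, receptor) gating params: depend on presynaptic type
    fib_pre = ["emf"] * config.n_emf + ["ubc"] * len(ubc_curves)
    syn_states = {rec: np.zeros((n_fib, 4)) for rec in _RECEPTORS}
    for rec in _RECEPTORS:
        for fi, pre in enumerate(fib_pre):
            syn_states[rec][fi, 3] = SYNAPSE_TABLE[pre, rec].U

    VT = rng.normal(gc.VT_mean, gc.VT_sd, config.n_gc)
    state = np.zeros((config.n_gc, 9))
    state[:, 0] = gc.EL + 20.0
    state[:, 3] = 0.0
    state[:, 6] = 1.0                    # g_control
    state[:, 7] = config.rate_target     # rate estimate

    n_dur = int(round(gc.tau_dur / dt))
    n_ref = int(round(gc.tau_ref / dt))
    ou_every = 10
    ou_a = float(np.exp(-ou_every * dt / gc.tau_N))
    ou_b = gc.sigma_N * float(np.sqrt(1.0 - ou_a ** 2))
    n_ctl = int(round(config.control_every_ms / dt))
    dummy = np.zeros((1, 1))

    chunk = int(round(chunk_ms / dt))
    chunk -= chunk % ou_every
    spk_cells, spk_times = [], []
    # split the eMF/UBC gating parameter sets once per receptor & pre type
    for start in range(0, n_total, chunk):
        n = min(chunk, n_total - start)
        gA = np.zeros((config.n_gc, n))
        gNm = None
        for ki, rec in enumerate(_RECEPTORS):
            R = np.empty((n_fib, n))
            for pre in ("emf", "ubc"):
                sel = [fi for fi, p in enumerate(fib_pre) if p == pre]
                if not sel:
                    continue
                p = SYNAPSE_TABLE[pre, rec]
                spk_local = [spike_steps[fi][(spike_steps[fi] >= start)
                                             & (spike_steps[fi] < start + n)] - start
                             for fi in sel]
                flat = np.concatenate(spk_local) if spk_local else np.empty(0, np.int64)
                offs = np.zeros(len(sel) + 1, dtype=np.int64)
                offs[1:] = np.cumsum([len(s) for s in spk_local])
                # fancy indexing copies: write the updated states back, or
                # every chunk would restart from virgin synapses
                states_sel = syn_states[rec][sel]
                out = synapse_gating_batch(
                    flat, offs, n, dt, p.a, p.tau_rise, p.tau_decay, p.U,
                    p.tau_rec if p.has_stp else 1.0,
                    p.tau_fac if p.has_stp else 1.0,
                    p.has_stp, states_sel)
                syn_states[rec][sel] = states_sel
                R[sel] = out
            prod = Ws[ki] @ R
            if rec == "NMDA":
                gNm = prod
            else:
                gA += prod
        noise = rng.standard_normal((config.n_gc, n // ou_every + 1))
        in_steady = (start + n) * dt <= steady_ms + 1e-9
        gain = config.control_gain if in_steady else config.control_gain_mod
        window = config.control_window_ms if in_steady \
            else config.control_window_mod_ms
        win_decay = float(np.exp(-config.control_every_ms / window))
        sc, st = gc_network_chunk(
            gA, gNm, noise, dummy, False, dt, start, state, VT,
            gc.Cm, gc.gL, gc.EK, gc.EL, gc.Vreset, gc.V_spike, n_dur, n_ref,
            gc.g_ahp_bar, gc.tau_ahp, gc.tau_ahp_x, gc.g_inh, gc.E_cl,
            ou_every, ou_a, ou_b, gc.V_E,
            True, config.rate_target, n_ctl, gain, win_decay,
            False, dummy)
        spk_cells.append(sc)
        spk_times.append(st)

    cells = np.concatenate(spk_cells)
    times = np.concatenate(spk_times)
    order = np.argsort(times, kind="stable")
    cells, times = cells[order], times[order]
    spike_times = [times[cells == g] for g in range(config.n_gc)]

    # the firing-rate controller re-converges over the first modulated
    # cycles (the modulated-input operating point differs from the steady
    # one); those transient cycles are excluded from the analysis window,
    # else their strong rate gradient aliases into a spurious late-phase
    # bias of every cell's phase histogram
    period = 1000.0 / protocol.f_mod
    n_cycles_total = int((protocol.total_ms - steady_ms) / period)
    skip = min(skip_cycles, max(n_cycles_total - 2, 0))
    t_fit = steady_ms + skip * period
    mod_ms = protocol.total_ms - t_fit
    tuning, phases, rates = [], [], []
    for g in range(config.n_gc):
        spk = spike_times[g]
        mod_spk = spk[spk >= t_fit]
        rates.append(len(mod_spk) / (mod_ms / 1000.0))
        curve = fit_tuning(mod_spk, protocol.f_mod, mod_ms,
                           n_bins=fit_bins, t_start_ms=t_fit)
        tuning.append(curve)
        phases.append(curve.phi)
    phases = np.asarray(phases)
    defined = np.isfinite(phases)
    ks = ks_uniform(phases[defined]) if defined.sum() >= 10 else np.nan
    t_burn = min(5000.0, 0.5 * steady_ms)
    burn_span_s = (protocol.total_ms - t_burn) / 1000.0
    rates_burn = np.array([np.sum(spk >= t_burn) / burn_span_s
                           for spk in spike_times])
    return NetworkResult(
        spike_times=spike_times, tuning=tuning, preferred_phases=phases,
        ks_distance=float(ks), mean_rates=np.asarray(rates),
        mean_rates_burnin=rates_burn,
        g_control=state[:, 6].copy(), config=config)


def simulate_gc(inputs, gc: GCParams = GCParams(), g_control: float = 1.0,
                duration_ms: float = 1000.0, dt: float = 0.1,
                seed: int = 0, i_inject=None, VT: float | None = None,
                control: bool = False, rate_target: float = 5.0,
                sigma_N: float | None = None):
    """Simulate a single granule cell.

    ``inputs`` is a list of (spike_times_ms, pre_type) with pre_type 'emf'
    or 'ubc'; ``i_inject`` an optional current trace in pA on the same
    grid (inward currents negative, as recorded).  Returns (spike_times,
    V_trace, final_g_control).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / dt))
    gA = np.zeros((1, n))
    gNm = np.zeros((1, n))
    for spk, pre in inputs:
        steps = np.round(np.asarray(spk) / dt).astype(np.int64)
        steps = steps[(steps >= 0) & (steps < n)]
        for rec in _RECEPTORS:
            p = SYNAPSE_TABLE[pre, rec]
            st = np.array([0.0, 0.0, 1.0, p.U])
            r = synapse_gating_chunk(steps, n, dt, p.a, p.tau_rise,
                                     p.tau_decay, p.U,
                                     p.tau_rec if p.has_stp else 1.0,
                                     p.tau_fac if p.has_stp else 1.0,
                                     p.has_stp, st)
            if rec == "NMDA":
                gNm[0] += p.gpeak / p.unit_peak * r
            else:
                gA[0] += p.gpeak / p.unit_peak * r
    sig = gc.sigma_N if sigma_N is None else sigma_N
    ou_every = 10
    ou_a = float(np.exp(-ou_every * dt / gc.tau_N))
    ou_b = sig * float(np.sqrt(1.0 - ou_a ** 2))
    noise = rng.standard_normal((1, n // ou_every + 1))
    state = np.zeros((1, 9))
    state[0, 0] = gc.EL + 20.0
    state[0, 6] = g_control
    state[0, 7] = rate_target
    vt = np.array([gc.VT_mean if VT is None else VT])
    inj = np.zeros((1, n)) if i_inject is None else np.asarray(i_inject, float).reshape(1, -1)
    has_inj = i_inject is not None
    v_out = np.empty((1, n))
    n_ctl = int(round(100.0 / dt))
    win_decay = float(np.exp(-100.0 / 5000.0))
    sc, st_ = gc_network_chunk(
        gA, gNm, noise, inj, has_inj, dt, 0, state, vt,
        gc.Cm, gc.gL, gc.EK, gc.EL, gc.Vreset, gc.V_spike,
        int(round(gc.tau_dur / dt)), int(round(gc.tau_ref / dt)),
        gc.g_ahp_bar, gc.tau_ahp, gc.tau_ahp_x, gc.g_inh, gc.E_cl,
        ou_every, ou_a, ou_b, gc.V_E,
        control, rate_target, n_ctl, 0.05, win_decay,
        True, v_out)
    if not np.all(np.isfinite(v_out)):
        raise FloatingPointError("membrane integration diverged")
    return st_, v_out[0], float(state[0, 6])
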