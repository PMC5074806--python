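# Methods

`ubcphase` models how glutamatergic synaptic diversity at the giant
mossy-fiber → unipolar-brush-cell (UBC) synapse of the vestibular
cerebellum produces diverse phase-coded responses, and how that diversity
propagates through the granular layer to enable Purkinje-cell learning of
arbitrary phase targets.  Every experimental input is replaced by a
synthetic-data generator calibrated to the published summary statistics,
so the whole pipeline runs and is tested without any recordings.

## AMPAR kinetics (`receptor_kinetics`)

The receptor is a four-state chain C ⇌ O2 ⇌ O1 ⇌ D with ligand-dependent
forward rates (α₂x for C→O2, α₁x for O2→O1), unbinding rates β₂ = β₁ =
10 ms⁻¹, desensitization on-rate α_D = 2 ms⁻¹ from O1 and recovery rate
β_D.  Defaults: α₁ = 0.03, α₂ = 0.15 µM⁻¹ms⁻¹.  β_D is never given
directly; it is fixed by requiring a 2.5% open fraction at saturating
glutamate, which for a chain gives the closed form β_D = α_D·f_sat/(1−f_sat)
≈ 0.0513 ms⁻¹.  Because D is entered from a ligand-bound state, the
steady-state open fraction is bell-shaped: with the defaults it peaks at
16.1% of total conductance at 25.6 µM and relaxes to 2.5% at saturation.
The steady state is evaluated analytically through detailed balance (the
scheme is a chain), which also serves as the oracle for the ODE
integrator.

A three-state comparison scheme C ⇌ O ⇌ D is constructed with the same
saturating open fraction and the same rising-limb half-activation
concentration, but a monotone steady-state curve; its binding rate is
solved from those two constraints.

Cleft glutamate follows per-spike step increments s into a rise variable
(τ_rise; instantaneous for receptors facing a release site) relaying into
the concentration x, which clears with the concentration-dependent time
constant τ_decay·(1 + x/u), u = 30 µM, capturing the slowed clearance of
crowded clefts.  The printed form of the clearance term is implemented
with a negative sign (decay must be dissipative).

Integration is RK4 with glutamate interpolated linearly within steps;
the step is subdivided automatically so that the fastest eigenvalue
(≈ (α₁+α₂)·x_max + β₁ + β₂ + α_D + β_D) stays inside the stability
region.  Occupancies are conserved to machine precision by construction
(closed fraction = 1 − r₂ − r₁ − d) and sub-denormal values are flushed
to zero (denormals otherwise dominate runtime).  Default dt = 0.02 ms.

**Frequency response.**  The sinusoidal-drive analysis replaces stochastic
spikes by the deterministic source s·rate(t) (the figure-level protocol is
smooth): rate(t) = [26 + 53·f·sin(2πft)]₊ Hz, per-spike transients
normalized so a single transient peaks at 2 µM with 15 ms rise and 600 ms
mono-exponential decay.  With a raw 2 µM step the mean cleft glutamate at
26 Hz would be ~0.8 µM, far below the bell peak, and no phase inversion
could occur; the peak-normalized reading puts the operating point at
~34 µM, just past the bell peak, which is the stated mechanism.  After a
settling period, five cycles are discarded and sinusoids are fitted to
glutamate and to fractional activation; amplitudes are peak-to-peak and
phases are relative to the rate modulation (peak at 90°).  The four-state
model inverts (activation ≈ 180° from glutamate above ~0.1 Hz under this
drive) and resonates at ≥ 1 Hz; the matched three-state model never
inverts and its response collapses with frequency.

## Composite EPSC model and fitting (`epsc_fitting`)

The compound train EPSC is the sum of three pools — close (τ_rise = 0),
intermediate, far — sharing the receptor constants, each with its own
conductance g and glutamate parameters (s, τ_rise, τ_decay); the current
is Σ g·(r₁+r₂)·V_hold at V_hold = −60 mV (nS·mV = pA, inward negative).
Both open states conduct equally.  The canonical demonstration geometry
(`default_pools`) uses glutamate steps (s, τ_rise, τ_decay) = (500, 0,
1.5), (500, 1, 250) and (4, 20, 250): at 50 Hz the intermediate pool's
mean glutamate s·rate·τ_rise ≈ 25 µM sits at the bell peak.

`fit_epsc` fits the 11 free parameters (g, s, τ_decay per pool; τ_rise for
intermediate and far) by bounded least squares on log-parameters with
multi-start (default 16 restarts jittered around the canonical geometry;
bounds s ∈ [0.1, 2000] µM, τ_decay ∈ [0.5, 2000] ms, τ_rise ∈ [0.1, 200] ms,
g ∈ (0, 50] nS).  The fit span runs from 50 ms before the first stimulus
(baseline) to 1.5 s after the last (rebound); simulation inside the fit
uses dt = 0.1 ms with stiffness-matched substeps segmented around the
train, and parameter corners whose glutamate buildup exceeds the substep
cap are deliberately allowed to go numerically unstable — the blow-up
guard converts them into off-scale residuals the optimizer rejects.

Identifiability: blind recovery of all 11 parameters from a single noisy
train is structurally degenerate (s–τ_rise trade-off in slow pools, g–s
trade-off at saturating glutamate, intermediate/far label ambiguity).
The recovery test suite therefore runs a *local* harness — initialization
jittered ×/÷ up to 1.4 around the truth — which verifies the optimizer
and local identifiability (median errors ≤ 20%, residual SD at the noise
floor).  Global fits remain useful for trace reproduction (residual SD
comparable to baseline noise) and phase prediction, which depend on the
waveform, not the labels.

**Phase prediction.**  The fitted model is simulated under deterministic
modulated stimulation (pulse times follow the rectified-sinusoid rate
law), the inward current is binned by cycle phase, and the exponentiated
cosine is fitted to the histogram; the predicted shift is reported
relative to the stimulation peak at 90°.  Fast-tracking cells (small,
quickly clearing transients) follow the stimulation (|Δφ| < 45°);
rebound-dominated cells (large, slowly clearing intermediate pools) are
shifted by > 90°, and removing desensitization (α_D → 0) moves them back
toward the stimulation peak — the cyclothiazide analogue.

## Data-analysis procedures (`phase_metrics`)

Phase convention: the stimulation rate peaks at 90° of the cycle; stored
phases are absolute, reported shifts subtract 90°.

*Tuning fits* use the exponentiated cosine
f(θ) = rmin + (rmax−rmin)·(e^{(k/2)cos(θ−φ)} − e^{−k/2})/(e^{k/2} − e^{−k/2}),
evaluated stably via expm1 (the k → 0 limit is the raised cosine).  Spikes
are binned at 20 bins/cycle; rate per bin = count/(cycles × bin duration).
Least squares with a moment-based phase/concentration start; an F test
against the flat model (α = 0.002, deliberately strict because the fitted
phase is optimized on the same data) flags unmodulated cells, which are
reported with rmax = rmin, k = 0 and undefined φ and excluded from phase
statistics.  With 10 cycles at typical rates, φ is recovered to a few
degrees (median < 10°); k is only weakly identified at that data volume
(its error is information-limited, shrinking with recording length), so
quantitative k claims should be confined to well-modulated cells and long
recordings.

*Train-EPSC decomposition*: the fast transient is quantified by an
exponential-plus-base fit of the first EPSC decay restricted to its
decaying phase (peak = fit amplitude, charge = amplitude × τ, steady
amplitude = fit base); the slow envelope is the interpolated
inter-stimulus minima, whose integral minus steady × duration is the
buildup charge; the offset rebound is isolated by subtracting a
forced-origin exponential (amplitude pinned to the slow envelope at
offset, τ fitted to the last 20% of the post-train decay) and fitting the
rising phase of the residue with a saturating exponential after dividing
out the residue's own falling-phase exponential (floored at 2× the peak
time; τ_ON capped at 1.5× the peak time).  On decay-consistent fixtures
(rise × decay residues with onset constants 25–99 ms) τ_ON is recovered
to within a few percent; on clearance-limited model waveforms whose rise
is nearly linear, the estimator returns a bounded operational value.

*Other measures*: CV2 = mean of 2|ISI₁−ISI₂|/(ISI₁+ISI₂); phase/delay
conversion 1000/(360·f) ms per degree (2.78 ms/deg at 1 Hz); KS distance
of preferred phases to the uniform distribution on [0°, 360°), computed
raw by default (the network comparison uses raw) with an optional
rotation-minimized variant (grid of 720 rotations).

## Stimulation and spike generation (`stimulus_protocols`)

Extrinsic mossy fibers (eMFs) follow rate(t) = [26 + 53·f·k·sign·
sin(2πft)]₊ Hz with per-fiber depth k ~ U(0,1) in the network (k = 1 for
slice protocols) and sign ±1 (in-phase/anti-phase, 50/50).  The 53 Hz/Hz
slope reproduces the ~42 Hz peak at 0.3 Hz modulation; the additive-Hz
reading of the modulation amplitude is kept across frequencies.  The
protocol is 10 s steady (26 Hz) plus 10 s modulated at 0.3/1/3 Hz.  UBC
rates evaluate the cell's tuning curve at the instantaneous cycle phase;
during the steady segment UBCs fire at their cycle-mean rate.  Spike
trains are drawn by time rescaling (unit-exponential interarrivals mapped
through the inverse cumulative intensity); deterministic stimulator
pulse trains emit a pulse at every unit crossing of the cumulative
intensity.

## Granular-layer network (`granular_network`)

Granule cells are integrate-and-fire units (C = 4.9 pF) with an
exponential KIR-like leak g_L·exp(−(V−E_L)/5) toward E_K = −90 mV, a
spike plateau (40 mV, 0.6 ms), reset to −65 mV, 2 ms refractoriness, an
afterhyperpolarization conductance (1 nS, double-exponential gating 1/3 ms),
tonic inhibition (0.9 nS, E_Cl = −75 mV), and slow Ornstein-Uhlenbeck
conductance noise (σ = 0.12 nS, τ = 1 s; exact discretization, so the
stationary SD is σ at any step).  Thresholds are drawn N(−50, 2.5) mV.

Each GC draws 4 inputs (eMF, or 50/50 eMF/UBC when UBCs are present)
through fast AMPA, slow AMPA and NMDA components with two-state gating
(r' = −r/τ_decay + a·s(1−r), rise variable s incremented by R·u per
spike) and Tsodyks-Markram short-term plasticity (facilitate u, release
R·u, deplete R).  The NMDA voltage gate is the printed sigmoidal form
(≈ 0.13 at −60 mV).  The source synapse table is typographically
corrupted; the adopted parse keeps the legible constants (eMF g_peak
0.43/0.8/0.96 nS with τ_rec = τ_fac = 600 ms and U = 0.5/0.5/0.05; UBC
g_peak 1.63/3.2/3.84 nS with τ_rec = τ_fac = 12 ms) and fills the two
unreadable decay constants with 1.0 ms (fast AMPA) and 6.0 ms (slow
AMPA); all values live in one table so alternative parses are one-line
changes.  Per-synapse peak conductances are scaled by N(1, 0.3) truncated
at 0.1.

Each cell's firing rate is held at 5 Hz by a multiplicative scaling
g_control on all its inputs, updated every 100 ms from an exponentially
windowed rate estimate.  The controller runs on a schedule: gain 0.2 with
a 1 s window during the steady burn-in (fast convergence; there is no
modulation to distort), then gain 0.15 with a 5 s window during the
modulated span.  The modulated-span setting was chosen from single-cell
phase-distortion measurements: a controller tracking near the modulation
period partially cancels the within-cycle rate modulation and adds tens
of degrees of scatter to preferred phases, while the chosen setting adds
~13°, comparable to the tuning-fit estimation noise.  Residual controller
wander leaves individual 10 s rate estimates spread around the target
(population mean within a few percent; most cells within 3–7 Hz).

The full network (4500 GCs, 500 eMFs, 500 UBCs; dt = 0.1 ms) runs the
10 s + 10 s protocol; per-cell tuning is fitted on the modulated span and
the population KS distance to uniform is computed over cells with a
defined preferred phase.  Simulation is chunked in time (sparse
fiber→cell conductance products per chunk, compiled membrane kernel),
keeping the full run within a few hundred MB and a few minutes of CPU.

Granule cells whose four inputs share a modulation phase lock to it
(plus a ~25–45° synaptic lag); a UBC pool covering all phases drives a
near-uniform GC phase distribution.  Under the full study conditions,
however — 50/50 in/anti-phase eMFs with uniform modulation depths, the
corrupted-table synapse constants as parsed, and the printed 0.12 nS slow
conductance noise — the per-cell net drive modulation is weak relative to
the noise, so both network variants' preferred-phase distributions end up
close to uniform (KS ≈ 0.05–0.09 at 1 Hz) rather than showing the strong
no-UBC clustering the original analysis reports — see Limitations.

## Purkinje learning (`purkinje_learning`)

The PC is a linear rate unit over the GC population.  Targets are
r̄(1 + cos(θ − φ)) with r̄ = 32 Hz; weights start at 0.5 and follow the
clipped delta rule driven by the climbing-fiber error E = target − output.
The printed per-update rule Δw = η·r·E with η = 0.001 and rates in Hz is
unstable at the full network size (per-bin loop gain η·Σr² ≈ 10²); the
implementation treats the rule as the discretization of dw/dt = η·r·E,
i.e. the bin update is η·r·E·Δt with Δt the bin duration in seconds,
which makes the printed η stable.  Updates sweep 100 phase bins per cycle
for up to 10000 cycles with early stopping (relative MSE change < 1e-6
over 100 cycles) and a divergence guard (sustained rises above twice the
best MSE).  Rate matrices binned from only ~10 modulation cycles are
Poisson-noisy enough to push the loop gain past the stability boundary,
so `rate_matrix_from_network` applies a 3-bin circular boxcar — a stand-in
for the trial averaging of a longer experiment — and `train_pc`
additionally caps the step so the largest per-bin loop gain stays below
1.5 (the cap affects convergence speed only, never the fixed point).  With clipping, training
approaches the nonnegative-least-squares optimum (verified within 10% on
synthetic tuning banks); a bank restricted to two antipodal phases cannot
reach quadrature targets, which is the mechanism probed by the
with/without-UBC comparison.

## Synthetic data (`synthetic_data`)

*UBC populations*: ON cells (n = 22) draw preferred phases from a wrapped
normal (140°, SD 105°), concentration factors from a truncated normal
(0.9 ± 1.5, > 0.05), modulation amplitudes 12 ± 23 Hz (≥ 0.5) and
baselines 11.7 ± 9.2 Hz (≥ 0); OFF cells (n = 25) use (274°, 28°),
k 2.2 ± 1.2, modulation 12 ± 8 Hz and zero baseline (their silencing
outside the burst phase is represented purely through rmin = 0; no mGluR2
mechanism is simulated).  Marginals are independent — the joint
distribution of the recorded cells is not published.

*EPSC datasets*: each surrogate cell draws pool parameters log-normally
(kinetics ×/÷ ~1.3 typical, conductances ×/÷ ~2, truncated at ×/÷4)
around centres calibrated so the measured population reproduces the
reported train statistics — fast transients of tens of pA decaying in
~1 ms, steady currents of 10–20 pA, and offset rebounds whose onset
constants span ~25–99 ms (centres: close 400 µM/0/1.2 ms/1 nS,
intermediate 60 µM/20 ms/10 ms/2 nS, far 4 µM/20 ms/150 ms/0.6 nS).
Gaussian baseline noise of SD 0.7 pA is added; ground truth is returned
separately from the traces and never written into fixture files used by
fitting tests.

## Problem sizes used in tests and the acceptance script

Receptor analyses run at full stated precision (they are cheap).  The
network checks run the full 4500-cell, 10 s + 10 s protocol once per
variant; unit tests use a 300-cell network.  EPSC fit-recovery tests use
4 surrogate cells with 2 restarts from truth-adjacent starts; tuning
round-trips use the 47-cell surrogate pool at 10 cycles.

## Known limitations

* The network-level KS comparison is not reproduced quantitatively: the
  published synapse table is typographically corrupted, and under the
  adopted parse the per-cell eMF drive modulation (after phase mixing,
  depression and rate-control downscaling) is weak relative to the printed
  membrane noise, so granule-cell preferred phases are nearly uniform with
  or without UBCs instead of strongly clustered without them.  The
  mechanism itself — phase-diverse UBC input spreading GC phases — is
  verified directly with controlled pools; the absolute KS values are
  sensitive to the unrecoverable synaptic constants.  A corollary is that
  the Purkinje cell learns every target phase in both network variants
  here, so the learning contrast between variants is much smaller than in
  the original analysis.
* k (concentration factor) estimates from ~10 cycles are
  information-limited; only φ is reliable at that data volume.
* OFF and complex UBCs enter only via tuning curves; mGluR biophysics,
  Golgi-cell dynamics, and spatial glomerular structure are out of scope.
* The delta-rule stability analysis assumes trial-averaged (smoothed)
  rate matrices; raw single-trial matrices at full size sit at the edge
  of stability by the printed learning rate.
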