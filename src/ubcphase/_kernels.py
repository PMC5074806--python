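"""Numba-compiled inner loops for receptor, glutamate and network integration.

Everything here works on plain float64 arrays in fixed units (ms, µM, nS,
mV, pA); the public modules wrap these kernels with typed containers.
"""

import numpy as np
from numba import njit


@njit
def integrate_four_state(x, dt, a1, a2, aD, bD, b1, b2, r2_0, r1_0, d_0, n_sub=1):
    """RK4 integration of the C<->O2<->O1<->D chain along a glutamate trace.

    ``x`` is the glutamate concentration (µM) on a uniform grid of step
    ``dt`` (ms); each grid interval is split into ``n_sub`` RK4 substeps
    with linearly interpolated glutamate for stiff (high-concentration)
    regimes.  Returns an (n, 3) array of (r2, r1, d); the closed fraction
    is 1 - r2 - r1 - d by conservation.
    """
    n = x.shape[0]
    out = np.empty((n, 3))
    r2, r1, d = r2_0, r1_0, d_0
    out[0, 0], out[0, 1], out[0, 2] = r2, r1, d
    h = dt / n_sub
    for i in range(n - 1):
        for j in range(n_sub):
            f0 = j / n_sub
            f1 = (j + 1) / n_sub
            x0 = x[i] * (1 - f0) + x[i + 1] * f0
            x1 = x[i] * (1 - f1) + x[i + 1] * f1
            xm = 0.5 * (x0 + x1)

            c = 1.0 - r1 - r2 - d
            k1_r2 = a2 * x0 * c - (b2 + a1 * x0) * r2 + b1 * r1
            k1_r1 = a1 * x0 * r2 - (b1 + aD) * r1 + bD * d
            k1_d = aD * r1 - bD * d
            t_r2 = r2 + 0.5 * h * k1_r2
            t_r1 = r1 + 0.5 * h * k1_r1
            t_d = d + 0.5 * h * k1_d
            c = 1.0 - t_r1 - t_r2 - t_d
            k2_r2 = a2 * xm * c - (b2 + a1 * xm) * t_r2 + b1 * t_r1
            k2_r1 = a1 * xm * t_r2 - (b1 + aD) * t_r1 + bD * t_d
            k2_d = aD * t_r1 - bD * t_d
            t_r2 = r2 + 0.5 * h * k2_r2
            t_r1 = r1 + 0.5 * h * k2_r1
            t_d = d + 0.5 * h * k2_d
            c = 1.0 - t_r1 - t_r2 - t_d
            k3_r2 = a2 * xm * c - (b2 + a1 * xm) * t_r2 + b1 * t_r1
            k3_r1 = a1 * xm * t_r2 - (b1 + aD) * t_r1 + bD * t_d
            k3_d = aD * t_r1 - bD * t_d
            t_r2 = r2 + h * k3_r2
            t_r1 = r1 + h * k3_r1
            t_d = d + h * k3_d
            c = 1.0 - t_r1 - t_r2 - t_d
            k4_r2 = a2 * x1 * c - (b2 + a1 * x1) * t_r2 + b1 * t_r1
            k4_r1 = a1 * x1 * t_r2 - (b1 + aD) * t_r1 + bD * t_d
            k4_d = aD * t_r1 - bD * t_d

            r2 += h / 6.0 * (k1_r2 + 2 * k2_r2 + 2 * k3_r2 + k4_r2)
            r1 += h / 6.0 * (k1_r1 + 2 * k2_r1 + 2 * k3_r1 + k4_r1)
            d += h / 6.0 * (k1_d + 2 * k2_d + 2 * k3_d + k4_d)
        # flush denormal-range occupancies (they stall the FPU)
        if -1e-30 < r2 < 1e-30:
            r2 = 0.0
        if -1e-30 < r1 < 1e-30:
            r1 = 0.0
        if -1e-30 < d < 1e-30:
            d = 0.0
        # numerical blow-up guard: fill the remainder with an off-scale
        # value so a caller's residual rejects this parameter corner
        if not (-1.0 <= r2 <= 2.0 and -1.0 <= r1 <= 2.0 and -1.0 <= d <= 2.0):
            out[i + 1:, :] = 1e3
            return out
        out[i + 1, 0], out[i + 1, 1], out[i + 1, 2] = r2, r1, d
    return out


@njit
def integrate_three_state(x, dt, a, b, aD, bD, o_0, d_0, n_sub=1):
    """RK4 integration of the comparison C<->O<->D scheme. Returns (n, 2): (o, d)."""
    n = x.shape[0]
    out = np.empty((n, 2))
    o, d = o_0, d_0
    out[0, 0], out[0, 1] = o, d
    h = dt / n_sub
    for i in range(n - 1):
        for j in range(n_sub):
            f0 = j / n_sub
            f1 = (j + 1) / n_sub
            x0 = x[i] * (1 - f0) + x[i + 1] * f0
            x1 = x[i] * (1 - f1) + x[i + 1] * f1
            xm = 0.5 * (x0 + x1)

            k1_o = a * x0 * (1.0 - o - d) - (b + aD) * o + bD * d
            k1_d = aD * o - bD * d
            t_o = o + 0.5 * h * k1_o
            t_d = d + 0.5 * h * k1_d
            k2_o = a * xm * (1.0 - t_o - t_d) - (b + aD) * t_o + bD * t_d
            k2_d = aD * t_o - bD * t_d
            t_o = o + 0.5 * h * k2_o
            t_d = d + 0.5 * h * k2_d
            k3_o = a * xm * (1.0 - t_o - t_d) - (b + aD) * t_o + bD * t_d
            k3_d = aD * t_o - bD * t_d
            t_o = o + h * k3_o
            t_d = d + h * k3_d
            k4_o = a * x1 * (1.0 - t_o - t_d) - (b + aD) * t_o + bD * t_d
            k4_d = aD * t_o - bD * t_d

            o += h / 6.0 * (k1_o + 2 * k2_o + 2 * k3_o + k4_o)
            d += h / 6.0 * (k1_d + 2 * k2_d + 2 * k3_d + k4_d)
        if -1e-30 < o < 1e-30:
            o = 0.0
        if -1e-30 < d < 1e-30:
            d = 0.0
        out[i + 1, 0], out[i + 1, 1] = o, d
    return out


@njit
def glut_from_spikes(spike_steps, n, dt, s, tau_rise, tau_decay, u, saturating):
    """Cleft glutamate concentration driven by presynaptic spikes.

    Instantaneous-rise pools (tau_rise == 0) receive a step ``s`` per spike
    directly in x; otherwise the step enters a rise variable y that relaxes
    into x.  With ``saturating`` the decay time constant is
    tau_decay*(1 + x/u), slowing clearance at high concentration.
    """
    x = np.zeros(n)
    k = 0
    n_spk = spike_steps.shape[0]
    xv = 0.0
    yv = 0.0
    decay_fac = np.exp(-dt / tau_decay)
    rise_fac = np.exp(-dt / tau_rise) if tau_rise > 0 else 0.0
    for i in range(n):
        while k < n_spk and spike_steps[k] == i:
            if tau_rise > 0:
                yv += s
            else:
                xv += s
            k += 1
        x[i] = xv
        if tau_rise > 0:
            # RK4 on x with y known analytically within the step
            y_mid = yv * np.exp(-0.5 * dt / tau_rise)
            y_end = yv * rise_fac
            if saturating:
                k1 = (yv - xv) / (tau_decay * (1.0 + xv / u))
                t = xv + 0.5 * dt * k1
                k2 = (y_mid - t) / (tau_decay * (1.0 + t / u))
                t = xv + 0.5 * dt * k2
                k3 = (y_mid - t) / (tau_decay * (1.0 + t / u))
                t = xv + dt * k3
                k4 = (y_end - t) / (tau_decay * (1.0 + t / u))
            else:
                k1 = (yv - xv) / tau_decay
                t = xv + 0.5 * dt * k1
                k2 = (y_mid - t) / tau_decay
                t = xv + 0.5 * dt * k2
                k3 = (y_mid - t) / tau_decay
                t = xv + dt * k3
                k4 = (y_end - t) / tau_decay
            xv += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            yv = y_end
        else:
            if saturating:
                k1 = -xv / (tau_decay * (1.0 + xv / u))
                t = xv + 0.5 * dt * k1
                k2 = -t / (tau_decay * (1.0 + t / u))
                t = xv + 0.5 * dt * k2
                k3 = -t / (tau_decay * (1.0 + t / u))
                t = xv + dt * k3
                k4 = -t / (tau_decay * (1.0 + t / u))
                xv += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            else:
                xv *= decay_fac
        if xv < 1e-12:
            xv = 0.0
        if yv < 1e-12:
            yv = 0.0
    return x


@njit
def glut_from_rate(rate_per_ms, dt, s, tau_rise, tau_decay, u, saturating):
    """Deterministic glutamate drive: spikes replaced by a continuous source
    s * rate(t).  Used for the smooth frequency-response protocol."""
    n = rate_per_ms.shape[0]
    x = np.zeros(n)
    xv = 0.0
    yv = 0.0
    for i in range(n - 1):
        x[i] = xv
        nu0 = rate_per_ms[i]
        nu1 = rate_per_ms[i + 1]
        num = 0.5 * (nu0 + nu1)
        if tau_rise > 0:
            k1y = -yv / tau_rise + s * nu0
            ty = yv + 0.5 * dt * k1y
            k2y = -ty / tau_rise + s * num
            ty = yv + 0.5 * dt * k2y
            k3y = -ty / tau_rise + s * num
            ty = yv + dt * k3y
            k4y = -ty / tau_rise + s * nu1
            y_mid2 = yv + 0.5 * dt * k2y  # midpoint estimate for x stages
            if saturating:
                k1 = (yv - xv) / (tau_decay * (1.0 + xv / u))
                t = xv + 0.5 * dt * k1
                k2 = (y_mid2 - t) / (tau_decay * (1.0 + t / u))
                t = xv + 0.5 * dt * k2
                k3 = (y_mid2 - t) / (tau_decay * (1.0 + t / u))
                t = xv + dt * k3
                y_end = yv + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
                k4 = (y_end - t) / (tau_decay * (1.0 + t / u))
            else:
                k1 = (yv - xv) / tau_decay
                t = xv + 0.5 * dt * k1
                k2 = (y_mid2 - t) / tau_decay
                t = xv + 0.5 * dt * k2
                k3 = (y_mid2 - t) / tau_decay
                t = xv + dt * k3
                y_end = yv + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
                k4 = (y_end - t) / tau_decay
            xv += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            yv = y_end
        else:
            if saturating:
                k1 = -xv / (tau_decay * (1.0 + xv / u)) + s * nu0
                t = xv + 0.5 * dt * k1
                k2 = -t / (tau_decay * (1.0 + t / u)) + s * num
                t = xv + 0.5 * dt * k2
                k3 = -t / (tau_decay * (1.0 + t / u)) + s * num
                t = xv + dt * k3
                k4 = -t / (tau_decay * (1.0 + t / u)) + s * nu1
            else:
                k1 = -xv / tau_decay + s * nu0
                t = xv + 0.5 * dt * k1
                k2 = -t / tau_decay + s * num
                t = xv + 0.5 * dt * k2
                k3 = -t / tau_decay + s * num
                t = xv + dt * k3
                k4 = -t / tau_decay + s * nu1
            xv += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if xv < 1e-12:
            xv = 0.0
        if yv < 1e-12:
            yv = 0.0
    x[n - 1] = xv
    return x




@njit
def synapse_gating_chunk(spike_steps, n, dt, a, tau_rise, tau_decay,
                         U, tau_rec, tau_fac, has_stp, state):
    """Two-state synaptic gating r with rise variable s and Tsodyks-Markram
    short-term plasticity, over one time chunk.

    ``spike_steps`` are presynaptic spike indices relative to the chunk
    start; ``state`` = [s, r, R, u] carries the synapse across chunks and is
    updated in place.  Spike order of operations: facilitation increment of
    u, efficacy R*u with the incremented u, then depletion of R.  Returns
    the gating trace r (n,).
    """
    r_out = np.empty(n)
    sv, rv, R, uv = state[0], state[1], state[2], state[3]
    k = 0
    n_spk = spike_steps.shape[0]
    s_decay = np.exp(-dt / tau_rise)
    rec_fac = np.exp(-dt / tau_rec) if has_stp else 1.0
    fac_fac = np.exp(-dt / tau_fac) if has_stp else 1.0
    for i in range(n):
        while k < n_spk and spike_steps[k] == i:
            if has_stp:
                uv += U * (1.0 - uv)
                eff = R * uv
                R -= uv * R
            else:
                eff = U
            sv += eff
            k += 1
        r_out[i] = rv
        # r' = -r/tau_decay + a*s*(1-r): linear in r with s frozen over dt
        gtot = 1.0 / tau_decay + a * sv
        rinf = a * sv / gtot
        rv = rinf + (rv - rinf) * np.exp(-dt * gtot)
        sv *= s_decay
        if sv < 1e-30:
            sv = 0.0
        if rv < 1e-30:
            rv = 0.0
        if has_stp:
            R = 1.0 + (R - 1.0) * rec_fac
            uv = U + (uv - U) * fac_fac
    state[0], state[1], state[2], state[3] = sv, rv, R, uv
    return r_out


@njit
def _gc_tables(gL, EL, dt, C):
    """Lookup tables for the V-dependent factors on a fine voltage grid."""
    v = np.arange(-100.0, 45.0001, 0.01)
    kir_tab = gL * np.exp(-(v - EL) / 5.0)
    ynm_tab = 1.0 / (1.0 + np.exp(-(v - 84.0) / 38.0) /
                     (np.exp((v + 119.0) / 38.0) + np.exp(-(v + 45.0) / 28.0)))
    z = np.arange(0.0, 3.0001, 0.0005)
    exp_tab = np.exp(-z)
    return v, kir_tab, ynm_tab, exp_tab


@njit(inline='always')
def _tab(tab, x0, inv_dx, x):
    p = (x - x0) * inv_dx
    if p <= 0.0:
        return tab[0]
    i = int(p)
    if i >= tab.shape[0] - 1:
        return tab[tab.shape[0] - 1]
    f = p - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit
def gc_network_chunk(g_ampa, g_nmda, noise, i_inject, has_inj, dt, step0,
                     state, VT_arr,
                     C, gL, EK, EL, Vreset, V_spike, n_dur, n_ref,
                     g_ahp_bar, tau_ahp, tau_ahp_x, g_inh, E_cl,
                     ou_every, ou_a, ou_b, V_E,
                     control_on, rate_target, n_ctl, control_gain, win_decay,
                     store_v, v_out):
    """Integrate-and-fire granule cells over one time chunk.

    g_ampa / g_nmda: (n_gc, n) summed synaptic conductances (nS);
    noise: (n_gc, n_ou) standard-normal draws consumed every ``ou_every``
    steps by the exact Ornstein-Uhlenbeck update; i_inject: (n_gc, n)
    injected current in pA (ignored unless has_inj);
    state: (n_gc, 9) rows [V, z_ahp, x_ahp, gN, plateau_left, ref_left,
    g_control, rate_est, count_in_win], updated in place; step0 is the
    absolute index of the chunk start (rate-control cadence is phased on
    absolute steps).  Returns (spike_cells, spike_times).
    """
    n_gc, n = g_ampa.shape
    _, kir_tab, ynm_tab, exp_tab = _gc_tables(gL, EL, dt, C)
    inv_dv = 100.0
    inv_dz = 2000.0
    max_spk = n_gc * (n // (n_dur + n_ref) + 2)
    spk_c = np.empty(max_spk, dtype=np.int64)
    spk_t = np.empty(max_spk)
    m = 0
    dxa = np.exp(-dt / tau_ahp_x)
    for g in range(n_gc):
        V = state[g, 0]
        z_ahp = state[g, 1]
        x_ahp = state[g, 2]
        gN = state[g, 3]
        plateau_left = int(state[g, 4])
        ref_left = int(state[g, 5])
        g_control = state[g, 6]
        rate_est = state[g, 7]
        count_in_win = state[g, 8]
        VT = VT_arr[g]
        iou = 0
        for i in range(n):
            step = step0 + i
            if step % ou_every == 0:
                gN = ou_a * gN + ou_b * noise[g, iou]
                iou += 1
            if store_v:
                v_out[g, i] = V
            if plateau_left > 0:
                plateau_left -= 1
                if plateau_left == 0:
                    V = Vreset
                    x_ahp += 1.0
                    ref_left = n_ref
                else:
                    V = V_spike
            elif ref_left > 0:
                ref_left -= 1
                V = Vreset
            else:
                kir = _tab(kir_tab, -100.0, inv_dv, V)
                ynm = _tab(ynm_tab, -100.0, inv_dv, V)
                g_exc = g_control * (g_ampa[g, i] + g_nmda[g, i] * ynm)
                gtot = kir + g_ahp_bar * z_ahp + gN + g_inh + g_exc
                isum = (kir * EK + g_ahp_bar * z_ahp * EK + gN * V_E +
                        g_inh * E_cl)
                if has_inj:
                    isum -= i_inject[g, i]
                Vinf = isum / gtot
                z = dt * gtot / C
                ef = _tab(exp_tab, 0.0, inv_dz, z) if z < 3.0 else np.exp(-z)
                V = Vinf + (V - Vinf) * ef
                if V >= VT:
                    spk_c[m] = g
                    spk_t[m] = step * dt
                    m += 1
                    count_in_win += 1.0
                    plateau_left = n_dur
                    V = V_spike
            x_ahp *= dxa
            z_ahp += dt * (x_ahp * (1.0 - z_ahp) - z_ahp / tau_ahp)
            if control_on and step > 0 and step % n_ctl == 0:
                inst = count_in_win / (n_ctl * dt / 1000.0)
                rate_est = win_decay * rate_est + (1.0 - win_decay) * inst
                count_in_win = 0.0
                g_control *= 1.0 + control_gain * (rate_target - rate_est) / rate_target
                if g_control < 1e-3:
                    g_control = 1e-3
                elif g_control > 1e3:
                    g_control = 1e3
        state[g, 0] = V
        state[g, 1] = z_ahp
        state[g, 2] = x_ahp
        state[g, 3] = gN
        state[g, 4] = plateau_left
        state[g, 5] = ref_left
        state[g, 6] = g_control
        state[g, 7] = rate_est
        state[g, 8] = count_in_win
    return spk_c[:m], spk_t[:m]


@njit
def synapse_gating_batch(spk_flat, offsets, n, dt, a, tau_rise, tau_decay,
                         U, tau_rec, tau_fac, has_stp, states):
    """synapse_gating_chunk over a batch of fibers sharing receptor params.

    spk_flat / offsets: concatenated per-fiber spike steps (CSR-style);
    states: (n_fib, 4) carried across chunks.  Returns (n_fib, n) gating.
    """
    n_fib = offsets.shape[0] - 1
    out = np.empty((n_fib, n))
    for f in range(n_fib):
        out[f] = synapse_gating_chunk(
            spk_flat[offsets[f]:offsets[f + 1]], n, dt, a, tau_rise,
            tau_decay, U, tau_rec, tau_fac, has_stp, states[f])
    return out
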