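"""Vectorized network integration kernel (numba).

Implements the same per-cell dynamics as the scalar reference in
:mod:`maskingnet.cells`: exponential-Euler compartment voltages, table-driven
Hodgkin–Huxley gating at the initial segment, calcium-pool adaptation,
single-exponential synaptic conductances with NMDA magnesium block, and
per-source short-term depression.  Delayed spike delivery goes through a
circular delay-line ring buffer keyed by delay-in-steps, which makes event
delivery exact and allocation-free.

Hot-loop numerics: voltage-relaxation exponentials and gating factors come
from fine lookup tables (linear interpolation; voltage grid 0.05 mV,
exp(-x) grid 2^-10), and synaptic conductance state is float32.  Both choices
are deterministic and keep membrane potentials accurate to far below the
0.05 mV table resolution.  Replay with the same seeds on the same machine
is bit-identical; fastmath is enabled, so trajectories may differ across
CPU generations (statistically equivalent realizations of the same model).

Status codes returned by :func:`run_kernel`: 0 ok, 1 spike-buffer overflow,
2 numerical instability (bad cell id and step reported).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import cells as C

#: gating/NMDA lookup-table voltage range
TAB_VMIN = -150.0
TAB_VMAX = 80.0
TAB_STEP = 0.05

#: exp(-x) lookup table range and resolution
EXP_XMAX = 16.0
EXP_INV_STEP = 1024.0


def build_gating_tables(dt: float):
    """Tabulate gating steady states, per-step relaxation factors and the
    NMDA block factor on a fine voltage grid.  Columns: m_inf, m_fac, h_inf,
    h_fac, n_inf, n_fac, nmda_block — fused so one index lookup serves all
    gates."""
    v = np.arange(TAB_VMIN, TAB_VMAX + TAB_STEP, TAB_STEP)
    cols = []
    for fa, fb in ((C.alpha_m, C.beta_m), (C.alpha_h, C.beta_h),
                   (C.alpha_n, C.beta_n)):
        a = np.array([fa(x) for x in v])
        b = np.array([fb(x) for x in v])
        tau = 1.0 / (a + b)
        cols += [a * tau, np.exp(-dt / tau)]
    cols.append(np.array([C.nmda_block(x) for x in v]))
    gtab = np.ascontiguousarray(np.stack(cols, axis=1))
    return np.float64(TAB_VMIN), np.float64(1.0 / TAB_STEP), gtab


def build_expneg_table():
    x = np.arange(0.0, EXP_XMAX + 2.0 / EXP_INV_STEP, 1.0 / EXP_INV_STEP)
    return np.exp(-x)


@njit(cache=True, inline="always", fastmath=True)
def _tab_index(n, vmin, inv_step, v):
    x = (v - vmin) * inv_step
    if x < 0.0:
        x = 0.0
    hi = n - 1.001
    if x > hi:
        x = hi
    i = int(x)
    return i, x - i


@njit(cache=True, inline="always", fastmath=True)
def _expneg(tab, x):
    # exp(-x) for x >= 0, clamped at the table end (exp(-16) ~ 1e-7 ~ 0)
    x *= EXP_INV_STEP
    hi = tab.shape[0] - 1.001
    if x > hi:
        x = hi
    i = int(x)
    f = x - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True, inline="always")
def _lcg(state):
    # 64-bit LCG (Knuth constants); returns uniform in [0, 1)
    s = state[0] * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    state[0] = s
    return np.float64(s >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True)
def run_kernel(n_steps, dt,
               cls, V, m, h, nk, ca, gsyn, last_spike,
               ncomp, cap, gl, el, gc_is, gc_dend, gc_ap,
               g_na, g_k, dca, ca_fac, g_ahp,
               slot_decay, slot_E,
               vmin, inv_step, gtab, expneg,
               indptr, syn_tgt, syn_slot, syn_w, syn_dstep,
               dep_r, dep_last, dep_U, dep_tau,
               ring, f_step, f_src,
               p_bg, w_bg, rng_state, i_ext,
               record_mask, n_relay,
               out_cell, out_step,
               refrac_steps, v_thresh):
    n = cls.shape[0]
    D = ring.shape[0]
    max_ev = out_cell.shape[0]
    ne = 0
    fp = 0
    nf = f_step.shape[0]
    E_NA = 50.0
    E_K = -90.0
    for t in range(n_steps):
        tmod = t % D
        tm = t * dt
        # forced spike events scheduled for this step
        while fp < nf and f_step[fp] == t:
            src = f_src[fp]
            fp += 1
            if ne >= max_ev:
                return 1, ne, -1, t
            out_cell[ne] = src
            out_step[ne] = t
            ne += 1
            # depression + fan-out
            r = 1.0 - (1.0 - dep_r[src]) * np.exp(-(tm - dep_last[src]) / dep_tau[src])
            dep_r[src] = r * (1.0 - dep_U[src])
            dep_last[src] = tm
            if src >= n_relay:
                last_spike[src - n_relay] = t
            for k in range(indptr[src], indptr[src + 1]):
                ring[(t + syn_dstep[k]) % D, syn_tgt[k], syn_slot[k]] += syn_w[k] * r

        for i in range(n):
            c = cls[i]
            # deliver ring + decay conductances
            for s in range(6):
                gsyn[i, s] = gsyn[i, s] * slot_decay[s] + ring[tmod, i, s]
                ring[tmod, i, s] = 0.0
            # background Poisson (excitatory, somatic AMPA)
            if p_bg > 0.0 and _lcg(rng_state) < p_bg:
                gsyn[i, 5] += w_bg[i]

            v0 = V[i, 0]
            v1 = V[i, 1]
            v2 = V[i, 2]
            v3 = V[i, 3]
            four = ncomp[c] == 4
            # --- soma ---
            gahp = g_ahp[c] * ca[i]
            g2 = np.float64(gsyn[i, 2])
            g5 = np.float64(gsyn[i, 5])
            gtot = gl[c, 0] + gc_is[c] + gc_dend[c] + gahp + g2 + g5
            gE = (gl[c, 0] * el + gc_is[c] * v1 + gc_dend[c] * v2 + gahp * E_K
                  + g2 * slot_E[2] + g5 * slot_E[5] + i_ext[i])
            if four:
                gtot += gc_ap[c]
                gE += gc_ap[c] * v3
            vinf = gE / gtot
            nv0 = vinf + (v0 - vinf) * _expneg(expneg, dt * gtot / cap[c, 0])
            # --- initial segment ---
            gna = g_na[c] * m[i] * m[i] * m[i] * h[i]
            gkk = g_k[c] * nk[i] * nk[i] * nk[i] * nk[i]
            gtot = gl[c, 1] + gc_is[c] + gna + gkk
            gE = gl[c, 1] * el + gc_is[c] * v0 + gna * E_NA + gkk * E_K
            vinf = gE / gtot
            nv1 = vinf + (v1 - vinf) * _expneg(expneg, dt * gtot / cap[c, 1])
            # --- basal / generic dendrite ---
            gi, gf = _tab_index(gtab.shape[0], vmin, inv_step, v2)
            bnm = gtab[gi, 6] * (1.0 - gf) + gtab[gi + 1, 6] * gf
            gs = np.float64(gsyn[i, 0]) + np.float64(gsyn[i, 1]) * bnm
            gtot = gl[c, 2] + gc_dend[c] + gs
            gE = gl[c, 2] * el + gc_dend[c] * v0  # excitatory reversal 0 mV
            vinf = gE / gtot
            nv2 = vinf + (v2 - vinf) * _expneg(expneg, dt * gtot / cap[c, 2])
            # --- apical dendrite (pyramidal only) ---
            if four:
                gi, gf = _tab_index(gtab.shape[0], vmin, inv_step, v3)
                bnm = gtab[gi, 6] * (1.0 - gf) + gtab[gi + 1, 6] * gf
                gs = np.float64(gsyn[i, 3]) + np.float64(gsyn[i, 4]) * bnm
                gtot = gl[c, 3] + gc_ap[c] + gs
                gE = gl[c, 3] * el + gc_ap[c] * v0
                vinf = gE / gtot
                nv3 = vinf + (v3 - vinf) * _expneg(expneg, dt * gtot / cap[c, 3])
            else:
                nv3 = v3

            # gating relaxes toward steady state at the old IS potential
            gi, gf = _tab_index(gtab.shape[0], vmin, inv_step, v1)
            g0 = 1.0 - gf
            xi = gtab[gi, 0] * g0 + gtab[gi + 1, 0] * gf
            m[i] = xi + (m[i] - xi) * (gtab[gi, 1] * g0 + gtab[gi + 1, 1] * gf)
            xi = gtab[gi, 2] * g0 + gtab[gi + 1, 2] * gf
            h[i] = xi + (h[i] - xi) * (gtab[gi, 3] * g0 + gtab[gi + 1, 3] * gf)
            xi = gtab[gi, 4] * g0 + gtab[gi + 1, 4] * gf
            nk[i] = xi + (nk[i] - xi) * (gtab[gi, 5] * g0 + gtab[gi + 1, 5] * gf)
            ca[i] *= ca_fac[c]

            if not (-200.0 < nv0 < 200.0 and -200.0 < nv1 < 200.0):
                return 2, ne, i + n_relay, t

            V[i, 0] = nv0
            V[i, 1] = nv1
            V[i, 2] = nv2
            V[i, 3] = nv3

            # spike: upward threshold crossing at the IS, outside refractory
            if nv1 >= v_thresh and v1 < v_thresh and t - last_spike[i] >= refrac_steps:
                last_spike[i] = t
                ca[i] += dca[c]
                if record_mask[i]:
                    if ne >= max_ev:
                        return 1, ne, -1, t
                    out_cell[ne] = i + n_relay
                    out_step[ne] = t
                    ne += 1
                src = i + n_relay
                r = 1.0 - (1.0 - dep_r[src]) * np.exp(-(tm - dep_last[src]) / dep_tau[src])
                dep_r[src] = r * (1.0 - dep_U[src])
                dep_last[src] = tm
                for k in range(indptr[src], indptr[src + 1]):
                    ring[(t + syn_dstep[k]) % D, syn_tgt[k], syn_slot[k]] += syn_w[k] * r
    return 0, ne, -1, -1
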