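"""Conductance-based multi-compartment cell dynamics.

Four cell classes are modeled: pyramidal cells (four compartments: soma,
initial segment, basal dendrite, apical dendrite), basket and RSNP
interneurons (three compartments: soma, initial segment, dendrite) and LGN
relay cells.  Spikes are generated by Hodgkin–Huxley-type Na/K currents on
the initial segment; the soma carries a calcium pool driving a potassium
after-hyperpolarization current, which makes pyramidal cells adapting, RSNP
cells weakly adapting, and basket and relay cells non-adapting.

Synaptic input arrives through AMPA/kainate, NMDA (voltage-dependent) and
GABA_A conductances; every synaptic channel carries single-release-variable
short-term depression.  All cortical cells receive 300 Hz of excitatory
Poisson background producing a small positive bias; relay cells receive no
background and are driven only by scheduled stimulation.

Units: mV, ms, uS (conductance), nF (capacitance), nA (current).

This module holds the scalar reference dynamics used by the unit tests and
the parameter containers; :mod:`maskingnet._kernel` implements the same
update vectorized for whole-network runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .architecture import CellClass

# Compartment indices (3-compartment cells use DEND and leave APICAL unused).
SOMA, INITSEG, DEND, APICAL = 0, 1, 2, 3

# Receptor indices.
AMPA, NMDA, GABA_A = 0, 1, 2

# Synaptic conductance slots: (receptor, compartment) pairs actually wired.
SLOT_AMPA_DEND = 0
SLOT_NMDA_DEND = 1
SLOT_GABA_SOMA = 2
SLOT_AMPA_APICAL = 3
SLOT_NMDA_APICAL = 4
SLOT_AMPA_SOMA = 5
N_SLOTS = 6

SLOT_OF = {(AMPA, DEND): SLOT_AMPA_DEND, (NMDA, DEND): SLOT_NMDA_DEND,
           (GABA_A, SOMA): SLOT_GABA_SOMA, (AMPA, APICAL): SLOT_AMPA_APICAL,
           (NMDA, APICAL): SLOT_NMDA_APICAL, (AMPA, SOMA): SLOT_AMPA_SOMA}

E_NA = 50.0
E_K = -90.0
SPIKE_THRESHOLD = 0.0   # mV, upward crossing at the initial segment
REFRACTORY_MS = 2.0


@dataclass(frozen=True)
class ReceptorChannel:
    """Kinetics of one synaptic receptor type.

    Rise times are fast relative to the decay for AMPA and GABA_A and are
    folded into an instantaneous-rise, single-exponential-decay conductance;
    NMDA additionally carries the magnesium-block voltage dependence
    B(V) = 1 / (1 + [Mg]/3.57 * exp(-0.062 V)).
    """

    receptor: int
    reversal_mV: float
    decay_ms: float
    voltage_dependent: bool = False
    # short-term depression (single release variable)
    release_fraction_U: float = 0.25
    recovery_tau_ms: float = 600.0


AMPA_CHANNEL = ReceptorChannel(AMPA, 0.0, 5.0)
NMDA_CHANNEL = ReceptorChannel(NMDA, 0.0, 150.0, voltage_dependent=True)
GABA_CHANNEL = ReceptorChannel(GABA_A, -80.0, 10.0)
CHANNELS = (AMPA_CHANNEL, NMDA_CHANNEL, GABA_CHANNEL)

#: reversal potential per slot
SLOT_REVERSAL = (0.0, 0.0, -80.0, 0.0, 0.0, 0.0)
SLOT_DECAY_MS = (5.0, 150.0, 10.0, 5.0, 150.0, 5.0)
SLOT_COMPARTMENT = (DEND, DEND, SOMA, APICAL, APICAL, SOMA)
SLOT_IS_NMDA = (False, True, False, False, True, False)


@dataclass(frozen=True)
class BackgroundDrive:
    """Excitatory Poisson background onto non-relay cells (AMPA, soma).

    The bias weight is per event; interneurons (basket, RSNP) receive the
    same rate at a reduced weight so their spontaneous rates stay in a
    plausible range despite their lower rheobase."""

    rate_hz: float = 300.0
    weight_uS: float = 0.0021
    interneuron_factor: float = 0.5


@dataclass(frozen=True)
class CellParameters:
    """Passive structure, spike currents and adaptation for one cell class."""

    cell_class: CellClass
    n_compartments: int
    # per-compartment passive properties, length 4 (unused trailing entries 0)
    capacitance_nF: tuple[float, ...]
    leak_uS: tuple[float, ...]
    leak_reversal_mV: float = -70.0
    # axial coupling soma<->(initial segment, basal/dend, apical)
    coupling_is_uS: float = 0.1
    coupling_dend_uS: float = 0.05
    coupling_apical_uS: float = 0.05
    # spike currents at the initial segment
    g_na_uS: float = 2.5
    g_k_uS: float = 1.0
    # calcium-dependent adaptation (potassium AHP current at the soma)
    ca_per_spike: float = 0.0
    ca_tau_ms: float = 1000.0
    g_ahp_uS_per_ca: float = 0.0


PYRAMIDAL_PARAMS = CellParameters(
    cell_class=CellClass.PYRAMIDAL, n_compartments=4,
    capacitance_nF=(0.10, 0.05, 0.20, 0.20),
    leak_uS=(0.010, 0.005, 0.010, 0.010),
    ca_per_spike=1.0, ca_tau_ms=1000.0, g_ahp_uS_per_ca=0.0015)

RSNP_PARAMS = CellParameters(
    cell_class=CellClass.RSNP, n_compartments=3,
    capacitance_nF=(0.10, 0.05, 0.20, 0.0),
    leak_uS=(0.010, 0.005, 0.010, 0.0),
    ca_per_spike=0.3, ca_tau_ms=1000.0, g_ahp_uS_per_ca=0.0015)

BASKET_PARAMS = CellParameters(
    cell_class=CellClass.BASKET, n_compartments=3,
    capacitance_nF=(0.10, 0.05, 0.20, 0.0),
    leak_uS=(0.010, 0.005, 0.010, 0.0),
    ca_per_spike=0.0, g_ahp_uS_per_ca=0.0)

RELAY_PARAMS = CellParameters(
    cell_class=CellClass.RELAY, n_compartments=3,
    capacitance_nF=(0.10, 0.05, 0.20, 0.0),
    leak_uS=(0.010, 0.005, 0.010, 0.0),
    ca_per_spike=0.0, g_ahp_uS_per_ca=0.0)

PARAMS_BY_CLASS = {CellClass.PYRAMIDAL: PYRAMIDAL_PARAMS,
                   CellClass.BASKET: BASKET_PARAMS,
                   CellClass.RSNP: RSNP_PARAMS,
                   CellClass.RELAY: RELAY_PARAMS}


# -- Hodgkin-Huxley gating kinetics (Traub-style rate functions) ------------

def _vtrap(x: float, y: float) -> float:
    """x / (1 - exp(-x/y)), stable near x = 0."""
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


def alpha_m(v: float) -> float:
    return 0.32 * _vtrap(v + 54.0, 4.0)


def beta_m(v: float) -> float:
    return 0.28 * _vtrap(-(v + 27.0), 5.0)


def alpha_h(v: float) -> float:
    return 0.128 * math.exp(-(v + 50.0) / 18.0)


def beta_h(v: float) -> float:
    return 4.0 / (1.0 + math.exp(-(v + 27.0) / 5.0))


def alpha_n(v: float) -> float:
    return 0.032 * _vtrap(v + 52.0, 5.0)


def beta_n(v: float) -> float:
    return 0.5 * math.exp(-(v + 57.0) / 40.0)


def nmda_block(v: float, mg_mM: float = 1.0) -> float:
    """Magnesium-block factor of the NMDA conductance at potential ``v``."""
    return 1.0 / (1.0 + (mg_mM / 3.57) * math.exp(-0.062 * v))


@dataclass
class CellState:
    """Full dynamical state of one cell."""

    params: CellParameters
    v: np.ndarray                      # (4,) compartment potentials, mV
    m: float
    h: float
    n: float
    ca: float = 0.0
    gsyn: np.ndarray = field(default_factory=lambda: np.zeros(N_SLOTS))
    last_spike_ms: float = -1e9
    t_ms: float = 0.0

    def copy(self) -> "CellState":
        return CellState(self.params, self.v.copy(), self.m, self.h, self.n,
                         self.ca, self.gsyn.copy(), self.last_spike_ms, self.t_ms)


def _gating_steady(v: float) -> tuple[float, float, float]:
    am, bm = alpha_m(v), beta_m(v)
    ah, bh = alpha_h(v), beta_h(v)
    an, bn = alpha_n(v), beta_n(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def initial_state(params: CellParameters, v0: float | None = None) -> CellState:
    v0 = params.leak_reversal_mV if v0 is None else v0
    m, h, n = _gating_steady(v0)
    return CellState(params, np.full(4, v0, dtype=float), m, h, n)


def resting_state(params: CellParameters, relax_ms: float = 3000.0,
                  dt: float = 0.1) -> CellState:
    """Relax a cell with all inputs silenced until it sits at its resting
    equilibrium (leak, coupling and HH window currents balanced)."""
    state = initial_state(params)
    for _ in range(int(round(relax_ms / dt))):
        step_cell(state, dt=dt)
    return state


def step_cell(state: CellState, dt: float = 0.1,
              i_ext_soma_nA: float = 0.0) -> bool:
    """Advance one cell by ``dt`` and return True if it spiked.

    Synaptic conductances in ``state.gsyn`` decay exponentially; deliveries
    are made by incrementing slots between calls.  Voltage uses exponential
    Euler per compartment (neighbor potentials frozen over the step), gating
    an exact exponential relaxation toward its voltage-dependent steady
    state.

    Raises ValueError on non-finite state (numerical instability).
    """
    p = state.params
    v = state.v
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")

    # synaptic decay
    for s in range(N_SLOTS):
        state.gsyn[s] *= math.exp(-dt / SLOT_DECAY_MS[s])

    has_apical = p.n_compartments == 4
    g_na = p.g_na_uS * state.m ** 3 * state.h
    g_k = p.g_k_uS * state.n ** 4
    g_ahp = p.g_ahp_uS_per_ca * state.ca

    # per-compartment synaptic conductance/reversal accumulation
    def syn_terms(comp: int, vc: float) -> tuple[float, float]:
        g_tot, gE = 0.0, 0.0
        for s in range(N_SLOTS):
            if SLOT_COMPARTMENT[s] != comp:
                continue
            g = state.gsyn[s]
            if SLOT_IS_NMDA[s]:
                g *= nmda_block(vc)
            g_tot += g
            gE += g * SLOT_REVERSAL[s]
        return g_tot, gE

    new_v = v.copy()
    for comp in range(p.n_compartments):
        gl = p.leak_uS[comp]
        g_tot = gl
        gE = gl * p.leak_reversal_mV
        i_const = 0.0
        if comp == SOMA:
            for other, gc in ((INITSEG, p.coupling_is_uS),
                              (DEND, p.coupling_dend_uS),
                              (APICAL, p.coupling_apical_uS if has_apical else 0.0)):
                g_tot += gc
                gE += gc * v[other]
            g_tot += g_ahp
            gE += g_ahp * E_K
            i_const += i_ext_soma_nA
        elif comp == INITSEG:
            g_tot += p.coupling_is_uS + g_na + g_k
            gE += p.coupling_is_uS * v[SOMA] + g_na * E_NA + g_k * E_K
        elif comp == DEND:
            g_tot += p.coupling_dend_uS
            gE += p.coupling_dend_uS * v[SOMA]
        else:  # APICAL
            g_tot += p.coupling_apical_uS
            gE += p.coupling_apical_uS * v[SOMA]
        gs, gsE = syn_terms(comp, v[comp])
        g_tot += gs
        gE += gsE
        v_inf = (gE + i_const) / g_tot
        new_v[comp] = v_inf + (v[comp] - v_inf) * math.exp(-dt * g_tot / p.capacitance_nF[comp])

    # gating at the (old) initial-segment potential
    vis_old = v[INITSEG]
    for name, a, b in (("m", alpha_m(vis_old), beta_m(vis_old)),
                       ("h", alpha_h(vis_old), beta_h(vis_old)),
                       ("n", alpha_n(vis_old), beta_n(vis_old))):
        x = getattr(state, name)
        tau = 1.0 / (a + b)
        x_inf = a * tau
        setattr(state, name, x_inf + (x - x_inf) * math.exp(-dt / tau))

    # calcium pool decay
    state.ca *= math.exp(-dt / p.ca_tau_ms)

    state.t_ms += dt
    spiked = (new_v[INITSEG] >= SPIKE_THRESHOLD and v[INITSEG] < SPIKE_THRESHOLD
              and state.t_ms - state.last_spike_ms >= REFRACTORY_MS)
    if spiked:
        state.last_spike_ms = state.t_ms
        state.ca += p.ca_per_spike
    state.v = new_v
    return spiked


# -- synaptic depression ---------------------------------------------------

@dataclass
class DepressionState:
    """Single release variable r in [0, 1] (Tsodyks–Markram style)."""

    release: float = 1.0
    last_spike_ms: float = -1e18


def apply_depression(dep: DepressionState, spike_time_ms: float,
                     U: float = 0.25, tau_rec_ms: float = 600.0) -> float:
    """Register a presynaptic spike; return the release fraction delivered.

    Between spikes the release variable recovers exponentially toward 1 with
    ``tau_rec_ms``; each spike multiplies it by (1 - U).  The returned value
    is the fraction (of the resting synaptic weight) delivered by this spike.
    """
    dt = spike_time_ms - dep.last_spike_ms
    r = 1.0 - (1.0 - dep.release) * math.exp(-dt / tau_rec_ms)
    delivered = r
    dep.release = r * (1.0 - U)
    dep.last_spike_ms = spike_time_ms
    return delivered


def depression_fixed_point(rate_hz: float, U: float = 0.25,
                           tau_rec_ms: float = 600.0) -> float:
    """Steady-state release fraction under a periodic spike train.

    Closed form of r* = 1 - (1 - r*(1-U)) exp(-T/tau) with T = 1000/rate.
    """
    e = math.exp(-1000.0 / (rate_hz * tau_rec_ms))
    return (1.0 - e) / (1.0 - (1.0 - U) * e)


def poisson_background(rate_hz: float, duration_ms: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson event times in [0, duration_ms)."""
    if rate_hz <= 0 or duration_ms <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def alpha_conductance(t_ms: np.ndarray, onset_ms: float, tau_ms: float,
                      gmax_uS: float) -> np.ndarray:
    """Alpha-shaped conductance waveform g(t) = gmax * (t'/tau) exp(1 - t'/tau).

    Provided as the time-gated somatic drive waveform for relay cells; the
    default stimulation pathway delivers relay spikes as scheduled events
    instead (see :mod:`maskingnet.protocol`).
    """
    tp = np.asarray(t_ms, dtype=float) - onset_ms
    out = np.zeros_like(tp)
    pos = tp > 0
    x = tp[pos] / tau_ms
    out[pos] = gmax_uS * x * np.exp(1.0 - x)
    return out
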