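"""Time-stepped network integration with delayed event delivery.

The engine owns two levels of seeding: the *individual* seed fixed the
wiring (handled in :mod:`maskingnet.connectivity`), the *trial* seed drives
background noise here; stimulus randomness is drawn by the protocol layer
before the run.  The same (individual, trial) pair replays bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .architecture import Area, CellClass, NetworkGeometry
from .cells import (BackgroundDrive, PARAMS_BY_CLASS, REFRACTORY_MS,
                    SLOT_DECAY_MS, SLOT_REVERSAL, SLOT_OF, SPIKE_THRESHOLD,
                    N_SLOTS, _gating_steady)
from .connectivity import Network
from .errors import ConfigurationError, NumericalError

AREA_NAMES = {int(Area.LGN): "LGN", int(Area.V1): "V1", int(Area.V2): "V2"}
LAYER_NAMES = {-1: "", 0: "L23", 1: "L4", 2: "L5"}
CLASS_NAMES = {0: "pyramidal", 1: "basket", 2: "rsnp", 3: "relay"}


@dataclass(frozen=True)
class EngineConfig:
    """Integration settings for one trial run."""

    duration_ms: float
    dt_ms: float = 0.1
    trial_seed: int = 0
    background: BackgroundDrive = field(default_factory=BackgroundDrive)
    record: str = "default"       # "default": pyramidals + relays; "all"
    max_events: int = 20_000_000
    i_ext_soma_nA: float = 0.0    # constant somatic current into every pyramidal

    def __post_init__(self):
        if self.dt_ms <= 0 or self.dt_ms > 0.1 + 1e-12:
            raise ConfigurationError(f"dt must be in (0, 0.1] ms, got {self.dt_ms}")
        if self.duration_ms <= 0:
            raise ConfigurationError("duration must be positive")


@dataclass
class StimulusSchedule:
    """Forced spike events: (time_ms, global cell id) pairs."""

    times_ms: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    cell_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))

    def __len__(self) -> int:
        return len(self.times_ms)

    @staticmethod
    def concat(parts) -> "StimulusSchedule":
        parts = [p for p in parts if len(p)]
        if not parts:
            return StimulusSchedule()
        return StimulusSchedule(np.concatenate([p.times_ms for p in parts]),
                                np.concatenate([p.cell_ids for p in parts]))


def force_spikes(geometry: NetworkGeometry, cell_ids, times_ms) -> StimulusSchedule:
    """Schedule forced spikes: listed cells emit at exactly the listed times,
    regardless of membrane state."""
    ids = np.asarray(cell_ids, dtype=np.int64)
    times = np.asarray(times_ms, dtype=float)
    if ids.shape != times.shape:
        raise ConfigurationError("cell_ids and times_ms must align")
    if len(ids) and (ids.min() < 0 or ids.max() >= geometry.n_cells):
        raise ConfigurationError(
            f"unknown cell id in schedule (valid range 0..{geometry.n_cells - 1})")
    return StimulusSchedule(times, ids.astype(np.int32))


class SpikeRaster:
    """Spike events (cell id, time ms) with geometry-aware indexing."""

    def __init__(self, geometry: NetworkGeometry, cell_ids: np.ndarray,
                 times_ms: np.ndarray, duration_ms: float):
        self.geometry = geometry
        self.cell_ids = cell_ids
        self.times_ms = times_ms
        self.duration_ms = duration_ms

    def __len__(self) -> int:
        return len(self.cell_ids)

    def select(self, area: Area | None = None, layer: int | None = None,
               minicolumn=None, cls: CellClass | None = None,
               t_start: float | None = None, t_stop: float | None = None):
        """Boolean-filtered (cell_ids, times_ms, minicolumn) arrays."""
        info = self.geometry.classify(self.cell_ids)
        keep = np.ones(len(self.cell_ids), dtype=bool)
        if area is not None:
            keep &= info["area"] == int(area)
        if layer is not None:
            keep &= info["layer"] == layer
        if cls is not None:
            keep &= info["cls"] == int(cls)
        if minicolumn is not None:
            keep &= np.isin(info["minicolumn"], np.atleast_1d(minicolumn))
        if t_start is not None:
            keep &= self.times_ms >= t_start
        if t_stop is not None:
            keep &= self.times_ms < t_stop
        return self.cell_ids[keep], self.times_ms[keep], info["minicolumn"][keep]

    def minicolumn_spike_counts(self, area: Area, layer: int,
                                minicolumns, cls: CellClass,
                                t_start: float, t_stop: float) -> np.ndarray:
        """Spike count per requested minicolumn (summed over its cells of
        ``cls``) within [t_start, t_stop)."""
        mcs = np.atleast_1d(np.asarray(minicolumns))
        _, _, mc_of_spike = self.select(area, layer, mcs, cls, t_start, t_stop)
        return np.array([(mc_of_spike == mc).sum() for mc in mcs])

    def to_dataframe(self) -> pd.DataFrame:
        info = self.geometry.classify(self.cell_ids)
        return pd.DataFrame({
            "time_ms": self.times_ms,
            "cell_id": self.cell_ids,
            "area": [AREA_NAMES[a] for a in info["area"]],
            "layer": [LAYER_NAMES[l] for l in info["layer"]],
            "minicolumn": info["minicolumn"],
            "cls": [CLASS_NAMES[c] for c in info["cls"]],
        })

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _class_tables():
    order = (CellClass.PYRAMIDAL, CellClass.BASKET, CellClass.RSNP)
    ncomp = np.array([PARAMS_BY_CLASS[c].n_compartments for c in order], np.int64)
    cap = np.array([PARAMS_BY_CLASS[c].capacitance_nF for c in order])
    gl = np.array([PARAMS_BY_CLASS[c].leak_uS for c in order])
    gc_is = np.array([PARAMS_BY_CLASS[c].coupling_is_uS for c in order])
    gc_dend = np.array([PARAMS_BY_CLASS[c].coupling_dend_uS for c in order])
    gc_ap = np.array([PARAMS_BY_CLASS[c].coupling_apical_uS for c in order])
    g_na = np.array([PARAMS_BY_CLASS[c].g_na_uS for c in order])
    g_k = np.array([PARAMS_BY_CLASS[c].g_k_uS for c in order])
    dca = np.array([PARAMS_BY_CLASS[c].ca_per_spike for c in order])
    ca_tau = np.array([PARAMS_BY_CLASS[c].ca_tau_ms for c in order])
    g_ahp = np.array([PARAMS_BY_CLASS[c].g_ahp_uS_per_ca for c in order])
    cap[cap == 0.0] = 1.0  # unused compartments: avoid division by zero
    return ncomp, cap, gl, gc_is, gc_dend, gc_ap, g_na, g_k, dca, ca_tau, g_ahp


def _build_csr(network: Network, dt: float):
    tab = network.synapses
    n_cells = network.geometry.n_cells
    order = np.argsort(tab.src, kind="stable")
    src = tab.src[order]
    slot = np.empty(len(tab), np.uint8)
    for (rec, comp), s in SLOT_OF.items():
        slot[(tab.receptor == rec) & (tab.compartment == comp)] = s
    indptr = np.zeros(n_cells + 1, np.int64)
    np.add.at(indptr[1:], src, 1)
    indptr = np.cumsum(indptr)
    dstep = np.maximum(1, np.round(tab.delay_ms[order] / dt).astype(np.int32))
    tgt_local = (tab.tgt[order] - network.geometry.n_relay_cells).astype(np.int32)
    if tgt_local.size and tgt_local.min() < 0:
        raise ConfigurationError("synapse targets a relay cell")
    # per-source depression parameters (uniform per source in this wiring)
    dep_U = np.full(n_cells, 0.25, np.float64)
    dep_tau = np.full(n_cells, 600.0, np.float64)
    has = indptr[:-1] < indptr[1:]
    dep_U[has] = tab.dep_U[order][indptr[:-1][has]]
    dep_tau[has] = tab.dep_tau_ms[order][indptr[:-1][has]]
    return (indptr, tgt_local, slot[order],
            tab.weight[order].astype(np.float32), dstep, dep_U, dep_tau)


def run(network: Network, schedule: StimulusSchedule,
        config: EngineConfig) -> SpikeRaster:
    """Integrate the network and return the spike raster.

    Delays are quantized to the nearest dt step (minimum one step); forced
    stimulus events are merged into the raster.  Deterministic given the
    network (individual seed) and ``config.trial_seed``.
    """
    g = network.geometry
    dt = config.dt_ms
    n_steps = int(round(config.duration_ms / dt))
    n = g.n_cortical

    if len(schedule) and (schedule.times_ms.min() < 0
                          or schedule.times_ms.max() >= config.duration_ms):
        raise ConfigurationError("stimulus schedule outside simulation bounds")

    tables = g.cell_tables()
    cort = slice(g.n_relay_cells, g.n_cells)
    cls = tables["cls"][cort].astype(np.uint8)

    ncomp, cap, gl, gc_is, gc_dend, gc_ap, g_na, g_k, dca, ca_tau, g_ahp = _class_tables()
    ca_fac = np.exp(-dt / ca_tau)
    el = PARAMS_BY_CLASS[CellClass.PYRAMIDAL].leak_reversal_mV

    V = np.full((n, 4), el, dtype=np.float64)
    m0, h0, n0 = _gating_steady(el)
    m = np.full(n, m0)
    h = np.full(n, h0)
    nk = np.full(n, n0)
    ca = np.zeros(n)
    gsyn = np.zeros((n, N_SLOTS), np.float32)
    last_spike = np.full(n, -10 ** 9, np.int64)

    slot_decay = np.exp(-dt / np.asarray(SLOT_DECAY_MS))
    slot_E = np.asarray(SLOT_REVERSAL)
    vmin, inv_step, gtab = _kernel.build_gating_tables(dt)
    expneg = _kernel.build_expneg_table()

    indptr, syn_tgt, syn_slot, syn_w, syn_dstep, dep_U, dep_tau = _build_csr(network, dt)
    dep_r = np.ones(g.n_cells)
    dep_last = np.full(g.n_cells, -1e18)

    D = int(syn_dstep.max()) + 1 if len(syn_dstep) else 2
    ring = np.zeros((D, n, N_SLOTS), np.float32)

    f_order = np.argsort(np.round(schedule.times_ms / dt).astype(np.int64),
                         kind="stable")
    f_step = np.round(schedule.times_ms / dt).astype(np.int64)[f_order]
    f_src = schedule.cell_ids[f_order].astype(np.int64)

    p_bg = config.background.rate_hz * dt * 1e-3
    w_bg = np.where(cls == int(CellClass.PYRAMIDAL),
                    config.background.weight_uS,
                    config.background.weight_uS
                    * config.background.interneuron_factor)
    rng_state = np.array([np.uint64(config.trial_seed) * np.uint64(2654435761)
                          + np.uint64(0x9E3779B97F4A7C15)], dtype=np.uint64)

    i_ext = np.zeros(n)
    if config.i_ext_soma_nA:
        i_ext[cls == 0] = config.i_ext_soma_nA

    if config.record == "all":
        record_mask = np.ones(n, dtype=np.bool_)
    else:
        record_mask = cls == int(CellClass.PYRAMIDAL)

    out_cell = np.empty(config.max_events, np.int32)
    out_step = np.empty(config.max_events, np.int32)

    status, ne, bad_cell, bad_step = _kernel.run_kernel(
        n_steps, dt, cls, V, m, h, nk, ca, gsyn, last_spike,
        ncomp, cap, gl, el, gc_is, gc_dend, gc_ap,
        g_na, g_k, dca, ca_fac, g_ahp,
        slot_decay, slot_E,
        vmin, inv_step, gtab, expneg,
        indptr, syn_tgt, syn_slot, syn_w, syn_dstep,
        dep_r, dep_last, dep_U, dep_tau,
        ring, f_step, f_src,
        p_bg, w_bg, rng_state, i_ext,
        record_mask, g.n_relay_cells,
        out_cell, out_step,
        int(round(REFRACTORY_MS / dt)), SPIKE_THRESHOLD)

    if status == 1:
        raise NumericalError(f"spike buffer overflow at t={bad_step * dt:.1f} ms "
                             f"({ne} events); raise max_events")
    if status == 2:
        raise NumericalError(
            f"numerical instability in cell {bad_cell} at t={bad_step * dt:.1f} ms")

    order = np.argsort(out_step[:ne], kind="stable")
    return SpikeRaster(g, out_cell[:ne][order].copy(),
                       (out_step[:ne][order] * dt).astype(np.float64),
                       config.duration_ms)
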