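"""Synaptic wiring: microcircuit, long-range pattern connections, projections.

Three wiring stages build one columnar :class:`SynapseTable`:

* :func:`wire_microcircuit` — within-minicolumn recurrent excitation,
  pyramidal->basket drive, basket->pyramidal lateral inhibition inside the
  hypercolumn (model 2 extends it horizontally with a falling probability
  profile), RSNP->pyramidal inhibition, and L4->L2/3 / L4->L5 interlaminar
  excitation.
* :func:`wire_longrange` — within-pattern excitation between minicolumns of
  the same stored memory (one randomly chosen source pyramidal per connected
  pair, 25% destination-pyramidal probability) plus di-synaptic targeting of
  RSNP cells in surrounding minicolumns.
* :func:`wire_projections` — LGN->V1 L4, feedforward V1->V2 (L4->L4 strong,
  L2/3->L2/3 weaker) and, when enabled, feedback V2 L4 -> V1 L5 plus
  V2 L4 -> V1 L2/3 at 10% strength; all inter-areal delays 10 ms.

Excitatory synapses onto pyramidal and RSNP cells are written as paired
AMPA + NMDA rows (NMDA at a fixed conductance ratio); basket cells carry no
NMDA channels and receive the AMPA row only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .architecture import (Area, AttractorPattern, CellClass, NetworkGeometry,
                           L23, L4, L5)
from .cells import AMPA, NMDA, GABA_A, SOMA, DEND, APICAL
from .errors import ConfigurationError

RECEPTOR_NAMES = ("AMPA", "NMDA", "GABA_A")


@dataclass
class SynapseTable:
    """All connections, column-oriented.

    Per-row: source cell, target cell, target compartment, receptor, weight
    (uS), axonal delay (ms), depression parameters (release fraction U and
    recovery time constant).
    """

    src: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    tgt: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    compartment: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    receptor: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    weight: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    delay_ms: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    dep_U: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    dep_tau_ms: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))

    def __len__(self) -> int:
        return len(self.src)

    def __post_init__(self):
        if np.any(self.delay_ms < 0):
            raise ConfigurationError("negative synaptic delay")
        if np.any(self.src == self.tgt):
            raise ConfigurationError("self-synapse in table")

    @staticmethod
    def concat(tables: Sequence["SynapseTable"]) -> "SynapseTable":
        tables = [t for t in tables if len(t)]
        if not tables:
            return SynapseTable()
        return SynapseTable(*[np.concatenate([getattr(t, f) for t in tables])
                              for f in ("src", "tgt", "compartment", "receptor",
                                        "weight", "delay_ms", "dep_U", "dep_tau_ms")])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({f: getattr(self, f)
                           for f in ("src", "tgt", "compartment", "receptor",
                                     "weight", "delay_ms", "dep_U", "dep_tau_ms")})
        return df

    def save(self, path: str) -> None:
        """Columnar parquet serialization of the full table."""
        self.to_dataframe().to_parquet(path)

    @staticmethod
    def load(path: str) -> "SynapseTable":
        df = pd.read_parquet(path)
        return SynapseTable(df.src.to_numpy(np.int32), df.tgt.to_numpy(np.int32),
                            df.compartment.to_numpy(np.int8),
                            df.receptor.to_numpy(np.int8),
                            df.weight.to_numpy(np.float32),
                            df.delay_ms.to_numpy(np.float32),
                            df.dep_U.to_numpy(np.float32),
                            df.dep_tau_ms.to_numpy(np.float32))


@dataclass(frozen=True)
class WiringConfig:
    """Connection probabilities, conductances (uS) and delays (ms).

    ``exc_scale`` / ``inh_scale`` are the global calibration multipliers
    applied to every excitatory / inhibitory conductance at network-assembly
    time (see :func:`maskingnet.protocol.calibrate`).
    """

    # probabilities
    p_recurrent: float = 0.25          # pyr<->pyr within minicolumn, per layer
    p_pyr_basket: float = 0.7          # pyr -> baskets of the home hypercolumn
    p_basket_pyr: float = 0.7          # basket -> pyr, scaled by distance profile
    p_rsnp_pyr: float = 0.7            # RSNP -> pyr of its own minicolumn
    p_pyr_rsnp: float = 0.7            # pyr -> RSNP of its own minicolumn
    p_interlaminar: float = 0.25       # L4 -> L2/3 and L4 -> L5 within minicolumn
    p_longrange_pair: float = 1.0      # minicolumn pair within a pattern connected?
    p_longrange_dest: float = 0.25     # destination pyramidal receives a synapse
    p_disynaptic: float = 0.25         # surrounding-minicolumn RSNP receives one
    p_lgn_pyr: float = 0.7
    p_lgn_basket: float = 0.25
    # lateral-inhibition probability scale by horizontal hypercolumn distance;
    # entry d applies at |column distance| = d within the same grid row
    # (model 1: inhibition confined to the hypercolumn).
    lateral_profile: tuple[float, ...] = (1.0,)
    # conductances
    w_recurrent: float = 0.0040
    w_pyr_basket: float = 0.0030
    w_basket_pyr: float = 0.0060
    w_rsnp_pyr: float = 0.0060
    w_pyr_rsnp: float = 0.0080         # local feedback loop: caps lone-minicolumn bursts
    w_interlaminar: float = 0.0050
    w_longrange: float = 0.0130
    longrange_layer_factor: tuple[float, float, float] = (1.0, 0.5, 1.0)  # L2/3, L4, L5
    w_disynaptic: float = 0.0060
    w_lgn_pyr: float = 0.0800
    w_lgn_basket: float = 0.0030
    w_feedforward: float = 0.0220      # V1 L4 -> V2 L4
    ff_l23_ratio: float = 0.25         # V1 L2/3 -> V2 L2/3, fraction of L4->L4
    w_feedback: float = 0.0500         # V2 L4 -> V1 L5
    fb_l23_ratio: float = 0.10         # V2 L4 -> V1 L2/3, fraction of the above
    v2_interlaminar_boost: float = 1.2 # V2 L4->L2/3 and L4->L5 conductance boost
    nmda_ratio: float = 0.30           # NMDA conductance as fraction of AMPA
    nmda_ratio_recurrent: float = 1.40 # within-minicolumn recurrence is NMDA-rich,
                                       # so sustained firing needs prior depolarization
    projection_fan_in: int = 4         # destination minicolumns per linked pattern
    # delays
    local_delay_ms: float = 1.0
    basket_delay_ms: float = 1.0       # basket->pyr; +3 ms models lagged inhibition
    interareal_delay_ms: float = 10.0
    lgn_delay_ms: float = 1.0
    # depression (all synaptic channels depress; inhibitory synapses use a
    # smaller release fraction so sustained basket firing does not
    # disinhibit the network wholesale)
    dep_U: float = 0.25
    dep_U_inh: float = 0.10
    dep_tau_ms: float = 600.0
    # global calibration multipliers
    exc_scale: float = 1.0
    inh_scale: float = 1.0
    # desk-scale subsampling compensation: when the per-minicolumn cell
    # counts are divided down, raise connection probabilities (capped at 1)
    # and rescale weights so the expected total synaptic input per target
    # cell matches the full-size network
    compensate_subsampling: bool = True

    def __post_init__(self):
        for name in ("p_recurrent", "p_pyr_basket", "p_basket_pyr", "p_rsnp_pyr",
                     "p_interlaminar", "p_longrange_pair", "p_longrange_dest",
                     "p_disynaptic", "p_lgn_pyr", "p_lgn_basket", "p_pyr_rsnp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        prof = self.lateral_profile
        if any(b > a + 1e-12 for a, b in zip(prof, prof[1:])):
            raise ConfigurationError("lateral profile must be nonincreasing")

    @staticmethod
    def model1(**kw) -> "WiringConfig":
        return WiringConfig(lateral_profile=(1.0,), **kw)

    @staticmethod
    def model2(**kw) -> "WiringConfig":
        # line-detector calibration: stronger feedforward and long-range
        # support for the 9-minicolumn vertical lines, with the lateral
        # inhibition probability extending horizontally
        kw.setdefault("lateral_profile", (1.0, 0.5, 0.25))
        kw.setdefault("w_feedforward", 0.033)
        kw.setdefault("w_longrange", 0.016)
        kw.setdefault("ff_l23_ratio", 0.45)
        kw.setdefault("w_recurrent", 0.003)
        kw.setdefault("nmda_ratio_recurrent", 1.8)
        return WiringConfig(**kw)


# -- low-level helpers -----------------------------------------------------

def _bernoulli_pairs(src: np.ndarray, tgt: np.ndarray, p: float,
                     rng: np.random.Generator,
                     no_self: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """All (src, tgt) pairs passing an independent coin flip with prob p."""
    if p <= 0 or len(src) == 0 or len(tgt) == 0:
        return np.empty(0, np.int32), np.empty(0, np.int32)
    mask = rng.random((len(src), len(tgt))) < p
    if no_self:
        eq = src[:, None] == tgt[None, :]
        mask &= ~eq
    si, ti = np.nonzero(mask)
    return src[si].astype(np.int32), tgt[ti].astype(np.int32)


def _rows(src, tgt, compartment, receptor, weight, delay, U, tau) -> SynapseTable:
    n = len(src)
    return SynapseTable(np.asarray(src, np.int32), np.asarray(tgt, np.int32),
                        np.full(n, compartment, np.int8),
                        np.full(n, receptor, np.int8),
                        np.full(n, weight, np.float32),
                        np.full(n, delay, np.float32),
                        np.full(n, U, np.float32),
                        np.full(n, tau, np.float32))


class _Builder:
    """Accumulates table fragments; expands excitatory rows to AMPA+NMDA."""

    def __init__(self, cfg: WiringConfig):
        self.cfg = cfg
        self.parts: list[SynapseTable] = []

    def exc(self, src, tgt, weight, delay, compartment=DEND,
            target_has_nmda=True, nmda_ratio=None):
        w = weight * self.cfg.exc_scale
        self.parts.append(_rows(src, tgt, compartment, AMPA, w, delay,
                                self.cfg.dep_U, self.cfg.dep_tau_ms))
        ratio = self.cfg.nmda_ratio if nmda_ratio is None else nmda_ratio
        if target_has_nmda and ratio > 0:
            self.parts.append(_rows(src, tgt, compartment, NMDA,
                                    w * ratio, delay,
                                    self.cfg.dep_U, self.cfg.dep_tau_ms))

    def inh(self, src, tgt, weight, delay):
        self.parts.append(_rows(src, tgt, SOMA, GABA_A,
                                weight * self.cfg.inh_scale, delay,
                                self.cfg.dep_U_inh, self.cfg.dep_tau_ms))

    def table(self) -> SynapseTable:
        return SynapseTable.concat(self.parts)


# -- wiring stages ---------------------------------------------------------

def _compensated(cfg: WiringConfig, p: float, w: float,
                 full_pool: int, desk_pool: int) -> tuple[float, float]:
    """Subsampling correction: preserve expected total input p*pool*w.

    With a shrunken source pool the probability is raised (capped at 1) and
    the weight rescaled, so the per-target synaptic budget matches the
    full-size network; at scale 1 this is the identity.
    """
    if (not cfg.compensate_subsampling or full_pool == desk_pool
            or desk_pool <= 0 or p <= 0):
        return p, w
    budget = p * full_pool
    p_eff = min(1.0, budget / desk_pool)
    return p_eff, w * budget / (p_eff * desk_pool)


def wire_microcircuit(geometry: NetworkGeometry, cfg: WiringConfig,
                      rng: np.random.Generator,
                      areas: Sequence[Area] = (Area.V1, Area.V2)) -> SynapseTable:
    """Within-minicolumn and within/near-hypercolumn microcircuit wiring."""
    b = _Builder(cfg)
    g = geometry
    base = g.config
    base_pyr = base.pyramidal_per_minicolumn_per_layer
    base_basket = base.basket_per_minicolumn_per_layer
    base_rsnp = base.rsnp_per_minicolumn_per_layer
    p_rec, w_rec = _compensated(cfg, cfg.p_recurrent, cfg.w_recurrent,
                                base_pyr - 1, g.n_pyr - 1)
    p_rp, w_rp = _compensated(cfg, cfg.p_rsnp_pyr, cfg.w_rsnp_pyr,
                              base_rsnp, g.n_rsnp)
    p_pr, w_pr = _compensated(cfg, cfg.p_pyr_rsnp, cfg.w_pyr_rsnp,
                              base_pyr, g.n_pyr)
    p_pb, w_pb = _compensated(cfg, cfg.p_pyr_basket, cfg.w_pyr_basket,
                              base_pyr, g.n_pyr)
    p_il, w_il = _compensated(cfg, cfg.p_interlaminar, cfg.w_interlaminar,
                              base_pyr, g.n_pyr)
    for area in areas:
        for layer in (L23, L4, L5):
            for mc in range(g.n_minicolumns):
                pyr = g.cells(area, layer, mc, CellClass.PYRAMIDAL)
                rsnp = g.cells(area, layer, mc, CellClass.RSNP)
                # recurrent excitation inside the minicolumn
                s, t = _bernoulli_pairs(pyr, pyr, p_rec, rng)
                b.exc(s, t, w_rec, cfg.local_delay_ms,
                      nmda_ratio=cfg.nmda_ratio_recurrent)
                # RSNP -> own-minicolumn pyramidals (di-synaptic inhibition leg)
                s, t = _bernoulli_pairs(rsnp, pyr, p_rp, rng)
                b.inh(s, t, w_rp, cfg.local_delay_ms)
                # pyr -> own-minicolumn RSNP: local feedback inhibition loop
                s, t = _bernoulli_pairs(pyr, rsnp, p_pr, rng)
                b.exc(s, t, w_pr, cfg.local_delay_ms)
            # hypercolumn-level basket circuitry
            for hc in range(g.n_hypercolumns):
                mcs = g.minicolumns_of_hc(hc)
                baskets = g.cells(area, layer, mcs, CellClass.BASKET)
                hc_pyr = g.cells(area, layer, mcs, CellClass.PYRAMIDAL)
                s, t = _bernoulli_pairs(hc_pyr, baskets, p_pb, rng)
                b.exc(s, t, w_pb, cfg.local_delay_ms, target_has_nmda=False)
                # lateral inhibition: baskets of minicolumn mc inhibit
                # pyramidals of other minicolumns, per the distance profile
                row, col = g.hc_coords(hc)
                for d, scale in enumerate(cfg.lateral_profile):
                    p, w_lat = _compensated(cfg, cfg.p_basket_pyr * scale,
                                            cfg.w_basket_pyr, base_basket,
                                            g.n_basket)
                    if p <= 0:
                        continue
                    cols = {col - d, col + d} if d else {col}
                    for c2 in cols:
                        if not 0 <= c2 < g.grid_cols:
                            continue
                        hc2 = g.hc_at(int(row), int(c2))
                        for mc in mcs:
                            bk = g.cells(area, layer, mc, CellClass.BASKET)
                            other = g.minicolumns_of_hc(hc2)
                            if d == 0:
                                other = other[other != mc]
                            tgt = g.cells(area, layer, other, CellClass.PYRAMIDAL)
                            s, t = _bernoulli_pairs(bk, tgt, p, rng)
                            b.inh(s, t, w_lat, cfg.basket_delay_ms)
            # interlaminar excitation L4 -> L2/3 and L4 -> L5, within minicolumn
            if layer == L4:
                boost = cfg.v2_interlaminar_boost if area == Area.V2 else 1.0
                for mc in range(g.n_minicolumns):
                    src = g.cells(area, L4, mc, CellClass.PYRAMIDAL)
                    for dst_layer in (L23, L5):
                        tgt = g.cells(area, dst_layer, mc, CellClass.PYRAMIDAL)
                        s, t = _bernoulli_pairs(src, tgt, p_il, rng)
                        b.exc(s, t, w_il * boost, cfg.local_delay_ms)
    return b.table()


def wire_longrange(geometry: NetworkGeometry,
                   patterns: Sequence[AttractorPattern], cfg: WiringConfig,
                   rng: np.random.Generator) -> SynapseTable:
    """Within-pattern long-range excitation plus di-synaptic RSNP targeting.

    For every ordered pair of distinct minicolumns in a pattern that passes
    the pairwise connection probability, one randomly chosen pyramidal in the
    source minicolumn originates the axon; each destination pyramidal
    receives a synapse with ``p_longrange_dest``, and RSNP cells of the other
    minicolumns in the destination hypercolumn (outside the pattern) receive
    di-synaptic synapses.
    """
    b = _Builder(cfg)
    g = geometry
    for pat in patterns:
        area = pat.area
        in_pattern = set(pat.minicolumn_ids)
        for src_mc in pat.minicolumn_ids:
            for dst_mc in pat.minicolumn_ids:
                if dst_mc == src_mc or rng.random() >= cfg.p_longrange_pair:
                    continue
                for layer, lf in zip((L23, L4, L5), cfg.longrange_layer_factor):
                    if lf <= 0:
                        continue
                    src_pyr = g.cells(area, layer, src_mc, CellClass.PYRAMIDAL)
                    axon = np.array([rng.choice(src_pyr)], np.int32)
                    tgt = g.cells(area, layer, dst_mc, CellClass.PYRAMIDAL)
                    s, t = _bernoulli_pairs(axon, tgt, cfg.p_longrange_dest, rng)
                    b.exc(s, t, cfg.w_longrange * lf, cfg.local_delay_ms)
                    # di-synaptic: RSNP of surrounding minicolumns in the
                    # destination hypercolumn, outside this pattern
                    hc = int(g.hc_of_mc(dst_mc))
                    surround = [m for m in g.minicolumns_of_hc(hc)
                                if m != dst_mc and m not in in_pattern]
                    if surround:
                        rs = g.cells(area, layer, np.array(surround), CellClass.RSNP)
                        s, t = _bernoulli_pairs(axon, rs, cfg.p_disynaptic, rng)
                        b.exc(s, t, cfg.w_disynaptic * lf, cfg.local_delay_ms)
    return b.table()


def _pattern_projection(b: _Builder, g: NetworkGeometry,
                        src_area: Area, dst_area: Area,
                        src_pat: AttractorPattern, dst_pat: AttractorPattern,
                        layer_pairs, cfg: WiringConfig,
                        rng: np.random.Generator) -> None:
    """Project a source pattern onto ``projection_fan_in`` destination
    minicolumns of its linked pattern (selection fixed by the wiring rng)."""
    k = min(cfg.projection_fan_in, len(dst_pat.minicolumn_ids))
    dest_mcs = rng.choice(np.asarray(dst_pat.minicolumn_ids), size=k,
                          replace=False)
    for src_layer, dst_layer, weight in layer_pairs:
        if weight <= 0:
            continue
        for src_mc in src_pat.minicolumn_ids:
            src_pyr = g.cells(src_area, src_layer, src_mc, CellClass.PYRAMIDAL)
            for dst_mc in dest_mcs:
                axon = np.array([rng.choice(src_pyr)], np.int32)
                tgt = g.cells(dst_area, dst_layer, int(dst_mc), CellClass.PYRAMIDAL)
                s, t = _bernoulli_pairs(axon, tgt, cfg.p_longrange_dest, rng)
                b.exc(s, t, weight, cfg.interareal_delay_ms)


def wire_projections(geometry: NetworkGeometry,
                     v1_patterns: Sequence[AttractorPattern],
                     v2_patterns: Sequence[AttractorPattern],
                     linkage: dict[int, int], cfg: WiringConfig,
                     feedback_enabled: bool,
                     rng: np.random.Generator) -> SynapseTable:
    """LGN->V1 and inter-areal pattern projections (all delays 10 ms)."""
    if feedback_enabled and not linkage:
        raise ConfigurationError("feedback requested with no pattern linkage")
    b = _Builder(cfg)
    g = geometry
    # LGN location i -> V1 L4 minicolumn i pyramidals + home-hypercolumn baskets
    for loc in range(g.lgn_locations):
        relays = g.relay_cells(loc)
        pyr = g.cells(Area.V1, L4, loc, CellClass.PYRAMIDAL)
        s, t = _bernoulli_pairs(relays, pyr, cfg.p_lgn_pyr, rng)
        b.exc(s, t, cfg.w_lgn_pyr, cfg.lgn_delay_ms)
        hc = int(g.hc_of_mc(loc))
        baskets = g.cells(Area.V1, L4, g.minicolumns_of_hc(hc), CellClass.BASKET)
        s, t = _bernoulli_pairs(relays, baskets, cfg.p_lgn_basket, rng)
        b.exc(s, t, cfg.w_lgn_basket, cfg.lgn_delay_ms, target_has_nmda=False)

    # all feedforward draws precede all feedback draws, so the feedforward
    # realization is identical with and without feedback for one individual
    v2_by_id = {p.pattern_id: p for p in v2_patterns}
    for p1 in v1_patterns:
        p2 = v2_by_id[linkage[p1.pattern_id]]
        ff = [(L4, L4, cfg.w_feedforward),
              (L23, L23, cfg.w_feedforward * cfg.ff_l23_ratio)]
        _pattern_projection(b, g, Area.V1, Area.V2, p1, p2, ff, cfg, rng)
    if feedback_enabled:
        for p1 in v1_patterns:
            p2 = v2_by_id[linkage[p1.pattern_id]]
            fb = [(L4, L5, cfg.w_feedback),
                  (L4, L23, cfg.w_feedback * cfg.fb_l23_ratio)]
            _pattern_projection(b, g, Area.V2, Area.V1, p2, p1, fb, cfg, rng)
    return b.table()


# -- full network assembly -------------------------------------------------

@dataclass
class Network:
    """An assembled individual: geometry, patterns, linkage and synapses."""

    geometry: NetworkGeometry
    v1_patterns: list[AttractorPattern]
    v2_patterns: list[AttractorPattern]
    linkage: dict[int, int]
    wiring: WiringConfig
    synapses: SynapseTable
    feedback_enabled: bool
    individual_seed: int


def assemble_network(geometry: NetworkGeometry,
                     v1_patterns: Sequence[AttractorPattern],
                     v2_patterns: Sequence[AttractorPattern],
                     linkage: dict[int, int], cfg: WiringConfig,
                     feedback_enabled: bool = True,
                     individual_seed: int = 0) -> Network:
    """Wire one individual: microcircuit + long-range + projections.

    The individual seed fixes every wiring draw, so regenerating with the
    same seed reproduces a bit-identical synapse table.
    """
    rng = np.random.default_rng(individual_seed)
    parts = [wire_microcircuit(geometry, cfg, rng),
             wire_longrange(geometry, v1_patterns, cfg, rng),
             wire_longrange(geometry, v2_patterns, cfg, rng),
             wire_projections(geometry, v1_patterns, v2_patterns, linkage,
                              cfg, feedback_enabled, rng)]
    table = SynapseTable.concat(parts)
    return Network(geometry, list(v1_patterns), list(v2_patterns), dict(linkage),
                   cfg, table, feedback_enabled, individual_seed)
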