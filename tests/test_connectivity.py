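"""Wiring statistics, projection structure and determinism."""

import numpy as np
import pytest

from maskingnet.architecture import (Area, CellClass, GeometryConfig,
                                     build_geometry, clone_patterns,
                                     generate_patterns_lines,
                                     generate_patterns_random, link_patterns)
from maskingnet.cells import AMPA, GABA_A, NMDA
from maskingnet.connectivity import (SynapseTable, WiringConfig,
                                     assemble_network, wire_longrange,
                                     wire_microcircuit, wire_projections)
from maskingnet.errors import ConfigurationError


def table_fingerprint(tab: SynapseTable) -> bytes:
    return b"".join(np.ascontiguousarray(getattr(tab, f)).tobytes()
                    for f in ("src", "tgt", "compartment", "receptor",
                              "weight", "delay_ms"))


class TestMicrocircuit:
    def test_model1_inhibition_stays_within_hypercolumn(self, tiny1):
        g = tiny1.geometry
        tab = tiny1.synapses
        inh = tab.receptor == GABA_A
        src_info = g.classify(tab.src[inh])
        tgt_info = g.classify(tab.tgt[inh])
        basket = src_info["cls"] == int(CellClass.BASKET)
        src_hc = g.hc_of_mc(src_info["minicolumn"][basket])
        tgt_hc = g.hc_of_mc(tgt_info["minicolumn"][basket])
        assert np.array_equal(src_hc, tgt_hc)

    def test_zero_probabilities_give_empty_fragment(self, geom1):
        cfg = WiringConfig(p_recurrent=0, p_pyr_basket=0, p_basket_pyr=0,
                           p_rsnp_pyr=0, p_pyr_rsnp=0, p_interlaminar=0)
        tab = wire_microcircuit(geom1, cfg, np.random.default_rng(0),
                                areas=(Area.V1,))
        assert len(tab) == 0

    def test_model2_lateral_profile_realized_fractions(self, geom2):
        """Cross-hypercolumn basket->pyramidal connection fractions follow
        the 0.5 / 0.25 falloff at column distances 1 and 2 (binomial check,
        3 standard errors)."""
        cfg = WiringConfig.model2()
        rng = np.random.default_rng(11)
        tab = wire_microcircuit(geom2, cfg, rng, areas=(Area.V1,))
        g = geom2
        inh = (tab.receptor == GABA_A)
        sinfo = g.classify(tab.src[inh])
        tinfo = g.classify(tab.tgt[inh])
        basket = sinfo["cls"] == int(CellClass.BASKET)
        src_hc = g.hc_of_mc(sinfo["minicolumn"][basket])
        tgt_hc = g.hc_of_mc(tinfo["minicolumn"][basket])
        sr, sc = g.hc_coords(src_hc)
        tr, tc = g.hc_coords(tgt_hc)
        assert np.array_equal(sr, tr)          # same grid row only
        dist = np.abs(sc - tc)
        n_basket_per_mc = g.n_basket
        n_pyr_per_mc = g.n_pyr
        # possible (basket, pyr) pairs at each distance, per layer
        n_b = g.n_minicolumns * n_basket_per_mc * 3  # all baskets, one area
        for d, expect in ((1, cfg.p_basket_pyr * 0.5),
                          (2, cfg.p_basket_pyr * 0.25)):
            # columns with a neighbor at distance d on each side
            cols = np.arange(g.grid_cols)
            n_neighbor_cols = int(((cols - d) >= 0).sum() + ((cols + d) < g.grid_cols).sum())
            n_pairs = (g.grid_rows * n_neighbor_cols * g.mc_per_hc
                       * n_basket_per_mc * 3
                       * g.mc_per_hc * n_pyr_per_mc)
            realized = int((dist == d).sum())
            p_hat = realized / n_pairs
            se = np.sqrt(expect * (1 - expect) / n_pairs)
            assert abs(p_hat - expect) < 3 * se, (d, p_hat, expect)

    def test_basket_cells_receive_no_nmda(self, tiny1, tiny2):
        for net in (tiny1, tiny2):
            g = net.geometry
            nmda = net.synapses.receptor == NMDA
            tgt = g.classify(net.synapses.tgt[nmda])
            assert not np.any(tgt["cls"] == int(CellClass.BASKET))


class TestLongRange:
    @pytest.fixture(scope="class")
    def full_longrange(self, geom1):
        pats = generate_patterns_random(geom1, 18, 10, seed=4)
        cfg = WiringConfig.model1()
        tab = wire_longrange(geom1, pats, cfg, np.random.default_rng(5))
        return geom1, pats, tab

    def test_destination_synapse_fraction(self, full_longrange):
        """Each destination minicolumn has 20 pyramidals: expect 5 synapses
        per connected pair, mean within 3 s.e. over hundreds of pairs."""
        g, pats, tab = full_longrange
        exc = (tab.receptor == AMPA)
        tgt = g.classify(tab.tgt[exc])
        pyr_tgt = tgt["cls"] == int(CellClass.PYRAMIDAL)
        src = tab.src[exc][pyr_tgt]
        tgt_mc = tgt["minicolumn"][pyr_tgt]
        tgt_layer = tgt["layer"][pyr_tgt]
        pairs = {}
        for s, mc, lay in zip(src, tgt_mc, tgt_layer):
            pairs.setdefault((s, mc, lay), 0)
            pairs[(s, mc, lay)] += 1
        counts = np.array(list(pairs.values()))
        assert len(counts) > 200
        p, n = 0.25, 20
        se = np.sqrt(n * p * (1 - p)) / np.sqrt(len(counts))
        assert abs(counts.mean() - 5.0) < 3 * se

    def test_excitation_stays_within_pattern(self, full_longrange):
        g, pats, tab = full_longrange
        owner = {}
        for p in pats:
            for mc in p.minicolumn_ids:
                owner[mc] = p.pattern_id
        exc = tab.receptor != GABA_A
        sinfo = g.classify(tab.src[exc])
        tinfo = g.classify(tab.tgt[exc])
        pyr2pyr = ((sinfo["cls"] == int(CellClass.PYRAMIDAL))
                   & (tinfo["cls"] == int(CellClass.PYRAMIDAL)))
        for smc, tmc in zip(sinfo["minicolumn"][pyr2pyr],
                            tinfo["minicolumn"][pyr2pyr]):
            assert owner[int(smc)] == owner[int(tmc)]

    def test_single_minicolumn_pattern_has_no_longrange(self, geom1):
        from maskingnet.architecture import AttractorPattern
        pat = [AttractorPattern(0, Area.V1, (3,))]
        tab = wire_longrange(geom1, pat, WiringConfig.model1(),
                             np.random.default_rng(0))
        assert len(tab) == 0


class TestProjections:
    @pytest.fixture(scope="class")
    def projected(self, geom1):
        v1 = generate_patterns_random(geom1, 6, 10, Area.V1, seed=1)
        v2 = generate_patterns_random(geom1, 6, 10, Area.V2, seed=2)
        link = link_patterns(v1, v2)
        cfg = WiringConfig.model1()
        tab = wire_projections(geom1, v1, v2, link, cfg, True,
                               np.random.default_rng(9))
        return geom1, v1, v2, tab

    def test_interareal_delays_exactly_ten_ms(self, projected):
        g, v1, v2, tab = projected
        sinfo = g.classify(tab.src)
        tinfo = g.classify(tab.tgt)
        inter = ((sinfo["area"] != int(Area.LGN))
                 & (sinfo["area"] != tinfo["area"]))
        assert inter.any()
        assert np.all(tab.delay_ms[inter] == 10.0)

    def test_no_feedback_means_no_v2_to_v1(self, geom1):
        v1 = generate_patterns_random(geom1, 4, 10, Area.V1, seed=1)
        v2 = generate_patterns_random(geom1, 4, 10, Area.V2, seed=2)
        link = link_patterns(v1, v2)
        tab = wire_projections(geom1, v1, v2, link, WiringConfig.model1(),
                               False, np.random.default_rng(3))
        sinfo = geom1.classify(tab.src)
        tinfo = geom1.classify(tab.tgt)
        v2_to_v1 = ((sinfo["area"] == int(Area.V2))
                    & (tinfo["area"] == int(Area.V1)))
        assert not v2_to_v1.any()

    def test_pattern_projection_targets_four_minicolumns(self, projected):
        g, v1, v2, tab = projected
        sinfo = g.classify(tab.src)
        tinfo = g.classify(tab.tgt)
        owner_v1 = {mc: p.pattern_id for p in v1 for mc in p.minicolumn_ids}
        ff = ((sinfo["area"] == int(Area.V1)) & (tinfo["area"] == int(Area.V2)))
        by_pattern = {}
        for smc, tmc in zip(sinfo["minicolumn"][ff], tinfo["minicolumn"][ff]):
            pid = owner_v1[int(smc)]
            by_pattern.setdefault(pid, set()).add(int(tmc))
        for pid, dests in by_pattern.items():
            assert len(dests) == 4

    def test_lgn_targets_matching_minicolumn(self, projected):
        g, v1, v2, tab = projected
        sinfo = g.classify(tab.src)
        tinfo = g.classify(tab.tgt)
        lgn = sinfo["area"] == int(Area.LGN)
        pyr_tgt = lgn & (tinfo["cls"] == int(CellClass.PYRAMIDAL))
        assert np.array_equal(sinfo["minicolumn"][pyr_tgt],
                              tinfo["minicolumn"][pyr_tgt])
        assert np.all(tinfo["area"][lgn] == int(Area.V1))
        assert np.all(tinfo["layer"][lgn] == 1)  # L4


class TestDeterminism:
    def test_same_individual_seed_reproduces_table(self, geom1):
        v1 = generate_patterns_random(geom1, 3, 10, Area.V1, seed=1)
        v2 = generate_patterns_random(geom1, 3, 10, Area.V2, seed=2)
        link = link_patterns(v1, v2)
        small = build_geometry(GeometryConfig.model1(scale=0.1))
        nets = [assemble_network(small, v1, v2, link, WiringConfig.model1(),
                                 True, individual_seed=7) for _ in range(2)]
        assert (table_fingerprint(nets[0].synapses)
                == table_fingerprint(nets[1].synapses))

    def test_different_seed_changes_wiring_not_geometry(self, geom1):
        v1 = generate_patterns_random(geom1, 3, 10, Area.V1, seed=1)
        v2 = generate_patterns_random(geom1, 3, 10, Area.V2, seed=2)
        link = link_patterns(v1, v2)
        small = build_geometry(GeometryConfig.model1(scale=0.1))
        a = assemble_network(small, v1, v2, link, WiringConfig.model1(), True, 7)
        b = assemble_network(small, v1, v2, link, WiringConfig.model1(), True, 8)
        assert table_fingerprint(a.synapses) != table_fingerprint(b.synapses)
        assert a.geometry.n_cells == b.geometry.n_cells


def test_table_rejects_bad_rows():
    with pytest.raises(ConfigurationError):
        SynapseTable(np.array([1], np.int32), np.array([1], np.int32),
                     np.zeros(1, np.int8), np.zeros(1, np.int8),
                     np.ones(1, np.float32), np.ones(1, np.float32),
                     np.ones(1, np.float32), np.ones(1, np.float32))
    with pytest.raises(ConfigurationError):
        SynapseTable(np.array([1], np.int32), np.array([2], np.int32),
                     np.zeros(1, np.int8), np.zeros(1, np.int8),
                     np.ones(1, np.float32), -np.ones(1, np.float32),
                     np.ones(1, np.float32), np.ones(1, np.float32))


def test_wiring_config_validation():
    with pytest.raises(ConfigurationError):
        WiringConfig(p_recurrent=1.5)
    with pytest.raises(ConfigurationError):
        WiringConfig(lateral_profile=(0.5, 1.0))
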