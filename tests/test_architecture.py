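"""Geometry indexing and attractor-pattern generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maskingnet.architecture import (Area, CellClass, GeometryConfig,
                                     build_geometry, clone_patterns,
                                     generate_patterns_lines,
                                     generate_patterns_random, link_patterns,
                                     patterns_from_json, patterns_to_json)
from maskingnet.errors import ConfigurationError, GenerationError


class TestGeometry:
    def test_paper_sized_cell_counts(self, geom1, geom2):
        """Both patch configurations reproduce the printed neuron totals."""
        assert geom1.n_cells == 39_424
        assert geom2.n_cells == 99_792
        assert geom1.lgn_locations == 256
        assert geom2.lgn_locations == 648

    def test_closed_form_matches_for_degenerate_grid(self):
        cfg = GeometryConfig(hypercolumn_grid=(1, 1),
                             minicolumns_per_hypercolumn=1,
                             pyramidal_per_minicolumn_per_layer=1,
                             basket_per_minicolumn_per_layer=1,
                             rsnp_per_minicolumn_per_layer=1,
                             lgn_relays_per_location=1)
        g = build_geometry(cfg)
        assert g.n_cells == 1 * 1 + 2 * 1 * 3 * 3 == 19
        assert g.n_cells == g.closed_form_count

    @pytest.mark.parametrize("scale", [0.1, 0.15, 0.25, 0.4, 1.0, 2.0])
    def test_closed_form_invariant_under_scaling(self, scale):
        g = build_geometry(GeometryConfig.model1(scale=scale))
        assert g.n_cells == g.closed_form_count
        assert g.n_pyr >= 1 and g.n_basket >= 1 and g.n_rsnp >= 1

    def test_every_cell_has_exactly_one_address(self, geom1):
        """classify() partitions the id range consistently with cells()."""
        tables = geom1.cell_tables()
        assert len(tables["area"]) == geom1.n_cells
        # round-trip a sample of addresses
        rng = np.random.default_rng(0)
        for _ in range(20):
            area = Area(rng.choice([1, 2]))
            layer = int(rng.integers(3))
            mc = int(rng.integers(geom1.n_minicolumns))
            cls = CellClass(rng.choice([0, 1, 2]))
            ids = geom1.cells(area, layer, mc, cls)
            info = geom1.classify(ids)
            assert (info["area"] == int(area)).all()
            assert (info["layer"] == layer).all()
            assert (info["minicolumn"] == mc).all()
            assert (info["cls"] == int(cls)).all()

    def test_relay_cells_per_location(self, geom1):
        ids = geom1.relay_cells(5)
        assert len(ids) == 10
        info = geom1.classify(ids)
        assert (info["cls"] == int(CellClass.RELAY)).all()
        assert (info["minicolumn"] == 5).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            GeometryConfig(scale=-1.0)
        with pytest.raises(ConfigurationError):
            GeometryConfig(scale=0.0)
        with pytest.raises(ConfigurationError):
            GeometryConfig(hypercolumn_grid=(0, 4))


class TestRandomPatterns:
    def test_paper_pattern_set(self, geom1):
        """18 disjoint memories of 10 minicolumns in distinct hypercolumns."""
        pats = generate_patterns_random(geom1, 18, 10, seed=3)
        assert len(pats) == 18
        used = [mc for p in pats for mc in p.minicolumn_ids]
        assert len(used) == 180 and len(set(used)) == 180
        for p in pats:
            hcs = geom1.hc_of_mc(np.array(p.minicolumn_ids))
            assert len(set(hcs.tolist())) == 10

    @pytest.mark.parametrize("seed", range(100))
    def test_disjointness_and_distinct_hypercolumns_every_seed(self, geom1, seed):
        pats = generate_patterns_random(geom1, 18, 10, seed=seed)
        used = [mc for p in pats for mc in p.minicolumn_ids]
        assert len(set(used)) == len(used)
        for p in pats:
            assert len(set(geom1.hc_of_mc(np.array(p.minicolumn_ids)).tolist())) == len(p)

    def test_single_pattern(self, geom1):
        pats = generate_patterns_random(geom1, 1, 10, seed=0)
        assert len(pats) == 1 and len(pats[0]) == 10

    @pytest.mark.parametrize("seed", range(100))
    def test_full_capacity_request_partitions_small_grid(self, seed):
        """2x2 grid, 2 minicolumns/hc: 4 patterns of 2 exactly partition."""
        g = build_geometry(GeometryConfig(hypercolumn_grid=(2, 2),
                                          minicolumns_per_hypercolumn=2))
        pats = generate_patterns_random(g, 4, 2, seed=seed)
        used = sorted(mc for p in pats for mc in p.minicolumn_ids)
        assert used == list(range(8))
        for p in pats:
            assert len(set(g.hc_of_mc(np.array(p.minicolumn_ids)).tolist())) == 2

    def test_reproducible_from_seed(self, geom1):
        a = generate_patterns_random(geom1, 18, 10, seed=42)
        b = generate_patterns_random(geom1, 18, 10, seed=42)
        assert [p.minicolumn_ids for p in a] == [p.minicolumn_ids for p in b]

    def test_infeasible_requests_raise(self, geom1):
        with pytest.raises(GenerationError):
            generate_patterns_random(geom1, 30, 10)   # 300 > 256 minicolumns
        with pytest.raises(GenerationError):
            generate_patterns_random(geom1, 1, 17)    # > 16 hypercolumns


class TestLinePatterns:
    def test_paper_line_set(self, geom2):
        """72 vertical lines of 9 minicolumns, partitioning the patch."""
        pats = generate_patterns_lines(geom2)
        assert len(pats) == 72
        assert all(len(p) == 9 for p in pats)
        used = [mc for p in pats for mc in p.minicolumn_ids]
        assert sorted(used) == list(range(geom2.n_minicolumns))
        for p in pats:
            rows, cols = geom2.hc_coords(geom2.hc_of_mc(np.array(p.minicolumn_ids)))
            assert len(set(cols.tolist())) == 1          # one grid column
            assert sorted(rows.tolist()) == list(range(9))

    def test_single_column_grid(self):
        g = build_geometry(GeometryConfig(model_id="model2",
                                          hypercolumn_grid=(3, 1),
                                          minicolumns_per_hypercolumn=2))
        pats = generate_patterns_lines(g)
        assert len(pats) == 2 and all(len(p) == 3 for p in pats)

    def test_deterministic_and_idempotent(self, geom2):
        a = generate_patterns_lines(geom2)
        b = generate_patterns_lines(geom2)
        assert [p.minicolumn_ids for p in a] == [p.minicolumn_ids for p in b]


class TestLinkage:
    def test_identity_bijection(self, geom1):
        v1 = generate_patterns_random(geom1, 18, 10, Area.V1, seed=1)
        v2 = generate_patterns_random(geom1, 18, 10, Area.V2, seed=2)
        link = link_patterns(v1, v2)
        assert len(link) == 18
        assert sorted(link.keys()) == sorted(link.values())
        assert all(p.linked_pattern_id is not None for p in v1 + v2)

    def test_empty_and_mismatch(self, geom1):
        assert link_patterns([], []) == {}
        v1 = generate_patterns_random(geom1, 2, 10, seed=1)
        v2 = generate_patterns_random(geom1, 3, 10, seed=2)
        with pytest.raises(GenerationError):
            link_patterns(v1, v2)

    def test_line_linkage_preserves_grid_column(self, geom2):
        v1 = generate_patterns_lines(geom2, Area.V1)
        v2 = generate_patterns_lines(geom2, Area.V2)
        link = link_patterns(v1, v2)
        for p in v1:
            q = v2[link[p.pattern_id]]
            assert p.minicolumn_ids == q.minicolumn_ids


@settings(max_examples=40, deadline=None, derandomize=True)
@given(rows=st.integers(1, 6), cols=st.integers(1, 6),
       mph=st.integers(1, 8), pyr=st.integers(1, 8),
       basket=st.integers(1, 3), rsnp=st.integers(1, 3),
       relays=st.integers(1, 6))
def test_closed_form_count_holds_for_any_geometry(rows, cols, mph, pyr,
                                                  basket, rsnp, relays):
    """N = locations x relays + 2 x minicolumns x 3 x (pyr+basket+rsnp)
    for every admissible configuration."""
    g = build_geometry(GeometryConfig(
        hypercolumn_grid=(rows, cols), minicolumns_per_hypercolumn=mph,
        pyramidal_per_minicolumn_per_layer=pyr,
        basket_per_minicolumn_per_layer=basket,
        rsnp_per_minicolumn_per_layer=rsnp,
        lgn_relays_per_location=relays))
    n_mc = rows * cols * mph
    assert g.n_cells == n_mc * relays + 2 * n_mc * 3 * (pyr + basket + rsnp)
    assert g.n_cells == g.closed_form_count


def test_pattern_json_round_trip(geom1):
    v1 = generate_patterns_random(geom1, 4, 10, Area.V1, seed=5)
    v2 = clone_patterns(v1, Area.V2)
    link_patterns(v1, v2)
    text = patterns_to_json(geom1, v1, v2)
    g2, r1, r2 = patterns_from_json(text)
    assert g2.n_cells == geom1.n_cells
    assert [p.minicolumn_ids for p in r1] == [p.minicolumn_ids for p in v1]
    assert [p.linked_pattern_id for p in r2] == [p.linked_pattern_id for p in v2]
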