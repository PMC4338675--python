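"""Network geometry and stored attractor-memory patterns.

The model covers three areas: an LGN sheet of on-center relay-cell stacks and
two neocortical patches (V1, V2), each a rectangular grid of hypercolumns
subdivided into minicolumns.  Every minicolumn holds pyramidal, basket and
RSNP (regular spiking non-pyramidal) cells in three laminae (L2/3, L4, L5).

Two stored-memory layouts are supported:

* ``model1`` — sparse, orthogonal random patterns: one minicolumn drawn from
  each of several distinct hypercolumns, no minicolumn reused across patterns.
* ``model2`` — vertically oriented line detectors: one pattern per
  (grid column, minicolumn slot) pair, spanning every hypercolumn row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, GenerationError

SCHEMA_VERSION = 1

#: Laminae modeled per cortical area.
LAYERS = ("L23", "L4", "L5")
L23, L4, L5 = 0, 1, 2


class CellClass(IntEnum):
    PYRAMIDAL = 0
    BASKET = 1
    RSNP = 2
    RELAY = 3


class Area(IntEnum):
    LGN = 0
    V1 = 1
    V2 = 2


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class GeometryConfig:
    """Structural parameters of one model instantiation.

    ``scale`` is a desk-scale divisor applied to the per-minicolumn cell
    counts only; grid geometry, pattern structure and analysis thresholds are
    unaffected, so scaled models remain structurally comparable to full-size
    ones.  Scaled counts round half up with a floor of one cell per class so
    that every minicolumn keeps a working excitation/inhibition microcircuit.
    """

    model_id: str = "model1"
    hypercolumn_grid: tuple[int, int] = (4, 4)
    minicolumns_per_hypercolumn: int = 16
    pyramidal_per_minicolumn_per_layer: int = 20
    basket_per_minicolumn_per_layer: int = 2
    rsnp_per_minicolumn_per_layer: int = 2
    lgn_relays_per_location: int = 10
    scale: float = 1.0

    @staticmethod
    def model1(scale: float = 1.0) -> "GeometryConfig":
        return GeometryConfig(model_id="model1", hypercolumn_grid=(4, 4),
                              minicolumns_per_hypercolumn=16, scale=scale)

    @staticmethod
    def model2(scale: float = 1.0) -> "GeometryConfig":
        return GeometryConfig(model_id="model2", hypercolumn_grid=(9, 9),
                              minicolumns_per_hypercolumn=8, scale=scale)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigurationError(f"scale must be > 0, got {self.scale}")
        if min(self.hypercolumn_grid) < 1:
            raise ConfigurationError(f"bad hypercolumn grid {self.hypercolumn_grid}")
        for name in ("minicolumns_per_hypercolumn", "lgn_relays_per_location",
                     "pyramidal_per_minicolumn_per_layer"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if _round_half_up(self.pyramidal_per_minicolumn_per_layer * self.scale) < 1:
            raise ConfigurationError(
                "scale drives pyramidal count below its minimum of 1")

    def scaled_count(self, cls: CellClass) -> int:
        base = {
            CellClass.PYRAMIDAL: self.pyramidal_per_minicolumn_per_layer,
            CellClass.BASKET: self.basket_per_minicolumn_per_layer,
            CellClass.RSNP: self.rsnp_per_minicolumn_per_layer,
        }[cls]
        if base == 0:
            return 0
        return max(1, _round_half_up(base * self.scale))


class NetworkGeometry:
    """Complete cell indexing for one LGN + V1 + V2 instantiation.

    Cell ids are a single contiguous range: relay cells first (location-major,
    ``relays`` per location), then V1, then V2.  Within an area the order is
    layer-major, then minicolumn, then class (pyramidal, basket, RSNP).
    Construction is deterministic: no randomness enters the geometry.
    """

    def __init__(self, config: GeometryConfig):
        self.config = config
        rows, cols = config.hypercolumn_grid
        self.grid_rows, self.grid_cols = rows, cols
        self.n_hypercolumns = rows * cols
        self.mc_per_hc = config.minicolumns_per_hypercolumn
        self.n_minicolumns = self.n_hypercolumns * self.mc_per_hc
        self.lgn_locations = self.n_minicolumns
        self.relays_per_location = config.lgn_relays_per_location

        self.n_pyr = config.scaled_count(CellClass.PYRAMIDAL)
        self.n_basket = config.scaled_count(CellClass.BASKET)
        self.n_rsnp = config.scaled_count(CellClass.RSNP)
        self.cells_per_mc_layer = self.n_pyr + self.n_basket + self.n_rsnp

        self.n_relay_cells = self.lgn_locations * self.relays_per_location
        self.cells_per_area = len(LAYERS) * self.n_minicolumns * self.cells_per_mc_layer
        self.area_offset = {
            Area.LGN: 0,
            Area.V1: self.n_relay_cells,
            Area.V2: self.n_relay_cells + self.cells_per_area,
        }
        self.n_cells = self.n_relay_cells + 2 * self.cells_per_area
        self.n_cortical = 2 * self.cells_per_area

    # -- closed-form check -------------------------------------------------
    @property
    def closed_form_count(self) -> int:
        return (self.lgn_locations * self.relays_per_location
                + 2 * self.n_minicolumns * len(LAYERS) * self.cells_per_mc_layer)

    # -- hypercolumn grid --------------------------------------------------
    def hc_of_mc(self, mc) -> np.ndarray:
        return np.asarray(mc) // self.mc_per_hc

    def hc_coords(self, hc) -> tuple[np.ndarray, np.ndarray]:
        hc = np.asarray(hc)
        return hc // self.grid_cols, hc % self.grid_cols

    def hc_at(self, row: int, col: int) -> int:
        return row * self.grid_cols + col

    def minicolumns_of_hc(self, hc: int) -> np.ndarray:
        start = hc * self.mc_per_hc
        return np.arange(start, start + self.mc_per_hc)

    # -- cell id arithmetic ------------------------------------------------
    def relay_cells(self, location) -> np.ndarray:
        """Relay-cell ids of one LGN location (or an array of locations)."""
        loc = np.atleast_1d(np.asarray(location))
        base = loc[:, None] * self.relays_per_location
        return (base + np.arange(self.relays_per_location)[None, :]).ravel()

    def _mc_layer_base(self, area: Area, layer: int, mc) -> np.ndarray:
        mc = np.asarray(mc)
        return (self.area_offset[area]
                + (layer * self.n_minicolumns + mc) * self.cells_per_mc_layer)

    def cells(self, area: Area, layer: int, mc, cls: CellClass) -> np.ndarray:
        """Ids of every cell of ``cls`` in the given (area, layer, minicolumns)."""
        if area == Area.LGN:
            raise ConfigurationError("use relay_cells() for LGN")
        base = np.atleast_1d(self._mc_layer_base(area, layer, mc))
        if cls == CellClass.PYRAMIDAL:
            off, n = 0, self.n_pyr
        elif cls == CellClass.BASKET:
            off, n = self.n_pyr, self.n_basket
        elif cls == CellClass.RSNP:
            off, n = self.n_pyr + self.n_basket, self.n_rsnp
        else:
            raise ConfigurationError(f"no {cls} cells in cortex")
        return (base[:, None] + off + np.arange(n)[None, :]).ravel()

    def classify(self, cell_ids) -> dict[str, np.ndarray]:
        """Decompose cell ids into (area, layer, minicolumn, class) arrays."""
        ids = np.asarray(cell_ids)
        out = {k: np.empty(ids.shape, dtype=np.int64)
               for k in ("area", "layer", "minicolumn", "cls")}
        is_relay = ids < self.n_relay_cells
        out["area"][is_relay] = int(Area.LGN)
        out["layer"][is_relay] = -1
        out["minicolumn"][is_relay] = ids[is_relay] // self.relays_per_location
        out["cls"][is_relay] = int(CellClass.RELAY)

        cort = ~is_relay
        rel = ids[cort] - self.n_relay_cells
        area = np.where(rel < self.cells_per_area, int(Area.V1), int(Area.V2))
        rel = rel % self.cells_per_area
        mc_layer = rel // self.cells_per_mc_layer
        within = rel % self.cells_per_mc_layer
        cls = np.where(within < self.n_pyr, int(CellClass.PYRAMIDAL),
                       np.where(within < self.n_pyr + self.n_basket,
                                int(CellClass.BASKET), int(CellClass.RSNP)))
        out["area"][cort] = area
        out["layer"][cort] = mc_layer // self.n_minicolumns
        out["minicolumn"][cort] = mc_layer % self.n_minicolumns
        out["cls"][cort] = cls
        return out

    def cell_tables(self) -> dict[str, np.ndarray]:
        """Per-cell (area, layer, minicolumn, class) arrays for all cells."""
        return self.classify(np.arange(self.n_cells))


def build_geometry(config: GeometryConfig) -> NetworkGeometry:
    """Build the complete deterministic cell indexing for ``config``."""
    return NetworkGeometry(config)


@dataclass
class AttractorPattern:
    """One stored memory: an ordered set of minicolumns acting as a feature
    detector, optionally linked to the corresponding pattern in the other
    area."""

    pattern_id: int
    area: Area
    minicolumn_ids: tuple[int, ...]
    geometry_kind: str = "random_orthogonal"  # or "vertical_line"
    linked_pattern_id: int | None = None

    def __len__(self) -> int:
        return len(self.minicolumn_ids)


def generate_patterns_random(geometry: NetworkGeometry,
                             n_patterns: int = 18,
                             minicolumns_per_pattern: int = 10,
                             area: Area = Area.V1,
                             seed: int = 0,
                             max_retries: int = 1000) -> list[AttractorPattern]:
    """Draw sparse orthogonal memory patterns by rejection sampling.

    Each pattern takes one unused minicolumn from each of
    ``minicolumns_per_pattern`` distinct hypercolumns, sampled uniformly.
    Patterns are pairwise disjoint in minicolumns.  If depletion leaves fewer
    eligible hypercolumns than needed, the whole set is redrawn, up to
    ``max_retries`` times.
    """
    k = minicolumns_per_pattern
    if k > geometry.n_hypercolumns:
        raise GenerationError(
            f"{k} minicolumns per pattern exceeds {geometry.n_hypercolumns} "
            "hypercolumns (one minicolumn per distinct hypercolumn)")
    if n_patterns * k > geometry.n_minicolumns:
        raise GenerationError(
            f"capacity exceeded: {n_patterns} patterns x {k} minicolumns "
            f"> {geometry.n_minicolumns} total minicolumns")

    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        free = [list(geometry.minicolumns_of_hc(h)) for h in range(geometry.n_hypercolumns)]
        patterns: list[AttractorPattern] = []
        ok = True
        for pid in range(n_patterns):
            eligible = [h for h in range(geometry.n_hypercolumns) if free[h]]
            if len(eligible) < k:
                ok = False
                break
            hcs = rng.choice(eligible, size=k, replace=False)
            mcs = []
            for h in hcs:
                mc = free[h].pop(rng.integers(len(free[h])))
                mcs.append(int(mc))
            patterns.append(AttractorPattern(pid, area, tuple(mcs),
                                             geometry_kind="random_orthogonal"))
        if ok:
            return patterns
    raise GenerationError(
        f"hypercolumn pool exhausted after {max_retries} retries: could not "
        f"place {n_patterns} patterns of {k} distinct hypercolumns each")


def generate_patterns_lines(geometry: NetworkGeometry,
                            area: Area = Area.V1) -> list[AttractorPattern]:
    """Deterministic vertical-line feature detectors.

    One pattern per (grid column, minicolumn slot): the pattern's minicolumns
    occupy the same slot in every hypercolumn of one grid column.  The
    patterns partition the minicolumn set exactly.
    """
    patterns = []
    pid = 0
    for col in range(geometry.grid_cols):
        for slot in range(geometry.mc_per_hc):
            mcs = tuple(int(geometry.hc_at(row, col) * geometry.mc_per_hc + slot)
                        for row in range(geometry.grid_rows))
            patterns.append(AttractorPattern(pid, area, mcs,
                                             geometry_kind="vertical_line"))
            pid += 1
    return patterns


def clone_patterns(patterns: Sequence[AttractorPattern],
                   area: Area) -> list[AttractorPattern]:
    """Replicate a pattern set into the other area (same minicolumn layout,
    as both patches share the same grid)."""
    return [AttractorPattern(p.pattern_id, area, p.minicolumn_ids,
                             p.geometry_kind) for p in patterns]


def link_patterns(v1_patterns: Sequence[AttractorPattern],
                  v2_patterns: Sequence[AttractorPattern]) -> dict[int, int]:
    """Pair pattern i in V1 with pattern i in V2 (identity bijection; for
    line patterns this preserves grid-column identity by construction)."""
    if len(v1_patterns) != len(v2_patterns):
        raise GenerationError(
            f"pattern count mismatch: {len(v1_patterns)} in V1 "
            f"vs {len(v2_patterns)} in V2")
    linkage = {}
    for p1, p2 in zip(v1_patterns, v2_patterns):
        p1.linked_pattern_id = p2.pattern_id
        p2.linked_pattern_id = p1.pattern_id
        linkage[p1.pattern_id] = p2.pattern_id
    return linkage


# -- serialization ---------------------------------------------------------

def patterns_to_json(geometry: NetworkGeometry,
                     v1_patterns: Sequence[AttractorPattern],
                     v2_patterns: Sequence[AttractorPattern]) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "geometry": asdict(geometry.config),
        "patterns": {
            "V1": [{"pattern_id": p.pattern_id,
                    "minicolumn_ids": list(p.minicolumn_ids),
                    "geometry_kind": p.geometry_kind,
                    "linked_pattern_id": p.linked_pattern_id}
                   for p in v1_patterns],
            "V2": [{"pattern_id": p.pattern_id,
                    "minicolumn_ids": list(p.minicolumn_ids),
                    "geometry_kind": p.geometry_kind,
                    "linked_pattern_id": p.linked_pattern_id}
                   for p in v2_patterns],
        },
    }
    return json.dumps(doc, indent=1)


def patterns_from_json(text: str):
    doc = json.loads(text)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported schema version {doc.get('schema_version')}")
    geo = doc["geometry"]
    geo["hypercolumn_grid"] = tuple(geo["hypercolumn_grid"])
    config = GeometryConfig(**geo)
    geometry = build_geometry(config)
    out = {}
    for area_name, area in (("V1", Area.V1), ("V2", Area.V2)):
        out[area_name] = [AttractorPattern(d["pattern_id"], area,
                                           tuple(d["minicolumn_ids"]),
                                           d["geometry_kind"],
                                           d["linked_pattern_id"])
                          for d in doc["patterns"][area_name]]
    return geometry, out["V1"], out["V2"]
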