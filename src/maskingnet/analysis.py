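"""Attractor-completion detection, masking curves and type classification.

Completion is the proxy for target perception: a stored pattern counts as
fully activated in an area when enough of its minicolumns fire enough
layer-2/3 pyramidal spikes inside the counting window (7 of 10 minicolumns
with at least 10 spikes each at paper defaults; the fraction 0.7 is kept for
other pattern sizes).  Regional activation — completion in both V1 and V2 —
is what conscious perception is assumed to require.

A masking function is the percentage of completed targets against SOA.
Type-A masking decreases monotonically with SOA; type-B is U-shaped, with
maximal masking at an intermediate SOA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .architecture import Area, AttractorPattern, CellClass, L23
from .engine import SpikeRaster
from .errors import ConfigurationError

CONDITIONS = ("target_only", "mask_only", "target_mask")
SCOPES = ("V1", "V2", "both")


@dataclass(frozen=True)
class CompletionCriterion:
    """Thresholds deciding when a pattern is 'complete' in an area.

    ``min_minicolumns=None`` applies the default fraction rule
    ceil(0.7 * pattern size).
    """

    min_minicolumns: int | None = None
    min_spikes_per_minicolumn: int = 10
    layer: int = L23

    def required_minicolumns(self, pattern_size: int) -> int:
        if self.min_minicolumns is not None:
            return self.min_minicolumns
        return math.ceil(0.7 * pattern_size)


def detect_completion(raster: SpikeRaster, pattern: AttractorPattern,
                      criterion: CompletionCriterion,
                      window: tuple[float, float]) -> bool:
    """True iff enough of the pattern's minicolumns each reach the spike
    threshold (layer-2/3 pyramidal spikes) within ``window``."""
    if pattern.area == Area.LGN:
        raise ConfigurationError("completion is defined for cortical areas")
    t0, t1 = window
    counts = raster.minicolumn_spike_counts(
        pattern.area, criterion.layer, np.asarray(pattern.minicolumn_ids),
        CellClass.PYRAMIDAL, t0, t1)
    need = criterion.required_minicolumns(len(pattern))
    return int((counts >= criterion.min_spikes_per_minicolumn).sum()) >= need


def detect_completion_scopes(raster: SpikeRaster,
                             v1_pattern: AttractorPattern,
                             v2_pattern: AttractorPattern,
                             criterion: CompletionCriterion,
                             window: tuple[float, float]) -> dict[str, bool]:
    """Completion per scope; 'both' requires V1 and V2 simultaneously."""
    v1 = detect_completion(raster, v1_pattern, criterion, window)
    v2 = detect_completion(raster, v2_pattern, criterion, window)
    return {"V1": v1, "V2": v2, "both": v1 and v2}


def masking_curve(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-trial completion flags into completion percentages.

    ``results`` must carry columns (individual, trial, condition, soa_ms,
    complete_V1, complete_V2, complete_both).  Returns tidy rows
    (condition, soa_ms, scope, n_trials, n_complete, percent); percentages
    are exact ratios of integer counts.
    """
    required = {"condition", "soa_ms", "complete_V1", "complete_V2",
                "complete_both"}
    missing = required - set(results.columns)
    if missing:
        raise ConfigurationError(f"result table lacks columns {sorted(missing)}")
    rows = []
    for (cond, soa), grp in results.groupby(["condition", "soa_ms"],
                                            dropna=False, sort=True):
        for scope in SCOPES:
            flags = grp[f"complete_{scope}"].to_numpy(dtype=bool)
            if len(flags) == 0:
                raise ConfigurationError(
                    f"empty result cell for ({cond}, {soa}, {scope})")
            rows.append({"condition": cond, "soa_ms": soa, "scope": scope,
                         "n_trials": len(flags),
                         "n_complete": int(flags.sum()),
                         "percent": 100.0 * int(flags.sum()) / len(flags)})
    return pd.DataFrame(rows)


def classify_masking_type(percent_by_soa: Sequence[float],
                          tolerance: float = 4.0) -> str:
    """Classify a completion-vs-SOA curve.

    * ``type_A`` — completion nondecreasing in SOA within tolerance
      (masking effect decays monotonically);
    * ``type_B`` — some interior SOA lies below both endpoints by more than
      tolerance (U-shaped visibility);
    * ``flat``  — total range within tolerance;
    * ``ambiguous`` otherwise.
    """
    y = np.asarray(percent_by_soa, dtype=float)
    if len(y) < 4:
        raise ConfigurationError("need at least 4 SOA points to classify")
    if y.max() - y.min() <= tolerance:
        return "flat"
    interior_dip = any(y[i] < y[0] - tolerance and y[i] < y[-1] - tolerance
                       for i in range(1, len(y) - 1))
    nondecreasing = all(y[i + 1] >= y[i] - tolerance for i in range(len(y) - 1))
    if nondecreasing and not interior_dip:
        return "type_A"
    if interior_dip:
        return "type_B"
    return "ambiguous"


def classify_curve_table(curve: pd.DataFrame, scope: str = "both",
                         condition: str = "target_mask",
                         tolerance: float | None = None) -> str:
    """Classify the masking type of one (condition, scope) slice of a curve
    table; default tolerance is one trial's worth of percentage."""
    sel = curve[(curve.scope == scope) & (curve.condition == condition)
                & curve.soa_ms.notna()].sort_values("soa_ms")
    if tolerance is None:
        tolerance = 100.0 / max(1, int(sel.n_trials.max()))
    return classify_masking_type(sel.percent.to_numpy(), tolerance)
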