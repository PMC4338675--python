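"""Backward-masking experiment protocol.

A *trial* presents, at one-second spacing: the target alone, the mask alone,
and target+mask at each SOA of a sliding set (20..120 ms).  Stimulation is
delivered by forcing LGN relay spikes: each stimulated location fires all of
its relay cells at 50 Hz for the presentation duration, i.e. one spike per
relay for a 20 ms target and three for a 60 ms mask, at independent uniform
times within the window.

Model 1 presents an abstract target (4 random minicolumns of a stored
pattern) and a metacontrast noise mask (4 or 5 minicolumns of *other*
patterns in the same hypercolumns).  Model 2 presents a vertical target line
and two flanking parallel mask lines 1-3 hypercolumn columns away.  Each
presentation uses a fresh stored pattern, since attractor adaptation does
not fully recover within the one-second spacing.

An *experiment* is n_individuals x n_trials trials (5 x 5 = 25 by default):
individuals differ in wiring (and, for model 1, pattern sets); trials differ
in noise and stimulus draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .architecture import (Area, AttractorPattern, CellClass, GeometryConfig,
                           NetworkGeometry, build_geometry, clone_patterns,
                           generate_patterns_lines, generate_patterns_random,
                           link_patterns)
from .analysis import CompletionCriterion, detect_completion_scopes
from .cells import BackgroundDrive
from .connectivity import Network, WiringConfig, assemble_network
from .engine import EngineConfig, SpikeRaster, StimulusSchedule, force_spikes, run
from .errors import CalibrationError, ConfigurationError

SOA_SET = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0)


@dataclass(frozen=True)
class StimulusSpec:
    """One presentation's stimulated LGN locations and timing."""

    kind: str                     # target | noise_mask | line_mask
    locations: tuple[int, ...]
    duration_ms: float
    relay_rate_hz: float = 50.0

    @property
    def spikes_per_relay(self) -> int:
        # round-half-even: a 20 ms target gives 1 spike, a 60 ms mask 3,
        # the 50 ms line mask (expectation 2.5 at ~50 Hz) gives 2
        return round(self.relay_rate_hz * self.duration_ms / 1000.0)


def make_stimulus(geometry: NetworkGeometry, spec: StimulusSpec,
                  onset_ms: float, rng: np.random.Generator) -> StimulusSchedule:
    """Forced relay spikes for one presentation, uniform over the window."""
    if not spec.locations:
        raise ConfigurationError("stimulus location set is empty")
    k = spec.spikes_per_relay
    if k == 0 or spec.duration_ms <= 0:
        return StimulusSchedule()
    relays = geometry.relay_cells(np.asarray(spec.locations))
    ids = np.repeat(relays, k)
    times = onset_ms + rng.uniform(0.0, spec.duration_ms, size=len(ids))
    return force_spikes(geometry, ids, times)


@dataclass
class Presentation:
    condition: str                # target_only | mask_only | target_mask
    soa_ms: float | None
    onset_ms: float               # target onset (actual or nominal)
    v1_target: AttractorPattern
    v2_target: AttractorPattern
    target_spec: StimulusSpec | None
    mask_spec: StimulusSpec | None


@dataclass
class TrialPlan:
    presentations: list[Presentation]
    schedule: StimulusSchedule
    spacing_ms: float
    duration_ms: float


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one masking experiment (both model flavors)."""

    model_id: str = "model1"
    scale: float = 1.0
    feedback: bool = True
    mask_points: int = 4              # model 1 noise-mask salience (4 or 5)
    mask_distance: int = 2            # model 2: mask lines this many columns away
    target_column: int = 4            # model 2: grid column of the target line
    soas: tuple[float, ...] = SOA_SET
    spacing_ms: float = 1000.0
    settle_ms: float = 100.0          # stimulus onset offset within each slot
    target_duration_ms: float = 20.0
    mask_duration_ms: float = 60.0
    relay_rate_hz: float = 50.0
    n_individuals: int = 5
    n_trials: int = 5
    n_patterns: int = 18              # model 1 stored memories per area
    pattern_size: int = 10            # model 1 minicolumns per memory
    target_points: int = 4            # model 1 stimulated target locations
    wiring: WiringConfig = field(default_factory=WiringConfig.model1)
    background: BackgroundDrive = field(default_factory=BackgroundDrive)
    criterion: CompletionCriterion = field(default_factory=CompletionCriterion)
    dt_ms: float = 0.1

    def __post_init__(self):
        if self.scale <= 0:
            raise ConfigurationError(f"scale must be > 0, got {self.scale}")
        if self.n_individuals < 1 or self.n_trials < 1:
            raise ConfigurationError("n_individuals and n_trials must be >= 1")
        if self.soas != tuple(sorted(self.soas)):
            raise ConfigurationError("SOAs must be strictly increasing")
        if self.soas and self.soas[-1] + self.settle_ms >= self.spacing_ms:
            raise ConfigurationError("largest SOA exceeds presentation spacing")

    @staticmethod
    def model1(**kw) -> "ExperimentConfig":
        kw.setdefault("wiring", WiringConfig.model1())
        return ExperimentConfig(model_id="model1", mask_duration_ms=60.0, **kw)

    @staticmethod
    def model2(**kw) -> "ExperimentConfig":
        kw.setdefault("wiring", WiringConfig.model2())
        return ExperimentConfig(model_id="model2", mask_duration_ms=50.0, **kw)

    def geometry_config(self) -> GeometryConfig:
        if self.model_id == "model1":
            return GeometryConfig.model1(scale=self.scale)
        return GeometryConfig.model2(scale=self.scale)


def build_model(config: ExperimentConfig, individual_seed: int) -> Network:
    """Build one individual: geometry, patterns, linkage, wiring."""
    geometry = build_geometry(config.geometry_config())
    if config.model_id == "model1":
        v1 = generate_patterns_random(geometry, config.n_patterns,
                                      config.pattern_size, Area.V1,
                                      seed=individual_seed * 2 + 1)
        v2 = generate_patterns_random(geometry, config.n_patterns,
                                      config.pattern_size, Area.V2,
                                      seed=individual_seed * 2 + 2)
    else:
        v1 = generate_patterns_lines(geometry, Area.V1)
        v2 = generate_patterns_lines(geometry, Area.V2)
    linkage = link_patterns(v1, v2)
    return assemble_network(geometry, v1, v2, linkage, config.wiring,
                            feedback_enabled=config.feedback,
                            individual_seed=individual_seed)


def _model1_presentation(network: Network, config: ExperimentConfig,
                         pattern: AttractorPattern,
                         rng: np.random.Generator):
    """Stimulated target dots + noise-mask locations for one presentation."""
    g = network.geometry
    mc_owner = {}
    for p in network.v1_patterns:
        for mc in p.minicolumn_ids:
            mc_owner[mc] = p.pattern_id
    target_mcs = rng.choice(np.asarray(pattern.minicolumn_ids),
                            size=config.target_points, replace=False)
    # mask: same hypercolumns as the stimulated dots (plus extra pattern
    # hypercolumns at higher salience), minicolumns of non-target patterns
    hcs = [int(g.hc_of_mc(mc)) for mc in target_mcs]
    if config.mask_points > config.target_points:
        spare = [int(g.hc_of_mc(mc)) for mc in pattern.minicolumn_ids
                 if int(g.hc_of_mc(mc)) not in hcs]
        extra = rng.choice(np.asarray(spare),
                           size=config.mask_points - config.target_points,
                           replace=False)
        hcs = hcs + [int(h) for h in extra]
    mask_mcs = []
    for hc in hcs:
        cands = [int(mc) for mc in network.geometry.minicolumns_of_hc(hc)
                 if mc_owner.get(int(mc), pattern.pattern_id) != pattern.pattern_id
                 and int(mc) in mc_owner]
        mask_mcs.append(int(rng.choice(np.asarray(cands))))
    target_spec = StimulusSpec("target", tuple(int(m) for m in target_mcs),
                               config.target_duration_ms, config.relay_rate_hz)
    mask_spec = StimulusSpec("noise_mask", tuple(mask_mcs),
                             config.mask_duration_ms, config.relay_rate_hz)
    return target_spec, mask_spec


def _model2_presentation(network: Network, config: ExperimentConfig,
                         slot: int):
    """Target line + two flanking mask lines, one fresh slot per presentation."""
    g = network.geometry
    d = config.mask_distance
    col = config.target_column
    if not (0 <= col - d and col + d < g.grid_cols):
        raise ConfigurationError(
            f"mask distance {d} from column {col} leaves the grid")
    mph = g.mc_per_hc
    pid = col * mph + slot
    target = next(p for p in network.v1_patterns if p.pattern_id == pid)
    mask_ids = [(col - d) * mph + slot, (col + d) * mph + slot]
    mask_mcs = []
    for mid in mask_ids:
        mask_mcs.extend(next(p for p in network.v1_patterns
                             if p.pattern_id == mid).minicolumn_ids)
    target_spec = StimulusSpec("target", target.minicolumn_ids,
                               config.target_duration_ms, config.relay_rate_hz)
    mask_spec = StimulusSpec("line_mask", tuple(mask_mcs),
                             config.mask_duration_ms, config.relay_rate_hz)
    return target, target_spec, mask_spec


def build_trial(network: Network, config: ExperimentConfig,
                trial_seed: int) -> TrialPlan:
    """Lay out one trial: target-only, mask-only, then each SOA, at 1 s
    spacing, and draw all stimulus spike times."""
    rng = np.random.default_rng(trial_seed)
    g = network.geometry
    conditions = [("target_only", None), ("mask_only", None)] \
        + [("target_mask", s) for s in config.soas]
    v2_by_id = {p.pattern_id: p for p in network.v2_patterns}

    if config.model_id == "model1":
        pool = rng.permutation(len(network.v1_patterns))

    presentations: list[Presentation] = []
    schedules: list[StimulusSchedule] = []
    for k, (cond, soa) in enumerate(conditions):
        onset = k * config.spacing_ms + config.settle_ms
        if config.model_id == "model1":
            pattern = network.v1_patterns[int(pool[k])]
            t_spec, m_spec = _model1_presentation(network, config, pattern, rng)
        else:
            pattern, t_spec, m_spec = _model2_presentation(network, config, k)
        v2_pattern = v2_by_id[network.linkage[pattern.pattern_id]]
        pres = Presentation(cond, soa, onset, pattern, v2_pattern,
                            t_spec if cond != "mask_only" else None,
                            m_spec if cond != "target_only" else None)
        presentations.append(pres)
        if pres.target_spec is not None:
            schedules.append(make_stimulus(g, pres.target_spec, onset, rng))
        if pres.mask_spec is not None:
            mask_onset = onset + (soa if soa is not None else 0.0)
            schedules.append(make_stimulus(g, pres.mask_spec, mask_onset, rng))
    duration = len(conditions) * config.spacing_ms
    return TrialPlan(presentations, StimulusSchedule.concat(schedules),
                     config.spacing_ms, duration)


def run_trial(network: Network, config: ExperimentConfig, trial_seed: int,
              individual: int = 0, trial: int = 0) -> pd.DataFrame:
    """Simulate one trial and score completion for every presentation."""
    plan = build_trial(network, config, trial_seed)
    ec = EngineConfig(duration_ms=plan.duration_ms, dt_ms=config.dt_ms,
                      trial_seed=trial_seed, background=config.background)
    raster = run(network, plan.schedule, ec)
    rows = []
    for k, pres in enumerate(plan.presentations):
        window = (pres.onset_ms, (k + 1) * config.spacing_ms)
        scopes = detect_completion_scopes(raster, pres.v1_target,
                                          pres.v2_target, config.criterion,
                                          window)
        rows.append({"individual": individual, "trial": trial,
                     "condition": pres.condition,
                     "soa_ms": np.nan if pres.soa_ms is None else pres.soa_ms,
                     "complete_V1": scopes["V1"], "complete_V2": scopes["V2"],
                     "complete_both": scopes["both"]})
    return pd.DataFrame(rows)


def _seed_streams(base_seed: int, n_individuals: int, n_trials: int):
    """Derived (individual, trial) seed pairs, all below 2**31."""
    ss = np.random.SeedSequence(base_seed)
    states = ss.generate_state(n_individuals * (n_trials + 1)).astype(np.int64)
    states = (states % (2 ** 31 - 1)).reshape(n_individuals, n_trials + 1)
    return states

def run_experiment(config: ExperimentConfig, base_seed: int = 0,
                   progress: bool = False) -> pd.DataFrame:
    """Full trial set: n_individuals wirings x n_trials noise seeds."""
    seeds = _seed_streams(base_seed, config.n_individuals, config.n_trials)
    frames = []
    for ind in range(config.n_individuals):
        network = build_model(config, int(seeds[ind, 0]))
        for tr in range(config.n_trials):
            if progress:
                print(f"[maskingnet] individual {ind} trial {tr}", flush=True)
            frames.append(run_trial(network, config, int(seeds[ind, tr + 1]),
                                    individual=ind, trial=tr))
    return pd.concat(frames, ignore_index=True)


# -- conductance calibration ----------------------------------------------

def _probe_config(config: ExperimentConfig) -> ExperimentConfig:
    return replace(config, soas=())       # target-only + mask-only, 2 s


def calibration_metrics(config: ExperimentConfig, exc_scale: float,
                        inh_scale: float, n_probes: int = 10,
                        base_seed: int = 12345) -> dict:
    """Run short probe trials and measure the three calibration criteria."""
    probe = replace(_probe_config(config),
                    wiring=replace(config.wiring, exc_scale=exc_scale,
                                   inh_scale=inh_scale))
    n_ind = min(probe.n_individuals, 2)
    seeds = _seed_streams(base_seed, n_ind, max(1, n_probes // n_ind))
    rows = []
    rates = []
    for ind in range(n_ind):
        network = build_model(probe, int(seeds[ind, 0]))
        n_pyr_cells = (network.geometry.n_pyr * network.geometry.n_minicolumns
                       * 3 * 2)
        for tr in range(seeds.shape[1] - 1):
            plan = build_trial(network, probe, int(seeds[ind, tr + 1]))
            ec = EngineConfig(duration_ms=plan.duration_ms, dt_ms=probe.dt_ms,
                              trial_seed=int(seeds[ind, tr + 1]),
                              background=probe.background)
            raster = run(network, plan.schedule, ec)
            info = raster.geometry.classify(raster.cell_ids)
            n_pyr_spikes = int((info["cls"] == int(CellClass.PYRAMIDAL)).sum())
            rates.append(1000.0 * n_pyr_spikes / n_pyr_cells / plan.duration_ms)
            for k, pres in enumerate(plan.presentations):
                window = (pres.onset_ms, (k + 1) * probe.spacing_ms)
                scopes = detect_completion_scopes(
                    raster, pres.v1_target, pres.v2_target, probe.criterion,
                    window)
                rows.append({"condition": pres.condition, **scopes})
    df = pd.DataFrame(rows)
    tgt = df[df.condition == "target_only"]
    msk = df[df.condition == "mask_only"]
    return {
        "target_completion": float(tgt.both.mean()),
        "mask_false_completion": float(msk.both.mean()),
        "mask_single_area_rate": float((msk.V1 | msk.V2).mean()),
        "mean_pyr_rate_hz": float(np.mean(rates)),
    }


def calibrate(config: ExperimentConfig,
              exc_grid: Sequence[float] = (0.7, 1.0, 1.4, 2.0),
              inh_grid: Sequence[float] = (0.7, 1.0, 1.4),
              n_probes: int = 10, bisect_steps: int = 3,
              base_seed: int = 12345) -> tuple[float, float]:
    """Find global conductance scales meeting the calibration contract.

    Contract over the probe trials: target-only completes regionally in at
    least 90%, mask-only never completes the target pattern, and mean
    pyramidal firing stays below 100 Hz.  Coarse grid search first, then
    bisection refinement on the excitatory scale.  Raises
    :class:`CalibrationError` with a diagnostic report when no setting
    satisfies all three criteria.
    """
    def ok(m):
        return (m["target_completion"] >= 0.9
                and m["mask_false_completion"] == 0.0
                and m["mean_pyr_rate_hz"] < 100.0)

    report = []
    best = None
    for inh in inh_grid:
        lo_fail, hi_pass = None, None
        for exc in exc_grid:
            m = calibration_metrics(config, exc, inh, n_probes, base_seed)
            report.append((exc, inh, m))
            if ok(m):
                best = (exc, inh)
                hi_pass = exc
                break
            if m["target_completion"] < 0.9:
                lo_fail = exc
        if best and lo_fail is not None and hi_pass is not None:
            # refine downward: smallest excitation that still completes
            lo, hi = lo_fail, hi_pass
            for _ in range(bisect_steps):
                mid = 0.5 * (lo + hi)
                m = calibration_metrics(config, mid, best[1], n_probes, base_seed)
                report.append((mid, best[1], m))
                if ok(m):
                    hi = mid
                    best = (mid, best[1])
                else:
                    lo = mid
        if best:
            return best
    lines = "\n".join(
        f"  exc={e:.3f} inh={i:.3f}: target={m['target_completion']:.2f} "
        f"mask_false={m['mask_false_completion']:.2f} "
        f"rate={m['mean_pyr_rate_hz']:.1f} Hz" for e, i, m in report)
    raise CalibrationError(
        "no conductance scale satisfied the calibration contract "
        "(target-only >= 90%, mask-only 0%, mean rate < 100 Hz):\n" + lines)
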