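"""Configuration files, presets, fixture networks and run manifests.

The whole experiment — geometry, wiring conductances, background drive,
protocol timings and completion criterion — lives in one human-readable
YAML document with an explicit schema version, so a simulation is fully
reproducible from (config, seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, replace
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .analysis import CompletionCriterion
from .architecture import (Area, AttractorPattern, GeometryConfig,
                           build_geometry, clone_patterns,
                           generate_patterns_lines, generate_patterns_random,
                           link_patterns)
from .cells import BackgroundDrive
from .connectivity import Network, WiringConfig, assemble_network
from .errors import ConfigurationError
from .protocol import ExperimentConfig

CONFIG_SCHEMA_VERSION = 1


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = set(data) - valid
    if bad:
        raise ConfigurationError(
            f"unknown key(s) {sorted(bad)} in section '{section}'")
    for key, val in data.items():
        if isinstance(val, list):
            data[key] = tuple(val)
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"bad value in section '{section}': {exc}")


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> ExperimentConfig:
    if not isinstance(doc, dict):
        raise ConfigurationError("config document must be a mapping")
    version = doc.get("schema_version")
    if version != CONFIG_SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported schema_version {version!r} "
            f"(expected {CONFIG_SCHEMA_VERSION})")
    wiring = _build_section(WiringConfig, doc.get("wiring", {}) or {}, "wiring")
    background = _build_section(BackgroundDrive, doc.get("background", {}) or {},
                                "background")
    criterion = _build_section(CompletionCriterion, doc.get("criterion", {}) or {},
                               "criterion")
    exp = dict(doc.get("experiment", {}) or {})
    exp["wiring"] = wiring
    exp["background"] = background
    exp["criterion"] = criterion
    return _build_section(ExperimentConfig, exp, "experiment")


def config_to_dict(config: ExperimentConfig) -> dict:
    exp = asdict(config)
    return {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "wiring": exp.pop("wiring"),
        "background": exp.pop("background"),
        "criterion": exp.pop("criterion"),
        "experiment": exp,
    }


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_preset(name: str) -> ExperimentConfig:
    """Load a packaged preset ('model1' or 'model2')."""
    ref = resources.files("maskingnet.presets").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise ConfigurationError(f"no packaged preset named {name!r}")
    return config_from_dict(yaml.safe_load(ref.read_text()))


def config_hash(config: ExperimentConfig) -> str:
    """Stable content hash of the effective configuration."""
    text = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# -- fixture networks ------------------------------------------------------

FIXTURE_PRESETS = ("tiny_model1", "tiny_model2")


def fixture_network(preset: str, feedback: bool = True,
                    individual_seed: int = 0) -> Network:
    """Miniature assembled networks for fast integration tests.

    ``tiny_model1``: 2x2 hypercolumns, 4 minicolumns each, 4/1/1 cells per
    minicolumn-layer, 4 relays per location, 3 random patterns of 4
    minicolumns.  ``tiny_model2``: 3x3 grid, 2 minicolumns each (6 vertical
    line patterns of 3 minicolumns).
    """
    if preset == "tiny_model1":
        geo = GeometryConfig(model_id="model1", hypercolumn_grid=(2, 2),
                             minicolumns_per_hypercolumn=4,
                             pyramidal_per_minicolumn_per_layer=4,
                             basket_per_minicolumn_per_layer=1,
                             rsnp_per_minicolumn_per_layer=1,
                             lgn_relays_per_location=4)
        geometry = build_geometry(geo)
        v1 = generate_patterns_random(geometry, 3, 4, Area.V1,
                                      seed=individual_seed * 2 + 1)
        v2 = generate_patterns_random(geometry, 3, 4, Area.V2,
                                      seed=individual_seed * 2 + 2)
        wiring = WiringConfig.model1()
    elif preset == "tiny_model2":
        geo = GeometryConfig(model_id="model2", hypercolumn_grid=(3, 3),
                             minicolumns_per_hypercolumn=2,
                             pyramidal_per_minicolumn_per_layer=4,
                             basket_per_minicolumn_per_layer=1,
                             rsnp_per_minicolumn_per_layer=1,
                             lgn_relays_per_location=4)
        geometry = build_geometry(geo)
        v1 = generate_patterns_lines(geometry, Area.V1)
        v2 = generate_patterns_lines(geometry, Area.V2)
        wiring = WiringConfig.model2()
    else:
        raise ConfigurationError(
            f"unknown fixture preset {preset!r}; choose from {FIXTURE_PRESETS}")
    linkage = link_patterns(v1, v2)
    return assemble_network(geometry, v1, v2, linkage, wiring,
                            feedback_enabled=feedback,
                            individual_seed=individual_seed)


# -- run manifest ----------------------------------------------------------

def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


class RunManifest:
    """Provenance record for one pipeline run: config hash, seeds, software
    version, per-stage wall times and output-file checksums."""

    def __init__(self, config: ExperimentConfig, seed: int):
        self.doc = {
            "schema_version": CONFIG_SCHEMA_VERSION,
            "software_version": __version__,
            "config_hash": config_hash(config),
            "seed": seed,
            "stages": {},
            "outputs": {},
        }
        self._t0 = None
        self._stage = None

    def start(self, stage: str) -> None:
        self._stage, self._t0 = stage, time.monotonic()

    def finish(self) -> None:
        if self._stage is not None:
            self.doc["stages"][self._stage] = round(time.monotonic() - self._t0, 3)
            self._stage = None

    def add_output(self, path: str | Path) -> None:
        self.doc["outputs"][str(path)] = file_checksum(path)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.doc, indent=1))

    @staticmethod
    def load(path: str | Path) -> dict:
        return json.loads(Path(path).read_text())
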