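"""Run configuration, compound-file IO and pipeline wiring.

A run configuration is a flat YAML/JSON document naming the compounds,
the individual or population, the dose regimen, solver settings and the
scenario grids. Compound parameter files are flat key-value YAML/JSON
documents whose keys match :class:`~irinopbpk.compound_model.CompoundProperties`
fields; the three shipped species can be referenced as ``builtin:cpt11``,
``builtin:sn38`` and ``builtin:sn38g``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .compound_model import (
    CompoundProperties,
    ConfigurationError,
    partition_coefficients,
)
from .pbpk_engine import DoseRegimen, PBPKModel, assemble_model, irinotecan_network
from .physiology import PopulationSpec, VirtualIndividual, build_reference_individual

__all__ = [
    "RunConfig",
    "load_config",
    "load_compound",
    "builtin_compound",
    "build_model",
    "config_hash",
    "OBSERVED_CSV_COLUMNS",
]

OBSERVED_CSV_COLUMNS = ("time_h", "species", "concentration_umol_per_l")

_BUILTIN_FILES = {"cpt11": "cpt11.yaml", "sn38": "sn38.yaml",
                  "sn38g": "sn38g.yaml"}

_COMPOUND_FIELDS = {
    "name", "molecular_weight", "effective_molecular_weight", "log_p",
    "fraction_unbound", "pka_acid", "pka_base", "solubility_at_ph7",
    "gfr_fraction", "specific_biliary_clearance",
}


def builtin_compound(key: str) -> CompoundProperties:
    """Load one of the shipped compound files (cpt11, sn38, sn38g)."""
    if key not in _BUILTIN_FILES:
        raise ConfigurationError(f"unknown builtin compound {key!r}")
    text = resources.files("irinopbpk.data").joinpath(
        _BUILTIN_FILES[key]).read_text()
    return _compound_from_mapping(yaml.safe_load(text), f"builtin:{key}")


def load_compound(source: str | Path) -> CompoundProperties:
    """Load a compound parameter file (YAML/JSON) or a builtin reference."""
    if isinstance(source, str) and source.startswith("builtin:"):
        return builtin_compound(source.split(":", 1)[1])
    path = Path(source)
    if not path.exists():
        raise ConfigurationError(f"compound file not found: {path}")
    data = yaml.safe_load(path.read_text())
    return _compound_from_mapping(data, str(path))


def _compound_from_mapping(data: Mapping[str, Any],
                           origin: str) -> CompoundProperties:
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{origin}: compound file is not a mapping")
    unknown = set(data) - _COMPOUND_FIELDS
    if unknown:
        raise ConfigurationError(f"{origin}: unknown keys {sorted(unknown)}")
    try:
        return CompoundProperties(**data)
    except TypeError as exc:
        raise ConfigurationError(f"{origin}: {exc}") from None


@dataclass
class RunConfig:
    """Parsed run configuration with defaults filled in."""

    seed: int
    compounds: list[str] = field(default_factory=lambda: [
        "builtin:cpt11", "builtin:sn38", "builtin:sn38g"])
    individual: dict = field(default_factory=dict)
    population: dict = field(default_factory=lambda: {"n_individuals": 100})
    regimen: dict = field(default_factory=lambda: {
        "compound": "CPT-11", "dose_per_bsa": 350.0, "infusion_duration": 30.0})
    network: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=lambda: {
        "t_end": 25.5, "grid_step": 0.02, "method": "expm"})
    calibration: dict = field(default_factory=dict)
    ph_scan: dict = field(default_factory=lambda: {
        "plasma": [6.0, 6.5, 7.0, 7.5], "tumor": [6.0, 6.5, 7.0, 7.5]})
    output_dir: str = "out"
    log_level: str = "INFO"

    def dose_regimen(self) -> DoseRegimen:
        return DoseRegimen(**self.regimen)

    def population_spec(self) -> PopulationSpec:
        pop = dict(self.population)
        pop.setdefault("random_seed", self.seed)
        return PopulationSpec(**pop)

    def load_compounds(self) -> list[CompoundProperties]:
        return [load_compound(c) for c in self.compounds]

    def reference_individual(self) -> VirtualIndividual:
        return build_reference_individual(**self.individual)

    def output_grid(self) -> np.ndarray:
        t_end = self.simulation.get("t_end", 25.5)
        step = self.simulation.get("grid_step", 0.02)
        return np.arange(0.0, t_end + 1e-12, step)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: config is not a mapping")
    if "seed" not in data:
        raise ConfigurationError(f"{path}: a seed is mandatory")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def build_model(config: RunConfig,
                individual: VirtualIndividual | None = None) -> PBPKModel:
    """Assemble the whole-body model described by ``config``."""
    if individual is None:
        individual = config.reference_individual()
    compounds = config.load_compounds()
    compositions = {
        name: {"water_fraction": organ.water_fraction,
               "lipid_fraction": organ.lipid_fraction}
        for name, organ in individual.organs.items()
    }
    kps = {c.name: partition_coefficients(c, compositions) for c in compounds}
    network = irinotecan_network(**config.network)
    return assemble_model(individual, compounds, kps, network)


def config_hash(config: RunConfig) -> str:
    """Stable hash identifying the numerical content of a configuration."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
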