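"""Run configuration: typed sections, YAML loading, strict validation.

All physical parameters carry their unit in the key name (``_A`` angstrom,
``_A2`` square angstrom, ``_M`` mol/L, ``_K`` kelvin, ``_ns`` nanoseconds).
Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from ..constants import debye_length
from ..errors import ConfigError


@dataclass
class SolverConfig:
    """Mean-field solver settings (box, electrolyte, relaxation)."""

    box_edge_A: float = 256.0
    grid_points: int = 64
    ionic_strength_M: float = 0.15
    temperature_K: float = 310.0
    relative_permittivity: float = 80.0
    convergence_tol: float = 1e-6
    max_iter: int = 500
    mixing: float = 0.5
    clearance_A: float = 2.0
    nonlinear_ions: bool = False

    def validate(self) -> None:
        for key in ("box_edge_A", "ionic_strength_M", "temperature_K",
                    "relative_permittivity", "convergence_tol"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be > 0 "
                                  f"(got {getattr(self, key)})")
        if self.grid_points < 8:
            raise ConfigError("grid_points must be >= 8")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if not (0.0 < self.mixing <= 1.0):
            raise ConfigError("mixing must lie in (0, 1]")
        if self.clearance_A < 0:
            raise ConfigError("clearance_A must be >= 0")
        if self.grid_spacing_A > self.debye_length_A / 2.0 + 1e-12:
            warnings.warn(
                f"grid spacing {self.grid_spacing_A:.2f} A exceeds half the "
                f"Debye length {self.debye_length_A:.2f} A; the field "
                "solution may miss the 2% oracle tolerance", stacklevel=2)

    @property
    def debye_length_A(self) -> float:
        return debye_length(self.ionic_strength_M, self.temperature_K,
                            self.relative_permittivity)

    @property
    def grid_spacing_A(self) -> float:
        return self.box_edge_A / self.grid_points


@dataclass
class MembraneConfig:
    n_per_leaflet: int = 200
    composition_percent: dict = field(default_factory=lambda: {
        "POPC": 44.0, "POPE": 23.0, "CHOL": 23.0, "PIP2": 10.0})
    anionic_species: str = "PIP2"
    anionic_charge_e: float = -4.0
    area_per_lipid_A2: float = 65.0
    lattice_spacing_A: float | None = None   # default: sqrt(area_per_lipid)

    def validate(self) -> None:
        if self.n_per_leaflet < 1:
            raise ConfigError("n_per_leaflet must be >= 1")
        total = sum(self.composition_percent.values())
        if abs(total - 100.0) > 1e-9:
            raise ConfigError(
                f"composition percentages sum to {total}, expected 100")
        if self.anionic_species not in self.composition_percent:
            raise ConfigError(
                f"anionic species {self.anionic_species!r} absent from "
                "composition")
        if self.area_per_lipid_A2 <= 0:
            raise ConfigError("area_per_lipid_A2 must be > 0")
        if self.lattice_spacing_A is not None and self.lattice_spacing_A <= 0:
            raise ConfigError("lattice_spacing_A must be > 0")

    @property
    def effective_lattice_spacing_A(self) -> float:
        if self.lattice_spacing_A is not None:
            return self.lattice_spacing_A
        return math.sqrt(self.area_per_lipid_A2)


@dataclass
class SegmentsConfig:
    cterm_helix: list = field(default_factory=lambda: [[203, 224]])
    omega1_loop: list = field(default_factory=list)
    beta_sheet: list = field(default_factory=list)

    def validate(self) -> None:
        for name in ("cterm_helix", "omega1_loop", "beta_sheet"):
            for span in getattr(self, name):
                if len(span) != 2 or span[0] > span[1]:
                    raise ConfigError(
                        f"segment {name}: bad residue range {span}")

    def ranges(self) -> dict[str, list[tuple[int, int]]]:
        return {name: [tuple(s) for s in getattr(self, name)]
                for name in ("cterm_helix", "omega1_loop", "beta_sheet")}


@dataclass
class ContactsConfig:
    cutoff_A: float = 4.0
    lipid_oxygen_atoms: dict = field(default_factory=lambda: {
        "POPS": ["O13A", "O13B", "OP32", "OP33", "OP34"],
        "PIP2": ["OP32", "OP33", "OP34", "OP42", "OP43", "OP44",
                 "OP52", "OP53", "OP54", "O2", "O3", "O4", "O5", "O6"],
        "PIP": ["O1"],
    })
    residue_polar_atoms: dict = field(default_factory=lambda: {
        "ARG": ["NE", "NH1", "NH2"],
        "LYS": ["NZ"],
        "SER": ["OG"],
    })

    def validate(self) -> None:
        if self.cutoff_A <= 0:
            raise ConfigError("cutoff_A must be > 0")
        for d in (self.lipid_oxygen_atoms, self.residue_polar_atoms):
            for key, names in d.items():
                if not names:
                    raise ConfigError(f"empty atom-name list for {key!r}")


@dataclass
class EmbeddingConfig:
    area_omega1_min_A2: float = 200.0
    area_beta9_cterm_min_A2: float = 150.0
    probe_A: float = 1.4
    n_sphere_points: int = 960

    def validate(self) -> None:
        if self.area_omega1_min_A2 <= 0 or self.area_beta9_cterm_min_A2 <= 0:
            raise ConfigError("embedding area thresholds must be > 0")
        if self.probe_A < 0:
            raise ConfigError("probe_A must be >= 0")
        if self.n_sphere_points < 16:
            raise ConfigError("n_sphere_points must be >= 16")


@dataclass
class KineticsConfig:
    f_eq: float = 0.5
    time_in_seconds: bool = False

    def validate(self) -> None:
        if not (0.0 < self.f_eq <= 1.0):
            raise ConfigError("f_eq must lie in (0, 1]")


@dataclass
class RunConfig:
    solver: SolverConfig = field(default_factory=SolverConfig)
    membrane: MembraneConfig = field(default_factory=MembraneConfig)
    segments: SegmentsConfig = field(default_factory=SegmentsConfig)
    contacts: ContactsConfig = field(default_factory=ContactsConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    analysis_window_last_ns: float = 720.0
    seed: int = 0

    def validate(self) -> None:
        for section in ("solver", "membrane", "segments", "contacts",
                        "embedding", "kinetics"):
            getattr(self, section).validate()
        if self.analysis_window_last_ns <= 0:
            raise ConfigError("analysis_window_last_ns must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: Mapping[str, Any], path: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s) at {path or 'top level'}: "
            + ", ".join(sorted(str(u) for u in unknown)))
    kwargs = {}
    for name, value in data.items():
        fobj = known[name]
        if dataclasses.is_dataclass(fobj.type) or name in (
                "solver", "membrane", "segments", "contacts", "embedding",
                "kinetics"):
            if not isinstance(value, Mapping):
                raise ConfigError(f"section {path + name!r} must be a mapping")
            sub_cls = RunConfig.__dataclass_fields__[name].default_factory  # type: ignore[union-attr]
            kwargs[name] = _build(sub_cls, value, f"{path}{name}.")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                data: Mapping[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML configuration.

    An empty (or absent) file yields the full default configuration.  Unknown
    keys and out-of-range values raise :class:`ConfigError`.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            raw = Path(path).read_text()
            data = yaml.safe_load(raw) or {}
    if not isinstance(data, Mapping):
        raise ConfigError("configuration root must be a mapping")
    cfg = _build(RunConfig, data, "")
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialize a configuration to canonical YAML (sorted keys)."""
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
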