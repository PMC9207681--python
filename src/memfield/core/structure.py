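"""Charged atomic structures with segment labels.

A :class:`ChargedStructure` is a flat table of atoms (coordinates in angstrom,
partial charges in elementary charges) plus a per-atom segment label used by
the orientation and embedding analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from ..errors import ConfigError, SelectionError


class Segment(str, Enum):
    CTERM_HELIX = "cterm_helix"
    OMEGA1_LOOP = "omega1_loop"
    BETA_SHEET = "beta_sheet"
    OTHER = "other"


#: Default residue-range segment assignment.  The C-terminal helix range is
#: the only one with a documented default; loop and sheet ranges are empty
#: until provided by configuration.
DEFAULT_SEGMENT_RANGES: dict[str, list[tuple[int, int]]] = {
    Segment.CTERM_HELIX.value: [(203, 224)],
    Segment.OMEGA1_LOOP.value: [],
    Segment.BETA_SHEET.value: [],
}

# Coarse default charge rule: +/-1 placed on the center of the terminal
# sidechain group.  Everything else is neutral.
DEFAULT_CHARGE_RULE: dict[str, tuple[str, float]] = {
    "ARG": ("CZ", +1.0),
    "LYS": ("NZ", +1.0),
    "ASP": ("CG", -1.0),
    "GLU": ("CD", -1.0),
}


@dataclass
class ChargedStructure:
    """Atoms with coordinates, partial charges and segment labels.

    All arrays share the first dimension (number of atoms).
    """

    atom_id: np.ndarray          # (n,) int
    name: np.ndarray             # (n,) str
    residue_name: np.ndarray     # (n,) str
    residue_id: np.ndarray       # (n,) int
    positions: np.ndarray        # (n, 3) float, angstrom
    charges: np.ndarray          # (n,) float, elementary charges
    elements: np.ndarray         # (n,) str
    segments: np.ndarray         # (n,) str, one of Segment values

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.positions)
        for attr in ("atom_id", "name", "residue_name", "residue_id",
                     "charges", "elements", "segments"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"field {attr!r} length mismatch")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        valid = {s.value for s in Segment}
        bad = set(np.unique(self.segments)) - valid
        if bad:
            raise ValueError(f"unknown segment labels: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def copy(self) -> "ChargedStructure":
        return ChargedStructure(
            atom_id=self.atom_id.copy(), name=self.name.copy(),
            residue_name=self.residue_name.copy(),
            residue_id=self.residue_id.copy(),
            positions=self.positions.copy(), charges=self.charges.copy(),
            elements=self.elements.copy(), segments=self.segments.copy())

    def with_positions(self, positions: np.ndarray) -> "ChargedStructure":
        out = self.copy()
        out.positions = np.asarray(positions, dtype=float)
        if out.positions.shape != (self.n_atoms, 3):
            raise ValueError("replacement positions have wrong shape")
        return out

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] | None = None
                    ) -> "ChargedStructure":
        """Return a copy with ``R x + t`` applied to every atom."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        return self.with_positions(pos)

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    # -- selections ------------------------------------------------------

    def mask_segment(self, segment: Segment | str) -> np.ndarray:
        label = segment.value if isinstance(segment, Segment) else segment
        return self.segments == label

    def mask_residue(self, residue_id: int) -> np.ndarray:
        return self.residue_id == residue_id

    def mask_atom_names(self, names: Iterable[str]) -> np.ndarray:
        return np.isin(self.name, list(names))

    def select(self, mask: np.ndarray) -> "ChargedStructure":
        mask = np.asarray(mask, dtype=bool)
        return ChargedStructure(
            atom_id=self.atom_id[mask], name=self.name[mask],
            residue_name=self.residue_name[mask],
            residue_id=self.residue_id[mask],
            positions=self.positions[mask], charges=self.charges[mask],
            elements=self.elements[mask], segments=self.segments[mask])


def assign_segments(residue_ids: np.ndarray,
                    segment_ranges: Mapping[str, Sequence[tuple[int, int]]]
                    | None = None) -> np.ndarray:
    """Map residue ids to segment labels via inclusive residue-id ranges.

    Residues falling in no range are labeled ``other``.  Overlapping ranges
    are a configuration error.
    """
    ranges = dict(DEFAULT_SEGMENT_RANGES)
    if segment_ranges is not None:
        for key, val in segment_ranges.items():
            if key not in ranges:
                raise ConfigError(f"unknown segment name {key!r}")
            ranges[key] = [(int(a), int(b)) for a, b in val]
    out = np.full(len(residue_ids), Segment.OTHER.value, dtype=object)
    claimed: dict[int, str] = {}
    for label, spans in ranges.items():
        for lo, hi in spans:
            if lo > hi:
                raise ConfigError(f"segment range ({lo}, {hi}) is inverted")
            for rid in range(lo, hi + 1):
                if rid in claimed and claimed[rid] != label:
                    raise ConfigError(
                        f"residue {rid} claimed by both {claimed[rid]!r} "
                        f"and {label!r}")
                claimed[rid] = label
            mask = (residue_ids >= lo) & (residue_ids <= hi)
            out[mask] = label
    return out.astype(str)


def apply_charge_table(structure: ChargedStructure,
                       table: Mapping[tuple[str, str], float],
                       strict: bool = False) -> ChargedStructure:
    """Attach charges from a ``(residue_name, atom_name) -> charge`` table.

    Atoms absent from the table default to zero charge; under ``strict`` any
    table entry that matches no atom raises :class:`SelectionError`.
    """
    out = structure.copy()
    charges = np.zeros(out.n_atoms)
    used = set()
    for i in range(out.n_atoms):
        key = (str(out.residue_name[i]), str(out.name[i]))
        if key in table:
            charges[i] = table[key]
            used.add(key)
    if strict:
        missing = set(table) - used
        if missing:
            raise SelectionError(
                "charge-table entries matched no atom: "
                + ", ".join(f"{r}/{a}" for r, a in sorted(missing)))
    out.charges = charges
    return out


def apply_default_charge_rule(structure: ChargedStructure) -> ChargedStructure:
    """Coarse +/-1 sidechain charge rule (Arg/Lys +1, Asp/Glu -1, rest 0)."""
    out = structure.copy()
    charges = np.zeros(out.n_atoms)
    for i in range(out.n_atoms):
        rule = DEFAULT_CHARGE_RULE.get(str(out.residue_name[i]))
        if rule is not None and str(out.name[i]) == rule[0]:
            charges[i] = rule[1]
    out.charges = charges
    return out
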