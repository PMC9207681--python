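"""Residue-lipid contact detection and binding-probability statistics.

A lipid is bound to a residue if any of its headgroup oxygen atoms lies
within the cutoff (inclusive, default 4.0 A) of any sidechain
nitrogen/oxygen atom of that residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ..core.structure import ChargedStructure
from ..core.tables import TableArtifact
from ..core.trajectory import Trajectory
from ..errors import SelectionError

__all__ = ["ContactCriterion", "ContactTable", "residue_lipid_contacts",
           "binding_probability_table", "parse_residue_label"]

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)$")

_ONE_TO_THREE = {"R": "ARG", "K": "LYS", "S": "SER", "H": "HIS",
                 "D": "ASP", "E": "GLU", "N": "ASN", "Q": "GLN",
                 "T": "THR", "Y": "TYR"}


def parse_residue_label(label: str) -> tuple[str, int]:
    """'R46' -> ('ARG', 46).  Used for paper-style residue names."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse residue label {label!r}")
    letter, rid = m.group(1).upper(), int(m.group(2))
    if letter not in _ONE_TO_THREE:
        raise ValueError(f"unknown residue letter in label {label!r}")
    return _ONE_TO_THREE[letter], rid


@dataclass
class ContactCriterion:
    cutoff_A: float = 4.0     # inclusive
    lipid_oxygen_atoms: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"PIP": ["O1"]})
    residue_polar_atoms: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"ARG": ["NE", "NH1", "NH2"],
                                 "LYS": ["NZ"], "SER": ["OG"]})

    def __post_init__(self) -> None:
        if self.cutoff_A <= 0:
            raise ValueError("cutoff must be > 0")
        for d in (self.lipid_oxygen_atoms, self.residue_polar_atoms):
            for key, names in d.items():
                if not list(names):
                    raise ValueError(f"empty atom-name list for {key!r}")


def _lipid_oxygen_selection(frame: ChargedStructure,
                            criterion: ContactCriterion,
                            lipid_species: Iterable[str]):
    """(positions, lipid molecule ids) of all headgroup oxygens."""
    species = list(lipid_species)
    missing = [s for s in species if s not in criterion.lipid_oxygen_atoms]
    if missing:
        raise SelectionError(
            f"no headgroup oxygen list for species: {missing}")
    mask = np.zeros(frame.n_atoms, dtype=bool)
    for s in species:
        names = criterion.lipid_oxygen_atoms[s]
        mask |= (frame.residue_name == s) & np.isin(frame.name, list(names))
    return frame.positions[mask], frame.residue_id[mask]


def residue_lipid_contacts(frame: ChargedStructure,
                           criterion: ContactCriterion,
                           residues: Sequence[int],
                           lipid_species: Iterable[str]
                           ) -> dict[int, set[int]]:
    """Per-residue set of bound lipid molecule ids for one frame.

    Residues are residue ids in the frame topology; lipid molecules are
    identified by their residue id.
    """
    lipid_pos, lipid_ids = _lipid_oxygen_selection(frame, criterion,
                                                   lipid_species)
    out: dict[int, set[int]] = {}
    for rid in residues:
        res_mask = frame.residue_id == rid
        if not np.any(res_mask):
            raise SelectionError(f"residue id {rid} not found in topology")
        res_name = str(frame.residue_name[res_mask][0])
        names = criterion.residue_polar_atoms.get(res_name)
        if names is None:
            raise SelectionError(
                f"no sidechain polar-atom list for residue type {res_name!r}")
        atom_mask = res_mask & np.isin(frame.name, list(names))
        if not np.any(atom_mask):
            raise SelectionError(
                f"residue {res_name}{rid}: none of {list(names)} present")
        bound: set[int] = set()
        if len(lipid_pos):
            d = cdist(frame.positions[atom_mask], lipid_pos)
            hit = np.any(d <= criterion.cutoff_A, axis=0)
            bound = set(int(i) for i in np.unique(lipid_ids[hit]))
        out[rid] = bound
    return out


@dataclass
class ContactTable:
    per_residue: pd.DataFrame    # residue_id, p_bound, p_two_or_more, ...
    per_pair: pd.DataFrame       # residue_a, residue_b, p_shared
    n_frames: int

    def __post_init__(self) -> None:
        pr = self.per_residue.set_index("residue_id")
        for _, row in pr.iterrows():
            if not (0.0 <= row["p_bound"] <= 1.0):
                raise ValueError("p_bound outside [0, 1]")
            if row["p_two_or_more"] > row["p_bound"] + 1e-12:
                raise ValueError("p_two_or_more exceeds p_bound")
        for _, row in self.per_pair.iterrows():
            cap = min(pr.loc[row["residue_a"], "p_bound"],
                      pr.loc[row["residue_b"], "p_bound"])
            if row["p_shared"] > cap + 1e-12:
                raise ValueError("p_shared exceeds member probability")

    def to_table(self, **provenance) -> TableArtifact:
        df = self.per_residue.copy()
        df["percent_occurrence"] = 100.0 * df["p_bound"]
        return TableArtifact.create(df, **provenance)


def binding_probability_table(trajectory: Trajectory,
                              criterion: ContactCriterion,
                              residues: Sequence[int],
                              lipid_species: Iterable[str],
                              shared_pairs: Sequence[tuple[int, int]] = ()
                              ) -> ContactTable:
    """Binding probabilities over all frames (equal frame weights).

    * ``p_bound``: fraction of frames with >= 1 bound lipid
    * ``p_two_or_more``: fraction with >= 2 distinct bound lipid molecules
    * ``mean_multiplicity``: average number of distinct bound lipids
    * ``p_shared``: fraction of frames where one lipid bridges both
      residues of a pair simultaneously
    """
    if trajectory.n_frames == 0:
        raise ValueError("trajectory has no frames")
    residues = list(residues)
    counts = {rid: {"bound": 0, "two": 0, "mult": 0} for rid in residues}
    pair_counts = {tuple(p): 0 for p in shared_pairs}
    for i in range(trajectory.n_frames):
        frame = trajectory.frame(i)
        bound = residue_lipid_contacts(frame, criterion, residues,
                                       lipid_species)
        for rid in residues:
            k = len(bound[rid])
            counts[rid]["mult"] += k
            if k >= 1:
                counts[rid]["bound"] += 1
            if k >= 2:
                counts[rid]["two"] += 1
        for (a, b) in pair_counts:
            if bound.get(a, set()) & bound.get(b, set()):
                pair_counts[(a, b)] += 1
    n = trajectory.n_frames
    per_residue = pd.DataFrame([
        {"residue_id": rid,
         "p_bound": counts[rid]["bound"] / n,
         "p_two_or_more": counts[rid]["two"] / n,
         "mean_multiplicity": counts[rid]["mult"] / n}
        for rid in residues])
    per_pair = pd.DataFrame(
        [{"residue_a": a, "residue_b": b, "p_shared": c / n}
         for (a, b), c in pair_counts.items()],
        columns=["residue_a", "residue_b", "p_shared"])
    return ContactTable(per_residue=per_residue, per_pair=per_pair,
                        n_frames=n)
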