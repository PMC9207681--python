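"""PDB readers/writers for structures and multi-model trajectories.

PDB parsing and serialization are delegated to :mod:`biotite`; this module
adds charge attachment, segment labeling, and trajectory time assignment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from ..errors import ParseError
from .structure import (ChargedStructure, apply_charge_table,
                        apply_default_charge_rule, assign_segments)
from .trajectory import Trajectory


def _validate_pdb_lines(path: str | Path) -> None:
    """Cheap pre-scan so malformed coordinate records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(
                        f"{path}:{lineno}: truncated coordinate record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: malformed coordinate record "
                        f"({exc})") from exc


def read_charge_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a charge table CSV with columns residue_name, atom_name, charge."""
    df = pd.read_csv(path, comment="#")
    required = {"residue_name", "atom_name", "charge"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: charge table needs columns {sorted(required)}, "
            f"found {list(df.columns)}")
    return {(str(r), str(a)): float(c)
            for r, a, c in zip(df["residue_name"], df["atom_name"],
                               df["charge"])}


def _from_atom_array(arr: bst.AtomArray,
                     segment_ranges=None) -> ChargedStructure:
    n = arr.array_length()
    segs = assign_segments(arr.res_id, segment_ranges)
    elements = np.array([e if e else "C" for e in arr.element], dtype=object)
    return ChargedStructure(
        atom_id=np.arange(1, n + 1),
        name=np.array(arr.atom_name, dtype=object),
        residue_name=np.array(arr.res_name, dtype=object),
        residue_id=np.array(arr.res_id, dtype=int),
        positions=np.array(arr.coord, dtype=float),
        charges=np.zeros(n),
        elements=elements,
        segments=segs)


def read_structure(path: str | Path,
                   charges: str | Path | Mapping[tuple[str, str], float]
                   | None = None,
                   segment_ranges: Mapping[str, Sequence[tuple[int, int]]]
                   | None = None,
                   use_default_charge_rule: bool = True,
                   strict: bool = False) -> ChargedStructure:
    """Read a single-model PDB file into a :class:`ChargedStructure`.

    Charges come from an explicit table (CSV path or mapping) when given,
    otherwise from the coarse default sidechain rule (Arg/Lys +1, Asp/Glu -1)
    unless ``use_default_charge_rule`` is disabled.
    """
    _validate_pdb_lines(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises several exception types
        raise ParseError(f"{path}: {exc}") from exc
    structure = _from_atom_array(arr, segment_ranges)
    if charges is not None:
        table = (read_charge_table(charges)
                 if isinstance(charges, (str, Path)) else dict(charges))
        structure = apply_charge_table(structure, table, strict=strict)
    elif use_default_charge_rule:
        structure = apply_default_charge_rule(structure)
    return structure


def _to_atom_array(structure: ChargedStructure) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(structure.positions, dtype=np.float32)
    arr.atom_name = np.array(structure.name, dtype="U6")
    arr.res_name = np.array(structure.residue_name, dtype="U5")
    arr.res_id = np.asarray(structure.residue_id, dtype=int)
    arr.chain_id = np.full(n, "A", dtype="U4")
    arr.element = np.array(structure.elements, dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_structure(structure: ChargedStructure, path: str | Path,
                    charges_path: str | Path | None = None) -> None:
    """Write a PDB file (and optionally the charge table CSV alongside)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    pdb.write(str(path))
    if charges_path is not None:
        df = pd.DataFrame({
            "residue_name": structure.residue_name,
            "atom_name": structure.name,
            "charge": structure.charges,
        })
        df = df[df["charge"] != 0.0].drop_duplicates()
        df.to_csv(charges_path, index=False)


def read_trajectory(topology_path: str | Path, traj_path: str | Path,
                    stride_ns: float = 1.0,
                    segment_ranges=None,
                    charges=None) -> Trajectory:
    """Read a multi-model PDB trajectory.

    Frame times are ``i * stride_ns`` (PDB carries no time metadata).  The
    topology file provides labels/charges; the trajectory file provides one
    model per frame and must match the topology atom count.
    """
    topology = read_structure(topology_path, charges=charges,
                              segment_ranges=segment_ranges)
    _validate_pdb_lines(traj_path)
    try:
        pdb = PDBFile.read(str(traj_path))
        stack = pdb.get_structure()
    except Exception as exc:
        raise ParseError(f"{traj_path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[0] == 0:
        raise ParseError(f"{traj_path}: trajectory contains zero frames")
    for i in range(coords.shape[0]):
        if coords.shape[1] != topology.n_atoms:
            raise ParseError(
                f"{traj_path}: frame {i} has {coords.shape[1]} atoms, "
                f"topology has {topology.n_atoms}")
    times = np.arange(coords.shape[0], dtype=float) * float(stride_ns)
    return Trajectory(topology=topology, times_ns=times, positions=coords)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB."""
    n_frames = trajectory.n_frames
    template = _to_atom_array(trajectory.topology)
    stack = bst.AtomArrayStack(n_frames, trajectory.topology.n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = np.asarray(trajectory.positions, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
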