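"""Numeric solvent-accessible surface areas and buried contact area.

Shrake-Rupley sampling on a deterministic golden-spiral sphere; the buried
contact area between two selections is half the SASA lost on forming the
complex: (A_P + A_M - A_PM) / 2.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from ..core.structure import ChargedStructure
from ..errors import GeometryError

__all__ = ["ELEMENT_RADII_A", "radii_for", "sasa", "buried_contact_area",
           "buried_area_between"]

# Bondi van der Waals radii (A); beads default to carbon
ELEMENT_RADII_A: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "K": 2.75, "NA": 2.27,
}


def radii_for(structure: ChargedStructure,
              table: dict[str, float] | None = None) -> np.ndarray:
    tab = dict(ELEMENT_RADII_A)
    if table:
        tab.update({k.upper(): v for k, v in table.items()})
    radii = np.empty(structure.n_atoms)
    for i, el in enumerate(structure.elements):
        radii[i] = tab.get(str(el).upper(), tab["C"])
    return radii


def _sphere_points(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([np.cos(phi) * r, np.sin(phi) * r, z])


def sasa(positions: np.ndarray, radii: np.ndarray, probe_A: float = 1.4,
         n_sphere_points: int = 960) -> float:
    """Total solvent-accessible surface area (A^2) of an atom set."""
    pos = np.asarray(positions, dtype=float)
    rad = np.asarray(radii, dtype=float)
    if len(pos) == 0:
        return 0.0
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise GeometryError("positions must have shape (n, 3)")
    if len(rad) != len(pos):
        raise GeometryError("radii/positions length mismatch")
    if np.any(rad <= 0.0):
        raise GeometryError("zero or negative atomic radius")
    sphere = _sphere_points(n_sphere_points)
    ext = rad + probe_A
    tree = cKDTree(pos)
    total = 0.0
    for i in range(len(pos)):
        nbrs = [j for j in tree.query_ball_point(pos[i], ext[i] + ext.max())
                if j != i
                and np.linalg.norm(pos[j] - pos[i]) < ext[i] + ext[j]]
        pts = pos[i] + ext[i] * sphere
        if nbrs:
            nb_pos = pos[nbrs]
            nb_ext = ext[nbrs]
            d2 = ((pts[:, None, :] - nb_pos[None, :, :]) ** 2).sum(axis=2)
            buried = np.any(d2 < nb_ext[None, :] ** 2, axis=1)
            acc = int(np.count_nonzero(~buried))
        else:
            acc = n_sphere_points
        total += 4.0 * math.pi * ext[i] ** 2 * acc / n_sphere_points
    return total


def buried_contact_area(positions_a: np.ndarray, radii_a: np.ndarray,
                        positions_b: np.ndarray, radii_b: np.ndarray,
                        probe_A: float = 1.4,
                        n_sphere_points: int = 960) -> float:
    """Buried contact area (A^2) between two atom sets.

    Symmetric in its selections; zero (to sampling noise) when the sets are
    separated by more than two probe diameters.
    """
    pos_a = np.asarray(positions_a, dtype=float)
    pos_b = np.asarray(positions_b, dtype=float)
    if len(pos_a) == 0 or len(pos_b) == 0:
        raise GeometryError("both selections must be non-empty")
    a_alone = sasa(pos_a, radii_a, probe_A, n_sphere_points)
    b_alone = sasa(pos_b, radii_b, probe_A, n_sphere_points)
    combined = sasa(np.vstack([pos_a, pos_b]),
                    np.concatenate([radii_a, radii_b]),
                    probe_A, n_sphere_points)
    return 0.5 * (a_alone + b_alone - combined)


def buried_area_between(frame: ChargedStructure, mask_a: np.ndarray,
                        mask_b: np.ndarray, probe_A: float = 1.4,
                        n_sphere_points: int = 960,
                        radii_table: dict[str, float] | None = None) -> float:
    """Buried contact area between two atom masks of one structure."""
    radii = radii_for(frame, radii_table)
    return buried_contact_area(frame.positions[mask_a], radii[mask_a],
                               frame.positions[mask_b], radii[mask_b],
                               probe_A=probe_A,
                               n_sphere_points=n_sphere_points)
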