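"""Orientation scan: probe protein poses over the membrane and rank them by
self-consistent adsorption free energy."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

from ..core.config import SolverConfig
from ..core.membrane import LatticeMembrane
from ..core.structure import ChargedStructure
from ..errors import ConvergenceError
from .energy import FreeEnergyBreakdown, PoseEnergyModel
from .solver import GridSolver

logger = logging.getLogger(__name__)

__all__ = ["OrientationPose", "ScanResult", "fibonacci_directions",
           "pose_protein", "evaluate_pose", "scan_orientations"]


@dataclass
class OrientationPose:
    direction: np.ndarray           # unit approach direction (protein frame)
    direction_index: int
    azimuth_deg: float
    azimuth_index: int
    translation: np.ndarray         # applied to the centered protein
    rotation: np.ndarray            # 3x3 matrix applied before translation
    adsorption_energy_kT: float
    breakdown: Optional[FreeEnergyBreakdown] = None
    phi: Optional[np.ndarray] = None
    converged: bool = True
    iterations: int = 0

    def sort_key(self):
        return (self.adsorption_energy_kT, self.direction_index,
                self.azimuth_index)


@dataclass
class ScanResult:
    ranked: list                    # converged poses, best (lowest F) first
    failed: list = dc_field(default_factory=list)

    @property
    def best(self) -> OrientationPose:
        if not self.ranked:
            raise ConvergenceError("no pose converged")
        return self.ranked[0]


def fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (golden-spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + 0.5
    phi_angle = math.pi * (3.0 - math.sqrt(5.0)) * i
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta ** 2, 0.0, 1.0))
    return np.column_stack([np.cos(phi_angle) * sin_theta,
                            np.sin(phi_angle) * sin_theta,
                            cos_theta])


def _rotation_to_minus_z(u: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``u`` onto (0, 0, -1)."""
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    target = np.array([0.0, 0.0, -1.0])
    c = float(u @ target)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])   # flip about x axis
    axis = np.cross(u, target)
    axis /= np.linalg.norm(axis)
    angle = math.acos(max(-1.0, min(1.0, c)))
    K = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    return np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * K @ K


def _rot_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def pose_protein(protein: ChargedStructure, direction: np.ndarray,
                 azimuth_deg: float, clearance_A: float
                 ) -> tuple[ChargedStructure, np.ndarray, np.ndarray]:
    """Rotate the centered protein so ``direction`` faces the membrane and
    translate it to the minimum clearance above the plane z = 0.

    Returns (posed structure, rotation matrix, translation vector).
    """
    centered = protein.transformed(translation=-protein.centroid())
    R = _rot_z(azimuth_deg) @ _rotation_to_minus_z(direction)
    rotated = centered.transformed(rotation=R)
    min_z = float(np.min(rotated.positions[:, 2]))
    t = np.array([0.0, 0.0, clearance_A - min_z])
    return rotated.transformed(translation=t), R, t


def evaluate_pose(protein: ChargedStructure, membrane: LatticeMembrane,
                  cfg: SolverConfig, direction: np.ndarray,
                  azimuth_deg: float, clearance_A: float = 2.0,
                  solver: Optional[GridSolver] = None,
                  direction_index: int = 0, azimuth_index: int = 0
                  ) -> OrientationPose:
    """Self-consistent adsorption free energy of a single pose."""
    posed, R, t = pose_protein(protein, direction, azimuth_deg, clearance_A)
    model = PoseEnergyModel(posed, membrane, cfg, solver=solver)
    phi, fe, info = model.relax()
    return OrientationPose(
        direction=np.asarray(direction, dtype=float),
        direction_index=direction_index, azimuth_deg=float(azimuth_deg),
        azimuth_index=azimuth_index, translation=t, rotation=R,
        adsorption_energy_kT=fe.F_total, breakdown=fe, phi=phi,
        converged=info["converged"], iterations=info["iterations"])


def scan_orientations(protein: ChargedStructure, membrane: LatticeMembrane,
                      cfg: SolverConfig, n_directions: int = 72,
                      n_azimuths: int = 12, clearance_A: float | None = None,
                      directions: Optional[Sequence[np.ndarray]] = None,
                      solver: Optional[GridSolver] = None) -> ScanResult:
    """Probe direction x azimuth poses; rank by adsorption free energy.

    The ranking is ascending in energy (strongest adsorption first); exact
    ties resolve by (direction index, azimuth index) so runs are
    deterministic.  Poses whose relaxation fails are excluded from the
    ranking and reported in ``failed``.
    """
    if clearance_A is None:
        clearance_A = cfg.clearance_A
    dirs = (np.asarray(directions, dtype=float) if directions is not None
            else fibonacci_directions(n_directions))
    if len(dirs) == 0:
        raise ValueError("orientation set must be non-empty")
    azimuths = np.arange(n_azimuths) * (360.0 / max(n_azimuths, 1))
    grid = solver if solver is not None else GridSolver(cfg)
    ranked: list[OrientationPose] = []
    failed: list[OrientationPose] = []
    for di, u in enumerate(dirs):
        for ai, az in enumerate(azimuths):
            try:
                pose = evaluate_pose(protein, membrane, cfg, u, az,
                                     clearance_A, solver=grid,
                                     direction_index=di, azimuth_index=ai)
                ranked.append(pose)
            except ConvergenceError as exc:
                logger.warning("pose (dir %d, az %.1f) failed: %s",
                               di, az, exc)
                posed, R, t = pose_protein(protein, u, az, clearance_A)
                failed.append(OrientationPose(
                    direction=np.asarray(u, dtype=float), direction_index=di,
                    azimuth_deg=float(az), azimuth_index=ai, translation=t,
                    rotation=R, adsorption_energy_kT=math.nan,
                    converged=False))
    ranked.sort(key=OrientationPose.sort_key)
    return ScanResult(ranked=ranked, failed=failed)
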