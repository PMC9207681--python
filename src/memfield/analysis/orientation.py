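"""Helix-referenced orientation angles and their 2D probability maps.

Conventions (documented, configuration-exposed upstream):

* tilt is the angle between the helix axis (N-to-C) and the outward
  membrane normal, in [0, 180] degrees; 0 means the helix points straight
  away from the membrane, larger tilt means it leans toward the plane.
* rotation is the signed angle about the helix axis from the projection of
  the outward normal to the projection of the vector from the helix center
  to a reference centroid (default: the omega1 loop), in [-180, 180).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core.structure import ChargedStructure, Segment
from ..core.tables import TableArtifact
from ..errors import GeometryError

__all__ = ["OrientationSample", "OrientationMap", "helix_axis",
           "orientation_angles", "orientation_map", "frame_orientation"]


@dataclass(frozen=True)
class OrientationSample:
    tilt_deg: float
    rotation_deg: float
    frame_time_ns: float = 0.0
    degenerate: bool = False      # rotation undefined (axis along normal)


@dataclass
class OrientationMap:
    probabilities: np.ndarray     # (n_tilt_bins, n_rotation_bins), sums to 1
    tilt_edges: np.ndarray
    rotation_edges: np.ndarray

    def to_table(self, **provenance) -> TableArtifact:
        """Long-format CSV: tilt_lo, tilt_hi, rot_lo, rot_hi, probability."""
        rows = []
        for i in range(self.probabilities.shape[0]):
            for j in range(self.probabilities.shape[1]):
                rows.append({
                    "tilt_lo_deg": self.tilt_edges[i],
                    "tilt_hi_deg": self.tilt_edges[i + 1],
                    "rotation_lo_deg": self.rotation_edges[j],
                    "rotation_hi_deg": self.rotation_edges[j + 1],
                    "probability": self.probabilities[i, j],
                })
        return TableArtifact.create(pd.DataFrame(rows), **provenance)


def helix_axis(ca_positions: np.ndarray) -> np.ndarray:
    """Helix axis of an ordered CA point set, oriented N -> C.

    The second differences of consecutive CA positions of an ideal helix
    point exactly radially (perpendicular to the axis), so the axis is
    recovered as the null direction of their second-moment matrix -- exact
    for ideal geometry, where the raw principal axis of the points carries
    an O(0.1 deg) finite-length bias.  Degenerate point sets fall back to
    the largest-variance direction.  Requires at least 4 CA atoms; always
    returns a unit vector.
    """
    pts = np.asarray(ca_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError("CA positions must have shape (n, 3)")
    if len(pts) < 4:
        raise GeometryError("helix axis needs at least 4 CA atoms")
    second = pts[2:] - 2.0 * pts[1:-1] + pts[:-2]
    moment = second.T @ second
    eigval, eigvec = np.linalg.eigh(moment)
    axis = eigvec[:, 0]
    scale = float(np.sum(second ** 2))
    if scale < 1e-20 or eigval[1] < 1e-10 * max(scale, 1.0):
        # near-collinear chain: second differences carry no plane; use the
        # principal axis of the points themselves
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    if float(axis @ (pts[-1] - pts[0])) < 0.0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _signed_angle_about(axis: np.ndarray, v_from: np.ndarray,
                        v_to: np.ndarray) -> float:
    """Signed angle (degrees) from v_from to v_to about ``axis``."""
    a = v_from - (v_from @ axis) * axis
    b = v_to - (v_to @ axis) * axis
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise GeometryError("projection degenerate")
    a, b = a / na, b / nb
    ang = math.degrees(math.atan2(float(np.cross(a, b) @ axis),
                                  float(a @ b)))
    if ang >= 180.0:
        ang -= 360.0
    if ang < -180.0:
        ang += 360.0
    return ang


def orientation_angles(helix_ca: np.ndarray, reference_centroid: np.ndarray,
                       plane_origin: np.ndarray, outward_normal: np.ndarray,
                       frame_time_ns: float = 0.0) -> OrientationSample:
    """Tilt/rotation of a helix relative to the membrane frame."""
    axis = helix_axis(helix_ca)
    n = np.asarray(outward_normal, dtype=float)
    n = n / np.linalg.norm(n)
    cos_tilt = float(np.clip(axis @ n, -1.0, 1.0))
    tilt = math.degrees(math.acos(cos_tilt))
    helix_center = np.asarray(helix_ca, dtype=float).mean(axis=0)
    ref_vec = np.asarray(reference_centroid, dtype=float) - helix_center
    if abs(cos_tilt) > 1.0 - 1e-12:
        # helix axis parallel to the normal: rotation undefined by convention
        return OrientationSample(tilt_deg=tilt, rotation_deg=0.0,
                                 frame_time_ns=frame_time_ns,
                                 degenerate=True)
    try:
        rot = _signed_angle_about(axis, n, ref_vec)
    except GeometryError:
        return OrientationSample(tilt_deg=tilt, rotation_deg=0.0,
                                 frame_time_ns=frame_time_ns,
                                 degenerate=True)
    return OrientationSample(tilt_deg=tilt, rotation_deg=rot,
                             frame_time_ns=frame_time_ns)


def frame_orientation(frame: ChargedStructure, plane_origin: np.ndarray,
                      outward_normal: np.ndarray,
                      helix_segment: str = Segment.CTERM_HELIX.value,
                      reference_segment: str = Segment.OMEGA1_LOOP.value,
                      frame_time_ns: float = 0.0) -> OrientationSample:
    """Orientation sample of one posed structure using segment selections."""
    helix_mask = frame.mask_segment(helix_segment) & (frame.name == "CA")
    if not np.any(helix_mask):
        helix_mask = frame.mask_segment(helix_segment)
    ref_mask = frame.mask_segment(reference_segment)
    if not np.any(ref_mask):
        raise GeometryError(
            f"reference segment {reference_segment!r} selects no atoms")
    return orientation_angles(frame.positions[helix_mask],
                              frame.positions[ref_mask].mean(axis=0),
                              plane_origin, outward_normal,
                              frame_time_ns=frame_time_ns)


def orientation_map(samples: list[OrientationSample], tilt_bins: int = 36,
                    rotation_bins: int = 36,
                    include_degenerate: bool = False) -> OrientationMap:
    """Normalized 2D histogram of (tilt, rotation) samples."""
    use = [s for s in samples if include_degenerate or not s.degenerate]
    if not use:
        raise ValueError("no valid orientation samples")
    tilts = np.array([s.tilt_deg for s in use])
    rots = np.array([s.rotation_deg for s in use])
    hist, t_edges, r_edges = np.histogram2d(
        tilts, rots, bins=[tilt_bins, rotation_bins],
        range=[[0.0, 180.0], [-180.0, 180.0]])
    total = hist.sum()
    if total == 0:
        raise ValueError("all samples fell outside the histogram range")
    return OrientationMap(probabilities=hist / total, tilt_edges=t_edges,
                          rotation_edges=r_edges)
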