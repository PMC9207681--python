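"""Membrane reference frame from headgroup positions."""

from __future__ import annotations

import numpy as np

from ..errors import GeometryError

__all__ = ["fit_membrane_plane"]


def fit_membrane_plane(headgroup_positions: np.ndarray,
                       protein_centroid: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through upper-leaflet headgroup atoms.

    Returns ``(origin, outward_normal)`` where the origin is the point
    centroid and the unit normal is oriented toward the protein centroid.

    Raises :class:`GeometryError` for fewer than three points or a
    degenerate (collinear) point set.
    """
    pts = np.asarray(headgroup_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError("headgroup positions must have shape (n, 3)")
    if len(pts) < 3:
        raise GeometryError("plane fit needs at least 3 points")
    origin = pts.mean(axis=0)
    centered = pts - origin
    # smallest principal direction of the covariance = plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise GeometryError("headgroup points are collinear; plane undefined")
    normal = vt[2]
    toward = np.asarray(protein_centroid, dtype=float) - origin
    if float(normal @ toward) < 0.0:
        normal = -normal
    return origin, normal / np.linalg.norm(normal)
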