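"""Membrane-embedding detection from buried contact areas.

A frame is membrane-embedded when the omega1-loop/membrane contact area is
strictly greater than 200 A^2 AND the (beta-sheet & C-terminal-helix)/
membrane contact area is strictly greater than 150 A^2 (both thresholds
configurable).  No persistence/hysteresis is applied: the criterion is
evaluated frame by frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ..core.structure import Segment
from ..core.tables import TableArtifact
from ..core.trajectory import Trajectory
from ..errors import SelectionError
from .surface import buried_area_between

__all__ = ["EmbeddingCriterion", "EmbeddingTimeline", "detect_embedding"]


@dataclass
class EmbeddingCriterion:
    area_omega1_min_A2: float = 200.0      # strict >
    area_beta9_cterm_min_A2: float = 150.0  # strict >
    omega1_segments: Sequence[str] = (Segment.OMEGA1_LOOP.value,)
    pair_segments: Sequence[str] = (Segment.BETA_SHEET.value,
                                    Segment.CTERM_HELIX.value)
    probe_A: float = 1.4
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.area_omega1_min_A2 <= 0 or self.area_beta9_cterm_min_A2 <= 0:
            raise ValueError("area thresholds must be > 0")


@dataclass
class EmbeddingTimeline:
    table: pd.DataFrame              # time_ns, area_omega1, area_pair, embedded
    first_embedding_time_ns: Optional[float]
    first_embedding_frame: Optional[int]

    def to_table(self, **provenance) -> TableArtifact:
        return TableArtifact.create(self.table, **provenance)


def _segment_mask(frame, segments: Iterable[str]) -> np.ndarray:
    mask = np.zeros(frame.n_atoms, dtype=bool)
    for seg in segments:
        mask |= frame.mask_segment(seg)
    if not np.any(mask):
        raise SelectionError(f"segments {list(segments)} select no atoms")
    return mask


def detect_embedding(trajectory: Trajectory, criterion: EmbeddingCriterion,
                     membrane_mask: np.ndarray) -> EmbeddingTimeline:
    """Per-frame embedding flags and the first-embedding time.

    ``membrane_mask`` selects the membrane atoms (e.g. headgroup beads) in
    the trajectory topology.
    """
    membrane_mask = np.asarray(membrane_mask, dtype=bool)
    if not np.any(membrane_mask):
        raise SelectionError("membrane selection is empty")
    rows = []
    first_frame: Optional[int] = None
    for i in range(trajectory.n_frames):
        frame = trajectory.frame(i)
        m_omega = _segment_mask(frame, criterion.omega1_segments)
        m_pair = _segment_mask(frame, criterion.pair_segments)
        a_omega = buried_area_between(
            frame, m_omega, membrane_mask, probe_A=criterion.probe_A,
            n_sphere_points=criterion.n_sphere_points)
        a_pair = buried_area_between(
            frame, m_pair, membrane_mask, probe_A=criterion.probe_A,
            n_sphere_points=criterion.n_sphere_points)
        embedded = (a_omega > criterion.area_omega1_min_A2
                    and a_pair > criterion.area_beta9_cterm_min_A2)
        if embedded and first_frame is None:
            first_frame = i
        rows.append({"time_ns": trajectory.times_ns[i],
                     "area_omega1_A2": a_omega,
                     "area_pair_A2": a_pair,
                     "embedded": embedded})
    table = pd.DataFrame(rows)
    first_time = (float(trajectory.times_ns[first_frame])
                  if first_frame is not None else None)
    return EmbeddingTimeline(table=table,
                             first_embedding_time_ns=first_time,
                             first_embedding_frame=first_frame)
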