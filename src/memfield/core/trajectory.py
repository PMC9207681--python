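"""Ordered coordinate frames over a fixed topology."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .membrane import LatticeMembrane
from .structure import ChargedStructure


@dataclass
class Trajectory:
    """Frames (time in ns, positions in angstrom) over a fixed topology."""

    topology: ChargedStructure
    times_ns: np.ndarray          # (n_frames,)
    positions: np.ndarray         # (n_frames, n_atoms, 3)
    membrane: Optional[LatticeMembrane] = None

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, atoms, 3)")
        if len(self.times_ns) != len(self.positions):
            raise ValueError("times and frames length mismatch")
        if len(self.times_ns) == 0:
            raise ValueError("trajectory must contain at least one frame")
        if self.positions.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"per-frame atom count {self.positions.shape[1]} does not "
                f"match topology atom count {self.topology.n_atoms}")
        if np.any(np.diff(self.times_ns) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times_ns)

    @property
    def duration_ns(self) -> float:
        return float(self.times_ns[-1] - self.times_ns[0])

    def frame(self, i: int) -> ChargedStructure:
        """Topology posed at frame ``i``."""
        return self.topology.with_positions(self.positions[i])

    def subset(self, frame_mask: np.ndarray) -> "Trajectory":
        frame_mask = np.asarray(frame_mask, dtype=bool)
        return Trajectory(
            topology=self.topology,
            times_ns=self.times_ns[frame_mask],
            positions=self.positions[frame_mask],
            membrane=self.membrane)


def concatenate(trajectories: list[Trajectory]) -> Trajectory:
    """Pool replica trajectories into one frame sequence.

    Times are shifted so the pooled sequence stays strictly increasing;
    frame weights are unchanged (every frame counts once).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    top = trajectories[0].topology
    for t in trajectories[1:]:
        if t.topology.n_atoms != top.n_atoms:
            raise ValueError("trajectories must share a topology")
    times = []
    offset = 0.0
    for t in trajectories:
        shifted = t.times_ns - t.times_ns[0] + offset
        times.append(shifted)
        dt = np.min(np.diff(t.times_ns)) if t.n_frames > 1 else 1.0
        offset = shifted[-1] + dt
    return Trajectory(
        topology=top,
        times_ns=np.concatenate(times),
        positions=np.concatenate([t.positions for t in trajectories]),
        membrane=trajectories[0].membrane)
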