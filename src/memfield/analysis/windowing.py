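"""Analysis windowing: keep the last N nanoseconds of a trajectory."""

from __future__ import annotations

import numpy as np

from ..core.trajectory import Trajectory

__all__ = ["analysis_window"]


def analysis_window(trajectory: Trajectory, last_ns: float = 720.0
                    ) -> Trajectory:
    """Sub-trajectory of frames with time >= (t_end - last_ns).

    The window boundary is inclusive (a trajectory of duration exactly
    ``last_ns`` keeps all its frames).  Frame order is preserved.  Raises
    if the trajectory is shorter than the requested window.
    """
    if last_ns <= 0:
        raise ValueError("last_ns must be > 0")
    if trajectory.duration_ns < last_ns - 1e-12:
        raise ValueError(
            f"trajectory spans {trajectory.duration_ns:g} ns, shorter than "
            f"the requested window of {last_ns:g} ns")
    cut = trajectory.times_ns[-1] - last_ns
    mask = trajectory.times_ns >= cut - 1e-9
    return trajectory.subset(mask)
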