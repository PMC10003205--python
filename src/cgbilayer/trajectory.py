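"""Trajectory container: frames of coordinates, boxes and times.

Times are stored in *actual* simulated nanoseconds together with the
effective-time factor of the run (4 by default for CG dynamics, 1 for
synthetic data generated directly on the effective clock). Analysis code
that needs physical time uses :attr:`Trajectory.effective_times`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    coords: np.ndarray  # (F, N, 3) A, wrapped or not (see `wrapped`)
    boxes: np.ndarray  # (F, 3) A
    times: np.ndarray  # (F,) actual ns
    effective_time_factor: float = 1.0
    wrapped: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must have shape (frames, beads, 3)")
        f = len(self.coords)
        if len(self.boxes) != f or len(self.times) != f:
            raise ValueError("boxes/times length must match frame count")
        if f > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.effective_time_factor <= 0:
            raise ValueError("effective-time factor must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def effective_times(self) -> np.ndarray:
        """Times on the effective (rescaled) clock, ns."""
        return self.times * self.effective_time_factor

    def unwrapped(self) -> np.ndarray:
        """Coordinates with periodic jumps removed by nearest-image continuity.

        Assumes no bead moves more than half a box length between
        consecutive frames; the frame interval must be chosen accordingly.
        """
        if not self.wrapped:
            return self.coords
        out = self.coords.copy()
        shift = np.zeros_like(out[0])
        for f in range(1, self.n_frames):
            box = self.boxes[f]
            delta = self.coords[f] - self.coords[f - 1]
            shift -= np.round(delta / box) * box
            out[f] = self.coords[f] + shift
        return out

    def __getitem__(self, idx) -> "Trajectory":
        """Sub-trajectory by frame slice/fancy index."""
        if isinstance(idx, int):
            idx = slice(idx, idx + 1)
        return Trajectory(
            coords=self.coords[idx],
            boxes=self.boxes[idx],
            times=self.times[idx],
            effective_time_factor=self.effective_time_factor,
            wrapped=self.wrapped,
            meta=dict(self.meta),
        )
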