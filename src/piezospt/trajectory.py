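"""Core trajectory container shared by every analysis stage.

A trajectory is one particle's time-ordered sequence of 2D positions in
micrometers, sampled at a fixed frame interval ``dt``.  Frames skipped by the
tracker are kept as placeholder rows whose coordinates are NaN, so that frame
indices stay contiguous and lag times remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Trajectory", "GroundTruthEnsemble"]


@dataclass
class Trajectory:
    """One particle's positions over time.

    Parameters
    ----------
    traj_id : str or int
        Identifier, unique within an ensemble.
    frames : ndarray of int
        Strictly increasing, contiguous frame indices (0-based).
    xy : ndarray, shape (n, 2)
        Positions in micrometers; NaN rows mark skipped frames (gaps).
    dt : float
        Frame interval in seconds.
    meta : dict
        Free-form metadata (``cell_id``, ``session_id``, ``condition``).
    """

    traj_id: Any
    frames: np.ndarray
    xy: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.shape != (self.frames.size, 2):
            raise ValueError("xy must have shape (len(frames), 2)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.frames.size >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("frames must be contiguous after gap insertion")
        valid = self.valid_mask
        if valid.sum() < 2:
            raise ValueError("trajectory needs at least 2 non-gap positions")
        if not (valid[0] and valid[-1]):
            raise ValueError("first and last positions must be non-gap")

    @property
    def n_slots(self) -> int:
        """Number of frame slots including gap placeholders."""
        return self.frames.size

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.xy).all(axis=1)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def duration_s(self) -> float:
        """Span in seconds counting frame slots inclusively."""
        return (self.frames[-1] - self.frames[0] + 1) * self.dt

    def valid_positions(self) -> np.ndarray:
        return self.xy[self.valid_mask]

    def steps(self) -> np.ndarray:
        """Displacement vectors between consecutive non-gap frames.

        A pair of frames separated by a gap contributes no step; step lengths
        across gaps would conflate two or more physical displacements.
        """
        v = self.valid_mask
        ok = v[:-1] & v[1:]
        return self.xy[1:][ok] - self.xy[:-1][ok]


@dataclass
class GroundTruthEnsemble:
    """A set of trajectories plus the generative truth used in recovery tests.

    ``true_labels`` and ``true_params`` align 1:1 with ``trajectories``; the
    truth channel is what lets classification and mixture fits be scored
    without real microscopy data.
    """

    trajectories: list[Trajectory]
    true_labels: list[str]
    true_params: list[dict]

    def __post_init__(self) -> None:
        n = len(self.trajectories)
        if len(self.true_labels) != n or len(self.true_params) != n:
            raise ValueError("labels and params must align 1:1 with trajectories")

    def __len__(self) -> int:
        return len(self.trajectories)
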