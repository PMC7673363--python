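"""Group activity and cohesion from 2-D trajectories.

Activity is the mean swimming speed (cm s^-1): per fish, the mean displacement
between consecutive tracked frames times the frame rate; the group value is
the unweighted mean over fish.  Cohesion is the mean pairwise Euclidean
distance among group members (cm), averaged first over the unordered pairs
within a frame and then over frames — smaller values mean a tighter group.
Tracking dropouts (missing positions) are skipped and the averages
renormalised; nothing is interpolated silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "ArenaConfig",
    "TrajectorySet",
    "ActivityResult",
    "CohesionResult",
    "calibrate",
    "mean_speed",
    "cohesion",
    "smooth",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Circular arena geometry and recording parameters.

    ``area`` cm^2 (default 3117 cm^2, a ~31.5 cm-radius circular tank);
    ``frame_rate`` frames s^-1 and ``px_per_cm`` have no defaults in the CLI —
    they depend on the recording setup and must be supplied.
    """

    area: float = 3117.0
    px_per_cm: float = 1.0
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        if self.area <= 0 or self.px_per_cm <= 0 or self.frame_rate <= 0:
            raise ValueError("area, px_per_cm and frame_rate must be positive")

    @property
    def radius(self) -> float:
        return float(np.sqrt(self.area / np.pi))


@dataclass
class TrajectorySet:
    """Positions (cm) as an array of shape (n_frames, n_fish, 2); NaN = missing."""

    positions: np.ndarray
    fish_ids: list
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.frames = np.asarray(self.frames)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_frames, n_fish, 2)")
        if self.frames.size >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame index must be strictly increasing")

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrajectorySet":
        """Build from a long table with columns frame, fish_id, x, y."""
        fish_ids = sorted(df["fish_id"].unique().tolist())
        frames = np.sort(df["frame"].unique())
        wide_x = df.pivot_table(index="frame", columns="fish_id", values="x")
        wide_y = df.pivot_table(index="frame", columns="fish_id", values="y")
        wide_x = wide_x.reindex(index=frames, columns=fish_ids)
        wide_y = wide_y.reindex(index=frames, columns=fish_ids)
        pos = np.stack([wide_x.to_numpy(), wide_y.to_numpy()], axis=-1)
        return cls(positions=pos, fish_ids=fish_ids, frames=frames)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for i, f in enumerate(self.frames):
            for j, fid in enumerate(self.fish_ids):
                recs.append((f, fid, self.positions[i, j, 0], self.positions[i, j, 1]))
        return pd.DataFrame(recs, columns=["frame", "fish_id", "x", "y"])


@dataclass(frozen=True)
class ActivityResult:
    mean_speed: float  # cm s^-1
    per_fish_speeds: dict
    frames_used: int


@dataclass(frozen=True)
class CohesionResult:
    cohesion: float  # cm
    n_pairs: int
    frames_used: int


def calibrate(traj: TrajectorySet, px_per_cm: float) -> TrajectorySet:
    """Convert pixel coordinates to cm by dividing by the calibration scale."""
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    return TrajectorySet(
        positions=traj.positions / px_per_cm,
        fish_ids=list(traj.fish_ids),
        frames=traj.frames.copy(),
    )


def smooth(traj: TrajectorySet, window: int) -> TrajectorySet:
    """Centred moving-average smoothing of positions (optional; off by default).

    Raw tracking jitter inflates speed estimates; a short window suppresses it.
    NaNs propagate: a window containing any missing frame stays missing, so
    smoothing never invents positions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return traj
    logger.info("smoothing trajectories with a %d-frame moving average", window)
    kernel = np.ones(window) / window
    pos = traj.positions.copy()
    for j in range(pos.shape[1]):
        for d in range(2):
            pos[:, j, d] = np.convolve(pos[:, j, d], kernel, mode="same")
    return TrajectorySet(positions=pos, fish_ids=list(traj.fish_ids), frames=traj.frames.copy())


def mean_speed(
    traj: TrajectorySet, arena: ArenaConfig, pooled: bool = False
) -> ActivityResult:
    """Mean swimming speed, cm s^-1.

    Per fish: mean over consecutive valid frame pairs of displacement x
    frame_rate; pairs with a missing endpoint are skipped.  The group value is
    the unweighted mean of per-fish speeds (robust to unequal valid-frame
    counts); ``pooled=True`` averages all frame-pair displacements in one pool
    instead.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    disp = np.linalg.norm(np.diff(traj.positions, axis=0), axis=2)  # (F-1, n_fish)
    valid = np.isfinite(disp)
    speeds: dict = {}
    for j, fid in enumerate(traj.fish_ids):
        if valid[:, j].any():
            speeds[fid] = float(disp[valid[:, j], j].mean() * arena.frame_rate)
        else:
            logger.warning("fish %r has no valid frame pair; excluded from speed", fid)
    if not speeds:
        raise ValueError("no fish with a valid frame pair")
    if pooled:
        group = float(disp[valid].mean() * arena.frame_rate)
    else:
        group = float(np.mean(list(speeds.values())))
    return ActivityResult(
        mean_speed=group,
        per_fish_speeds=speeds,
        frames_used=int(valid.any(axis=1).sum()),
    )


def cohesion(traj: TrajectorySet) -> CohesionResult:
    """Mean pairwise inter-individual distance, cm.

    Within each frame: mean Euclidean distance over all unordered pairs with
    both positions tracked; frames with fewer than two valid fish are skipped.
    The trial value is the mean over retained frames.
    """
    per_frame = []
    for i in range(traj.n_frames):
        pts = traj.positions[i]
        pts = pts[np.isfinite(pts).all(axis=1)]
        if pts.shape[0] >= 2:
            per_frame.append(pdist(pts).mean())
    if not per_frame:
        raise ValueError("no frame with >= 2 valid fish")
    n = traj.n_fish
    return CohesionResult(
        cohesion=float(np.mean(per_frame)),
        n_pairs=n * (n - 1) // 2,
        frames_used=len(per_frame),
    )
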