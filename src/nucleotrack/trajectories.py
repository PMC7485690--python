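"""Trajectory container shared by the simulation and analysis stages.

A :class:`TrajectorySet` is a thin wrapper around a long-form
:class:`pandas.DataFrame` holding time-ordered localizations of single
molecules, one row per (track, frame). All analysis modules consume and
produce this container; positions are always in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

#: Required columns, in canonical order, of the trajectory table.
CORE_COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um", "intensity"]
#: Optional columns appended after the core ones when present.
OPTIONAL_COLUMNS = ["state_truth", "cell_id"]


@dataclass
class TrajectorySet:
    """A set of single-molecule trajectories sharing one frame interval.

    Parameters
    ----------
    data
        Long-form table with columns ``track_id, frame, time_s, x_um,
        y_um, intensity`` (plus optional ``state_truth``, ``cell_id``),
        sorted by track then frame, with strictly increasing frames
        within each track.
    frame_interval
        Time between consecutive frames, seconds.
    meta
        Free-form provenance (seed, generating parameters, QC reports).
    """

    data: pd.DataFrame
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or not np.isfinite(self.frame_interval):
            raise ValueError(f"frame_interval must be positive, got {self.frame_interval}")
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table is missing columns: {missing}")
        dup = self.data.duplicated(subset=["track_id", "frame"])
        if dup.any():
            raise ValueError("duplicate (track_id, frame) rows in trajectory table")
        self.data = self.data.sort_values(["track_id", "frame"], kind="stable").reset_index(
            drop=True
        )

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def n_localizations(self) -> int:
        return len(self.data)

    @property
    def n_steps(self) -> int:
        """Total number of single-frame displacements over all tracks."""
        return int((self.data.groupby("track_id").size() - 1).clip(lower=0).sum())

    def track_lengths(self) -> pd.Series:
        """Number of localizations per track."""
        return self.data.groupby("track_id").size()

    def itertracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        yield from self.data.groupby("track_id", sort=True)

    def subset(self, track_ids) -> "TrajectorySet":
        sel = self.data[self.data["track_id"].isin(track_ids)]
        return TrajectorySet(sel.copy(), self.frame_interval, dict(self.meta))

    def __len__(self) -> int:
        return self.n_tracks

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TrajectorySet(n_tracks={self.n_tracks}, n_steps={self.n_steps}, "
            f"frame_interval={self.frame_interval})"
        )


def from_arrays(
    track_id: np.ndarray,
    frame: np.ndarray,
    x_um: np.ndarray,
    y_um: np.ndarray,
    frame_interval: float,
    intensity: np.ndarray | None = None,
    state_truth: np.ndarray | None = None,
    cell_id: np.ndarray | None = None,
    meta: dict | None = None,
) -> TrajectorySet:
    """Assemble a :class:`TrajectorySet` from flat per-localization arrays."""
    frame = np.asarray(frame, dtype=int)
    cols = {
        "track_id": np.asarray(track_id, dtype=int),
        "frame": frame,
        "time_s": frame * frame_interval,
        "x_um": np.asarray(x_um, dtype=float),
        "y_um": np.asarray(y_um, dtype=float),
        "intensity": (
            np.asarray(intensity, dtype=float)
            if intensity is not None
            else np.ones(len(frame))
        ),
    }
    if state_truth is not None:
        cols["state_truth"] = np.asarray(state_truth)
    if cell_id is not None:
        cols["cell_id"] = np.asarray(cell_id)
    return TrajectorySet(pd.DataFrame(cols), frame_interval, meta or {})
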