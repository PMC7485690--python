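"""File formats: trajectory CSV, movie TIFF, JSON configs and reports.

Trajectory CSV schema (exact column order): ``track_id, frame, time_s,
x_um, y_um, intensity`` plus optional ``state_truth, cell_id``. Frames
are 0-based; floats are written with 6 significant digits, which
round-trips all analysis results losslessly at localization precision.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectories import CORE_COLUMNS, OPTIONAL_COLUMNS, TrajectorySet

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_movie",
    "write_movie",
    "read_config",
    "provenance_block",
    "write_report",
]


def write_trajectories(trajset: TrajectorySet, path) -> Path:
    path = Path(path)
    cols = CORE_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in trajset.data.columns]
    trajset.data[cols].to_csv(path, index=False, float_format="%.6g")
    return path


def read_trajectories(path, frame_interval: float | None = None) -> TrajectorySet:
    """Read a trajectory CSV, validating the schema.

    ``frame_interval`` may be omitted when the file's ``time_s`` column
    determines it (two or more frames in some track).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col in ("track_id", "frame"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            rows = (bad.index + 2).tolist()[:5]  # 1-based + header
            raise ValueError(f"{path.name}: non-numeric {col!r} at row(s) {rows}")
    for col in ("time_s", "x_um", "y_um", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[coerced.isna() & df[col].notna()]
        if len(bad):
            rows = (bad.index + 2).tolist()[:5]
            raise ValueError(f"{path.name}: non-numeric {col!r} at row(s) {rows}")
        df[col] = coerced
    if frame_interval is None:
        srt = df.sort_values(["track_id", "frame"], kind="stable")
        same = srt["track_id"].to_numpy()[1:] == srt["track_id"].to_numpy()[:-1]
        dfr = np.diff(srt["frame"].to_numpy())[same]
        dti = np.diff(srt["time_s"].to_numpy())[same]
        ok = dfr > 0
        if not ok.any():
            raise ValueError(f"{path.name}: cannot infer frame interval "
                             "(no multi-frame track); pass frame_interval")
        frame_interval = float(np.median(dti[ok] / dfr[ok]))
    return TrajectorySet(df, frame_interval, meta={"source": str(path)})


def write_movie(stack: np.ndarray, path) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))
    return path


def read_movie(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(Path(path))


def read_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def provenance_block(config: dict, seed: int | None = None) -> dict:
    """Provenance stamped into every report: version, config hash, time, seed."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "tool": "nucleotrack",
        "version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "as_dict"):
            return o.as_dict()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
    return path
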