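"""Spot detection and track linking for sparse single-molecule movies.

Detection follows the classic centroid approach for colloidal/particle
tracking: a spatial band-pass (short-scale Gaussian smoothing minus a
boxcar background estimate on the feature scale) suppresses pixel noise
and slow background, candidate peaks are local maxima above an intensity
threshold, and each peak is refined to subpixel precision by an iterated
intensity centroid within the feature window (an optional Gaussian
least-squares refinement is available).

Linking is greedy nearest-neighbour in order of increasing displacement,
valid at the enforced density of one to two visible molecules per cell;
a density guard warns when a frame carries more candidates than that
assumption supports. Gaps of up to ``memory`` frames are bridged.

Pixel convention: pixel centres at integer coordinates, origin top-left,
frames 0-based; ``x_um = x_px * pixel_size`` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .trajectories import TrajectorySet, from_arrays

__all__ = [
    "detect_spots",
    "link_tracks",
    "filter_tracks",
    "QCReport",
    "MIN_TRACKS_QC",
]

#: Datasets with fewer surviving tracks than this are flagged by QC.
MIN_TRACKS_QC = 100


def _bandpass(frame: np.ndarray, diameter: int, noise_scale: float = 1.0) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(frame.astype(float), noise_scale)
    background = ndimage.uniform_filter(frame.astype(float), diameter)
    return np.clip(smoothed - background, 0.0, None)


def _refine_centroid(bp: np.ndarray, row: int, col: int, w: int,
                     n_iter: int = 3) -> tuple[float, float, float]:
    """Iterated intensity centroid in a (2w+1)^2 window; returns (r, c, mass)."""
    ny, nx = bp.shape
    r, c = float(row), float(col)
    mass = 0.0
    for _ in range(n_iter):
        r0, c0 = int(round(r)), int(round(c))
        rs = slice(max(r0 - w, 0), min(r0 + w + 1, ny))
        cs = slice(max(c0 - w, 0), min(c0 + w + 1, nx))
        win = bp[rs, cs]
        mass = float(win.sum())
        if mass <= 0:
            return r, c, 0.0
        rr, cc = np.mgrid[rs, cs]
        r_new = float((rr * win).sum() / mass)
        c_new = float((cc * win).sum() / mass)
        if abs(r_new - r) < 1e-4 and abs(c_new - c) < 1e-4:
            r, c = r_new, c_new
            break
        r, c = r_new, c_new
    return r, c, mass


def _refine_gaussian(frame: np.ndarray, row: float, col: float, w: int):
    """2D Gaussian least-squares refinement around a candidate peak."""
    from lmfit import Parameters, minimize

    ny, nx = frame.shape
    r0, c0 = int(round(row)), int(round(col))
    rs = slice(max(r0 - w, 0), min(r0 + w + 1, ny))
    cs = slice(max(c0 - w, 0), min(c0 + w + 1, nx))
    win = frame[rs, cs].astype(float)
    rr, cc = np.mgrid[rs, cs]
    params = Parameters()
    params.add("amp", value=float(win.max() - win.min()), min=0)
    params.add("r", value=row, min=rs.start - 0.5, max=rs.stop - 0.5)
    params.add("c", value=col, min=cs.start - 0.5, max=cs.stop - 0.5)
    params.add("sigma", value=max(w / 2.0, 0.8), min=0.3, max=2.0 * w)
    params.add("offset", value=float(win.min()))

    def resid(p):
        g = p["amp"].value * np.exp(
            -((rr - p["r"].value) ** 2 + (cc - p["c"].value) ** 2)
            / (2 * p["sigma"].value ** 2)
        ) + p["offset"].value
        return (g - win).ravel()

    res = minimize(resid, params)
    return float(res.params["r"].value), float(res.params["c"].value), float(win.sum())


def detect_spots(
    stack: np.ndarray,
    feature_diameter: int = 7,
    threshold_percentile: float = 99.0,
    pixel_size: float = 0.106,
    refine: str = "centroid",
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Detect fluorescent spots in every frame of a movie.

    Parameters
    ----------
    stack
        3D array (frames, rows, cols); a single 2D frame is also accepted.
    feature_diameter
        Approximate spot extent in pixels; odd, >= 3. Sets the band-pass
        background scale and the refinement window.
    threshold_percentile
        Peaks must exceed this percentile of the band-passed stack's
        pixel values.
    refine
        ``"centroid"`` (default) or ``"gaussian"``.

    Returns a table with ``frame, x_px, y_px, x_um, y_um,
    integrated_intensity, quality`` (x = column, y = row).
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("stack must be 2D or 3D")
    if not np.isfinite(stack).all():
        raise ValueError("stack contains NaN or infinite values")
    if feature_diameter < 3 or feature_diameter % 2 == 0:
        raise ValueError("feature_diameter must be odd and >= 3")
    if refine not in ("centroid", "gaussian"):
        raise ValueError("refine must be 'centroid' or 'gaussian'")
    w = feature_diameter // 2

    bp_frames = [_bandpass(f, feature_diameter, noise_scale) for f in stack]
    # "signal" pixels: positive band-passed values above numerical residue
    global_max = max((float(bp.max()) for bp in bp_frames), default=0.0)
    floor = 1e-6 * global_max
    positive = (
        np.concatenate([bp[bp > floor].ravel() for bp in bp_frames])
        if global_max > 0 else np.array([0.0])
    )
    thresh = max(
        float(np.percentile(positive, threshold_percentile)) if positive.size else 0.0,
        floor,
    )

    rows_out = []
    for fi, bp in enumerate(bp_frames):
        if bp.max() <= 0:
            continue
        footprint = np.ones((feature_diameter, feature_diameter), bool)
        local_max = (bp == ndimage.maximum_filter(bp, footprint=footprint)) & (bp > thresh) \
            & (bp > 0)
        for r0, c0 in zip(*np.nonzero(local_max)):
            if refine == "centroid":
                r, c, mass = _refine_centroid(bp, r0, c0, w)
            else:
                r, c, mass = _refine_gaussian(stack[fi].astype(float), float(r0),
                                              float(c0), w)
            rows_out.append((fi, c, r, mass, float(bp[r0, c0])))
    det = pd.DataFrame(rows_out, columns=["frame", "x_px", "y_px",
                                          "integrated_intensity", "quality"])
    det["x_um"] = det["x_px"] * pixel_size
    det["y_um"] = det["y_px"] * pixel_size
    return det[["frame", "x_px", "y_px", "x_um", "y_um",
                "integrated_intensity", "quality"]]


def link_tracks(
    detections: pd.DataFrame,
    max_displacement: float = 0.5,
    memory: int = 1,
    frame_interval: float = 0.030,
    density_guard: int = 5,
) -> TrajectorySet:
    """Link detections into trajectories by greedy nearest-neighbour assignment.

    Candidate (track end, detection) pairs within ``max_displacement``
    (um, over the elapsed gap) are accepted in order of increasing
    displacement, each track and detection at most once per frame — a
    greedy approximation to minimum total squared displacement that is
    exact at the enforced density of 1-2 molecules in view. Tracks missing
    for more than ``memory`` frames are closed; unmatched detections seed
    new tracks. Frames with more than ``density_guard`` detections
    trigger a warning (assignments become ambiguous at high density).
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be positive")
    if memory < 0:
        raise ValueError("memory must be >= 0")
    det = detections.sort_values(["frame"], kind="stable").reset_index(drop=True)
    crowded = det.groupby("frame").size()
    n_crowded = int((crowded > density_guard).sum())
    if n_crowded:
        warnings.warn(
            f"{n_crowded} frame(s) carry more than {density_guard} detections; "
            "greedy nearest-neighbour linking may be ambiguous", stacklevel=2,
        )
    return _link_full(det, max_displacement, memory, frame_interval)


def _link_full(det: pd.DataFrame, max_displacement: float, memory: int,
               frame_interval: float) -> TrajectorySet:
    next_id = 0
    active: list[dict] = []
    closed: list[dict] = []
    for frame, group in det.groupby("frame", sort=True):
        idxs = group.index.to_numpy()
        xy = group[["x_um", "y_um"]].to_numpy()
        still_active = []
        for tr in active:
            if frame - tr["last_frame"] <= memory + 1:
                still_active.append(tr)
            else:
                closed.append(tr)
        active = still_active
        pairs = []
        for ti, tr in enumerate(active):
            d = np.hypot(xy[:, 0] - tr["xy"][0], xy[:, 1] - tr["xy"][1])
            for di in np.flatnonzero(d <= max_displacement):
                pairs.append((float(d[di]), ti, int(di)))
        pairs.sort(key=lambda p: p[0])
        used_t: set[int] = set()
        used_d: set[int] = set()
        for _, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = active[ti]
            tr["xy"] = xy[di]
            tr["last_frame"] = int(frame)
            tr["rows"].append(int(idxs[di]))
        for di in range(len(idxs)):
            if di not in used_d:
                active.append({"id": next_id, "xy": xy[di], "last_frame": int(frame),
                               "rows": [int(idxs[di])]})
                next_id += 1
    closed.extend(active)

    tid_col = np.empty(len(det), dtype=int)
    keep = np.zeros(len(det), dtype=bool)
    for tr in closed:
        if len(tr["rows"]) >= 2:
            for ri in tr["rows"]:
                tid_col[ri] = tr["id"]
                keep[ri] = True
    sub = det[keep]
    return from_arrays(
        track_id=tid_col[keep],
        frame=sub["frame"].to_numpy(),
        x_um=sub["x_um"].to_numpy(),
        y_um=sub["y_um"].to_numpy(),
        frame_interval=frame_interval,
        intensity=sub["integrated_intensity"].to_numpy(),
        meta={"linker": "greedy-nearest-neighbour", "memory": memory,
              "max_displacement_um": max_displacement},
    )


@dataclass(frozen=True)
class QCReport:
    n_tracks_in: int
    n_tracks_out: int
    min_steps: int
    flagged: bool
    note: str = ""


def filter_tracks(trajset: TrajectorySet, min_steps: int = 4) -> TrajectorySet:
    """Drop tracks with fewer than ``min_steps`` displacements.

    The surviving set carries a :class:`QCReport` in ``meta['qc']``;
    datasets retaining fewer than ``MIN_TRACKS_QC`` tracks are flagged
    (and warned about), mirroring the minimum-statistics rule that at
    least 100 tracks back every reported fit.
    """
    if min_steps < 1:
        raise ValueError("min_steps must be >= 1")
    lengths = trajset.track_lengths()
    keep = lengths.index[lengths - 1 >= min_steps]
    out = trajset.subset(keep)
    flagged = out.n_tracks < MIN_TRACKS_QC
    note = (f"only {out.n_tracks} tracks survive filtering (minimum "
            f"{MIN_TRACKS_QC} expected)") if flagged else ""
    if flagged:
        warnings.warn(note, stacklevel=2)
    out.meta["qc"] = QCReport(
        n_tracks_in=trajset.n_tracks,
        n_tracks_out=out.n_tracks,
        min_steps=min_steps,
        flagged=flagged,
        note=note,
    )
    return out
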