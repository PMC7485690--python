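"""Synthetic single-molecule data with known ground truth.

Everything the analysis stages consume can be generated here: multi-state
Brownian trajectories confined to a rod-shaped (spherocylindrical) cell,
slimfield-style movies with Gaussian point spread functions and Poisson
shot noise, exponential FRAP recovery traces, dwell-time draws from
exponential mixtures, and cell/foci tables with a controlled
pole-distance/length relationship. Each generator takes an explicit seed
and records it, so every downstream fit can be validated by parameter
recovery against the generating values.

The simulation is two-dimensional (the image plane): molecules take
Gaussian steps with per-coordinate variance ``2 D dt``, are reflected
specularly at the cell outline, switch motion state with first-order
probability ``1 - exp(-dt / mean_residence)`` per frame, and photobleach
with probability ``1 - exp(-dt / bleach_lifetime)`` per frame, which sets
the observed track-length distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectories import TrajectorySet, from_arrays

__all__ = [
    "CellGeometry",
    "MotionState",
    "MotionModel",
    "Photophysics",
    "AcquisitionConfig",
    "GroundTruth",
    "simulate_trajectories",
    "simulate_movie",
    "simulate_frap_curve",
    "simulate_dwell_times",
    "simulate_foci_cells",
]


def _check_positive(name: str, value: float, allow_zero: bool = False) -> None:
    if not np.isfinite(value) or value < 0 or (value == 0 and not allow_zero):
        raise ValueError(f"{name} must be {'non-negative' if allow_zero else 'positive'} "
                         f"and finite, got {value}")


@dataclass(frozen=True)
class CellGeometry:
    """2D projection of a rod-shaped cell: a stadium (rectangle + half-discs).

    ``length`` is the pole-to-pole distance and ``radius`` the cell
    half-width, both in micrometres; the straight segment of the long axis
    spans ``length - 2 * radius``. The cell is centred at the origin with
    its long axis along x.
    """

    length: float
    radius: float

    def __post_init__(self) -> None:
        _check_positive("radius", self.radius)
        if not np.isfinite(self.length) or self.length < 2 * self.radius:
            raise ValueError(
                f"length must satisfy length >= 2*radius, got length={self.length}, "
                f"radius={self.radius}"
            )

    @property
    def half_axis(self) -> float:
        """Half-length of the straight segment of the medial axis."""
        return self.length / 2.0 - self.radius

    @staticmethod
    def default_cell() -> "CellGeometry":
        """A typical exponentially growing B. subtilis cell (3.0 x 0.9 um)."""
        return CellGeometry(length=3.0, radius=0.45)

    @staticmethod
    def unconfined_proxy(scale: float = 50.0) -> "CellGeometry":
        """A geometry large enough that boundary effects are negligible.

        Used for parameter-recovery simulations where the generative model
        is the free-diffusion Rayleigh mixture itself (published apparent
        diffusion coefficients already include in-cell confinement, so
        re-confining them would double-count the effect).
        """
        return CellGeometry(length=4.0 * scale, radius=scale)

    def _axis_distance(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distance from each point to the medial-axis segment and the foot point x."""
        a = self.half_axis
        qx = np.clip(xy[..., 0], -a, a)
        d = np.hypot(xy[..., 0] - qx, xy[..., 1])
        return d, qx

    def contains(self, xy: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        d, _ = self._axis_distance(np.asarray(xy, float))
        return d <= self.radius + tol

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the stadium, by rejection from the bounding box."""
        out = np.empty((0, 2))
        while len(out) < n:
            cand = rng.uniform(
                [-self.length / 2, -self.radius], [self.length / 2, self.radius],
                size=(max(n, 16), 2),
            )
            out = np.vstack([out, cand[self.contains(cand)]])
        return out[:n]

    def reflect(self, xy: np.ndarray, max_folds: int = 16) -> np.ndarray:
        """Fold points outside the cell back inside by specular reflection.

        The boundary normal of a stadium always points away from the
        medial-axis segment, so one fold maps a point at axis-distance
        ``d > R`` to distance ``2R - d``; repeated for (rare) steps longer
        than the cell width.
        """
        xy = np.array(xy, dtype=float, copy=True)
        for _ in range(max_folds):
            d, qx = self._axis_distance(xy)
            outside = d > self.radius
            if not outside.any():
                break
            q = np.column_stack([qx[outside], np.zeros(outside.sum())])
            u = (xy[outside] - q) / d[outside, None]
            xy[outside] = q + (2.0 * self.radius - d[outside])[:, None] * u
        else:  # pragma: no cover - pathological step sizes
            d, qx = self._axis_distance(xy)
            bad = d > self.radius
            q = np.column_stack([qx[bad], np.zeros(bad.sum())])
            xy[bad] = q + (xy[bad] - q) * (self.radius / d[bad, None])
        return xy


@dataclass(frozen=True)
class MotionState:
    """One diffusive population: apparent D (um^2/s) and mean residence (s)."""

    name: str
    D: float
    mean_residence: float = math.inf

    def __post_init__(self) -> None:
        if not np.isfinite(self.D) or self.D < 0:
            raise ValueError(f"D must be >= 0 and finite, got {self.D}")
        if self.mean_residence <= 0:
            raise ValueError(f"mean_residence must be > 0, got {self.mean_residence}")


@dataclass(frozen=True)
class MotionModel:
    """A mixture of diffusive states with equilibrium occupancies.

    For two-state models with finite residences the occupancies are not
    free: detailed balance requires ``f1 / tau1 == f2 / tau2``, which is
    checked at construction.
    """

    states: tuple[MotionState, ...]
    equilibrium_fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.equilibrium_fractions, float)
        if len(f) != len(self.states) or len(f) == 0:
            raise ValueError("need one equilibrium fraction per state")
        if (f < 0).any() or not math.isclose(f.sum(), 1.0, abs_tol=1e-8):
            raise ValueError(f"equilibrium fractions must be >= 0 and sum to 1, got {f}")
        taus = [s.mean_residence for s in self.states]
        if len(self.states) == 2 and all(np.isfinite(taus)):
            flux = [fi / ti for fi, ti in zip(f, taus)]
            if not math.isclose(flux[0], flux[1], rel_tol=1e-3):
                raise ValueError(
                    "two-state model violates detailed balance: "
                    f"f1/tau1={flux[0]:.4g} != f2/tau2={flux[1]:.4g}"
                )

    @staticmethod
    def single(D: float, name: str = "state") -> "MotionModel":
        return MotionModel((MotionState(name, D),), (1.0,))

    @staticmethod
    def two_state(
        D_mobile: float,
        D_slow: float,
        f_mobile: float,
        residence_mobile: float = math.inf,
    ) -> "MotionModel":
        """Two-state model; slow-state residence derived from detailed balance."""
        if np.isfinite(residence_mobile):
            residence_slow = residence_mobile * (1 - f_mobile) / f_mobile
        else:
            residence_slow = math.inf
        return MotionModel(
            (
                MotionState("mobile", D_mobile, residence_mobile),
                MotionState("slow", D_slow, residence_slow),
            ),
            (f_mobile, 1.0 - f_mobile),
        )


@dataclass(frozen=True)
class Photophysics:
    """Fluorophore model: exponential bleaching, localization noise, brightness.

    ``bleach_lifetime`` (s) sets the expected observed track length,
    ``bleach_lifetime / dt`` steps; ``localization_sigma`` (um, per
    coordinate) is added to reported positions only.
    """

    bleach_lifetime: float = 0.237
    localization_sigma: float = 0.0
    mean_photons: float = 400.0
    background: float = 10.0

    def __post_init__(self) -> None:
        _check_positive("bleach_lifetime", self.bleach_lifetime)
        _check_positive("localization_sigma", self.localization_sigma, allow_zero=True)
        _check_positive("mean_photons", self.mean_photons, allow_zero=True)
        _check_positive("background", self.background, allow_zero=True)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera/stream settings: frame interval (s), frames, pixel size (um)."""

    frame_interval: float = 0.030
    n_frames: int = 1500
    pixel_size: float = 0.106
    image_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        _check_positive("frame_interval", self.frame_interval)
        _check_positive("pixel_size", self.pixel_size)
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def fov_um(self) -> tuple[float, float]:
        """Field of view (height, width) in micrometres."""
        return (self.image_shape[0] * self.pixel_size, self.image_shape[1] * self.pixel_size)


@dataclass
class GroundTruth:
    """Per-frame truth for simulated molecules (noise-free positions, states).

    ``positions`` is long-form: molecule, frame, x_um, y_um, state (lab
    frame, matching the movie renderer's pixel mapping
    ``column = x_um / pixel_size``). ``bleach_frame`` maps molecule id to
    the first frame at which it is no longer visible.
    """

    positions: pd.DataFrame
    bleach_frame: pd.Series
    cell_center: tuple[float, float]
    geometry: CellGeometry
    model: MotionModel
    seed: int


def simulate_trajectories(
    model: MotionModel,
    geom: CellGeometry,
    phot: Photophysics,
    acq: AcquisitionConfig,
    n_molecules: int,
    seed: int,
    cell_center: tuple[float, float] | None = None,
) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate confined multi-state Brownian trajectories with bleaching.

    Each molecule starts uniformly inside ``geom`` in a state drawn from
    the equilibrium fractions. Per frame interval it takes a Gaussian step
    (per-coordinate variance ``2 D dt``), is reflected at the cell outline,
    may switch state, and may bleach, ending its track. Observed positions
    are the true positions plus i.i.d. Gaussian localization noise.

    Returns the observed :class:`TrajectorySet` (tracks with >= 2
    localizations) and the full :class:`GroundTruth`.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if phot.localization_sigma > geom.radius:
        warnings.warn(
            "localization_sigma exceeds the cell radius; observed positions will "
            "routinely fall outside the cell", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    dt = acq.frame_interval
    if cell_center is None:
        h, w = acq.fov_um
        cell_center = (w / 2.0, h / 2.0)

    n_states = len(model.states)
    D = np.array([s.D for s in model.states])
    step_sigma = np.sqrt(2.0 * D * dt)
    p_switch = np.array(
        [1.0 - math.exp(-dt / s.mean_residence) if np.isfinite(s.mean_residence) else 0.0
         for s in model.states]
    )
    fractions = np.asarray(model.equilibrium_fractions)

    pos = geom.sample_uniform(n_molecules, rng)
    state = rng.choice(n_states, size=n_molecules, p=fractions)
    alive = np.ones(n_molecules, dtype=bool)
    p_bleach = 1.0 - math.exp(-dt / phot.bleach_lifetime)

    rec_mol: list[np.ndarray] = []
    rec_frame: list[np.ndarray] = []
    rec_pos: list[np.ndarray] = []
    rec_state: list[np.ndarray] = []
    bleach_frame = np.full(n_molecules, acq.n_frames, dtype=int)
    ids = np.arange(n_molecules)

    frame = 0
    while frame < acq.n_frames and alive.any():
        idx = ids[alive]
        rec_mol.append(idx.copy())
        rec_frame.append(np.full(idx.size, frame))
        rec_pos.append(pos[alive].copy())
        rec_state.append(state[alive].copy())

        # evolve to the next frame
        steps = rng.normal(0.0, 1.0, size=(idx.size, 2)) * step_sigma[state[alive], None]
        pos[alive] = geom.reflect(pos[alive] + steps)
        # state switching, evaluated once per interval
        if p_switch.any():
            switching = rng.random(idx.size) < p_switch[state[alive]]
            if switching.any() and n_states > 1:
                cur = state[alive].copy()
                for i in np.flatnonzero(switching):
                    s = cur[i]
                    others = np.delete(np.arange(n_states), s)
                    w = fractions[others]
                    cur[i] = rng.choice(others, p=w / w.sum())
                state[alive] = cur
        # photobleaching ends the track before the next frame is recorded
        bleached = rng.random(idx.size) < p_bleach
        if bleached.any():
            died = idx[bleached]
            bleach_frame[died] = frame + 1
            keep = alive.copy()
            keep[died] = False
            alive = keep
        frame += 1

    mol = np.concatenate(rec_mol)
    frames = np.concatenate(rec_frame)
    true_xy = np.vstack(rec_pos) + np.asarray(cell_center)
    states = np.concatenate(rec_state)
    state_names = np.array([s.name for s in model.states])

    truth = GroundTruth(
        positions=pd.DataFrame(
            {
                "molecule": mol,
                "frame": frames,
                "x_um": true_xy[:, 0],
                "y_um": true_xy[:, 1],
                "state": state_names[states],
            }
        ).sort_values(["molecule", "frame"], kind="stable").reset_index(drop=True),
        bleach_frame=pd.Series(bleach_frame, index=ids, name="bleach_frame"),
        cell_center=cell_center,
        geometry=geom,
        model=model,
        seed=seed,
    )

    obs_xy = true_xy + rng.normal(0.0, phot.localization_sigma, size=true_xy.shape) \
        if phot.localization_sigma > 0 else true_xy.copy()

    # keep only molecules observed in >= 2 frames (a single localization is not a track)
    counts = np.bincount(mol, minlength=n_molecules)
    keep = counts[mol] >= 2
    trajset = from_arrays(
        track_id=mol[keep],
        frame=frames[keep],
        x_um=obs_xy[keep, 0],
        y_um=obs_xy[keep, 1],
        frame_interval=dt,
        intensity=np.full(keep.sum(), phot.mean_photons),
        state_truth=state_names[states[keep]],
        meta={"seed": seed, "generator": "simulate_trajectories"},
    )
    return trajset, truth


def simulate_movie(
    truth: GroundTruth,
    phot: Photophysics,
    acq: AcquisitionConfig,
    seed: int,
    psf_sigma_px: float = 1.0,
) -> np.ndarray:
    """Render ground-truth molecules into a 16-bit movie.

    Each live molecule becomes a 2D Gaussian point spread function of
    standard deviation ``psf_sigma_px`` whose integral is
    ``phot.mean_photons``, on a uniform background, with Poisson shot
    noise. Pixel centres sit at integer coordinates, origin top-left:
    a molecule at x = 1.06 um with 0.106-um pixels renders at column 10.
    An empty ground truth yields a pure-background stack.
    """
    rng = np.random.default_rng(seed)
    ny, nx = acq.image_shape
    stack = np.zeros((acq.n_frames, ny, nx), dtype=float)
    pos = truth.positions
    if len(pos):
        col = pos["x_um"].to_numpy() / acq.pixel_size
        row = pos["y_um"].to_numpy() / acq.pixel_size
        if (col < -0.5).any() or (col > nx - 0.5).any() or (row < -0.5).any() \
                or (row > ny - 0.5).any():
            raise ValueError("ground-truth positions fall outside the image")
        yy = np.arange(ny)
        xx = np.arange(nx)
        amp = phot.mean_photons / (2.0 * math.pi * psf_sigma_px**2)
        for f, c, r in zip(pos["frame"].to_numpy(), col, row):
            if f >= acq.n_frames:
                continue
            gx = np.exp(-((xx - c) ** 2) / (2 * psf_sigma_px**2))
            gy = np.exp(-((yy - r) ** 2) / (2 * psf_sigma_px**2))
            stack[f] += amp * np.outer(gy, gx)
    stack += phot.background
    noisy = rng.poisson(stack) if (phot.mean_photons > 0 or phot.background > 0) \
        else stack
    return np.clip(noisy, 0, np.iinfo(np.uint16).max).astype(np.uint16)


def simulate_frap_curve(
    halftime: float,
    bleach_depth: float = 0.5,
    plateau: float = 90.0,
    noise_sd: float = 0.0,
    sampling: float = 5.0,
    duration: float = 600.0,
    seed: int = 0,
    n_prebleach: int = 5,
):
    """Synthetic FRAP trace: exponential recovery toward a plateau.

    Pre-bleach intensity is 100% (``n_prebleach`` samples at negative
    times); immediately after the bleach the intensity is
    ``I0 = 100 * (1 - bleach_depth)`` and recovers as
    ``I(t) = plateau - (plateau - I0) * exp(-t * ln2 / halftime)``, with
    i.i.d. Gaussian noise of ``noise_sd`` (percent points) throughout.
    Returns a :class:`nucleotrack.frap.FrapCurve`.
    """
    from .frap import FrapCurve  # local import avoids a cycle at module load

    _check_positive("halftime", halftime)
    if not 0.0 <= bleach_depth <= 1.0:
        raise ValueError(f"bleach_depth must be in [0, 1], got {bleach_depth}")
    rng = np.random.default_rng(seed)
    t_pre = -sampling * np.arange(n_prebleach, 0, -1)
    t_post = np.arange(0.0, duration + 0.5 * sampling, sampling)
    i0 = 100.0 * (1.0 - bleach_depth)
    if bleach_depth == 0.0:
        post = np.full_like(t_post, 100.0)
    else:
        post = plateau - (plateau - i0) * np.exp(-t_post * math.log(2.0) / halftime)
    t = np.concatenate([t_pre, t_post])
    intensity = np.concatenate([np.full(n_prebleach, 100.0), post])
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.size)
    return FrapCurve(t=t, intensity=intensity,
                     meta={"seed": seed, "halftime_truth": halftime})


def simulate_dwell_times(
    tau1: float,
    tau2: float,
    f1: float,
    frame_interval: float,
    n_events: int,
    seed: int,
    min_positions: int = 3,
):
    """Draw confinement dwell durations from a two-exponential mixture.

    Continuous dwell times are sampled from
    ``f1 * Exp(tau1) + (1 - f1) * Exp(tau2)``, discretized to the frame
    grid (a dwell spanning ``k`` whole frame intervals is observed with
    duration ``k * frame_interval``), and kept only if it covers at least
    ``min_positions`` localizations, i.e. ``min_positions - 1`` intervals —
    the same minimum-event rule the confinement detector applies. Exactly
    ``n_events`` retained events are returned as
    :class:`nucleotrack.dwell_time.DwellEvent` objects.
    """
    from .dwell_time import DwellEvent

    _check_positive("tau1", tau1)
    _check_positive("tau2", tau2)
    if not 0.0 <= f1 <= 1.0:
        raise ValueError(f"f1 must be in [0, 1], got {f1}")
    rng = np.random.default_rng(seed)
    min_intervals = min_positions - 1
    durations: list[np.ndarray] = []
    total = 0
    while total < n_events:
        m = max(2 * n_events, 100)
        comp = rng.random(m) < f1
        t = np.where(comp, rng.exponential(tau1, m), rng.exponential(tau2, m))
        k = np.floor(t / frame_interval).astype(int)
        k = k[k >= min_intervals]
        durations.append(k * frame_interval)
        total += len(k)
    d = np.concatenate(durations)[:n_events]
    return [
        DwellEvent(track_id=i, start_frame=0, duration=float(di), censored=False)
        for i, di in enumerate(d)
    ]


def simulate_foci_cells(
    n_cells: int,
    length_range: tuple[float, float] = (2.0, 4.0),
    placement: tuple[float, float, float] = (0.2, 0.2, 0.15),
    offset_sd: float = 0.12,
    seed: int = 0,
    radius: float = 0.45,
    foci_per_cell: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells with paired two-channel foci and a controlled length trend.

    Each cell lies along x with ``pole1 = (0, 0)`` and ``pole2 =
    (length, 0)``. Channel-A foci are placed at a pole distance drawn from
    the linear model ``intercept + slope * length + N(0, noise_sd)``
    (clamped to ``[0, length / 2]``), alternating between the two poles;
    channel-B foci sit at the channel-A position plus an isotropic 2D
    Gaussian offset of per-coordinate standard deviation ``offset_sd``, so
    A-to-B distances are Rayleigh(``offset_sd``) distributed.

    Returns ``(cells, foci)`` tables in the foci-geometry CSV schema.
    """
    lo, hi = length_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi or lo <= 2 * radius:
        raise ValueError(f"degenerate length_range {length_range}")
    intercept, slope, noise_sd = placement
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(lo, hi, n_cells)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "pole1_x": 0.0,
            "pole1_y": 0.0,
            "pole2_x": lengths,
            "pole2_y": 0.0,
            "length_um": lengths,
        }
    )
    rows = []
    for cid, L in zip(cells["cell_id"], lengths):
        for j in range(foci_per_cell):
            d = intercept + slope * L + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            d = float(np.clip(d, 0.0, L / 2.0))
            x = d if j % 2 == 0 else L - d
            rows.append((cid, "A", x, 0.0))
            off = rng.normal(0.0, offset_sd, 2) if offset_sd > 0 else np.zeros(2)
            rows.append((cid, "B", x + off[0], off[1]))
    foci = pd.DataFrame(rows, columns=["cell_id", "channel", "x_um", "y_um"])
    foci["intensity"] = 1.0
    return cells, foci
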