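"""FRAP analysis: normalization, single-exponential recovery fits, group tests.

After photobleaching a cluster of fluorescent molecules, exchange with
the unbleached pool recovers the signal as

    I(t) = plateau - (plateau - I0) * exp(-k t),

where I0 is the post-bleach intensity, the plateau reflects the mobile
fraction, and the recovery rate k gives the residence half-time
t_half = ln2 / k of the bound population. Intensities are expressed as a
percentage of the pre-bleach mean, time is zero at the first post-bleach
sample. Groups of per-cell half-times are compared with a two-sample
t-test (Welch by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FrapCurve",
    "FrapFit",
    "HalftimeComparison",
    "normalize_frap",
    "fit_frap",
    "fit_frap_ensemble",
    "compare_halftimes",
]


@dataclass
class FrapCurve:
    """Normalized recovery trace: t = 0 at the first post-bleach sample.

    Pre-bleach samples are retained at negative times; intensity is in
    percent of the pre-bleach mean.
    """

    t: np.ndarray
    intensity: np.ndarray
    cell_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must have the same shape")
        if (np.diff(self.t) <= 0).any():
            raise ValueError("t must be strictly increasing")

    @property
    def post(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.t >= 0
        return self.t[m], self.intensity[m]

    @property
    def pre(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.t < 0
        return self.t[m], self.intensity[m]


def normalize_frap(
    raw_intensity: np.ndarray,
    times: np.ndarray,
    bleach_index: int,
    cell_id: str = "",
    min_prebleach: int = 3,
    min_postbleach: int = 5,
    bleach_depth_warn: float = 0.10,
) -> FrapCurve:
    """Normalize a raw intensity series to percent of its pre-bleach mean.

    ``bleach_index`` is the index of the first post-bleach sample; the
    time axis is shifted so that sample sits at t = 0. A bleach depth
    below ``bleach_depth_warn`` (fraction of pre-bleach signal) triggers
    a poor-bleach warning.
    """
    raw = np.asarray(raw_intensity, dtype=float)
    times = np.asarray(times, dtype=float)
    if bleach_index < min_prebleach:
        raise ValueError(f"need >= {min_prebleach} pre-bleach samples")
    if len(raw) - bleach_index < min_postbleach:
        raise ValueError(f"need >= {min_postbleach} post-bleach samples")
    pre_mean = raw[:bleach_index].mean()
    if pre_mean <= 0:
        raise ValueError("non-positive pre-bleach mean")
    intensity = 100.0 * raw / pre_mean
    depth = 1.0 - raw[bleach_index] / pre_mean
    if depth < bleach_depth_warn:
        warnings.warn(
            f"bleach depth {100 * depth:.1f}% is below "
            f"{100 * bleach_depth_warn:.0f}%: poor bleach", stacklevel=2,
        )
    t = times - times[bleach_index]
    return FrapCurve(t=t, intensity=intensity, cell_id=cell_id,
                     meta={"bleach_depth": float(depth)})


@dataclass
class FrapFit:
    """Single-exponential recovery fit of one cell's FRAP curve."""

    k: float
    I0: float
    plateau: float
    stderr: dict
    cell_id: str = ""
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def halftime(self) -> float:
        return math.log(2.0) / self.k

    @property
    def halftime_stderr(self) -> float | None:
        se_k = self.stderr.get("k")
        return math.log(2.0) / self.k**2 * se_k if se_k else None

    def model(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.plateau - (self.plateau - self.I0) * np.exp(-self.k * t)

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "k_per_s": self.k,
            "halftime_s": self.halftime,
            "I0_pct": self.I0,
            "plateau_pct": self.plateau,
            "stderr": dict(self.stderr),
            "converged": self.converged,
            "flags": list(self.flags),
        }


def fit_frap(curve: FrapCurve, min_postbleach: int = 5) -> FrapFit:
    """Nonlinear least-squares fit of the exponential recovery model.

    Fails with a flagged, non-converged result (no half-time asserted)
    when the curve shows no recovery, e.g. a flat post-bleach signal.
    """
    from lmfit import Model

    t, I = curve.post
    if len(t) < min_postbleach:
        raise ValueError(f"need >= {min_postbleach} post-bleach samples")

    def model(t, k, I0, plateau):
        return plateau - (plateau - I0) * np.exp(-k * t)

    i0_guess = float(I[0])
    plat_guess = float(max(I[-5:].mean(), i0_guess + 1.0))
    span = t[-1] - t[0] or 1.0
    m = Model(model)
    params = m.make_params(
        k=dict(value=2.0 / span, min=1e-8),
        I0=dict(value=i0_guess),
        plateau=dict(value=plat_guess),
    )
    result = m.fit(I, params, t=t)
    p = result.params
    flags: list[str] = []
    converged = bool(result.success)
    recovery = p["plateau"].value - p["I0"].value
    noise = float(np.std(I - result.best_fit)) if len(I) > 3 else 0.0
    if recovery <= max(2.0 * noise, 1e-6):
        flags.append("no detectable recovery; half-time not meaningful")
        converged = False
    if p["k"].value <= 2e-8:
        flags.append("rate pinned at lower bound")
        converged = False
    stderr = {
        name: (float(p[name].stderr) if p[name].stderr is not None else None)
        for name in ("k", "I0", "plateau")
    }
    return FrapFit(
        k=float(p["k"].value),
        I0=float(p["I0"].value),
        plateau=float(p["plateau"].value),
        stderr=stderr,
        cell_id=curve.cell_id,
        converged=converged,
        flags=flags,
    )


def fit_frap_ensemble(curves: list[FrapCurve]) -> list[FrapFit]:
    """Per-cell fits; non-converged cells are kept but flagged."""
    return [fit_frap(c) for c in curves]


@dataclass
class HalftimeComparison:
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p_value: float
    test: str

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def compare_halftimes(
    group_a: list[FrapFit], group_b: list[FrapFit], test: str = "welch"
) -> HalftimeComparison:
    """Two-sample t-test on per-cell recovery half-times.

    ``test="welch"`` (unequal variances, default) or ``"student"``
    (pooled variance). Requires >= 3 converged fits per group.
    """
    ha = np.array([f.halftime for f in group_a if f.converged])
    hb = np.array([f.halftime for f in group_b if f.converged])
    if len(ha) < 3 or len(hb) < 3:
        raise ValueError("need >= 3 converged fits per group")
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    res = stats.ttest_ind(ha, hb, equal_var=(test == "student"))
    return HalftimeComparison(
        mean_a=float(ha.mean()),
        mean_b=float(hb.mean()),
        se_a=float(ha.std(ddof=1) / math.sqrt(len(ha))),
        se_b=float(hb.std(ddof=1) / math.sqrt(len(hb))),
        n_a=len(ha),
        n_b=len(hb),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        test=test,
    )


def plot_halftime_boxes(groups: dict[str, list[FrapFit]], ax=None):
    """Box plot of per-cell half-times per group."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * len(groups) + 1, 4))
    labels = list(groups)
    data = [[f.halftime for f in fits if f.converged] for fits in groups.values()]
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("recovery half-time (s)")
    return ax
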