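"""Jump-distance analysis: Rayleigh mixture fits of step-length distributions.

For a molecule diffusing freely in 2D with coefficient D, the Euclidean
displacement r between frames dt apart is Rayleigh distributed,

    p(r) = r / (2 D dt) * exp(-r^2 / (4 D dt)),

and a sample of molecules drawn from several diffusive populations follows
a mixture of such densities with weights f_i. Fitting that mixture to the
pooled single-lag step lengths of a tracked dataset yields the apparent
diffusion coefficient and occupancy of each population — the standard
jump-distance decomposition of single-molecule tracking data.

Two estimators are provided: maximum likelihood on the raw step lengths
via expectation-maximization (the default; for one component the MLE has
the closed form ``sum(r^2) / (4 n dt)``), and least squares on the binned
empirical density, which mirrors how such fits are usually displayed.
Components can be frozen at a fixed D (e.g. a slow/static component pinned
at the localization-precision floor of 0.02 um^2/s), in which case only
their weight is optimized. Model choice between one and two components
uses the Bayesian information criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trajectories import TrajectorySet

__all__ = [
    "JumpDistanceSample",
    "RayleighComponent",
    "RayleighMixtureFit",
    "ModelSelection",
    "compute_jump_distances",
    "rayleigh_mixture_pdf",
    "fit_rayleigh_mixture",
    "select_model",
    "summarize_fractions",
]

#: Numerical floor on fitted D (um^2/s); avoids the Dirac limit at D = 0.
D_FLOOR = 1e-4


@dataclass
class JumpDistanceSample:
    """Pooled single-lag step lengths of one dataset."""

    r: np.ndarray
    frame_interval: float
    source: str = ""
    #: Track id of each step, for track-level bootstrap resampling.
    track_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if (self.r < 0).any():
            raise ValueError("step lengths must be non-negative")

    @property
    def n_steps(self) -> int:
        return len(self.r)


@dataclass(frozen=True)
class RayleighComponent:
    D: float
    f: float
    fixed_D: bool = False

    def __post_init__(self) -> None:
        if self.D < 0 or not 0.0 <= self.f <= 1.0 + 1e-9:
            raise ValueError(f"invalid component D={self.D}, f={self.f}")


@dataclass
class RayleighMixtureFit:
    """Result of a one- or two-component Rayleigh mixture fit.

    Components are ordered by descending D: ``components[0]`` is the
    mobile population, ``components[-1]`` the slow/static one.
    """

    components: tuple[RayleighComponent, ...]
    log_likelihood: float
    r_squared: float
    n_steps: int
    frame_interval: float
    method: str = "mle"
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    stderr: dict | None = None
    source: str = ""

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_free_parameters(self) -> int:
        k = sum(0 if c.fixed_D else 1 for c in self.components)
        return k + (self.n_components - 1)  # weights carry k-1 dof

    @property
    def bic(self) -> float:
        return self.n_free_parameters * math.log(self.n_steps) - 2.0 * self.log_likelihood

    @property
    def D_mobile(self) -> float:
        return self.components[0].D

    @property
    def D_slow(self) -> float:
        return self.components[-1].D

    @property
    def f_mobile(self) -> float:
        return self.components[0].f

    @property
    def f_slow(self) -> float:
        return self.components[-1].f

    def as_dict(self) -> dict:
        return {
            "components": [
                {"D": c.D, "f": c.f, "fixed_D": c.fixed_D} for c in self.components
            ],
            "log_likelihood": self.log_likelihood,
            "r_squared": self.r_squared,
            "bic": self.bic,
            "n_steps": self.n_steps,
            "frame_interval": self.frame_interval,
            "method": self.method,
            "converged": self.converged,
            "flags": list(self.flags),
            "stderr": self.stderr,
            "source": self.source,
        }


def compute_jump_distances(trajset: TrajectorySet, lag: int = 1) -> JumpDistanceSample:
    """Euclidean displacements between detections ``lag`` frames apart.

    Steps are taken within tracks only, between frames exactly ``lag``
    apart (gaps bridged by the linker therefore contribute no step at the
    base lag). The sample's time base is ``lag * frame_interval``.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    df = trajset.data
    r_parts: list[np.ndarray] = []
    id_parts: list[np.ndarray] = []
    for tid, g in df.groupby("track_id", sort=True):
        frames = g["frame"].to_numpy()
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        if len(frames) <= lag:
            continue
        dfr = frames[lag:] - frames[:-lag]
        ok = dfr == lag
        if ok.any():
            d = np.hypot(x[lag:] - x[:-lag], y[lag:] - y[:-lag])[ok]
            r_parts.append(d)
            id_parts.append(np.full(d.size, tid))
    r = np.concatenate(r_parts) if r_parts else np.empty(0)
    ids = np.concatenate(id_parts) if id_parts else np.empty(0, dtype=int)
    return JumpDistanceSample(
        r=r,
        frame_interval=lag * trajset.frame_interval,
        source=str(trajset.meta.get("source", "")),
        track_ids=ids,
    )


def rayleigh_mixture_pdf(r, components, frame_interval: float) -> np.ndarray:
    """Mixture density ``sum_i f_i * r/(2 D_i dt) * exp(-r^2/(4 D_i dt))``.

    ``components`` is an iterable of :class:`RayleighComponent` or
    ``(D, f)`` pairs. A component with D = 0 is a point mass at r = 0 and
    has no proper density; D is floored at ``D_FLOOR``.
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("r must be non-negative")
    out = np.zeros_like(r)
    for c in components:
        D, f = (c.D, c.f) if isinstance(c, RayleighComponent) else (c[0], c[1])
        s = 2.0 * max(D, D_FLOOR) * frame_interval  # Rayleigh scale^2
        out += f * (r / s) * np.exp(-(r**2) / (2.0 * s))
    return out


def _em_fit(r2, frame_interval, D_init, fixed_mask, max_iter, tol):
    """EM for a Rayleigh mixture on squared step lengths; returns (D, f, ll, ok)."""
    n = len(r2)
    k = len(D_init)
    s = np.maximum(2.0 * np.asarray(D_init, float) * frame_interval,
                   2.0 * D_FLOOR * frame_interval)
    f = np.full(k, 1.0 / k)
    ll_old = -np.inf
    converged = False
    # log-density up to the common factor log(r), which cancels in responsibilities
    for _ in range(max_iter):
        logc = np.log(f)[:, None] - np.log(s)[:, None] - r2[None, :] / (2.0 * s[:, None])
        m = logc.max(axis=0)
        w = np.exp(logc - m)
        tot = w.sum(axis=0)
        gamma = w / tot
        ll = float((m + np.log(tot)).sum())
        f = gamma.mean(axis=1)
        for i in range(k):
            if not fixed_mask[i]:
                denom = gamma[i].sum()
                if denom > 0:
                    s[i] = max((gamma[i] * r2).sum() / (2.0 * denom),
                               2.0 * D_FLOOR * frame_interval)
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    # final log-likelihood including the log(r) factor (r > 0 assumed; zeros floored)
    return s / (2.0 * frame_interval), f, ll, converged


def _full_loglik(r, components, frame_interval):
    p = rayleigh_mixture_pdf(r, components, frame_interval)
    return float(np.log(np.maximum(p, 1e-300)).sum())


def _binned_density(r, bins):
    edges = np.histogram_bin_edges(r, bins=bins)
    dens, edges = np.histogram(r, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def _r_squared(r, components, frame_interval, bins) -> float:
    centers, dens = _binned_density(r, bins)
    model = rayleigh_mixture_pdf(centers, components, frame_interval)
    ss_res = float(((dens - model) ** 2).sum())
    ss_tot = float(((dens - dens.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def _binned_ls_fit(r, frame_interval, D_init, fixed_mask, bins):
    """Least squares on the binned empirical density (display-style fit)."""
    from lmfit import Parameters, minimize

    centers, dens = _binned_density(r, bins)
    k = len(D_init)
    params = Parameters()
    for i, (D0, fx) in enumerate(zip(D_init, fixed_mask)):
        params.add(f"D{i}", value=max(D0, D_FLOOR), min=D_FLOOR, vary=not fx)
    if k == 2:
        params.add("f0", value=0.5, min=0.0, max=1.0)

    def resid(p):
        comps = [(p[f"D{i}"].value, p["f0"].value if (k == 2 and i == 0)
                  else (1.0 - p["f0"].value if k == 2 else 1.0)) for i in range(k)]
        return rayleigh_mixture_pdf(centers, comps, frame_interval) - dens

    res = minimize(resid, params)
    p = res.params
    D = np.array([p[f"D{i}"].value for i in range(k)])
    f = np.array([p["f0"].value, 1.0 - p["f0"].value]) if k == 2 else np.array([1.0])
    return D, f, res.success


def fit_rayleigh_mixture(
    sample: JumpDistanceSample,
    n_components: int = 2,
    fixed_D: dict[str, float] | None = None,
    method: str = "mle",
    n_bootstrap: int = 100,
    bins: int | str = 50,
    max_iter: int = 2000,
    tol: float = 1e-10,
    min_steps_two_component: int = 500,
    seed: int = 0,
) -> RayleighMixtureFit:
    """Fit a one- or two-component Rayleigh mixture to pooled step lengths.

    Parameters
    ----------
    sample
        Pooled single-lag steps from :func:`compute_jump_distances`.
    n_components
        1 or 2 diffusive populations.
    fixed_D
        Optional constraints, e.g. ``{"slow": 0.02}`` to pin the slow
        component at the localization-precision floor (its weight is still
        optimized). Keys: ``"mobile"``, ``"slow"``.
    method
        ``"mle"`` (EM on raw steps, default) or ``"binned"`` (least squares
        on the binned empirical density).
    n_bootstrap
        Track-level bootstrap resamples for standard errors; 0 disables.

    The reported R^2 is always computed against the binned empirical
    density, regardless of estimator. Fractions sum to 1 by construction.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    r = sample.r
    dt = sample.frame_interval
    flags: list[str] = []
    if n_components == 2 and sample.n_steps < min_steps_two_component:
        flags.append(f"fewer than {min_steps_two_component} steps for a 2-component fit")
        warnings.warn(flags[-1], stacklevel=2)
    if sample.n_steps == 0:
        raise ValueError("empty jump-distance sample")

    fixed_D = fixed_D or {}
    r2_mean = float((r**2).mean())
    D_closed = max(r2_mean / (4.0 * dt), D_FLOOR)  # one-component closed-form MLE
    if n_components == 1:
        D_init = [fixed_D.get("mobile", D_closed)]
        fixed_mask = ["mobile" in fixed_D]
    else:
        D_init = [fixed_D.get("mobile", 2.0 * D_closed), fixed_D.get("slow", D_closed / 5.0)]
        fixed_mask = ["mobile" in fixed_D, "slow" in fixed_D]

    if method == "mle":
        if np.all(r == 0):
            D = np.full(n_components, D_FLOOR)
            f = np.array([1.0] if n_components == 1 else [0.5, 0.5])
            converged = True
            flags.append("all step lengths are zero; D at numerical floor")
        else:
            r2 = r**2
            D, f, _, converged = _em_fit(r2, dt, D_init, fixed_mask, max_iter, tol)
    elif method == "binned":
        D, f, converged = _binned_ls_fit(r, dt, D_init, fixed_mask, bins)
    else:
        raise ValueError(f"unknown method {method!r}")

    comps = [
        RayleighComponent(D=float(Di), f=float(fi), fixed_D=bool(fx))
        for Di, fi, fx in zip(D, f, fixed_mask)
    ]
    comps.sort(key=lambda c: c.D, reverse=True)
    components = tuple(comps)

    if not converged:
        flags.append("estimator did not converge")
    for c in components:
        if n_components == 2 and (c.f <= 1e-6 or c.f >= 1 - 1e-6):
            flags.append("a mixture fraction is pinned at its bound")
            break

    ll = _full_loglik(r[r > 0] if (r == 0).any() else r, components, dt)
    fit = RayleighMixtureFit(
        components=components,
        log_likelihood=ll,
        r_squared=_r_squared(r, components, dt, bins) if r.max() > 0 else float("nan"),
        n_steps=sample.n_steps,
        frame_interval=dt,
        method=method,
        converged=converged,
        flags=flags,
        source=sample.source,
    )

    if n_bootstrap > 0 and sample.track_ids is not None and len(sample.track_ids):
        fit.stderr = _bootstrap_stderr(
            sample, fit, n_components, fixed_D, method, bins, max_iter, tol,
            n_bootstrap, seed,
        )
    return fit


def _bootstrap_stderr(sample, fit, n_components, fixed_D, method, bins,
                      max_iter, tol, n_bootstrap, seed) -> dict:
    """Bootstrap over tracks (not steps), respecting within-track correlation."""
    rng = np.random.default_rng(seed)
    unique_ids = np.unique(sample.track_ids)
    order = np.argsort(sample.track_ids, kind="stable")
    r_sorted = sample.r[order]
    ids_sorted = sample.track_ids[order]
    bounds = np.searchsorted(ids_sorted, unique_ids)
    bounds = np.append(bounds, len(ids_sorted))
    groups = [r_sorted[bounds[i]:bounds[i + 1]] for i in range(len(unique_ids))]
    est = []
    for _ in range(n_bootstrap):
        pick = rng.integers(0, len(groups), len(groups))
        rb = np.concatenate([groups[i] for i in pick])
        boot = JumpDistanceSample(rb, sample.frame_interval)
        try:
            bfit = fit_rayleigh_mixture(
                boot, n_components=n_components, fixed_D=fixed_D, method=method,
                bins=bins, max_iter=max_iter, tol=tol, n_bootstrap=0,
                min_steps_two_component=0,
            )
        except ValueError:
            continue
        est.append([v for c in bfit.components for v in (c.D, c.f)])
    if not est:
        return {}
    arr = np.asarray(est)
    out = {}
    for i in range(len(fit.components)):
        out[f"D{i + 1}"] = float(arr[:, 2 * i].std(ddof=1))
        out[f"f{i + 1}"] = float(arr[:, 2 * i + 1].std(ddof=1))
    out["n_resamples"] = len(est)
    return out


@dataclass
class ModelSelection:
    chosen: RayleighMixtureFit
    fit1: RayleighMixtureFit
    fit2: RayleighMixtureFit
    delta_bic: float
    reason: str

    @property
    def n_components(self) -> int:
        return self.chosen.n_components


def select_model(
    fit1: RayleighMixtureFit,
    fit2: RayleighMixtureFit,
    min_delta_bic: float = 10.0,
    min_fraction: float = 0.05,
) -> ModelSelection:
    """Choose between one- and two-component fits of the same sample by BIC.

    The two-component model is preferred only when it improves the BIC by
    more than ``min_delta_bic`` *and* both of its fractions are at least
    ``min_fraction`` — a second population carrying almost no weight is
    not evidence of a second state.
    """
    if fit1.n_steps != fit2.n_steps or fit1.frame_interval != fit2.frame_interval:
        raise ValueError("model selection requires fits of the same sample")
    delta = fit1.bic - fit2.bic  # > 0 favours the 2-component model
    fractions_ok = all(c.f >= min_fraction for c in fit2.components)
    if delta > min_delta_bic and fractions_ok:
        return ModelSelection(fit2, fit1, fit2, delta,
                              f"2 components: delta BIC {delta:.1f} > {min_delta_bic} "
                              "and both fractions above threshold")
    reason = (f"1 component: delta BIC {delta:.1f} <= {min_delta_bic}"
              if delta <= min_delta_bic
              else "1 component: a 2-component fraction fell below threshold")
    return ModelSelection(fit1, fit1, fit2, delta, reason)


def summarize_fractions(fits: dict[str, RayleighMixtureFit]) -> pd.DataFrame:
    """Long-form summary of labelled fits (one row per mixture component).

    Columns: dataset, component (D1 = mobile, D2 = slow/static), D, SE(D)
    when available, fraction in percent, and the number of steps fitted —
    the layout of a diffusion-coefficient summary table, and the data
    behind a bubble plot of D versus dataset with bubble area
    proportional to the population fraction.
    """
    rows = []
    for label, fit in fits.items():
        k = fit.n_components
        for i, c in enumerate(fit.components):
            name = "D1" if (k == 2 and i == 0) else "D2"
            se = (fit.stderr or {}).get(f"D{i + 1}")
            rows.append(
                {
                    "dataset": label,
                    "component": name if k == 2 else "D2",
                    "D_um2_s": c.D,
                    "D_stderr": se,
                    "fraction_pct": 100.0 * c.f,
                    "n_steps": fit.n_steps,
                }
            )
    return pd.DataFrame(
        rows, columns=["dataset", "component", "D_um2_s", "D_stderr",
                       "fraction_pct", "n_steps"]
    )


def plot_bubble(summary: pd.DataFrame, ax=None):
    """Bubble plot of diffusion coefficients; area encodes the fraction."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 0.9 * summary["dataset"].nunique(), 4))
    datasets = list(dict.fromkeys(summary["dataset"]))
    xpos = {d: i for i, d in enumerate(datasets)}
    for _, row in summary.iterrows():
        x = xpos[row["dataset"]]
        ax.scatter(x, row["D_um2_s"], s=12.0 * row["fraction_pct"],
                   alpha=0.6, edgecolor="k")
        ax.annotate(f"{row['fraction_pct']:.0f}%", (x, row["D_um2_s"]),
                    textcoords="offset points", xytext=(8, 0), fontsize=8)
    ax.set_xticks(range(len(datasets)), datasets, rotation=45, ha="right")
    ax.set_ylabel(r"D ($\mu m^2\,s^{-1}$)")
    ax.set_yscale("log")
    return ax
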