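"""Confinement-episode detection and dwell-time survival analysis.

A molecule transiently bound to DNA stays, up to localization error,
within a small circle; its trajectory therefore contains runs of
consecutive positions confined within a fixed radius (default one camera
pixel, 0.106 um). The durations of such runs — dwell times — follow an
exponential distribution for a single unbinding rate, or a mixture of
exponentials when several bound species coexist. This module extracts
those episodes, builds their survival function S(t) = 1 - ECDF(t), and
fits one- and two-component exponential survival models by maximum
likelihood.

Event semantics (locked by a brute-force oracle in the test suite): an
episode is a maximal run of consecutive positions all within ``radius``
of the run's *first* position; runs of at least 3 positions (2 frame
intervals) count, shorter ones are indistinguishable from a single slow
step. Scanning is greedy left-to-right, resuming after each emitted
event. An episode that reaches the end of its track is marked censored;
censored episodes are included as observed durations by default, which
(together with photobleaching) biases dwell times downward — the
competing-exponentials correction :func:`bleach_corrected_tau` quantifies
the bleaching part.

Durations measured on a frame grid are multiples of the frame interval;
when the interval is supplied, the fit uses an interval-censored
(grid-aware) likelihood that removes the ~dt/2 discretization bias of a
continuous-density likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .trajectories import TrajectorySet

__all__ = [
    "DwellEvent",
    "SurvivalCurve",
    "SurvivalFit",
    "detect_confinement_events",
    "survival_function",
    "fit_survival",
    "select_survival_model",
    "bleach_corrected_tau",
]

MIN_EVENT_POSITIONS = 3


@dataclass(frozen=True)
class DwellEvent:
    """One confinement episode: (run length - 1) * dt seconds from start_frame."""

    track_id: int
    start_frame: int
    duration: float
    censored: bool

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def detect_confinement_events(
    trajset: TrajectorySet, radius: float = 0.106
) -> list[DwellEvent]:
    """Maximal anchored confinement runs of >= 3 positions per track."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    dt = trajset.frame_interval
    events: list[DwellEvent] = []
    for tid, g in trajset.data.groupby("track_id", sort=True):
        xy = g[["x_um", "y_um"]].to_numpy()
        frames = g["frame"].to_numpy()
        n = len(xy)
        i = 0
        while i < n:
            d = np.hypot(xy[i:, 0] - xy[i, 0], xy[i:, 1] - xy[i, 1])
            outside = np.flatnonzero(d > radius)
            j = (i + outside[0] - 1) if outside.size else (n - 1)
            run = j - i + 1
            if run >= MIN_EVENT_POSITIONS:
                events.append(
                    DwellEvent(
                        track_id=int(tid),
                        start_frame=int(frames[i]),
                        duration=float((frames[j] - frames[i]) * dt),
                        censored=bool(j == n - 1),
                    )
                )
                i = j + 1
            else:
                i += 1
    return events


@dataclass
class SurvivalCurve:
    """Right-continuous survival function S(t) = 1 - ECDF on event durations."""

    t: np.ndarray
    S: np.ndarray
    n_events: int

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.t, t, side="right")
        S_ext = np.concatenate([[1.0], self.S])
        return S_ext[idx]


def survival_function(
    events: list[DwellEvent], include_censored: bool = True
) -> SurvivalCurve:
    """Empirical survival function of dwell durations.

    Censored episodes enter as if fully observed by default (their true
    dwell is at least the recorded duration, so S is biased low — the
    same acknowledged bias a bleaching-limited experiment carries).
    """
    durations = np.array(
        [e.duration for e in events if include_censored or not e.censored]
    )
    if durations.size == 0:
        raise ValueError("no events to build a survival function from")
    t = np.sort(np.unique(durations))
    n = durations.size
    S = 1.0 - np.searchsorted(np.sort(durations), t, side="right") / n
    return SurvivalCurve(t=t, S=S, n_events=n)


@dataclass
class SurvivalFit:
    """One- or two-exponential survival fit.

    Ordering convention: ``tau1`` is the short (usually majority)
    component with weight ``f1``; for one component ``f1 = 1``.
    Weights refer to the un-truncated mixture: the likelihood is
    renormalized for the minimum observable duration, so ``f1`` estimates
    the fraction of all binding events, not just the detectable ones.
    """

    n_components: int
    tau1: float
    tau2: float | None
    f1: float
    log_likelihood: float
    n_events: int
    truncation: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def n_free_parameters(self) -> int:
        return 1 if self.n_components == 1 else 3

    @property
    def bic(self) -> float:
        return self.n_free_parameters * math.log(self.n_events) - 2.0 * self.log_likelihood

    def survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.n_components == 1:
            return np.exp(-t / self.tau1)
        return self.f1 * np.exp(-t / self.tau1) + (1.0 - self.f1) * np.exp(-t / self.tau2)

    def as_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "tau1_s": self.tau1,
            "tau2_s": self.tau2,
            "f1": self.f1,
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_events": self.n_events,
            "truncation_s": self.truncation,
            "converged": self.converged,
            "flags": list(self.flags),
        }


def _mixture_nll(durations, taus, weights, t0, frame_interval):
    """Negative log-likelihood, left-truncated at t0.

    With ``frame_interval`` set, durations are taken to lie on the frame
    grid and each observation d contributes P(d <= T < d + dt); otherwise
    the continuous density is used. Both are renormalized by P(T >= t0).
    """
    d = durations[:, None]
    taus = np.asarray(taus)[None, :]
    weights = np.asarray(weights)[None, :]
    if frame_interval is not None:
        p = (np.exp(-d / taus) - np.exp(-(d + frame_interval) / taus)) * weights
    else:
        p = (np.exp(-d / taus) / taus) * weights
    norm = float((np.exp(-t0 / np.asarray(taus)) * np.asarray(weights)).sum())
    ll = np.log(np.maximum(p.sum(axis=1), 1e-300)).sum() - len(durations) * math.log(
        max(norm, 1e-300)
    )
    return -float(ll)


def fit_survival(
    events: list[DwellEvent],
    n_components: int = 2,
    frame_interval: float | None = None,
    truncation: float | None = None,
    include_censored: bool = True,
    min_events_two_component: int = 50,
) -> SurvivalFit:
    """Maximum-likelihood exponential(-mixture) fit of dwell durations.

    ``S(t) = f1 exp(-t/tau1) + (1 - f1) exp(-t/tau2)``, left-truncated at
    the minimum observable duration (2 frame intervals when
    ``frame_interval`` is given, else the shortest duration present;
    override with ``truncation``, 0 disables). With no truncation and one
    component the MLE is the sample mean.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    durations = np.array(
        [e.duration for e in events if include_censored or not e.censored]
    )
    if durations.size == 0:
        raise ValueError("no events to fit")
    flags: list[str] = []
    if n_components == 2 and durations.size < min_events_two_component:
        flags.append(f"fewer than {min_events_two_component} events for a 2-component fit")
        warnings.warn(flags[-1], stacklevel=2)
    if truncation is None:
        truncation = (
            (MIN_EVENT_POSITIONS - 1) * frame_interval
            if frame_interval is not None
            else float(durations.min())
        )
    t0 = float(truncation)
    mean = float(durations.mean())

    if n_components == 1:
        if frame_interval is None and t0 == 0.0:
            tau1 = mean  # closed-form exponential MLE
            nll = _mixture_nll(durations, [tau1], [1.0], t0, None)
            converged = True
        else:
            res = minimize(
                lambda p: _mixture_nll(durations, [math.exp(p[0])], [1.0], t0,
                                       frame_interval),
                x0=[math.log(max(mean - t0, mean / 10))],
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10},
            )
            tau1 = math.exp(res.x[0])
            nll = res.fun
            converged = bool(res.success)
        fit = SurvivalFit(1, tau1, None, 1.0, -nll, durations.size, t0, converged, flags)
    else:
        # parameterize (log tau1, log(tau2 - tau1) offset, logit f1) to keep ordering
        def unpack(p):
            tau1 = math.exp(p[0])
            tau2 = tau1 + math.exp(p[1])
            f1 = 1.0 / (1.0 + math.exp(-p[2]))
            return tau1, tau2, f1

        def nll_fn(p):
            tau1, tau2, f1 = unpack(p)
            return _mixture_nll(durations, [tau1, tau2], [f1, 1.0 - f1], t0,
                                frame_interval)

        base = max(mean - t0, mean / 10)
        x0 = [math.log(base * 0.6), math.log(base * 2.0), math.log(0.8 / 0.2)]
        res = minimize(nll_fn, x0=x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000,
                                "maxfev": 20000})
        tau1, tau2, f1 = unpack(res.x)
        converged = bool(res.success)
        if not converged:
            flags.append("optimizer did not converge")
        if tau2 > 10.0 * durations.max():
            flags.append("tau2 exceeds 10x the longest event; long component "
                         "unidentifiable")
        fit = SurvivalFit(2, tau1, tau2, f1, -res.fun, durations.size, t0,
                          converged, flags)
    return fit


def select_survival_model(
    fit1: SurvivalFit, fit2: SurvivalFit, min_delta_bic: float = 10.0,
    min_fraction: float = 0.05,
) -> SurvivalFit:
    """BIC choice between one- and two-exponential survival fits."""
    delta = fit1.bic - fit2.bic
    fractions_ok = min_fraction <= fit2.f1 <= 1.0 - min_fraction
    return fit2 if (delta > min_delta_bic and fractions_ok) else fit1


@dataclass(frozen=True)
class CorrectedTau:
    tau_corrected: float
    tau_observed: float
    bleach_lifetime: float
    valid: bool
    note: str = ""


def bleach_corrected_tau(tau_obs: float, bleach_lifetime: float) -> CorrectedTau:
    """Correct an observed dwell time for photobleaching.

    Track termination by bleaching competes with true unbinding, so the
    observed rate is the sum of the two: ``1/tau_corrected = 1/tau_obs -
    1/bleach_lifetime``. As tau_obs approaches the bleach lifetime the
    correction blows up — the result carries a validity flag and is NaN
    when tau_obs >= bleach_lifetime (pure bleaching explains the data).
    """
    if bleach_lifetime <= 0 or tau_obs <= 0:
        raise ValueError("tau_obs and bleach_lifetime must be positive")
    if math.isinf(bleach_lifetime):
        return CorrectedTau(tau_obs, tau_obs, bleach_lifetime, True)
    ratio = tau_obs / bleach_lifetime
    if ratio >= 1.0:
        return CorrectedTau(
            float("nan"), tau_obs, bleach_lifetime, False,
            "tau_obs >= bleach_lifetime: correction undefined",
        )
    tau = 1.0 / (1.0 / tau_obs - 1.0 / bleach_lifetime)
    if ratio > 0.5:
        return CorrectedTau(
            tau, tau_obs, bleach_lifetime, False,
            "tau_obs within a factor 2 of the bleach lifetime: corrected value "
            "unreliable",
        )
    return CorrectedTau(tau, tau_obs, bleach_lifetime, True)
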