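"""Named simulation presets for the studied B. subtilis fusion proteins.

Each tracking preset carries the published apparent diffusion
coefficients and population fractions of one fluorescent-protein fusion
(condensin Smc and variants, gyrase GyrA, the HU-family nucleoid protein
HBsu), the frame interval it was imaged at, and whether the slow/static
component's D was constrained during fitting (0.02 um^2/s for the
Smc-family datasets, which is the localization-precision floor).

Because the published coefficients are *apparent* values — measured in
confined cells with localization noise folded in — the presets simulate
them as free Rayleigh-mixture diffusion in an unconfined geometry proxy
with zero localization noise: the published numbers are the ground truth
being recovered, and re-confining them inside a cell would apply the
confinement correction twice. Realistic in-cell simulation (confinement,
noise, movies) is available by passing an explicit geometry and
photophysics to the generators.

The Smc-YFP fractions were published as 66/35 (rounding to 101); the
preset normalizes them to 65/35.
"""

from __future__ import annotations

from dataclasses import dataclass

from .synthetic import (
    AcquisitionConfig,
    CellGeometry,
    MotionModel,
    MotionState,
    Photophysics,
)

__all__ = [
    "TrackingPreset",
    "TRACKING_PRESETS",
    "HBSU_DWELL",
    "FRAP_HALFTIMES",
    "MEAN_TRACK_STEPS",
    "get_preset",
]

#: Average observed track length (steps) at 30-ms frames; fixes the default
#: bleach lifetime of :class:`Photophysics` at 7.9 * 0.030 = 0.237 s.
MEAN_TRACK_STEPS = 7.9


@dataclass(frozen=True)
class TrackingPreset:
    """Ground-truth mixture for one fusion protein dataset."""

    name: str
    frame_interval: float
    #: (D um^2/s, fraction) per component, mobile first.
    components: tuple[tuple[float, float], ...]
    #: D (um^2/s) at which the slow component is constrained during fitting,
    #: or None for a free fit.
    fixed_slow_D: float | None = None

    @property
    def n_components(self) -> int:
        return len(self.components)

    def motion_model(self) -> MotionModel:
        states = tuple(
            MotionState(("mobile", "slow")[i] if self.n_components == 2 else "single", D)
            for i, (D, _) in enumerate(self.components)
        )
        fractions = tuple(f for _, f in self.components)
        return MotionModel(states, fractions)

    def acquisition(self, **overrides) -> AcquisitionConfig:
        kw = dict(frame_interval=self.frame_interval)
        kw.update(overrides)
        return AcquisitionConfig(**kw)

    def recovery_conditions(self) -> tuple[MotionModel, CellGeometry, Photophysics]:
        """Generating conditions for parameter-recovery runs (see module docs)."""
        return (
            self.motion_model(),
            CellGeometry.unconfined_proxy(),
            Photophysics(localization_sigma=0.0),
        )


TRACKING_PRESETS: dict[str, TrackingPreset] = {
    p.name: p
    for p in [
        TrackingPreset("Smc-YFP", 0.030, ((0.38, 0.65), (0.02, 0.35)), fixed_slow_D=0.02),
        TrackingPreset(
            "Smc-YFP+rifampin", 0.030, ((0.57, 0.79), (0.02, 0.21)), fixed_slow_D=0.02
        ),
        TrackingPreset(
            "Smc-YFP+novobiocin", 0.030, ((0.34, 0.49), (0.02, 0.51)), fixed_slow_D=0.02
        ),
        TrackingPreset(
            "Smc-CBP-ScpA-mVenus", 0.030, ((0.14, 0.77), (0.02, 0.23)), fixed_slow_D=0.02
        ),
        TrackingPreset("Heads-mVenus", 0.0074, ((2.43, 0.67), (0.59, 0.33))),
        TrackingPreset("Heads-neck-mVenus", 0.0074, ((2.63, 0.73), (0.50, 0.27))),
        TrackingPreset("GyrA-mVenus", 0.010, ((0.21, 1.0),)),
        TrackingPreset("HBsu-mVenus", 0.010, ((0.719, 0.375), (0.091, 0.625))),
    ]
}

#: Dwell-time mixture for HBsu confinement episodes (30-ms frames):
#: short component ~210 ms carrying 84% of events, long component ~750 ms.
HBSU_DWELL = {
    "tau1": 0.210,
    "tau2": 0.750,
    "f1": 0.84,
    "frame_interval": 0.030,
}

#: FRAP recovery half-times (s) of the condensin fusions.
FRAP_HALFTIMES = {
    "Smc-YFP": 162.0,
    "Smc-CBP-ScpA-mVenus": 288.0,
}


def get_preset(name: str) -> TrackingPreset:
    try:
        return TRACKING_PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(TRACKING_PRESETS))
        raise KeyError(f"unknown preset {name!r}; available presets: {known}") from None
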