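"""Reproducible end-to-end runs: simulate -> (render/track) -> fit -> report.

A run is described by a JSON-able config dict::

    {
      "preset": "Smc-YFP",          # or explicit "model": {...}
      "n_molecules": 2000,
      "seed": 1,
      "stages": ["simulate", "jd", "dwell"],   # optional subset
      "via_movie": false,           # render + detect + link instead of
                                    # using simulated positions directly
      "jd": {"n_components": 2},    # per-stage overrides
      "dwell": {"radius": 0.106},
      "out_dir": "results/run1"     # optional; files written when set
    }

Every report embeds the resolved config, a config hash, the seed and the
package version, so each number is traceable to exactly one invocation.
Stage failures abort with the failing stage named; outputs of completed
stages are retained in the partial report.
"""

from __future__ import annotations

from pathlib import Path

from . import io as nio
from .dwell_time import detect_confinement_events, fit_survival, select_survival_model
from .jump_distance import compute_jump_distances, fit_rayleigh_mixture, select_model
from .presets import get_preset
from .synthetic import AcquisitionConfig, Photophysics, simulate_movie, simulate_trajectories
from .tracking import detect_spots, filter_tracks, link_tracks

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _simulate_stage(config: dict):
    preset = get_preset(config.get("preset", "Smc-YFP"))
    model, geom, phot = preset.recovery_conditions()
    if config.get("via_movie"):
        # realistic conditions: confined cell, localization handled by detection
        from .synthetic import CellGeometry

        geom = CellGeometry.default_cell()
        phot = Photophysics()
    acq = preset.acquisition(**config.get("acquisition", {}))
    n_molecules = int(config.get("n_molecules", 2000))
    seed = int(config.get("seed", 0))
    trajset, truth = simulate_trajectories(model, geom, phot, acq, n_molecules, seed)
    return preset, trajset, truth, acq, phot


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages and return the aggregated report."""
    stages = config.get("stages", ["simulate", "jd", "dwell"])
    out_dir = Path(config["out_dir"]) if config.get("out_dir") else None
    seed = int(config.get("seed", 0))
    report: dict = {"provenance": nio.provenance_block(config, seed), "config": config}

    trajset = None
    preset = None
    try:
        if "simulate" in stages:
            preset, trajset, truth, acq, phot = _simulate_stage(config)
            report["simulate"] = {
                "preset": preset.name,
                "n_molecules": int(config.get("n_molecules", 2000)),
                "n_tracks": trajset.n_tracks,
                "n_steps": trajset.n_steps,
            }
            if config.get("via_movie"):
                stack = simulate_movie(truth, phot, acq, seed + 1)
                det = detect_spots(
                    stack, pixel_size=acq.pixel_size,
                    **config.get("detect", {}),
                )
                trajset = link_tracks(
                    det, frame_interval=acq.frame_interval,
                    **config.get("link", {}),
                )
                report["simulate"]["n_tracks_from_movie"] = trajset.n_tracks
            if out_dir:
                out_dir.mkdir(parents=True, exist_ok=True)
                nio.write_trajectories(trajset, out_dir / "trajectories.csv")
        elif config.get("trajectories"):
            trajset = nio.read_trajectories(
                config["trajectories"], config.get("frame_interval")
            )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("simulate", e) from e

    if trajset is not None and config.get("min_steps"):
        trajset = filter_tracks(trajset, int(config["min_steps"]))
        qc = trajset.meta.get("qc")
        if qc is not None:
            report["qc"] = qc.__dict__

    if "jd" in stages and trajset is not None:
        try:
            jd_cfg = dict(config.get("jd", {}))
            sample = compute_jump_distances(trajset, lag=int(jd_cfg.pop("lag", 1)))
            fixed_D = None
            if preset is not None and preset.fixed_slow_D is not None:
                fixed_D = {"slow": preset.fixed_slow_D}
            if "fixed_slow_D" in jd_cfg:
                v = jd_cfg.pop("fixed_slow_D")
                fixed_D = {"slow": v} if v is not None else None
            n_components = jd_cfg.pop("n_components", "auto")
            n_boot = int(jd_cfg.pop("n_bootstrap", 0))
            if n_components == "auto":
                fit1 = fit_rayleigh_mixture(sample, 1, n_bootstrap=0, **jd_cfg)
                fit2 = fit_rayleigh_mixture(sample, 2, fixed_D=fixed_D,
                                            n_bootstrap=0, **jd_cfg)
                sel = select_model(fit1, fit2)
                fit = sel.chosen
                report["jd_model_selection"] = {
                    "delta_bic": sel.delta_bic, "chosen": sel.n_components,
                    "reason": sel.reason,
                }
            else:
                fit = fit_rayleigh_mixture(
                    sample, int(n_components),
                    fixed_D=fixed_D if int(n_components) == 2 else None,
                    n_bootstrap=n_boot, **jd_cfg,
                )
            report["jd"] = fit.as_dict()
        except Exception as e:
            nio.write_report(report, out_dir / "report.json") if out_dir else None
            raise PipelineError("jd", e) from e

    if "dwell" in stages and trajset is not None:
        try:
            dw_cfg = dict(config.get("dwell", {}))
            radius = float(dw_cfg.pop("radius", 0.106))
            events = detect_confinement_events(trajset, radius=radius)
            report["dwell"] = {"radius_um": radius, "n_events": len(events)}
            n_comp = dw_cfg.pop("n_components", "auto")
            if events:
                if n_comp == "auto":
                    f1 = fit_survival(events, 1,
                                      frame_interval=trajset.frame_interval, **dw_cfg)
                    f2 = fit_survival(events, 2,
                                      frame_interval=trajset.frame_interval,
                                      min_events_two_component=0, **dw_cfg)
                    fit = select_survival_model(f1, f2)
                else:
                    fit = fit_survival(events, int(n_comp),
                                       frame_interval=trajset.frame_interval, **dw_cfg)
                report["dwell"]["fit"] = fit.as_dict()
        except Exception as e:
            nio.write_report(report, out_dir / "report.json") if out_dir else None
            raise PipelineError("dwell", e) from e

    if out_dir:
        nio.write_report(report, out_dir / "report.json")
    return report
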