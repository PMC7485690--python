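"""Generator correctness: closed-form MSD, boundaries, bleaching, equilibrium."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucleotrack.synthetic import (
    AcquisitionConfig,
    CellGeometry,
    MotionModel,
    MotionState,
    Photophysics,
    simulate_foci_cells,
    simulate_frap_curve,
    simulate_movie,
    simulate_trajectories,
)


def _single_step_r2(trajset):
    parts = []
    for _, g in trajset.itertracks():
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        parts.append((x[1:] - x[:-1]) ** 2 + (y[1:] - y[:-1]) ** 2)
    return np.concatenate(parts)


class TestCellGeometry:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CellGeometry(length=0.5, radius=0.45)  # length < 2 radius
        with pytest.raises(ValueError):
            CellGeometry(length=3.0, radius=-0.1)

    def test_uniform_samples_inside(self):
        geom = CellGeometry(3.0, 0.45)
        pts = geom.sample_uniform(5000, np.random.default_rng(0))
        assert geom.contains(pts).all()
        # corners of the bounding box are NOT in the stadium
        assert not geom.contains(np.array([[1.49, 0.449]]))[0]

    def test_reflection_returns_points_inside(self):
        geom = CellGeometry(3.0, 0.45)
        rng = np.random.default_rng(1)
        inside = geom.sample_uniform(2000, rng)
        kicked = inside + rng.normal(0, 0.3, inside.shape)
        assert geom.contains(geom.reflect(kicked)).all()


class TestSimulateTrajectories:
    def test_zero_diffusion_zero_noise_is_constant(self):
        model = MotionModel.single(0.0)
        geom = CellGeometry(3.0, 0.45)
        phot = Photophysics(localization_sigma=0.0)
        acq = AcquisitionConfig(n_frames=200)
        ts, _ = simulate_trajectories(model, geom, phot, acq, 20, seed=0)
        for _, g in ts.itertracks():
            assert g["x_um"].nunique() == 1
            assert g["y_um"].nunique() == 1

    def test_single_step_msd_matches_closed_form(self):
        # mean r^2 over one frame = 4 D dt + 4 sigma^2, within 2% at 1e5 steps
        D, dt, sigma = 0.38, 0.030, 0.02
        model = MotionModel.single(D)
        geom = CellGeometry.unconfined_proxy()
        phot = Photophysics(bleach_lifetime=1e6, localization_sigma=sigma)
        acq = AcquisitionConfig(frame_interval=dt, n_frames=1001)
        ts, _ = simulate_trajectories(model, geom, phot, acq, 100, seed=2)
        r2 = _single_step_r2(ts)
        assert len(r2) >= 1e5
        expected = 4 * D * dt + 4 * sigma**2
        assert r2.mean() == pytest.approx(expected, rel=0.02)

    def test_true_positions_inside_cell(self):
        p = Photophysics()
        geom = CellGeometry(2.5, 0.45)
        acq = AcquisitionConfig()
        model = MotionModel.two_state(0.38, 0.02, 0.65)
        _, truth = simulate_trajectories(model, geom, p, acq, 300, seed=3)
        xy = truth.positions[["x_um", "y_um"]].to_numpy() - np.asarray(truth.cell_center)
        assert geom.contains(xy).all()

    def test_track_length_distribution_is_geometric(self):
        # observed localization count per track: geometric with
        # p = 1 - exp(-dt / bleach_lifetime)
        dt, tau = 0.030, 0.237
        model = MotionModel.single(0.1)
        ts, truth = simulate_trajectories(
            MotionModel.single(0.1), CellGeometry.unconfined_proxy(),
            Photophysics(bleach_lifetime=tau), AcquisitionConfig(frame_interval=dt),
            10_000, seed=4,
        )
        frames_seen = truth.bleach_frame.to_numpy()
        assert (frames_seen < 1500).all()  # nothing censored at the movie end
        p = 1 - math.exp(-dt / tau)
        # chi-square goodness of fit against the geometric pmf (a one-sample
        # KS test is not valid for discrete distributions)
        kmax = 40
        observed = np.bincount(np.minimum(frames_seen, kmax + 1),
                               minlength=kmax + 2)[1:]
        pmf = stats.geom(p).pmf(np.arange(1, kmax + 1))
        expected = len(frames_seen) * np.append(pmf, 1 - pmf.sum())
        chi = stats.chisquare(observed, expected)
        assert chi.pvalue > 0.01
        assert frames_seen.mean() == pytest.approx(1 / p, rel=0.05)

    def test_state_occupancy_matches_equilibrium(self):
        # switching two-state model: long-run frame occupancy ~ equilibrium
        model = MotionModel.two_state(0.38, 0.02, 0.65, residence_mobile=0.3)
        phot = Photophysics(bleach_lifetime=1e9)
        acq = AcquisitionConfig(n_frames=2000)
        _, truth = simulate_trajectories(
            model, CellGeometry(3.0, 0.45), phot, acq, 50, seed=5
        )
        occ = (truth.positions["state"] == "mobile").mean()
        assert len(truth.positions) >= 1e5
        assert abs(occ - 0.65) < 0.02

    def test_same_seed_bit_identical(self):
        args = (
            MotionModel.two_state(0.5, 0.02, 0.7),
            CellGeometry(3.0, 0.45),
            Photophysics(),
            AcquisitionConfig(),
            200,
        )
        a, ta = simulate_trajectories(*args, seed=42)
        b, tb = simulate_trajectories(*args, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ta.positions, tb.positions)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            MotionState("s", D=-0.1)
        with pytest.raises(ValueError):
            Photophysics(bleach_lifetime=0.0)
        with pytest.raises(ValueError):
            MotionModel((MotionState("a", 0.1),), (0.7,))  # fractions don't sum to 1
        with pytest.raises(ValueError):
            # detailed balance violated: f1/tau1 != f2/tau2
            MotionModel(
                (MotionState("a", 0.1, 0.2), MotionState("b", 0.0, 0.2)),
                (0.8, 0.2),
            )


class TestSimulateMovie:
    def test_dark_movie_is_all_zero(self):
        model = MotionModel.single(0.1)
        acq = AcquisitionConfig(n_frames=5, image_shape=(16, 16))
        _, truth = simulate_trajectories(
            model, CellGeometry(1.2, 0.3), Photophysics(mean_photons=0, background=0),
            acq, 3, seed=0,
        )
        stack = simulate_movie(truth, Photophysics(mean_photons=0, background=0),
                               acq, seed=1)
        assert stack.shape == (5, 16, 16)
        assert stack.dtype == np.uint16
        assert (stack == 0).all()

    def test_bright_static_molecule_near_argmax(self):
        model = MotionModel.single(0.0)
        acq = AcquisitionConfig(n_frames=10, image_shape=(24, 24))
        phot = Photophysics(mean_photons=20000, background=1, bleach_lifetime=1e6)
        _, truth = simulate_trajectories(
            model, CellGeometry(1.2, 0.3), phot, acq, 1, seed=6,
        )
        stack = simulate_movie(truth, phot, acq, seed=7)
        x = truth.positions["x_um"].iloc[0] / acq.pixel_size
        y = truth.positions["y_um"].iloc[0] / acq.pixel_size
        for frame in stack:
            r, c = np.unravel_index(frame.argmax(), frame.shape)
            assert abs(r - y) <= 1.0 and abs(c - x) <= 1.0

    def test_pixel_mapping(self):
        # a molecule at x = 10 * 0.106 um sits at pixel column 10
        pos = pd.DataFrame(
            {"molecule": [0], "frame": [0], "x_um": [1.06], "y_um": [0.636],
             "state": ["s"]}
        )
        from nucleotrack.synthetic import GroundTruth

        truth = GroundTruth(pos, pd.Series([1]), (0, 0), CellGeometry(3, 0.45),
                            MotionModel.single(0.0), 0)
        acq = AcquisitionConfig(n_frames=1, image_shape=(16, 16))
        phot = Photophysics(mean_photons=50000, background=0)
        stack = simulate_movie(truth, phot, acq, seed=0)
        r, c = np.unravel_index(stack[0].argmax(), stack[0].shape)
        assert (r, c) == (6, 10)


class TestSimulateFrap:
    def test_halftime_definition_exact(self):
        curve = simulate_frap_curve(162.0, bleach_depth=0.5, plateau=90.0,
                                    noise_sd=0.0, sampling=162.0, duration=648.0)
        t, I = curve.post
        i0 = I[0]
        idx = np.argmin(np.abs(t - 162.0))
        assert t[idx] == 162.0
        assert I[idx] - i0 == pytest.approx((90.0 - i0) / 2, abs=1e-12)

    def test_no_bleach_flat_curve(self):
        curve = simulate_frap_curve(100.0, bleach_depth=0.0, noise_sd=0.0)
        assert np.allclose(curve.intensity, 100.0)

    def test_rejects_nonpositive_halftime(self):
        with pytest.raises(ValueError):
            simulate_frap_curve(0.0)


class TestSimulateFociCells:
    def test_zero_offset_means_coincident_channels(self):
        cells, foci = simulate_foci_cells(50, offset_sd=0.0, seed=0)
        a = foci[foci["channel"] == "A"].reset_index()
        b = foci[foci["channel"] == "B"].reset_index()
        assert np.allclose(a[["x_um", "y_um"]], b[["x_um", "y_um"]])

    def test_degenerate_length_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_foci_cells(10, length_range=(3.0, 3.0))
        with pytest.raises(ValueError):
            simulate_foci_cells(10, length_range=(0.5, 0.8), radius=0.45)
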