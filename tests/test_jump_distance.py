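"""Jump-distance statistics and Rayleigh mixture estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import spearmanr

from nucleotrack.jump_distance import (
    JumpDistanceSample,
    compute_jump_distances,
    fit_rayleigh_mixture,
    rayleigh_mixture_pdf,
    select_model,
    summarize_fractions,
)
from nucleotrack.trajectories import from_arrays


def _mixture_sample(rng, n, dt, components):
    """Direct Rayleigh-mixture draw (independent of the trajectory simulator)."""
    Ds = np.array([c[0] for c in components])
    fs = np.array([c[1] for c in components])
    which = rng.choice(len(Ds), size=n, p=fs)
    sigma = np.sqrt(2 * Ds[which] * dt)
    return np.hypot(rng.normal(0, sigma), rng.normal(0, sigma))


class TestComputeJumpDistances:
    def test_three_four_five(self):
        ts = from_arrays([0, 0], [0, 1], [0.0, 3.0], [0.0, 4.0], 0.03)
        s = compute_jump_distances(ts)
        assert s.r.tolist() == [5.0]
        assert s.frame_interval == 0.03

    def test_lag_scales_time_base(self):
        ts = from_arrays([0] * 5, range(5), np.arange(5.0), np.zeros(5), 0.03)
        s = compute_jump_distances(ts, lag=2)
        assert s.frame_interval == pytest.approx(0.06)
        assert np.allclose(s.r, 2.0)

    def test_gapped_frames_skipped_at_base_lag(self):
        ts = from_arrays([0, 0, 0], [0, 1, 3], [0.0, 1.0, 9.0], [0.0] * 3, 0.03)
        s = compute_jump_distances(ts)
        assert s.r.tolist() == [1.0]  # the frame-1 -> frame-3 gap is not a 1-lag step

    def test_mean_squared_step_closed_form(self, single_state_steps):
        s = compute_jump_distances(single_state_steps)
        assert (s.r**2).mean() == pytest.approx(4 * 0.21 * 0.010, rel=0.02)


class TestRayleighPdf:
    @given(D=st.floats(0.01, 5.0), dt=st.sampled_from([0.0074, 0.010, 0.030]))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_normalization(self, D, dt):
        val, err = quad(lambda r: rayleigh_mixture_pdf(np.array([r]), [(D, 1.0)], dt)[0],
                        0, np.inf)
        assert abs(val - 1.0) < 1e-6

    def test_mode_at_sqrt_2Ddt(self):
        D, dt = 0.38, 0.03
        r_star = np.sqrt(2 * D * dt)
        r = np.linspace(0.0, 0.8, 20001)
        p = rayleigh_mixture_pdf(r, [(D, 1.0)], dt)
        assert r[p.argmax()] == pytest.approx(r_star, abs=1e-3)

    def test_degenerate_mixture_equals_single(self):
        r = np.linspace(0, 1, 200)
        two = rayleigh_mixture_pdf(r, [(0.3, 1.0), (0.05, 0.0)], 0.03)
        one = rayleigh_mixture_pdf(r, [(0.3, 1.0)], 0.03)
        assert np.allclose(two, one)

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_mixture_pdf(np.array([-0.1]), [(0.3, 1.0)], 0.03)


class TestFitRayleighMixture:
    def test_one_component_mle_equals_closed_form(self, single_state_steps):
        s = compute_jump_distances(single_state_steps)
        fit = fit_rayleigh_mixture(s, 1, n_bootstrap=0)
        closed = (s.r**2).sum() / (4 * s.n_steps * s.frame_interval)
        assert fit.components[0].D == pytest.approx(closed, rel=1e-3)
        assert fit.components[0].f == 1.0

    def test_two_component_recovery_from_direct_mixture(self):
        rng = np.random.default_rng(3)
        comps = [(0.719, 0.375), (0.091, 0.625)]
        r = _mixture_sample(rng, 20_000, 0.01, comps)
        fit = fit_rayleigh_mixture(JumpDistanceSample(r, 0.01), 2, n_bootstrap=0)
        assert fit.D_mobile == pytest.approx(0.719, rel=0.05)
        assert fit.D_slow == pytest.approx(0.091, rel=0.05)
        assert fit.f_slow == pytest.approx(0.625, abs=0.02)

    def test_fixed_slow_component_stays_fixed(self, smc_trajectories):
        ts, _, preset = smc_trajectories
        s = compute_jump_distances(ts)
        fit = fit_rayleigh_mixture(s, 2, fixed_D={"slow": 0.02}, n_bootstrap=0)
        assert fit.D_slow == 0.02
        assert fit.components[-1].fixed_D
        assert fit.D_mobile == pytest.approx(0.38, rel=0.10)
        assert fit.f_slow == pytest.approx(0.35, abs=0.05)

    def test_fractions_sum_to_one_exactly(self, smc_trajectories):
        ts, _, _ = smc_trajectories
        fit = fit_rayleigh_mixture(compute_jump_distances(ts), 2,
                                   fixed_D={"slow": 0.02}, n_bootstrap=0)
        assert sum(c.f for c in fit.components) == pytest.approx(1.0, abs=1e-12)

    def test_mle_and_binned_agree_on_well_sampled_data(self):
        rng = np.random.default_rng(5)
        r = _mixture_sample(rng, 30_000, 0.03, [(0.38, 0.65), (0.02, 0.35)])
        s = JumpDistanceSample(r, 0.03)
        mle = fit_rayleigh_mixture(s, 2, fixed_D={"slow": 0.02}, n_bootstrap=0)
        binned = fit_rayleigh_mixture(s, 2, fixed_D={"slow": 0.02}, method="binned",
                                      n_bootstrap=0, bins=60)
        assert binned.D_mobile == pytest.approx(mle.D_mobile, rel=0.05)
        assert binned.f_slow == pytest.approx(mle.f_slow, abs=0.03)

    def test_all_zero_steps_hits_floor(self):
        s = JumpDistanceSample(np.zeros(1000), 0.03)
        fit = fit_rayleigh_mixture(s, 1, n_bootstrap=0)
        assert fit.components[0].D == pytest.approx(1e-4)
        assert fit.components[0].f == 1.0
        assert fit.flags

    def test_fraction_monotonicity(self):
        # estimated slow fraction increases monotonically with the true one
        rng = np.random.default_rng(6)
        truths = [0.15, 0.30, 0.45, 0.60, 0.75]
        ests = []
        for f_slow in truths:
            r = _mixture_sample(rng, 10_000, 0.03,
                                [(0.38, 1 - f_slow), (0.02, f_slow)])
            fit = fit_rayleigh_mixture(JumpDistanceSample(r, 0.03), 2,
                                       fixed_D={"slow": 0.02}, n_bootstrap=0)
            ests.append(fit.f_slow)
        rho, _ = spearmanr(truths, ests)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_bootstrap_stderr_reasonable(self):
        rng = np.random.default_rng(7)
        tracks = 300
        rs, ids = [], []
        for tid in range(tracks):
            n = rng.integers(4, 12)
            rs.append(_mixture_sample(rng, n, 0.03, [(0.38, 0.65), (0.02, 0.35)]))
            ids.append(np.full(n, tid))
        s = JumpDistanceSample(np.concatenate(rs), 0.03,
                               track_ids=np.concatenate(ids))
        fit = fit_rayleigh_mixture(s, 2, fixed_D={"slow": 0.02}, n_bootstrap=50)
        assert fit.stderr is not None
        assert 0 < fit.stderr["D1"] < 0.1
        assert 0 < fit.stderr["f2"] < 0.1

    def test_small_sample_two_component_warns(self):
        rng = np.random.default_rng(8)
        s = JumpDistanceSample(_mixture_sample(rng, 100, 0.03, [(0.3, 1.0)]), 0.03)
        with pytest.warns(UserWarning):
            fit_rayleigh_mixture(s, 2, n_bootstrap=0)


class TestSelectModel:
    def test_single_population_selects_one_component(self):
        rng = np.random.default_rng(9)
        r = _mixture_sample(rng, 8_000, 0.01, [(0.21, 1.0)])
        s = JumpDistanceSample(r, 0.01)
        fit1 = fit_rayleigh_mixture(s, 1, n_bootstrap=0)
        fit2 = fit_rayleigh_mixture(s, 2, n_bootstrap=0)
        assert select_model(fit1, fit2).n_components == 1

    def test_two_populations_select_two_components(self):
        rng = np.random.default_rng(10)
        r = _mixture_sample(rng, 8_000, 0.03, [(0.38, 0.65), (0.02, 0.35)])
        s = JumpDistanceSample(r, 0.03)
        fit1 = fit_rayleigh_mixture(s, 1, n_bootstrap=0)
        fit2 = fit_rayleigh_mixture(s, 2, fixed_D={"slow": 0.02}, n_bootstrap=0)
        assert select_model(fit1, fit2).n_components == 2

    def test_tiny_null_sample_prefers_parsimony(self):
        rng = np.random.default_rng(11)
        r = _mixture_sample(rng, 50, 0.03, [(0.2, 1.0)])
        s = JumpDistanceSample(r, 0.03)
        fit1 = fit_rayleigh_mixture(s, 1, n_bootstrap=0)
        fit2 = fit_rayleigh_mixture(s, 2, n_bootstrap=0, min_steps_two_component=0)
        assert select_model(fit1, fit2).n_components == 1


class TestSummarizeFractions:
    def test_two_component_fit_two_rows(self, smc_trajectories):
        ts, _, _ = smc_trajectories
        fit = fit_rayleigh_mixture(compute_jump_distances(ts), 2,
                                   fixed_D={"slow": 0.02}, n_bootstrap=0)
        table = summarize_fractions({"Smc-YFP": fit})
        assert len(table) == 2
        assert table["fraction_pct"].sum() == pytest.approx(100.0)
        assert list(table["component"]) == ["D1", "D2"]

    def test_empty_input_empty_table(self):
        assert len(summarize_fractions({})) == 0
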