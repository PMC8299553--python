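import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdefit import (
    EmpiricalPDF,
    FitConfig,
    Grid1D,
    SimSpec,
    StationaryPDF,
    TimeSeries,
    build_polynomial_library,
    euler_maruyama,
    finite_time_moments,
    fit,
    fit_no_adjoint,
    kl_divergence,
    moment_cost,
    ssr,
    stationary_pdf_numeric,
    total_cost,
)
from sdefit.fitting import FitFailureError, nearest_power_of_ten
from sdefit.moments import BinnedMoments

from conftest import make_model


def synthetic_binned(model, grid, tau, weight=1.0):
    """Noise-free binned moments generated from the model itself."""
    ftm = finite_time_moments(model, grid, tau)
    n = grid.n_bins
    return BinnedMoments(
        grid=grid,
        tau=tau,
        m1=ftm.m1.copy(),
        m2=ftm.m2.copy(),
        counts=np.full(n, 100),
        weights1=np.full(n, weight),
        weights2=np.full(n, weight),
        valid=np.ones(n, dtype=bool),
    )


@pytest.fixture
def self_consistent(cubic_model):
    # grid resolved enough (cell Peclet < 2) for the numeric stationary solver
    grid = Grid1D.uniform(-1.6, 1.6, 60)
    model = cubic_model.with_domain((-1.6, 1.6))
    binned = synthetic_binned(model, grid, 0.2)
    p = stationary_pdf_numeric(model, grid)
    p_hat = EmpiricalPDF(grid=grid, density=p.density.copy())
    return model, binned, p_hat


class TestKLDivergence:
    def test_identical_is_zero(self):
        g = Grid1D.uniform(-3, 3, 50)
        d = np.exp(-g.centers**2)
        d /= d.sum() * g.h
        p = EmpiricalPDF(g, d)
        q = StationaryPDF(g, d.copy(), "analytic")
        assert kl_divergence(p, q) == pytest.approx(0.0, abs=1e-14)

    def test_shifted_gaussian_closed_form(self):
        # oracle: KL(N(0,1) || N(0.5,1)) = (0.5)^2 / 2 = 0.125
        g = Grid1D.uniform(-6.25, 6.75, 500)
        a = np.exp(-g.centers**2 / 2)
        b = np.exp(-((g.centers - 0.5) ** 2) / 2)
        a /= a.sum() * g.h
        b /= b.sum() * g.h
        val = kl_divergence(EmpiricalPDF(g, a), StationaryPDF(g, b, "analytic"))
        assert val == pytest.approx(0.125, abs=2e-3)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        g = Grid1D.uniform(0, 1, 20)
        a = rng.uniform(0.01, 1, 20)
        b = rng.uniform(0.01, 1, 20)
        a /= a.sum() * g.h
        b /= b.sum() * g.h
        assert kl_divergence(
            EmpiricalPDF(g, a), StationaryPDF(g, b, "analytic")
        ) >= 0

    def test_mismatched_grids_rejected(self):
        g1 = Grid1D.uniform(0, 1, 10)
        g2 = Grid1D.uniform(0, 2, 10)
        d = np.full(10, 1.0)
        with pytest.raises(ValueError):
            kl_divergence(EmpiricalPDF(g1, d), StationaryPDF(g2, d, "analytic"))


class TestMomentCost:
    def test_self_consistent_is_zero(self, self_consistent):
        model, binned, _ = self_consistent
        assert moment_cost(model, binned) == pytest.approx(0.0, abs=1e-16)

    def test_perturbation_increases_cost(self, self_consistent):
        model, binned, _ = self_consistent
        base = moment_cost(model, binned)
        bumped = model.with_coeff_vector(
            model.coeff_vector() + np.array([0.1, 0, 0])
        )
        assert moment_cost(bumped, binned) > base

    def test_infeasible_returns_penalty(self, self_consistent):
        model, binned, _ = self_consistent
        bad = model.with_coeff_vector([1.0, -1.0, -0.5])  # sigma < 0
        assert moment_cost(bad, binned, infeasibility_penalty=123.0) == 123.0


class TestTotalCost:
    def test_eta_zero_reduces_to_moment_term(self, self_consistent):
        model, binned, p_hat = self_consistent
        cb = total_cost(model, binned, p_hat, eta=0.0)
        assert cb.total == cb.moment_term
        assert cb.kl_term == 0.0

    def test_self_consistent_total_zero(self, self_consistent):
        model, binned, p_hat = self_consistent
        cb = total_cost(model, binned, p_hat, eta=1.0)
        assert cb.total == pytest.approx(0.0, abs=1e-10)

    def test_eta_linearity(self, self_consistent):
        model, binned, p_hat = self_consistent
        bumped = model.with_coeff_vector([1.2, -0.9, 0.55])
        c1 = total_cost(bumped, binned, p_hat, eta=1.0)
        c2 = total_cost(bumped, binned, p_hat, eta=2.0)
        assert c2.kl_term == pytest.approx(c1.kl_term)
        assert c2.total - c2.moment_term == pytest.approx(
            2 * (c1.total - c1.moment_term)
        )

    def test_breakdown_identity(self, self_consistent):
        model, binned, p_hat = self_consistent
        cb = total_cost(model, binned, p_hat, eta=3.0)
        assert cb.total == cb.moment_term + cb.eta * cb.kl_term


class TestChooseEta:
    def test_nearest_power_of_ten(self):
        assert nearest_power_of_ten(0.8) == 1.0
        assert nearest_power_of_ten(3e-3) == 1e-3
        assert nearest_power_of_ten(0.0) == 1e-6  # configured floor
        assert nearest_power_of_ten(250.0) == 100.0


class TestFit:
    def test_recovers_cubic_model_from_simulation(self, cubic_model):
        # ground truth from the simulator; fast sampling, small stride
        ts = euler_maruyama(
            cubic_model,
            SimSpec(dt=0.01, n_steps=1_000_000, initial_state=[1.0], seed=11),
        )
        struct = make_model([0.0, 0.0], [0.0])
        res = fit(struct, ts, FitConfig(stride=2, seed=11))
        lam, neg_mu = res.model.drift_coeffs
        sig = res.model.diffusion_coeffs[0]
        assert lam == pytest.approx(1.0, rel=0.02)
        assert -neg_mu == pytest.approx(1.0, rel=0.02)
        assert sig == pytest.approx(0.5, rel=0.02)

    def test_self_consistency_neighborhood(self, self_consistent):
        model, binned, p_hat = self_consistent
        from sdefit.fitting import _optimize

        cfg = FitConfig(seed=0, max_iter=600)
        active = np.ones(3, dtype=bool)
        res = _optimize(
            model, binned, p_hat, 1.0, cfg, active,
            [np.array([0.7, -1.3, 0.4])],
        )
        np.testing.assert_allclose(
            res.model.coeff_vector(), [1.0, -1.0, 0.5], atol=5e-3
        )

    def test_fit_result_cost_matches_reevaluation(self, cubic_model):
        ts = euler_maruyama(
            cubic_model,
            SimSpec(dt=0.01, n_steps=100_000, initial_state=[1.0], seed=5),
        )
        struct = make_model([0.0, 0.0], [0.0])
        cfg = FitConfig(stride=2, seed=5, max_iter=150, eta=1.0)
        res = fit(struct, ts, cfg)
        grid = Grid1D.uniform(*res.model.domain, cfg.n_bins)
        from sdefit import SamplingPlan, empirical_pdf, estimate_moments, subsample

        binned = estimate_moments(ts, grid, SamplingPlan(2))
        p_hat = empirical_pdf(subsample(ts, SamplingPlan(2)), grid)
        cb = total_cost(res.model, binned, p_hat, eta=1.0)
        assert cb.total == pytest.approx(res.cost.total, rel=1e-9)


class TestFitNoAdjoint:
    def test_exact_on_noise_free_small_tau(self, cubic_model):
        grid = Grid1D.uniform(-1.8, 1.8, 40)
        x = grid.centers
        tau = 1e-8  # tau -> 0 limit: m1 = f tau, m2 = 2 a tau
        binned = BinnedMoments(
            grid=grid, tau=tau,
            m1=cubic_model.drift(x, check_domain=False) * tau,
            m2=2 * cubic_model.diffusion_a(x) * tau,
            counts=np.full(40, 100),
            weights1=np.ones(40), weights2=np.ones(40),
            valid=np.ones(40, dtype=bool),
        )
        from sdefit.fitting import _no_adjoint_theta

        theta = _no_adjoint_theta(cubic_model, binned)
        np.testing.assert_allclose(theta, [1.0, -1.0, 0.5], atol=1e-6)

    def test_brownian_drift_near_zero(self):
        model = make_model([0.0, 0.0], [0.6])
        ts = euler_maruyama(
            model, SimSpec(dt=0.01, n_steps=200_000, initial_state=[0.0],
                           seed=13),
        )
        res = fit_no_adjoint(model, ts, FitConfig(stride=1, seed=13))
        assert np.all(np.abs(res.model.drift_coeffs) < 0.05)
        assert res.model.diffusion_coeffs[0] == pytest.approx(0.6, rel=0.05)

    def test_rank_deficient_raises(self, cubic_model):
        grid = Grid1D.uniform(-1.8, 1.8, 40)
        binned = synthetic_binned(
            cubic_model.with_domain((-1.8, 1.8)), grid, 0.1
        )
        binned.valid[:] = False
        binned.valid[3] = True  # one bin cannot pin two drift terms
        from sdefit.fitting import _no_adjoint_theta

        with pytest.raises(FitFailureError):
            _no_adjoint_theta(cubic_model, binned)


@pytest.fixture(scope="module")
def cubic_ts():
    model = make_model([1.0, -1.0], [0.5])
    return euler_maruyama(
        model,
        SimSpec(dt=0.01, n_steps=500_000, initial_state=[1.0], seed=21),
    )


class TestSSR:
    def test_discovers_cubic_structure(self, cubic_ts):
        drift = build_polynomial_library(5, "odd", "drift")
        diff = build_polynomial_library(2, "even", "diffusion")
        cfg = FitConfig(stride=2, seed=21, max_iter=250)
        path = ssr(drift, diff, cubic_ts, cfg)
        assert set(path.levels[path.selected_index].active_terms) == {
            "drift:x", "drift:x^3", "diff:1",
        }
        # removing a true term jumps the cost
        totals = [lv.cost.total for lv in path.levels]
        i = path.selected_index
        assert totals[i + 1] > 2 * totals[i]

    def test_level_structure_and_monotonicity(self, cubic_ts):
        drift = build_polynomial_library(3, "odd", "drift")
        diff = build_polynomial_library(2, "even", "diffusion")
        cfg = FitConfig(stride=2, seed=21, max_iter=250)
        path = ssr(drift, diff, cubic_ts, cfg)
        sizes = [len(lv.active_terms) for lv in path.levels]
        assert sizes == list(range(4, 0, -1))
        totals = np.array([lv.cost.total for lv in path.levels])
        # non-decreasing up to fit noise
        assert np.all(totals[1:] >= totals[:-1] * 0.95)

    def test_determinism(self, cubic_ts):
        drift = build_polynomial_library(3, "odd", "drift")
        diff = build_polynomial_library(0, "all", "diffusion")
        cfg = FitConfig(stride=4, seed=33, max_iter=120)
        p1 = ssr(drift, diff, cubic_ts, cfg)
        p2 = ssr(drift, diff, cubic_ts, cfg)
        assert [lv.active_terms for lv in p1.levels] == [
            lv.active_terms for lv in p2.levels
        ]
        assert p1.selected_index == p2.selected_index
        for a, b in zip(p1.levels, p2.levels):
            np.testing.assert_array_equal(a.coeffs, b.coeffs)

    def test_path_ends_with_diffusion_term(self, cubic_ts):
        # the last removable term can never be the only diffusion term
        drift = build_polynomial_library(3, "odd", "drift")
        diff = build_polynomial_library(0, "all", "diffusion")
        cfg = FitConfig(stride=4, seed=33, max_iter=120)
        path = ssr(drift, diff, cubic_ts, cfg)
        assert path.levels[-1].active_terms == ("diff:1",)
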