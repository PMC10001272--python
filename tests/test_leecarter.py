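import numpy as np
import pytest

from tvlc import LeeCarter, SyntheticSpec, fit_rwd, generate_surface
from tvlc.leecarter import _poisson_adjust_k

from conftest import make_surface


class TestFitLC:
    def test_recovers_noiseless_rank_one_truth(self, small_noiseless_static):
        _, surface, truth = small_noiseless_static
        res = LeeCarter(surface).fit()
        np.testing.assert_allclose(res.a, truth.a, atol=1e-8)
        np.testing.assert_allclose(res.b, truth.b_t[:, 0], atol=1e-8)
        np.testing.assert_allclose(res.k, truth.k, atol=1e-8)

    def test_normalisation_constraints(self, small_rotating):
        _, surface, _ = small_rotating
        res = LeeCarter(surface).fit()
        assert abs(res.b.sum() - 1.0) < 1e-10
        assert abs(res.k.sum()) < 1e-10

    def test_a_equals_row_means(self, small_rotating):
        _, surface, _ = small_rotating
        res = LeeCarter(surface).fit()
        np.testing.assert_allclose(res.a, surface.log_m.mean(axis=1), atol=1e-12)

    def test_scale_identifiability(self):
        """Rescaling (b, k) -> (c b, k/c) in the generator leaves the fit
        unchanged: the decomposition is identified by the constraints."""
        rng = np.random.default_rng(7)
        n, t = 8, 12
        a = rng.normal(-4, 1, n)
        b = rng.dirichlet(np.ones(n))
        k = rng.normal(0, 3, t)
        k -= k.mean()
        for c in (1.0, 3.7):
            log_m = a[:, None] + np.outer(c * b, k / c)
            res = LeeCarter(make_surface(log_m)).fit()
            np.testing.assert_allclose(res.b, b, atol=1e-8)
            np.testing.assert_allclose(res.k, k, atol=1e-8)

    def test_degenerate_matrix_raises(self):
        surf = make_surface(np.full((4, 5), -3.0))
        with pytest.raises(np.linalg.LinAlgError):
            LeeCarter(surf).fit()

    def test_rank_one_optimality_vs_random_competitor(self, small_rotating):
        """SVD gives the best rank-1 reconstruction of the centred matrix
        (Eckart-Young): no random competitor with the same a does better."""
        _, surface, _ = small_rotating
        res = LeeCarter(surface).fit()
        centred = surface.log_m - res.a[:, None]
        rss_fit = np.sum((centred - np.outer(res.b, res.k)) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            b_alt = res.b + rng.normal(0, 0.05, res.b.size)
            b_alt /= b_alt.sum()
            k_alt = res.k + rng.normal(0, 0.5, res.k.size)
            k_alt -= k_alt.mean()
            rss_alt = np.sum((centred - np.outer(b_alt, k_alt)) ** 2)
            assert rss_fit <= rss_alt + 1e-12


class TestFitRWD:
    def test_exact_linear_trend(self):
        d, sigma = fit_rwd(np.array([0.0, 1.0, 2.0, 3.0]))
        assert d == pytest.approx(1.0)
        assert sigma == pytest.approx(0.0, abs=1e-14)

    def test_sign_symmetry(self):
        d, _ = fit_rwd(np.array([3.0, 2.0, 1.0, 0.0]))
        assert d == pytest.approx(-1.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            fit_rwd(np.array([0.0, 1.0]))

    def test_simulation_consistency(self):
        """On a long simulated random walk the estimates sit within 3
        Monte-Carlo standard errors of the truth."""
        rng = np.random.default_rng(123)
        T, d_true, s_true = 5000, -1.7, 0.5
        k = np.cumsum(d_true + rng.normal(0, s_true, T))
        d, sigma = fit_rwd(k)
        se_d = s_true / np.sqrt(T - 1)
        assert abs(d - d_true) < 3 * se_d
        se_s = s_true / np.sqrt(2 * (T - 2))
        assert abs(sigma - s_true) < 3 * se_s


class TestPoissonAdjustment:
    def test_noiseless_truth_is_fixed_point(self, small_noiseless_static):
        _, surface, _ = small_noiseless_static
        res = LeeCarter(surface).fit()
        adj = LeeCarter(surface).fit(adjust_drift=True)
        np.testing.assert_allclose(adj.k, res.k, atol=1e-6)
        np.testing.assert_allclose(adj.a, res.a, atol=1e-6)

    def test_single_age_saturated_model(self):
        """With one age and b = 1 the Poisson ML k_t is exactly
        ln m_t - a (the model can match every observation)."""
        rng = np.random.default_rng(5)
        log_m = rng.normal(-3, 0.5, size=(1, 6))
        a = log_m.mean(axis=1)
        b = np.array([1.0])
        k0 = np.zeros(6)
        k = _poisson_adjust_k(log_m, a, b, k0, exposures=None)
        np.testing.assert_allclose(k, log_m[0] - a[0], atol=1e-9)

    def test_matches_brute_force_grid_newton(self):
        """On a small 3x4 surface each adjusted k_t agrees with an
        independent dense grid search over the per-t Poisson likelihood."""
        rng = np.random.default_rng(9)
        log_m = rng.normal(-3, 0.4, size=(3, 4))
        a = log_m.mean(axis=1)
        b = np.array([0.5, 0.3, 0.2])
        k0 = np.zeros(4)
        k = _poisson_adjust_k(log_m, a, b, k0, exposures=None)
        D = np.exp(log_m)
        for t in range(4):
            grid = np.linspace(k[t] - 2, k[t] + 2, 200001)
            ll = np.array(
                [
                    np.sum(D[:, t] * (a + b * g) - np.exp(a + b * g))
                    for g in grid[:: 1000]
                ]
            )
            coarse = grid[::1000][np.argmax(ll)]
            fine = grid[np.abs(grid - coarse) <= 0.03]
            ll_fine = np.array(
                [np.sum(D[:, t] * (a + b * g) - np.exp(a + b * g)) for g in fine]
            )
            assert abs(k[t] - fine[np.argmax(ll_fine)]) < 1e-4

    def test_never_decreases_poisson_likelihood(self, small_rotating):
        _, surface, _ = small_rotating
        plain = LeeCarter(surface).fit()
        adjusted = LeeCarter(surface).fit(adjust_drift=True)
        assert adjusted.poisson_loglik() >= plain.poisson_loglik() - 1e-9


class TestSelectFittingPeriod:
    @staticmethod
    def _rank_one_surface(k, n_ages=6, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(-4, 1, n_ages)
        b = rng.dirichlet(np.ones(n_ages))
        return make_surface(a[:, None] + np.outer(b, k), first_year=1950)

    def test_exactly_linear_k_returns_first_year(self):
        k = -0.8 * np.arange(40.0)
        surf = self._rank_one_surface(k)
        assert LeeCarter(surf).select_fitting_period(min_length=15) == 1950

    def test_kink_pushes_start_past_break(self):
        """Piecewise-linear k with a slope break at year 20 of 60: on
        noiseless data the selected start falls at or after the break."""
        t = np.arange(60.0)
        k = np.where(t < 20, -0.2 * t, -0.2 * 20 - 1.5 * (t - 20))
        surf = self._rank_one_surface(k)
        start = LeeCarter(surf).select_fitting_period(min_length=20)
        assert start >= 1950 + 20

    def test_single_candidate_returns_first_year(self, small_rotating):
        _, surface, _ = small_rotating
        start = LeeCarter(surface).select_fitting_period(
            min_length=surface.n_years
        )
        assert start == surface.years[0]


class TestForecast:
    def test_zero_drift_freezes_rates(self, small_noiseless_static):
        _, surface, _ = small_noiseless_static
        res = LeeCarter(surface).fit()
        res.d = 0.0
        fc = res.forecast(5)
        fitted_T = res.a + res.b * res.k[-1]
        for h in range(5):
            np.testing.assert_allclose(fc[:, h], fitted_T, atol=1e-12)

    def test_two_step_arithmetic(self):
        k = np.array([-4.0, -4.5, -5.0])
        d, _ = fit_rwd(k)  # d = -0.5
        rng = np.random.default_rng(1)
        surf = make_surface(rng.normal(-4, 0.5, (4, 3)))
        res = LeeCarter(surf).fit()
        res.d = -0.5
        res.k[-1] = -5.0
        assert res.forecast_k(2)[-1] == pytest.approx(-6.0)

    def test_affine_in_horizon_with_slope_b_d(self, small_rotating):
        _, surface, _ = small_rotating
        res = LeeCarter(surface).fit()
        fc = res.forecast(10)
        diffs = np.diff(fc, axis=1)
        expected = np.tile((res.b * res.d)[:, None], (1, 9))
        np.testing.assert_allclose(diffs, expected, atol=1e-10)

    def test_h_zero_rejected(self, lc_fit):
        with pytest.raises(ValueError):
            lc_fit.forecast(0)
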