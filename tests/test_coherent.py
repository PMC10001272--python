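import numpy as np
import pytest

from tvlc import (
    CoherentVAR,
    KernelSpec,
    LeeCarter,
    center_bstar,
    fit_tv_bx,
    var_diagnostics,
)


def pls_loss_and_grad(theta, bstar, lambdas):
    """Independent loop-based implementation of the penalized loss.

    Written deliberately without the solver's matrix assembly so it can
    serve as an oracle: per-age one-lag regressions with edge equations
    for the first two ages, plus squared-difference penalties across ages.
    """
    N, T = bstar.shape
    la, lb, lg = lambdas
    alpha = theta[:N]
    beta = np.concatenate([[0.0], theta[N : 2 * N - 1]])
    gamma = np.concatenate([[0.0, 0.0], theta[2 * N - 1 :]])
    grad_a = np.zeros(N)
    grad_b = np.zeros(N)
    grad_g = np.zeros(N)
    loss = 0.0
    for i in range(N):
        for t in range(1, T):
            pred = alpha[i] * bstar[i, t - 1]
            if i >= 1:
                pred += beta[i] * bstar[i - 1, t - 1]
            if i >= 2:
                pred += gamma[i] * bstar[i - 2, t - 1]
            r = bstar[i, t] - pred
            loss += r * r
            grad_a[i] += -2.0 * r * bstar[i, t - 1]
            if i >= 1:
                grad_b[i] += -2.0 * r * bstar[i - 1, t - 1]
            if i >= 2:
                grad_g[i] += -2.0 * r * bstar[i - 2, t - 1]
    for i in range(1, N):
        diff = alpha[i] - alpha[i - 1]
        loss += la * diff * diff
        grad_a[i] += 2.0 * la * diff
        grad_a[i - 1] -= 2.0 * la * diff
    for i in range(2, N):
        diff = beta[i] - beta[i - 1]
        loss += lb * diff * diff
        grad_b[i] += 2.0 * lb * diff
        grad_b[i - 1] -= 2.0 * lb * diff
    for i in range(3, N):
        diff = gamma[i] - gamma[i - 1]
        loss += lg * diff * diff
        grad_g[i] += 2.0 * lg * diff
        grad_g[i - 1] -= 2.0 * lg * diff
    return loss, np.concatenate([grad_a, grad_b[1:], grad_g[2:]])


def minimize_pls(bstar, lambdas):
    """Generic numerical minimiser of the quadratic loss: one exact Newton
    step from the origin, with gradient and Hessian obtained only from the
    independent loop-based objective (the Hessian column-by-column as the
    gradient's exact finite difference, which is error-free for a
    quadratic).  Robust even when weak penalties leave the problem
    ill-conditioned, where quasi-Newton iterations stall."""
    n = 3 * bstar.shape[0] - 3
    g0 = pls_loss_and_grad(np.zeros(n), bstar, lambdas)[1]
    H = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        H[:, j] = pls_loss_and_grad(e, bstar, lambdas)[1] - g0
    return np.linalg.solve(H, -g0)


@pytest.fixture(scope="module")
def fitted_bstar():
    from tvlc import SyntheticSpec, generate_surface

    spec = SyntheticSpec(N=12, T=40, seed=21)
    surface, _ = generate_surface(spec)
    base = LeeCarter(surface).fit()
    tv = fit_tv_bx(surface, base, KernelSpec("gaussian", 0.3))
    return center_bstar(tv)


class TestCenterBstar:
    def test_flat_loadings_center_to_zero(self):
        b_t = np.full((5, 7), 0.2)
        np.testing.assert_array_equal(center_bstar(b_t), np.zeros((5, 7)))

    def test_column_sums_vanish(self, fitted_bstar):
        np.testing.assert_allclose(fitted_bstar.sum(axis=0), 0.0, atol=1e-12)

    def test_add_back_inverts_centering(self, fitted_bstar):
        N = fitted_bstar.shape[0]
        b_t = fitted_bstar + 1.0 / N
        np.testing.assert_array_equal(center_bstar(b_t) + 1.0 / N, b_t)


class TestFitPLS:
    def test_zero_penalty_equals_per_age_ols(self, fitted_bstar):
        """At lambda = 0 the joint solve decouples into each age's own
        least-squares regression."""
        res = CoherentVAR(fitted_bstar).fit((0.0, 0.0, 0.0))
        N = fitted_bstar.shape[0]
        lag, cur = fitted_bstar[:, :-1], fitted_bstar[:, 1:]
        for i in range(N):
            cols = [lag[i]]
            if i >= 1:
                cols.append(lag[i - 1])
            if i >= 2:
                cols.append(lag[i - 2])
            X = np.stack(cols, axis=1)
            coef, *_ = np.linalg.lstsq(X, cur[i], rcond=None)
            assert res.alpha[i] == pytest.approx(coef[0], abs=1e-8)
            if i >= 1:
                assert res.beta[i] == pytest.approx(coef[1], abs=1e-8)
            if i >= 2:
                assert res.gamma[i] == pytest.approx(coef[2], abs=1e-8)

    def test_huge_penalty_forces_equal_coefficients(self, fitted_bstar):
        """lambda -> infinity collapses each coefficient sequence to a
        single value: the pooled equality-constrained OLS solution."""
        res = CoherentVAR(fitted_bstar).fit((1e8, 1e8, 1e8))
        assert np.ptp(res.alpha) < 1e-4
        assert np.ptp(res.beta[1:]) < 1e-4
        assert np.ptp(res.gamma[2:]) < 1e-4
        # pooled oracle: one shared (alpha, beta, gamma) by stacked OLS
        N, T = fitted_bstar.shape
        lag, cur = fitted_bstar[:, :-1], fitted_bstar[:, 1:]
        rows, ys = [], []
        for i in range(N):
            x1 = lag[i]
            x2 = lag[i - 1] if i >= 1 else np.zeros(T - 1)
            x3 = lag[i - 2] if i >= 2 else np.zeros(T - 1)
            rows.append(np.stack([x1, x2, x3], axis=1))
            ys.append(cur[i])
        X = np.vstack(rows)
        y = np.concatenate(ys)
        shared, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert res.alpha.mean() == pytest.approx(shared[0], abs=1e-4)
        assert res.beta[1:].mean() == pytest.approx(shared[1], abs=1e-4)
        assert res.gamma[2:].mean() == pytest.approx(shared[2], abs=1e-4)

    @pytest.mark.parametrize("lambdas", [(0.3, 1.7, 0.05), (10.0, 0.0, 2.0)])
    def test_matches_generic_minimizer(self, fitted_bstar, lambdas):
        """The closed-form solve agrees with an independent quasi-Newton
        minimisation of the loss to 1e-6."""
        res = CoherentVAR(fitted_bstar).fit(lambdas)
        theta = minimize_pls(fitted_bstar, lambdas)
        N = fitted_bstar.shape[0]
        np.testing.assert_allclose(res.alpha, theta[:N], atol=1e-6)
        np.testing.assert_allclose(res.beta[1:], theta[N : 2 * N - 1], atol=1e-6)
        np.testing.assert_allclose(res.gamma[2:], theta[2 * N - 1 :], atol=1e-6)

    def test_constant_loadings_need_penalty(self):
        bstar = np.tile(np.linspace(-0.1, 0.1, 6)[:, None], (1, 10))
        with pytest.raises(np.linalg.LinAlgError, match="penalt"):
            CoherentVAR(bstar).fit((0.0, 0.0, 0.0))

    def test_loss_beats_random_perturbations(self, fitted_bstar):
        res = CoherentVAR(fitted_bstar).fit((0.5, 0.5, 0.5))
        base_loss = res.loss()
        rng = np.random.default_rng(0)
        N = fitted_bstar.shape[0]
        theta0 = np.concatenate([res.alpha, res.beta[1:], res.gamma[2:]])
        for _ in range(100):
            theta = theta0 + rng.normal(0, 0.01, theta0.size)
            loss, _ = pls_loss_and_grad(theta, fitted_bstar, (0.5, 0.5, 0.5))
            assert base_loss <= loss + 1e-12

    def test_alpha_roughness_monotone_in_penalty(self, fitted_bstar):
        roughness = [
            np.sum(np.diff(CoherentVAR(fitted_bstar).fit((lam, 0.1, 0.1)).alpha) ** 2)
            for lam in (0.0, 1.0, 100.0)
        ]
        assert roughness[0] >= roughness[1] >= roughness[2]


class TestForecast:
    def test_zero_coefficients_forecast_flat(self, fitted_bstar):
        res = CoherentVAR(fitted_bstar).fit((1.0, 1.0, 1.0))
        res.alpha[:] = 0.0
        res.beta[:] = 0.0
        res.gamma[:] = 0.0
        N = fitted_bstar.shape[0]
        np.testing.assert_allclose(res.forecast_b(4), 1.0 / N, atol=1e-14)

    def test_iteration_matches_matrix_power_oracle(self, fitted_bstar):
        res = CoherentVAR(fitted_bstar).fit((0.5, 0.5, 0.5))
        A = res.companion()
        for h in (1, 3, 7):
            oracle = np.linalg.matrix_power(A, h) @ res.last_bstar
            np.testing.assert_allclose(res.forecast_bstar(h)[:, -1], oracle, atol=1e-12)

    def test_stationary_forecast_converges_to_uniform(self, fitted_bstar):
        res = CoherentVAR(fitted_bstar).fit((1.0, 1.0, 1.0))
        assert res.is_stationary
        N = fitted_bstar.shape[0]
        devs = np.abs(res.forecast_b(300) - 1.0 / N).max(axis=0)
        tail = devs[50:]
        assert np.all(np.diff(tail) <= 1e-12)  # monotone beyond mixing time
        assert devs[-1] < 0.05 * devs[49]      # and geometrically shrinking

    def test_forecast_columns_sum_to_one(self, fitted_bstar):
        res = CoherentVAR(fitted_bstar).fit((1.0, 1.0, 1.0))
        np.testing.assert_allclose(res.forecast_b(20).sum(axis=0), 1.0, atol=1e-12)


class TestDiagnostics:
    def test_white_noise_passes_stationarity_screen(self):
        rng = np.random.default_rng(17)
        bstar = rng.normal(0, 0.01, size=(40, 70))
        report = var_diagnostics(bstar)
        assert report.loc["Stationarity (ADF)", "failures"] <= 5

    def test_random_walks_fail_stationarity_screen(self):
        rng = np.random.default_rng(18)
        bstar = np.cumsum(rng.normal(0, 0.01, size=(40, 70)), axis=1)
        report = var_diagnostics(bstar)
        assert report.loc["Stationarity (ADF)", "failures"] >= 32

    def test_report_schema(self):
        rng = np.random.default_rng(19)
        report = var_diagnostics(rng.normal(0, 1, size=(5, 40)))
        assert list(report.index) == ["Stationarity (ADF)", "VAR(1) adequacy (GC)"]
        assert list(report.columns) == ["failures", "n_ages", "n_tested"]
        assert (report["n_ages"] == 5).all()

    def test_too_short_series_flagged_untestable(self):
        rng = np.random.default_rng(20)
        report = var_diagnostics(rng.normal(0, 1, size=(4, 8)))
        assert (report["n_tested"] < 4).any()
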