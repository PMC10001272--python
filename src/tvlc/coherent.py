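"""Age-coherent constrained VAR for time-varying age effects.

Because the age loadings satisfy sum_x b_{x,t} = 1 and, for age-coherent
forecasts, every b_{x,T+h} must converge to the common value 1/N, the
centred sequence  b*_{x,t} = b_{x,t} - 1/N  is treated as stationary with
zero mean and modelled by a one-lag VAR whose coefficient matrix is
constrained to a lower band:

    b*_{1,t} = alpha_1 b*_{1,t-1} + e_{1,t}
    b*_{2,t} = alpha_2 b*_{2,t-1} + beta_2 b*_{1,t-1} + e_{2,t}
    b*_{i,t} = alpha_i b*_{i,t-1} + beta_i b*_{i-1,t-1}
               + gamma_i b*_{i-2,t-1} + e_{i,t},   i = 3..N.

alpha_i carries the temporal effect, beta_i the same-cohort effect and
gamma_i the nearest-younger-cohort effect.  Estimation is penalized least
squares: the squared-error loss plus smoothness penalties
lambda_a sum (alpha_i - alpha_{i-1})^2 (and likewise for beta, gamma)
is minimised in closed form by one symmetric positive-definite solve in
all 3N-3 coefficients; the penalties couple neighbouring ages, so the
system cannot be solved per age.

Forecasts iterate the fitted recursion with zero innovations, add back
1/N and rescale each horizon to sum exactly to 1.  Whenever the companion
matrix is stable (spectral radius < 1) the forecast loadings converge to
1/N, which is precisely the age-coherence requirement: log-rate forecasts
at any two ages then share the same long-run drift b d and never diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from statsmodels.tsa.stattools import adfuller

from .kernels import TVFit

__all__ = ["center_bstar", "CoherentVAR", "CoherentVARResults", "var_diagnostics"]


def center_bstar(tv: TVFit | np.ndarray) -> np.ndarray:
    """Centred loadings b* = b - 1/N; every column sums to zero."""
    b_t = tv.b_t if isinstance(tv, TVFit) else np.asarray(tv, float)
    return b_t - 1.0 / b_t.shape[0]


class CoherentVAR:
    """Constrained VAR(1) model for centred age loadings.

    Parameters
    ----------
    bstar : ndarray, shape (N, T)
        Centred loadings, N >= 3 ages by T >= 3 years.
    """

    def __init__(self, bstar: np.ndarray):
        bstar = np.asarray(bstar, float)
        if bstar.ndim != 2:
            raise ValueError("bstar must be a 2-d (ages x years) array")
        N, T = bstar.shape
        if N < 3 or T < 3:
            raise ValueError("constrained VAR needs N >= 3 ages and T >= 3 years")
        self.bstar = bstar
        self.N = N
        self.T = T

    # coefficient layout in the joint solve:
    #   alpha_1..alpha_N      -> 0 .. N-1
    #   beta_2..beta_N        -> N .. 2N-2
    #   gamma_3..gamma_N      -> 2N-1 .. 3N-4
    def _indices(self, i: int) -> list[int]:
        """Joint-vector indices of the coefficients of age i (1-based)."""
        N = self.N
        idx = [i - 1]
        if i >= 2:
            idx.append(N + i - 2)
        if i >= 3:
            idx.append(2 * N - 1 + i - 3)
        return idx

    def fit(
        self, lambdas: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ) -> "CoherentVARResults":
        """Minimise the penalized least-squares loss in closed form.

        Parameters
        ----------
        lambdas : (lambda_alpha, lambda_beta, lambda_gamma)
            Nonnegative smoothness penalties on the cross-age differences
            of each coefficient sequence.  All zero reduces to ordinary
            least squares per age.
        """
        la, lb, lg = (float(v) for v in lambdas)
        if min(la, lb, lg) < 0:
            raise ValueError("penalties must be nonnegative")
        N, T = self.N, self.T
        p = 3 * N - 3
        M = np.zeros((p, p))
        rhs = np.zeros(p)
        lag = self.bstar[:, :-1]
        cur = self.bstar[:, 1:]
        for i in range(1, N + 1):
            rows = [lag[i - 1]]
            if i >= 2:
                rows.append(lag[i - 2])
            if i >= 3:
                rows.append(lag[i - 3])
            X = np.stack(rows, axis=1)  # (T-1, n_coef)
            y = cur[i - 1]
            idx = self._indices(i)
            M[np.ix_(idx, idx)] += X.T @ X
            rhs[idx] += X.T @ y
        # smoothness penalties: lambda * D'D on each coefficient block
        for lam, start, size in (
            (la, 0, N),
            (lb, N, N - 1),
            (lg, 2 * N - 1, N - 2),
        ):
            if lam > 0 and size >= 2:
                D = np.diff(np.eye(size), axis=0)
                M[start : start + size, start : start + size] += lam * D.T @ D
        try:
            c, low = scipy.linalg.cho_factor(M)
            theta = scipy.linalg.cho_solve((c, low), rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular penalized normal equations; the centred loadings "
                "carry too little temporal variation — use positive penalties"
            ) from exc
        alpha = theta[:N]
        beta = np.concatenate([[0.0], theta[N : 2 * N - 1]])
        gamma = np.concatenate([[0.0, 0.0], theta[2 * N - 1 :]])
        return CoherentVARResults(
            model=self,
            alpha=alpha,
            beta=beta,
            gamma=gamma,
            lambdas=(la, lb, lg),
            last_bstar=self.bstar[:, -1].copy(),
        )


@dataclass
class CoherentVARResults:
    """Fitted constrained-VAR coefficients and forecasting machinery.

    ``beta[0]`` and ``gamma[:2]`` are structural zeros (those lags do not
    exist for the first ages).
    """

    model: CoherentVAR
    alpha: np.ndarray   # (N,)
    beta: np.ndarray    # (N,); beta[0] == 0
    gamma: np.ndarray   # (N,); gamma[0] == gamma[1] == 0
    lambdas: tuple[float, float, float]
    last_bstar: np.ndarray

    @property
    def N(self) -> int:
        return self.alpha.size

    def companion(self) -> np.ndarray:
        """The banded N x N transition matrix of the recursion."""
        A = np.diag(self.alpha)
        idx = np.arange(1, self.N)
        A[idx, idx - 1] = self.beta[1:]
        idx = np.arange(2, self.N)
        A[idx, idx - 2] = self.gamma[2:]
        return A

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    @property
    def is_stationary(self) -> bool:
        return self.spectral_radius < 1.0

    def forecast_bstar(self, h: int) -> np.ndarray:
        """Raw h-step mean path of b*, shape (N, h), no rescaling."""
        if h < 1:
            raise ValueError("forecast horizon must be >= 1")
        A = self.companion()
        out = np.empty((self.N, h))
        state = self.last_bstar
        for step in range(h):
            state = A @ state
            out[:, step] = state
        return out

    def forecast_b(self, h: int) -> np.ndarray:
        """Forecast loadings b_{x,T+h}: add back 1/N, then rescale each
        horizon so the loadings sum exactly to 1."""
        path = self.forecast_bstar(h) + 1.0 / self.N
        sums = path.sum(axis=0)
        if np.any(np.abs(sums) < 1e-12):
            raise ZeroDivisionError("forecast loadings sum to zero; cannot rescale")
        return path / sums

    def loss(self, bstar: np.ndarray | None = None) -> float:
        """The penalized least-squares objective at the fitted coefficients."""
        b = self.model.bstar if bstar is None else np.asarray(bstar, float)
        pred = self.companion() @ b[:, :-1]
        sse = float(np.sum((b[:, 1:] - pred) ** 2))
        la, lb, lg = self.lambdas
        pen = (
            la * float(np.sum(np.diff(self.alpha) ** 2))
            + lb * float(np.sum(np.diff(self.beta[1:]) ** 2))
            + lg * float(np.sum(np.diff(self.gamma[2:]) ** 2))
        )
        return sse + pen

    def coefficients_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma}
        )

    def summary(self) -> str:
        la, lb, lg = self.lambdas
        return "\n".join(
            [
                "Age-coherent constrained VAR(1)",
                "=" * 40,
                f"ages (N):          {self.N}",
                f"penalties:         la={la:g}, lb={lb:g}, lg={lg:g}",
                f"spectral radius:   {self.spectral_radius:.4f}"
                f" ({'stationary' if self.is_stationary else 'NON-stationary'})",
                f"loss at optimum:   {self.loss():.6g}",
            ]
        )


def var_diagnostics(
    bstar: np.ndarray, level: float = 0.05, max_lag: int = 4
) -> pd.DataFrame:
    """Per-age stationarity and VAR(1)-adequacy screening.

    For each age the augmented Dickey-Fuller test (constant, no trend,
    AIC lag selection up to ``max_lag``) screens for a unit root; failing
    to reject at ``level`` counts as a stationarity failure.  Adequacy of
    one lag is screened by an F-test of the lag-2 block (own age and the
    two next-younger ages) added to the constrained VAR(1) regressors;
    rejection counts as an adequacy failure.

    Returns a two-row table (test x {failures, n_ages, n_tested}).
    """
    bstar = np.asarray(bstar, float)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    N, T = bstar.shape
    adf_fail = adf_tested = 0
    gc_fail = gc_tested = 0
    for i in range(N):
        series = bstar[i]
        if T >= 10 and np.ptp(series) > 0:
            try:
                pval = adfuller(series, maxlag=max_lag, regression="c", autolag="AIC")[1]
                adf_tested += 1
                if pval > level:
                    adf_fail += 1
            except (ValueError, np.linalg.LinAlgError):
                pass
        pval = _lag2_ftest(bstar, i)
        if pval is not None:
            gc_tested += 1
            if pval < level:
                gc_fail += 1
    return pd.DataFrame(
        {
            "failures": [adf_fail, gc_fail],
            "n_ages": [N, N],
            "n_tested": [adf_tested, gc_tested],
        },
        index=["Stationarity (ADF)", "VAR(1) adequacy (GC)"],
    )


def _lag2_ftest(bstar: np.ndarray, i: int) -> float | None:
    """F-test p-value of lag-2 predictability beyond the constrained lag-1
    terms for age row ``i`` (0-based); None when not testable."""
    N, T = bstar.shape
    rows1 = [bstar[j] for j in range(max(0, i - 2), i + 1)]
    y = bstar[i, 2:]
    X_r = np.stack([r[1:-1] for r in rows1], axis=1)
    X_u = np.hstack([X_r, np.stack([r[:-2] for r in rows1], axis=1)])
    n = y.size
    q = X_u.shape[1] - X_r.shape[1]
    if n - X_u.shape[1] < 3:
        return None
    rss_r = _rss(X_r, y)
    rss_u = _rss(X_u, y)
    if rss_u <= 0:
        return None
    F = (rss_r - rss_u) / q / (rss_u / (n - X_u.shape[1]))
    return float(scipy.stats.f.sf(F, q, n - X_u.shape[1]))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)
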