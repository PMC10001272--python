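"""Classic Lee-Carter mortality model.

The model decomposes logged central death rates as

    ln m_{x,t} = a_x + b_x k_t + eps_{x,t},

with the normalisation sum_t k_t = 0 and sum_x b_x = 1, estimated by SVD
of the row-centred log-rate matrix.  The period index k_t is extrapolated
as a random walk with drift d:

    k_t = k_{t-1} + d + e_t,   e_t ~ N(0, sigma_e^2),

giving mean forecasts  k_{T+h} = k_T + h d  and
ln m_{x,T+h} = a_x + b_x k_{T+h}.

Two optional adjustments in the Booth-Maindonald-Smith (BMS) spirit are
provided: re-estimation of each k_t by Poisson maximum likelihood for the
death counts implied by the rates (which adjusts the drift), and a
data-driven choice of the fitting period based on the linearity of k_t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surface import MortalitySurface

__all__ = ["LeeCarter", "LeeCarterResults", "fit_rwd"]


def fit_rwd(k: np.ndarray) -> tuple[float, float]:
    """Fit a random walk with drift to a period index.

    Returns ``(d, sigma_e)`` where ``d`` is the mean first difference
    (equivalently ``(k_T - k_1)/(T-1)``) and ``sigma_e`` the sample s.d.
    of the differences about ``d`` with denominator T-2 (one degree of
    freedom spent on the drift).
    """
    k = np.asarray(k, float)
    if k.size < 3:
        raise ValueError(f"need at least 3 observations of k, got {k.size}")
    diffs = np.diff(k)
    d = float(diffs.mean())
    sigma_e = float(np.sqrt(np.sum((diffs - d) ** 2) / (diffs.size - 1)))
    return d, sigma_e


def _svd_leading_pair(centred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading rank-1 factors (b, k) of a row-centred log-rate matrix.

    Normalised so sum(b) = 1; the sign is fixed by requiring the raw
    leading age vector to have a positive sum before rescaling, which
    makes the decomposition deterministic.
    """
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise np.linalg.LinAlgError("degenerate (zero-variance) log-rate matrix")
    u1, v1 = u[:, 0], vt[0]
    colsum = u1.sum()
    if colsum == 0:
        raise np.linalg.LinAlgError("leading age vector sums to zero; cannot normalise")
    if colsum < 0:
        u1, v1 = -u1, -v1
        colsum = -colsum
    b = u1 / colsum
    k = s[0] * v1 * colsum
    return b, k - k.mean()  # row-centring already makes sum(k)=0; enforce exactly


def _poisson_adjust_k(
    log_m: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    k0: np.ndarray,
    exposures: np.ndarray | None,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> np.ndarray:
    """Re-estimate each k_t by Poisson ML with a, b fixed.

    Deaths are D_{x,t} = m_{x,t} E_{x,t} with mean E_{x,t} exp(a_x+b_x k_t);
    the per-t log-likelihood is concave in k_t, so one-dimensional Newton
    from the SVD value converges quadratically.
    """
    E = np.ones_like(log_m) if exposures is None else np.asarray(exposures, float)
    D = np.exp(log_m) * E
    k = k0.astype(float).copy()
    for t in range(k.size):
        kt = k[t]
        for _ in range(max_iter):
            mu = E[:, t] * np.exp(a + b * kt)
            grad = np.sum(b * (D[:, t] - mu))
            hess = -np.sum(b * b * mu)
            if hess >= 0:  # all-zero b column; cannot happen with sum(b)=1
                raise RuntimeError(f"non-concave Poisson step at t index {t}")
            step = grad / hess
            kt -= step
            if abs(step) < tol * (1.0 + abs(kt)):
                break
        else:
            raise RuntimeError(f"Poisson adjustment failed to converge at t index {t}")
        k[t] = kt
    return k


class LeeCarter:
    """Lee-Carter model for one complete mortality surface.

    Parameters
    ----------
    surface : MortalitySurface
        Complete (gap-free) surface with N >= 2 ages and T >= 3 years.

    Examples
    --------
    >>> res = LeeCarter(surface).fit()
    >>> log_rates_2030 = res.forecast(h=11)[:, -1]
    """

    def __init__(self, surface: MortalitySurface):
        surface.require_complete()
        if surface.n_ages < 2 or surface.n_years < 3:
            raise ValueError("Lee-Carter needs at least 2 ages and 3 years")
        self.surface = surface

    def fit(
        self,
        adjust_drift: bool = False,
        select_period: bool = False,
        min_length: int = 10,
        exposures: np.ndarray | None = None,
    ) -> "LeeCarterResults":
        """Estimate (a, b, k) by SVD and the drift by a random walk.

        Parameters
        ----------
        adjust_drift : bool
            Re-estimate k_t by Poisson ML (BMS drift adjustment) before
            refitting the drift.
        select_period : bool
            Restrict the fitting period to the data-driven start year of
            :meth:`select_fitting_period` before estimation (the second
            BMS adjustment).
        exposures : ndarray, optional
            Person-years matching the surface shape; unit exposures are
            assumed when absent (rates treated as deaths per unit exposure).
        """
        surface = self.surface
        if select_period:
            start = self.select_fitting_period(min_length=min_length)
            keep = surface.years >= start
            surface = surface.window(int(start), int(surface.years[-1]))
            if exposures is not None:
                exposures = exposures[:, keep]
        log_m = surface.log_m
        a = log_m.mean(axis=1)
        b, k = _svd_leading_pair(log_m - a[:, None])
        if adjust_drift:
            k = _poisson_adjust_k(log_m, a, b, k, exposures)
            shift = k.mean()
            k = k - shift
            a = a + b * shift  # recentring absorbed so fitted rates are unchanged
        d, sigma_e = fit_rwd(k)
        resid = log_m - a[:, None] - np.outer(b, k)
        sigma_eps = resid.std(axis=1, ddof=1)
        return LeeCarterResults(
            model=self,
            surface=surface,
            a=a,
            b=b,
            k=k,
            d=d,
            sigma_e=sigma_e,
            sigma_eps=sigma_eps,
            fit_years=(int(surface.years[0]), int(surface.years[-1])),
            drift_adjusted=adjust_drift,
        )

    def select_fitting_period(self, min_length: int = 10) -> int:
        """Data-driven start year for the fitting period.

        For each candidate start year the model is refitted and the mean
        squared deviation of k_t about its linear trend is compared with
        the squared mean increment of that trend.  The earliest start
        whose ratio is within 5% of the minimum is returned, favouring
        longer samples when the linearity is comparable.
        """
        if min_length < 10:
            raise ValueError("min_length must be at least 10")
        years = self.surface.years
        n_candidates = years.size - min_length + 1
        if n_candidates < 1:
            raise ValueError(
                f"no fitting period of length {min_length} in {years.size} years"
            )
        ratios = np.empty(n_candidates)
        for i in range(n_candidates):
            sub = self.surface.window(int(years[i]), int(years[-1]))
            log_m = sub.log_m
            a = log_m.mean(axis=1)
            _, k = _svd_leading_pair(log_m - a[:, None])
            t = np.arange(k.size, dtype=float)
            slope, intercept = np.polyfit(t, k, 1)
            trend = intercept + slope * t
            lack_of_fit = np.mean((k - trend) ** 2)
            increment = slope**2
            ratios[i] = lack_of_fit / increment if increment > 0 else np.inf
        best = ratios.min()
        threshold = best * 1.05 + 1e-12  # absolute floor for exactly-linear k
        first_ok = int(np.argmax(ratios <= threshold))
        return int(years[first_ok])


@dataclass
class LeeCarterResults:
    """Fitted Lee-Carter parameters and forecasts."""

    model: LeeCarter
    surface: MortalitySurface
    a: np.ndarray
    b: np.ndarray
    k: np.ndarray
    d: float
    sigma_e: float
    sigma_eps: np.ndarray
    fit_years: tuple[int, int]
    drift_adjusted: bool = False

    @property
    def fittedvalues(self) -> np.ndarray:
        """In-sample fitted log rates."""
        return self.a[:, None] + np.outer(self.b, self.k)

    def forecast_k(self, h: int) -> np.ndarray:
        """Mean path k_{T+1..T+h} = k_T + h d."""
        if h < 1:
            raise ValueError("forecast horizon must be >= 1")
        return self.k[-1] + self.d * np.arange(1, h + 1)

    def forecast(self, h: int) -> np.ndarray:
        """Mean forecast log rates, shape (n_ages, h)."""
        return self.a[:, None] + np.outer(self.b, self.forecast_k(h))

    def poisson_loglik(self, exposures: np.ndarray | None = None) -> float:
        """Poisson log-likelihood of the fit (constant terms dropped)."""
        log_m = self.surface.log_m
        E = np.ones_like(log_m) if exposures is None else exposures
        D = np.exp(log_m) * E
        eta = np.log(E) + self.fittedvalues
        return float(np.sum(D * eta - np.exp(eta)))

    def params_frame(self) -> pd.DataFrame:
        age_part = pd.DataFrame(
            {"age": self.surface.ages, "a": self.a, "b": self.b,
             "sigma_eps": self.sigma_eps}
        )
        return age_part

    def summary(self) -> str:
        lo, hi = self.fit_years
        lines = [
            "Lee-Carter model results",
            "=" * 40,
            f"population:      {self.surface.population_id or '<unnamed>'}",
            f"fit period:      {lo}-{hi}  ({self.k.size} years, {self.a.size} ages)",
            f"drift d:         {self.d:+.4f} per year",
            f"innovation s.d.: {self.sigma_e:.4f}",
            f"drift adjusted:  {'yes (Poisson)' if self.drift_adjusted else 'no'}",
            f"sum(b) = {self.b.sum():.10f}, sum(k) = {self.k.sum():.2e}",
        ]
        return "\n".join(lines)
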