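"""Period life tables and life expectancy at birth (e0).

A year's full age schedule of central death rates m_x is converted to a
period life table with the standard actuarial approximation a_x = 0.5
(deaths uniformly spread within the year of age):

    q_x = m_x / (1 + 0.5 m_x),      x < N-1,
    l_0 = 1,  d_x = l_x q_x,  L_x = l_x - 0.5 d_x,

with the last age treated as an open group closed by exposure,
L_{N-1} = l_{N-1} / m_{N-1}.  Then e0 = sum_x L_x.  Under a constant
rate m at every age this telescopes exactly to e0 = 1/m, which pins the
convention down (no infant separation-factor correction is applied).

Prediction intervals simulate only the innovation uncertainty of the
period index (the random-walk shocks e_t); the drift, loadings and their
forecast paths are held at their point estimates.  The band is the
empirical percentile interval of the simulated e0 paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LifeExpectancyResult", "e0_from_mx", "e0_path", "simulate_pi"]


def _e0_columns(m: np.ndarray) -> np.ndarray:
    """Life expectancy at birth for each column of an (N, S) rate matrix."""
    m = np.atleast_2d(np.asarray(m, float))
    if np.any(m <= 0) or not np.all(np.isfinite(m)):
        raise ValueError("death rates must be strictly positive and finite")
    q = m[:-1] / (1.0 + 0.5 * m[:-1])
    p = 1.0 - q
    l = np.vstack([np.ones((1, m.shape[1])), np.cumprod(p, axis=0)])
    L = l[:-1] * (1.0 - 0.5 * q)  # l_x - 0.5 d_x
    L_open = l[-1] / m[-1]
    return L.sum(axis=0) + L_open


def e0_from_mx(mx: np.ndarray) -> float:
    """Period life expectancy at birth from one year's central death rates.

    The last entry of ``mx`` is treated as the open age group.
    """
    mx = np.asarray(mx, float)
    if mx.ndim != 1:
        raise ValueError("mx must be a 1-d age schedule")
    return float(_e0_columns(mx[:, None])[0])


@dataclass
class LifeExpectancyResult:
    """e0 point path and (optionally) its simulated prediction band."""

    years: np.ndarray
    e0_point: np.ndarray
    e0_lower: np.ndarray | None = None
    e0_upper: np.ndarray | None = None
    level: float = 0.95
    n_sims: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, "e0": self.e0_point}
        if self.e0_lower is not None:
            data["lower"] = self.e0_lower
            data["upper"] = self.e0_upper
        return pd.DataFrame(data)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def e0_path(forecast, years: np.ndarray | None = None) -> LifeExpectancyResult:
    """Point e0 path from a forecast of log rates.

    ``forecast`` is a ForecastResult (``log_m_hat`` attribute) or a plain
    (N, H) matrix of forecast log rates.
    """
    log_m = getattr(forecast, "log_m_hat", forecast)
    log_m = np.asarray(log_m, float)
    if years is None:
        years = getattr(forecast, "years", None)
    if years is None:
        years = np.arange(1, log_m.shape[1] + 1)
    e0 = _e0_columns(np.exp(log_m))
    return LifeExpectancyResult(np.asarray(years), e0)


def _extract_paths(results, h: int):
    """(a, k_last, d, sigma_e, b_path (N,h), years) from a fitted model."""
    a = results.a
    sigma_e = results.sigma_e
    d = results.d
    k_last = results.k[-1]
    if hasattr(results, "b_path"):          # time-varying model
        b_path = results.b_path(h)
    else:                                    # static Lee-Carter
        b_path = np.tile(results.b[:, None], (1, h))
    last_year = int(results.surface.years[-1])
    years = last_year + np.arange(1, h + 1)
    return a, float(k_last), float(d), float(sigma_e), b_path, years


def simulate_pi(
    results,
    h: int,
    n_sims: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> LifeExpectancyResult:
    """Simulation-based prediction interval for the e0 path.

    ``results`` is a fitted LeeCarterResults or TVLCResults.  ``n_sims``
    Gaussian innovation paths of the period index are drawn, each mapped
    to log rates via the model's (static or forecast) loading path and
    then to e0 per year; the band is the empirical percentile interval at
    ``level``.  With sigma_e = 0 the band degenerates to the point path.
    """
    if h < 1:
        raise ValueError("horizon must be >= 1")
    if n_sims < 1000:
        raise ValueError("need at least 1000 simulations for stable percentiles")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    a, k_last, d, sigma_e, b_path, years = _extract_paths(results, h)

    k_point = k_last + d * np.arange(1, h + 1)
    point = _e0_columns(np.exp(a[:, None] + b_path * k_point[None, :]))

    if sigma_e == 0.0:
        return LifeExpectancyResult(
            years, point, point.copy(), point.copy(), level, n_sims, seed
        )

    rng = np.random.default_rng(seed)
    shocks = rng.normal(0.0, sigma_e, size=(n_sims, h))
    k_paths = k_last + np.cumsum(d + shocks, axis=1)  # (n_sims, h)
    lower = np.empty(h)
    upper = np.empty(h)
    tail = (1.0 - level) / 2.0
    for j in range(h):
        log_m = a[:, None] + np.outer(b_path[:, j], k_paths[:, j])
        e0_sims = _e0_columns(np.exp(log_m))
        lower[j], upper[j] = np.quantile(e0_sims, [tail, 1.0 - tail])
    return LifeExpectancyResult(years, point, lower, upper, level, n_sims, seed)
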