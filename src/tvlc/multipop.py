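"""Li-Lee multi-population mortality models (LL, LL-BMS, LL-E, LL-G).

A group of populations shares a common factor plus population-specific
deviations:

    ln m_{x,t,j} = a_{x,j} + B_x K_t + b_{x,j} k_{t,j} + eps_{x,t,j},

where the common component B_x K_t is the chosen single-population model
(LC / BMS / LC-E / LC-G) fitted to the log rates averaged over all the
populations, a_{x,j} are the per-population age means, and the
population-specific pair (b_j, k_j) is the leading SVD factor of the
residual matrix.  Each k_{t,j} is fitted by a stationary AR(1) with
intercept, so its forecasts mean-revert and the populations never
diverge from the common trend (population coherence).  When the common
factor is time-varying (LL-E / LL-G), its loadings B_{x,T+h} come from
the age-coherent constrained VAR, making the forecasts coherent across
ages as well.

Forecasts follow

    ln m_{x,T+h,j} = a_{x,j} + B-term_{x,h} K_{T+h} + b_{x,j} k_{T+h,j},

with the B-term static for LL / LL-BMS and the VAR loading path for
LL-E / LL-G.  Tuning parameters of the time-varying variants are
selected on the averaged population only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .leecarter import LeeCarter, LeeCarterResults
from .surface import MortalitySurface, average_populations
from .tvmodel import ForecastResult, TimeVaryingLeeCarter, Tuning, TuningGrid, TVLCResults

__all__ = ["LiLee", "LiLeeResults", "PopulationFactors"]

_VARIANTS = ("LL", "LL-BMS", "LL-E", "LL-G")


@dataclass
class PopulationFactors:
    """Population-specific parameters of a Li-Lee fit."""

    population_id: str
    a: np.ndarray          # (N,) age means of the population's log rates
    b: np.ndarray          # (N,) idiosyncratic loadings, sum to 1
    k: np.ndarray          # (T,) idiosyncratic index
    phi: float             # AR(1) coefficient
    intercept: float
    sigma: float           # AR(1) innovation s.d.

    @property
    def ar1_stationary(self) -> bool:
        return abs(self.phi) < 1.0

    def forecast_k(self, h: int) -> np.ndarray:
        """Mean recursion k_{T+s} = c + phi k_{T+s-1}."""
        out = np.empty(h)
        k = self.k[-1]
        for s in range(h):
            k = self.intercept + self.phi * k
            out[s] = k
        return out


def _residual_svd_pair(resid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading SVD factor (b, k) of a residual matrix, sum(b) = 1.

    Unlike the Lee-Carter decomposition the index k is not re-centred:
    the residual matrix need not have zero row means and its level
    belongs to k, not to a.
    """
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    u1, v1 = u[:, 0], vt[0]
    colsum = u1.sum()
    if colsum == 0:
        raise np.linalg.LinAlgError("residual loading vector sums to zero")
    if colsum < 0:
        u1, v1 = -u1, -v1
        colsum = -colsum
    return u1 / colsum, s[0] * v1 * colsum


def _fit_ar1(k: np.ndarray) -> tuple[float, float, float]:
    """Least-squares AR(1) with intercept: k_t = c + phi k_{t-1} + e_t."""
    y, x = k[1:], k[:-1]
    X = np.column_stack([np.ones_like(x), x])
    (c, phi), *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - c - phi * x
    dof = max(y.size - 2, 1)
    return float(phi), float(c), float(np.sqrt(resid @ resid / dof))


class LiLee:
    """Li-Lee model for a panel of aligned mortality surfaces.

    Parameters
    ----------
    surfaces : list of MortalitySurface
        At least two populations on identical age/year grids.
    variant : {"LL", "LL-BMS", "LL-E", "LL-G"}
        Which single-population model drives the common factor.
    grid : TuningGrid, optional
        Tuning grids for the time-varying variants.
    """

    def __init__(
        self,
        surfaces: list[MortalitySurface],
        variant: str = "LL",
        grid: TuningGrid | None = None,
        leakage_mode: str = "paper",
    ):
        if len(surfaces) < 2:
            raise ValueError("Li-Lee modelling needs at least 2 populations")
        variant = variant.upper()
        if variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
        for s in surfaces:
            s.require_complete()
        self.surfaces = surfaces
        self.variant = variant
        self.grid = grid
        self.leakage_mode = leakage_mode

    def fit(self, tuning: Tuning | None = None) -> "LiLeeResults":
        avg = average_populations(self.surfaces)
        if self.variant == "LL":
            common = LeeCarter(avg).fit(adjust_drift=True)
        elif self.variant == "LL-BMS":
            common = LeeCarter(avg).fit(adjust_drift=True, select_period=True)
        else:
            kernel = "epanechnikov" if self.variant == "LL-E" else "gaussian"
            common = TimeVaryingLeeCarter(
                avg, kernel=kernel, grid=self.grid, leakage_mode=self.leakage_mode
            ).fit(tuning=tuning)

        # in-sample common component B_x K_t (time-varying loadings for
        # LL-E / LL-G), on the common fitting period
        if isinstance(common, TVLCResults):
            common_component = common.tv.b_t * common.k[None, :]
            common_years = common.surface.years
        else:
            common_component = np.outer(common.b, common.k)
            common_years = common.surface.years

        pops: list[PopulationFactors] = []
        flagged: list[str] = []
        for s in self.surfaces:
            sub = s.window(int(common_years[0]), int(common_years[-1]))
            log_m = sub.log_m
            a_j = log_m.mean(axis=1)
            resid = log_m - a_j[:, None] - common_component
            b_j, k_j = _residual_svd_pair(resid)
            phi, c, sigma = _fit_ar1(k_j)
            factors = PopulationFactors(
                s.population_id, a_j, b_j, k_j, phi, c, sigma
            )
            if not factors.ar1_stationary:
                flagged.append(
                    f"population '{s.population_id}': fitted AR(1) is "
                    f"non-stationary (phi={phi:.3f}); forecasts proceed"
                )
            pops.append(factors)
        return LiLeeResults(
            model=self, common=common, pops=pops, warnings=flagged
        )


@dataclass
class LiLeeResults:
    """Fitted common factor and per-population deviations."""

    model: LiLee
    common: LeeCarterResults | TVLCResults
    pops: list[PopulationFactors]
    warnings: list[str] = field(default_factory=list)

    @property
    def variant(self) -> str:
        return self.model.variant

    def common_forecast_terms(self, h: int) -> tuple[np.ndarray, np.ndarray]:
        """(B-term path (N, h), K_hat (h,)) of the common factor."""
        if isinstance(self.common, TVLCResults):
            return self.common.b_path(h), self.common.base.forecast_k(h)
        B_path = np.tile(self.common.b[:, None], (1, h))
        return B_path, self.common.forecast_k(h)

    def forecast(self, h: int) -> dict[str, ForecastResult]:
        """Per-population h-step forecasts of the log rates."""
        if h < 1:
            raise ValueError("forecast horizon must be >= 1")
        B_path, K_hat = self.common_forecast_terms(h)
        last_year = int(self.common.surface.years[-1])
        years = last_year + np.arange(1, h + 1)
        out: dict[str, ForecastResult] = {}
        for p in self.pops:
            k_j = p.forecast_k(h)
            log_m = p.a[:, None] + B_path * K_hat[None, :] + np.outer(p.b, k_j)
            out[p.population_id] = ForecastResult(
                log_m_hat=log_m,
                b_hat_path=B_path,
                k_hat=K_hat,
                model_tag=self.variant,
                years=years,
                warnings=list(self.warnings),
            )
        return out

    def summary(self) -> str:
        lines = [
            f"Li-Lee model results ({self.variant})",
            "=" * 44,
            f"populations:  {len(self.pops)}",
        ]
        if isinstance(self.common, TVLCResults):
            t = self.common.tuning
            lines.append(
                f"common factor: {self.common.model.model_tag}, bandwidth "
                f"{t.bandwidth:g}, penalties ({t.lambda_alpha:g}, "
                f"{t.lambda_beta:g}, {t.lambda_gamma:g})"
            )
        else:
            lines.append(
                f"common factor: Lee-Carter, drift {self.common.d:+.4f}/yr"
            )
        for p in self.pops:
            flag = "" if p.ar1_stationary else "  [non-stationary]"
            lines.append(
                f"  {p.population_id or '<pop>'}: phi={p.phi:+.3f}, "
                f"c={p.intercept:+.3f}, sigma={p.sigma:.3f}{flag}"
            )
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)

    def factors_frame(self) -> pd.DataFrame:
        rows = [
            {
                "population": p.population_id,
                "phi": p.phi,
                "intercept": p.intercept,
                "sigma": p.sigma,
                "stationary": p.ar1_stationary,
            }
            for p in self.pops
        ]
        return pd.DataFrame(rows)
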