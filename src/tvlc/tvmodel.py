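"""Time-varying Lee-Carter models (LC-E / LC-G): tuning and forecasting.

The model generalises Lee-Carter by letting the age loadings drift:

    ln m_{x,t} = a_x + b_{x,t} k_t + eps_{x,t},
    ln m_{x,T+h} = a_x + b_{x,T+h} k_{T+h},

with b_{x,t} estimated by local-constant kernel smoothing (Epanechnikov
-> LC-E, Gaussian -> LC-G) and forecast by the age-coherent constrained
VAR.  The kernel bandwidth and the three VAR smoothness penalties are
tuning parameters selected on a hold-out sample: the last third of the
years is reserved, every grid combination is scored by the root mean
squared forecasting error (RMSFE) of the logged rates over that test
window, and the minimiser is kept (ties broken towards the larger
bandwidth, then larger penalties — the smoother model).

The full pipeline is:

1. fit the static Lee-Carter model on the full sample (Poisson-adjusted
   drift) for a_x, k_T and d;
2. estimate b_{x,t} on the training sample with the chosen kernel and fit
   the constrained VAR to b_{x,t} - 1/N;
3. select (bandwidth, lambda_a, lambda_b, lambda_g) by grid search on the
   hold-out RMSFE;
4. refit the kernel loadings and the VAR on the full sample at the
   selected tuning;
5. forecast b_{x,T+h} from the VAR and assemble the log rates with the
   step-1 a_x and k_{T+h} = k_T + h d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coherent import CoherentVAR, center_bstar
from .kernels import KernelSpec, TVFit, fit_tv_bx
from .leecarter import LeeCarter, LeeCarterResults
from .surface import MortalitySurface

__all__ = [
    "TuningGrid",
    "ForecastResult",
    "holdout_split",
    "rmsfe",
    "rmsfe_h",
    "TimeVaryingLeeCarter",
    "TVLCResults",
    "fit_forecast",
]

logger = logging.getLogger(__name__)

#: kernel name behind each model tag
MODEL_KERNELS = {"lc-e": "epanechnikov", "lc-g": "gaussian"}


@dataclass
class TuningGrid:
    """Search grids for the bandwidth and the shared penalty level.

    The default bandwidth grid spans both plausible bandwidth regimes
    (well below 1 on the rescaled-time scale up to effectively-uniform
    weighting); penalties are searched with a shared value for
    lambda_alpha = lambda_beta = lambda_gamma first, optionally followed
    by one pass of per-penalty coordinate refinement.
    """

    bandwidths: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8)
    lambda_grid: tuple[float, ...] = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)
    refine: bool = True

    def __post_init__(self) -> None:
        self.bandwidths = tuple(sorted(float(b) for b in self.bandwidths))
        self.lambda_grid = tuple(sorted(float(l) for l in self.lambda_grid))
        if not self.bandwidths or not self.lambda_grid:
            raise ValueError("grids must be non-empty")
        if self.bandwidths[0] <= 0:
            raise ValueError("bandwidths must be positive")
        if self.lambda_grid[0] < 0:
            raise ValueError("penalties must be nonnegative")


@dataclass
class Tuning:
    """A selected tuning-parameter combination."""

    bandwidth: float
    lambda_alpha: float
    lambda_beta: float
    lambda_gamma: float

    @property
    def lambdas(self) -> tuple[float, float, float]:
        return (self.lambda_alpha, self.lambda_beta, self.lambda_gamma)


@dataclass
class ForecastResult:
    """An h-step mortality forecast and the paths behind it."""

    log_m_hat: np.ndarray    # (N, h)
    b_hat_path: np.ndarray   # (N, h); each column sums to 1
    k_hat: np.ndarray        # (h,); affine in the horizon
    model_tag: str
    tuning: Tuning | None = None
    years: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


def holdout_split(T: int) -> tuple[np.ndarray, np.ndarray]:
    """Partition 0-based year indices into training and hold-out ranges.

    The hold-out sample is the last third of the years: with the 1-based
    boundary floor(2T/3), training covers years 1..boundary-1 and the
    test window boundary..T.
    """
    if T < 9:
        raise ValueError(f"need T >= 9 years to split, got {T}")
    boundary = (2 * T) // 3  # 1-based first test year
    return np.arange(boundary - 1), np.arange(boundary - 1, T)


def rmsfe(pred: np.ndarray, actual: np.ndarray) -> float:
    """Root mean squared forecasting error over all age-horizon cells
    (logged-rate scale)."""
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if pred.shape != actual.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    return float(np.sqrt(np.mean((pred - actual) ** 2)))


def rmsfe_h(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Cumulative-horizon RMSFE_h, h = 1..H.

    RMSFE_h aggregates squared errors over all ages and the first h
    forecast steps, so RMSFE_H is the overall accuracy measure.
    """
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if pred.shape != actual.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    sq = (pred - actual) ** 2
    N = sq.shape[0]
    cum = np.cumsum(sq.sum(axis=0))
    h = np.arange(1, sq.shape[1] + 1)
    return np.sqrt(cum / (N * h))


class TimeVaryingLeeCarter:
    """LC-E / LC-G model for one complete mortality surface.

    Parameters
    ----------
    surface : MortalitySurface
    kernel : {"gaussian", "epanechnikov"}
    grid : TuningGrid, optional
    leakage_mode : {"paper", "strict"}
        "paper" uses the full-sample a_x, k and d inside the tuning loop
        (the literal 5-step procedure); "strict" refits them on the
        training range so no hold-out information leaks into tuning.

    Examples
    --------
    >>> res = TimeVaryingLeeCarter(surface, kernel="gaussian").fit()
    >>> fc = res.forecast(h=30)
    """

    def __init__(
        self,
        surface: MortalitySurface,
        kernel: str = "gaussian",
        grid: TuningGrid | None = None,
        leakage_mode: str = "paper",
    ):
        surface.require_complete()
        if kernel not in ("gaussian", "epanechnikov"):
            raise ValueError(f"unknown kernel {kernel!r}")
        if leakage_mode not in ("paper", "strict"):
            raise ValueError(f"leakage_mode must be 'paper' or 'strict'")
        if surface.n_years < 9:
            raise ValueError("tuning requires at least 9 years of data")
        self.surface = surface
        self.kernel_name = kernel
        self.grid = grid if grid is not None else TuningGrid()
        self.leakage_mode = leakage_mode
        self.model_tag = "LC-G" if kernel == "gaussian" else "LC-E"

    # -- tuning ---------------------------------------------------------
    def _holdout_score(
        self,
        bandwidth: float,
        lambdas: tuple[float, float, float],
        context: dict,
    ) -> float:
        """RMSFE of the hold-out window at one tuning combination."""
        tv = context["tv_cache"].get(bandwidth)
        if tv is None:
            tv = fit_tv_bx(
                context["train_surface"],
                context["base"],
                KernelSpec(self.kernel_name, bandwidth),
            )
            context["tv_cache"][bandwidth] = tv
        var = CoherentVAR(center_bstar(tv)).fit(lambdas)
        H = context["test_idx"].size
        b_path = var.forecast_b(H)
        k_hat = context["k_train_end"] + context["d"] * np.arange(1, H + 1)
        pred = context["a"][:, None] + b_path * k_hat[None, :]
        return rmsfe(pred, context["actual"])

    def select_tuning(
        self, base_full: LeeCarterResults | None = None
    ) -> tuple[Tuning, list[dict]]:
        """Grid-search the tuning parameters on the hold-out sample.

        Returns the selected combination and a log of every evaluation
        (bandwidth, lambdas, score or failure reason).
        """
        surface = self.surface
        T = surface.n_years
        train_idx, test_idx = holdout_split(T)
        train_surface = surface.window(
            int(surface.years[train_idx[0]]), int(surface.years[train_idx[-1]])
        )
        if self.leakage_mode == "paper":
            base = base_full if base_full is not None else LeeCarter(surface).fit(
                adjust_drift=True
            )
            a, d = base.a, base.d
            k_train_end = base.k[train_idx[-1]]
        else:
            base = LeeCarter(train_surface).fit(adjust_drift=True)
            a, d = base.a, base.d
            k_train_end = base.k[-1]
        context = {
            "train_surface": train_surface,
            "base": base,
            "a": a,
            "d": d,
            "k_train_end": k_train_end,
            "test_idx": test_idx,
            "actual": surface.log_m[:, test_idx],
            "tv_cache": {},
        }

        trace: list[dict] = []

        def evaluate(bw: float, lambdas: tuple[float, float, float]) -> float | None:
            try:
                score = self._holdout_score(bw, lambdas, context)
            except (ValueError, np.linalg.LinAlgError, ZeroDivisionError) as exc:
                logger.info(
                    "tuning combination bw=%g lambdas=%s failed: %s", bw, lambdas, exc
                )
                trace.append({"bandwidth": bw, "lambdas": lambdas, "error": str(exc)})
                return None
            trace.append({"bandwidth": bw, "lambdas": lambdas, "score": score})
            return score

        # stage 1: shared penalty level
        best: tuple[float, Tuning] | None = None
        for bw in self.grid.bandwidths:
            for lam in self.grid.lambda_grid:
                score = evaluate(bw, (lam, lam, lam))
                if score is None:
                    continue
                cand = Tuning(bw, lam, lam, lam)
                if best is None or _better(score, cand, best):
                    best = (score, cand)
        if best is None:
            raise RuntimeError("every tuning combination failed to fit")

        # stage 2: one pass of per-penalty coordinate refinement
        if self.grid.refine:
            score0, tuning = best
            lams = list(tuning.lambdas)
            for slot in range(3):
                for lam in self.grid.lambda_grid:
                    trial = lams.copy()
                    trial[slot] = lam
                    score = evaluate(tuning.bandwidth, tuple(trial))
                    if score is None:
                        continue
                    cand = Tuning(tuning.bandwidth, *trial)
                    if _better(score, cand, best):
                        best = (score, cand)
                        lams = trial
        return best[1], trace

    # -- fitting --------------------------------------------------------
    def fit(self, tuning: Tuning | None = None) -> "TVLCResults":
        """Run the full pipeline; pass ``tuning`` to skip the grid search."""
        base = LeeCarter(self.surface).fit(adjust_drift=True)
        trace: list[dict] = []
        if tuning is None:
            tuning, trace = self.select_tuning(base_full=base)
        tv = fit_tv_bx(
            self.surface, base, KernelSpec(self.kernel_name, tuning.bandwidth)
        )
        var = CoherentVAR(center_bstar(tv)).fit(tuning.lambdas)
        warnings: list[str] = []
        if not var.is_stationary:
            warnings.append(
                f"fitted VAR is non-stationary (spectral radius "
                f"{var.spectral_radius:.3f}); long-run forecasts may not be "
                f"age coherent"
            )
        return TVLCResults(
            model=self,
            base=base,
            tv=tv,
            var=var,
            tuning=tuning,
            tuning_trace=trace,
            warnings=warnings,
        )


def _better(
    score: float, cand: Tuning, best: tuple[float, Tuning], rel_tol: float = 1e-9
) -> bool:
    """Is (score, cand) preferable to the incumbent?  Lower score wins;
    near-ties go to the larger bandwidth, then larger penalties."""
    best_score, best_t = best
    if score < best_score - rel_tol * (1.0 + abs(best_score)):
        return True
    if score > best_score + rel_tol * (1.0 + abs(best_score)):
        return False
    key_new = (cand.bandwidth, cand.lambda_alpha, cand.lambda_beta, cand.lambda_gamma)
    key_old = (best_t.bandwidth, best_t.lambda_alpha, best_t.lambda_beta,
               best_t.lambda_gamma)
    return key_new > key_old


@dataclass
class TVLCResults:
    """Fitted LC-E / LC-G model: static base fit, kernel loadings,
    coherent VAR and the selected tuning."""

    model: TimeVaryingLeeCarter
    base: LeeCarterResults
    tv: TVFit
    var: "CoherentVARResults"
    tuning: Tuning
    tuning_trace: list[dict]
    warnings: list[str]

    # delegate the static-parameter surface to the step-1 fit
    @property
    def a(self) -> np.ndarray:
        return self.base.a

    @property
    def k(self) -> np.ndarray:
        return self.base.k

    @property
    def d(self) -> float:
        return self.base.d

    @property
    def sigma_e(self) -> float:
        return self.base.sigma_e

    @property
    def surface(self) -> MortalitySurface:
        return self.model.surface

    def b_path(self, h: int) -> np.ndarray:
        """Forecast loadings b_{x,T+h}, each horizon summing to 1."""
        return self.var.forecast_b(h)

    def forecast(self, h: int) -> ForecastResult:
        """Mean forecast: ln m_{x,T+h} = a_x + b_{x,T+h} (k_T + h d)."""
        if h < 1:
            raise ValueError("forecast horizon must be >= 1")
        b_path = self.b_path(h)
        k_hat = self.base.forecast_k(h)
        last_year = int(self.surface.years[-1])
        return ForecastResult(
            log_m_hat=self.a[:, None] + b_path * k_hat[None, :],
            b_hat_path=b_path,
            k_hat=k_hat,
            model_tag=self.model.model_tag,
            tuning=self.tuning,
            years=last_year + np.arange(1, h + 1),
            warnings=list(self.warnings),
        )

    def summary(self) -> str:
        t = self.tuning
        lines = [
            f"{self.model.model_tag} (time-varying Lee-Carter) results",
            "=" * 48,
            f"population:        {self.surface.population_id or '<unnamed>'}",
            f"ages x years:      {self.surface.n_ages} x {self.surface.n_years}",
            f"kernel:            {self.model.kernel_name}",
            f"bandwidth:         {t.bandwidth:g} (rescaled-time scale)",
            f"penalties:         la={t.lambda_alpha:g}, lb={t.lambda_beta:g}, "
            f"lg={t.lambda_gamma:g}",
            f"drift d:           {self.d:+.4f} per year",
            f"innovation s.d.:   {self.sigma_e:.4f}",
            f"VAR spectral rad.: {self.var.spectral_radius:.4f}",
        ]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def fit_forecast(
    surface: MortalitySurface,
    model_tag: str,
    h: int,
    grid: TuningGrid | None = None,
    leakage_mode: str = "paper",
    tuning: Tuning | None = None,
) -> ForecastResult:
    """Fit any single-population model and forecast ``h`` steps.

    ``model_tag`` is one of ``lc`` (Lee-Carter with Poisson-adjusted
    drift), ``bms`` (additionally the data-driven fitting period),
    ``lc-e`` or ``lc-g``.
    """
    tag = model_tag.lower()
    if tag in ("lc", "bms"):
        res = LeeCarter(surface).fit(adjust_drift=True, select_period=(tag == "bms"))
        k_hat = res.forecast_k(h)
        b_path = np.tile(res.b[:, None], (1, h))
        last_year = int(res.surface.years[-1])
        return ForecastResult(
            log_m_hat=res.forecast(h),
            b_hat_path=b_path,
            k_hat=k_hat,
            model_tag=tag.upper(),
            years=last_year + np.arange(1, h + 1),
        )
    if tag in MODEL_KERNELS:
        model = TimeVaryingLeeCarter(
            surface, kernel=MODEL_KERNELS[tag], grid=grid, leakage_mode=leakage_mode
        )
        return model.fit(tuning=tuning).forecast(h)
    raise ValueError(f"unknown model tag {model_tag!r}")
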