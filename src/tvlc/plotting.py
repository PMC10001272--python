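"""Basic plots: loading rotation, forecast fans and e0 paths.

Each function accepts and returns a matplotlib Axes so plots compose
into user figures; matplotlib is imported lazily.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_loadings", "plot_e0", "plot_log_rate_forecast"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_loadings(tv_or_matrix, ages=None, years=None, every: int = 10, ax=None):
    """Age-loading curves b_{x,t} for a subset of years.

    Parameters
    ----------
    tv_or_matrix : TVFit, TVLCResults or (N, T) array
    every : int
        Plot one curve per ``every`` years.
    """
    b_t = getattr(tv_or_matrix, "b_t", None)
    if b_t is None:
        tv = getattr(tv_or_matrix, "tv", None)
        b_t = tv.b_t if tv is not None else np.asarray(tv_or_matrix, float)
    ax = _get_ax(ax)
    N, T = b_t.shape
    x = np.arange(N) if ages is None else np.asarray(ages)
    yrs = np.arange(T) if years is None else np.asarray(years)
    for j in range(0, T, max(every, 1)):
        ax.plot(x, b_t[:, j], label=str(yrs[j]), alpha=0.8)
    ax.axhline(1.0 / N, color="grey", ls=":", lw=1, label="1/N")
    ax.set_xlabel("age")
    ax.set_ylabel("loading $b_{x,t}$")
    ax.legend(fontsize="small", title="year")
    return ax


def plot_e0(result, ax=None, **kwargs):
    """Life-expectancy path with its prediction band when present."""
    ax = _get_ax(ax)
    ax.plot(result.years, result.e0_point, **kwargs)
    if result.e0_lower is not None:
        ax.fill_between(
            result.years, result.e0_lower, result.e0_upper, alpha=0.25,
            label=f"{100 * result.level:.0f}% PI",
        )
    ax.set_xlabel("year")
    ax.set_ylabel("life expectancy at birth (years)")
    return ax


def plot_log_rate_forecast(forecast, ages=None, horizons=(1, -1), ax=None):
    """Forecast log-rate age profiles at selected horizons."""
    ax = _get_ax(ax)
    log_m = forecast.log_m_hat
    x = np.arange(log_m.shape[0]) if ages is None else np.asarray(ages)
    years = forecast.years
    for h in horizons:
        label = str(years[h]) if years is not None else f"h={h}"
        ax.plot(x, log_m[:, h], label=label)
    ax.set_xlabel("age")
    ax.set_ylabel(r"$\ln \hat m_{x,t}$")
    ax.legend(fontsize="small")
    return ax
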