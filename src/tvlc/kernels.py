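"""Local-constant (Nadaraya-Watson) kernel machinery for time-varying
age effects.

Calendar time is rescaled to tau = t/T in (0, 1]; the bandwidth ``b`` is
expressed on that scale, so b >> 1 approaches uniform weights and the
static Lee-Carter fit.  For each target year t the weighted SVD of the
centred log-rate matrix, with column s scaled by sqrt(K_b(tau_s - tau)),
yields that year's age-loading vector b_{x,t}, rescaled to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .leecarter import LeeCarterResults
from .surface import MortalitySurface

__all__ = ["KernelSpec", "kernel_weights", "TVFit", "fit_tv_bx"]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class KernelSpec:
    """A named kernel and its bandwidth on the rescaled-time scale."""

    name: str = "gaussian"
    bandwidth: float = 0.3

    def __post_init__(self) -> None:
        if self.name not in ("gaussian", "epanechnikov"):
            raise ValueError(f"unknown kernel {self.name!r}")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")

    def __call__(self, u: np.ndarray) -> np.ndarray:
        """Kernel weight K_b(u) at rescaled-time lag u (unnormalised)."""
        z = np.asarray(u, float) / self.bandwidth
        if self.name == "gaussian":
            return np.exp(-0.5 * z * z) / (_SQRT_2PI * self.bandwidth)
        return 0.75 / self.bandwidth * np.maximum(0.0, 1.0 - z * z)


def kernel_weights(kernel: KernelSpec, t: int, T: int) -> np.ndarray:
    """Weights K_b(tau_s - tau), s = 1..T, for target year t (1-based)."""
    if not 1 <= t <= T:
        raise ValueError(f"target index t={t} outside 1..{T}")
    tau = t / T
    tau_s = np.arange(1, T + 1) / T
    return kernel(tau_s - tau)


@dataclass
class TVFit:
    """Time-varying age effects b_{x,t} with their estimation metadata."""

    b_t: np.ndarray          # (N, T); every column sums to 1
    base: LeeCarterResults   # static fit supplying a_x and the sign reference
    kernel: KernelSpec

    @property
    def n_ages(self) -> int:
        return self.b_t.shape[0]

    def total_variation(self) -> np.ndarray:
        """Per-age total variation of b_{x,.} over time (roughness measure)."""
        return np.abs(np.diff(self.b_t, axis=1)).sum(axis=1)


def fit_tv_bx(
    surface: MortalitySurface, base: LeeCarterResults, kernel: KernelSpec
) -> TVFit:
    """Estimate b_{x,t} by local-constant weighted SVD.

    For each year t the columns of the centred log-rate matrix
    (ln m_{x,s} - a_x) are scaled by sqrt of the kernel weights and the
    leading left singular vector, oriented to correlate positively with
    the static loading vector, is rescaled to sum to 1.  Boundary years
    use the same (one-sided, truncated) weights.
    """
    surface.require_complete("kernel estimation")
    log_m = surface.log_m
    centred = log_m - base.a[:, None]
    T = surface.n_years
    b_t = np.empty((surface.n_ages, T))
    for t in range(1, T + 1):
        w = kernel_weights(kernel, t, T)
        if not np.any(w > 0):
            raise ValueError(
                f"all kernel weights vanish at year index {t}; "
                f"bandwidth {kernel.bandwidth} is pathologically small"
            )
        weighted = centred * np.sqrt(w)[None, :]
        u, s, _ = np.linalg.svd(weighted, full_matrices=False)
        if s[0] <= 0:
            raise ValueError(f"degenerate weighted window at year index {t}")
        v = u[:, 0]
        if v @ base.b < 0:
            v = -v
        total = v.sum()
        if total == 0:
            raise ValueError(f"loading vector sums to zero at year index {t}")
        b_t[:, t - 1] = v / total
    return TVFit(b_t=b_t, base=base, kernel=kernel)
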