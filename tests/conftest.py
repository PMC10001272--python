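import numpy as np
import pytest

from tvlc import LeeCarter, MortalitySurface, SyntheticSpec, generate_surface


@pytest.fixture(scope="session")
def small_rotating():
    """Small rotating-truth surface with noise (N=20, T=30)."""
    spec = SyntheticSpec(N=20, T=30, seed=11)
    surface, truth = generate_surface(spec)
    return spec, surface, truth


@pytest.fixture(scope="session")
def small_noiseless_static():
    """Noiseless static-loading surface: exactly rank-1 in the log scale."""
    spec = SyntheticSpec(
        N=20, T=30, rotation="none", sigma_e=0.0, sigma_eps=0.0, seed=3
    )
    surface, truth = generate_surface(spec)
    return spec, surface, truth


@pytest.fixture(scope="session")
def small_noiseless_rotating():
    """Noiseless surface whose b_{x,t} drifts linearly between two shapes."""
    spec = SyntheticSpec(
        N=20, T=40, rotation="linear", sigma_e=0.0, sigma_eps=0.0, seed=4
    )
    surface, truth = generate_surface(spec)
    return spec, surface, truth


@pytest.fixture(scope="session")
def lc_fit(small_rotating):
    _, surface, _ = small_rotating
    return LeeCarter(surface).fit()


def make_surface(log_m: np.ndarray, first_year: int = 2000) -> MortalitySurface:
    log_m = np.asarray(log_m, float)
    n, t = log_m.shape
    return MortalitySurface(np.arange(n), first_year + np.arange(t), np.exp(log_m))
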