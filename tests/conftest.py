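import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chronolux.colorimetry import PhotoreceptorBasis
from chronolux.simulate import SessionDesign

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ODDBALL_DURATIONS = np.array(
    [750.0, 833.0, 900.0, 983.0, 1050.0, 1133.0, 1200.0, 1283.0, 1350.0]
)


@pytest.fixture(scope="session")
def basis() -> PhotoreceptorBasis:
    return PhotoreceptorBasis.default()


@pytest.fixture(scope="session")
def design() -> SessionDesign:
    return SessionDesign()


@pytest.fixture(scope="session")
def durations() -> np.ndarray:
    return ODDBALL_DURATIONS.copy()


def grid_search_weibull_mle(d, k, n, alpha_grid=None, beta_grid=None):
    """Brute-force MLE on an (alpha, beta) grid — independent oracle."""
    A = np.arange(600.0, 1600.0, 0.5) if alpha_grid is None else alpha_grid
    B = np.arange(1.0, 40.0, 0.05) if beta_grid is None else beta_grid
    f = -np.expm1(-((d[None, None, :] / A[:, None, None]) ** B[None, :, None]))
    f = np.clip(f, 1e-12, 1 - 1e-12)
    ll = np.sum(k * np.log(f) + (n - k) * np.log1p(-f), axis=2)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return A[i], B[j]
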