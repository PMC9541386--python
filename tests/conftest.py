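import numpy as np
import pytest
from scipy.integrate import quad

from mphpk.release_models import release_rate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def convolution_quadrature(release, kel: float, dose: float, t: float) -> float:
    """Independent oracle for the convolution model: adaptive quadrature of
    Dose·∫₀ᵗ f(τ)·exp(−kel·(t−τ)) dτ."""
    if t <= 0:
        return 0.0
    val, _ = quad(
        lambda tau: release_rate(release, tau) * np.exp(-kel * (t - tau)),
        0.0,
        t,
        limit=300,
        epsabs=1e-12,
        epsrel=1e-12,
    )
    return dose * val
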