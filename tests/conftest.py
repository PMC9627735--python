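import numpy as np
import pytest

from fibrilkit import KineticParameters


@pytest.fixture
def ab42_params() -> KineticParameters:
    """Realistic unseeded parameter set at 3 umol/L monomer."""
    return KineticParameters(k_n=3e-4, k_plus=3e6, k_2=1e4, m0=3e-6)


@pytest.fixture
def baseline_params() -> KineticParameters:
    """Generator baseline: half time ~3 h at 3 umol/L."""
    return KineticParameters(k_n=3e-5, k_plus=3e6, k_2=2e3, m0=3e-6)


def secondary_dominated_grid(n: int, seed: int = 0):
    """Log-uniform parameter sets spanning 3 decades in each rate constant.

    Centered on the regime the integrated rate law is designed for
    (secondary-pathway dominated, lambda/kappa <= 0.1 at 3 umol/L).
    """
    rng = np.random.default_rng(seed)
    k_n = 10.0 ** rng.uniform(np.log10(3e-7), np.log10(3e-4), n)
    k_plus = 10.0 ** rng.uniform(np.log10(3e5), np.log10(3e8), n)
    k_2 = 10.0 ** rng.uniform(np.log10(1e4), np.log10(1e7), n)
    return [
        KineticParameters(k_n=a, k_plus=b, k_2=c, m0=3e-6)
        for a, b, c in zip(k_n, k_plus, k_2)
    ]
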