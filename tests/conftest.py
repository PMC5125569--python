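from dataclasses import replace

import numpy as np
import pytest

from dendrifield.params import (
    BiophysicalParams,
    SpikeMechanismParams,
    derive_cable_params,
    lif_limit,
)


@pytest.fixture(scope="session")
def bio():
    return BiophysicalParams()


@pytest.fixture(scope="session")
def cable(bio):
    return derive_cable_params(bio)


@pytest.fixture(scope="session")
def eif():
    return SpikeMechanismParams()


@pytest.fixture(scope="session")
def lif(eif):
    return lif_limit(eif)


@pytest.fixture(scope="session")
def nospike(lif):
    """LIF spike params with the threshold pushed out of reach (subthreshold studies)."""
    return replace(lif, V_T=0.9, V_s=1.0, V_r_prime=0.45)


@pytest.fixture(scope="session")
def nospike_eif(eif):
    """EIF params kept, but tests using this must drive weakly enough not to spike."""
    return eif


def poisson_train(rng: np.random.Generator, rate_hz: float, duration_ms: float):
    """Homogeneous Poisson spike train helper (times in ms)."""
    n = rng.poisson(rate_hz * duration_ms * 1e-3)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))
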