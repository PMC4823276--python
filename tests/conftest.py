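import numpy as np
import pytest

from ebcpnn.params import (
    BCPNNParams, DerivedCoefficients, VALIDATION_AMPA, VALIDATION_NEURON,
)
from ebcpnn.kernel import SpikeTrain


@pytest.fixture(scope="session")
def val_params() -> BCPNNParams:
    return VALIDATION_AMPA


@pytest.fixture(scope="session")
def val_coeffs(val_params) -> DerivedCoefficients:
    return DerivedCoefficients.from_params(val_params)


def poisson_pair(seed: int, rate_i: float, rate_j: float, t_end: float,
                 grid: float = 0.01) -> tuple[SpikeTrain, SpikeTrain]:
    """A pair of independent Poisson trains snapped to an integration grid
    (so the time-driven oracle sees identical spike times)."""
    rng = np.random.default_rng(seed)
    out = []
    for rate in (rate_i, rate_j):
        n = rng.poisson(rate * 1e-3 * (t_end - 2))
        t = np.unique(np.round(np.sort(
            rng.uniform(1.0, t_end - 1.0, n)) / grid)) * grid
        out.append(SpikeTrain(t))
    return out[0], out[1]
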