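import math

import numpy as np
import pytest

from residuecrop.dissipation import ResidueObservation, ResidueSeries
from residuecrop.synthetic import generate_model_fixture
from residuecrop.uptake import build_rate_matrix, default_time_grid, simulate

LN2 = math.log(2.0)

#: The dissipation-trial sampling schedule (2 h encoded as 0.083 d).
SCHEDULE = (0.083, 1.0, 3.0, 5.0, 7.0, 14.0, 21.0, 30.0)


def exponential_series(
    c0: float,
    k: float,
    times=SCHEDULE,
    matrix: str = "straw",
    site: str = "site_X",
    loq: float = 0.01,
) -> ResidueSeries:
    """Noiseless first-order series C(t) = c0 exp(-k t)."""
    observations = [
        ResidueObservation(
            time_days=t, concentration=c0 * math.exp(-k * t), loq=loq
        )
        for t in times
    ]
    return ResidueSeries(site_id=site, matrix=matrix, observations=observations)


@pytest.fixture(scope="session")
def diflufenican_params():
    return generate_model_fixture("diflufenican_like")


@pytest.fixture(scope="session")
def flufenacet_params():
    return generate_model_fixture("flufenacet_like")


@pytest.fixture(scope="session")
def diflufenican_sim(diflufenican_params):
    """Foliar-route simulation of the diflufenican-like fixture."""
    K = build_rate_matrix(diflufenican_params)
    return simulate(K, diflufenican_params.application_split, default_time_grid())


def random_rate_matrix(rng: np.random.Generator, n_states: int = 9) -> np.ndarray:
    """Random proper rate matrix: non-negative off-diagonals (single-process
    rates below ~5/day), zero column sums, absorbing last (sink) state."""
    K = rng.uniform(0.0, 5.0 / n_states, size=(n_states, n_states))
    K *= rng.random(size=K.shape) < 0.5  # sparse-ish transfer structure
    K[:, -1] = 0.0  # nothing leaves the sink
    np.fill_diagonal(K, 0.0)
    for j in range(n_states):
        K[j, j] = -K[:, j].sum()
    return K
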