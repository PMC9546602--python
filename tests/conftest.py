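import numpy as np
import pytest

from quadbias import (
    BiasDirection,
    QuadParameters,
    QuadSpecification,
    simulate_counts,
)
from quadbias.synthetic_data import fixture_small


@pytest.fixture(scope="session")
def outgroup_spec():
    return QuadSpecification(BiasDirection.OUTGROUP_BIAS)


@pytest.fixture(scope="session")
def ingroup_spec():
    return QuadSpecification(BiasDirection.INGROUP_BIAS)


@pytest.fixture(scope="session")
def fixture_sessions():
    return fixture_small()


@pytest.fixture(scope="session")
def reference_params():
    """Moderate, well-separated process parameters used across tests."""
    return QuadParameters(0.25, 0.10, 0.85, 0.50, 0.55)


def simulate_participants(spec, means, concentration, n_participants,
                          trials_per_cell, seed):
    """Draw per-participant theta from Betas and simulate count tables."""
    rng = np.random.default_rng(seed)
    means = np.asarray(means)
    tables = []
    thetas = []
    for _ in range(n_participants):
        theta = rng.beta(means * concentration, (1 - means) * concentration)
        thetas.append(theta)
        tables.append(
            simulate_counts(QuadParameters.from_array(theta), spec,
                            trials_per_cell, seed=rng)
        )
    return tables, np.asarray(thetas)
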