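import numpy as np
import pandas as pd
import pytest

from nestedvar import SimulationParams, canonical_design, simulate_experiment


@pytest.fixture(scope="session")
def design():
    return canonical_design()


@pytest.fixture(scope="session")
def default_sim():
    """One default paired simulation shared across tests (seed 1)."""
    params = SimulationParams(seed=1)
    truth, counts, arrays = simulate_experiment(params)
    return params, truth, counts, arrays


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_profile(rng, n=16, scale=1.0):
    return rng.normal(0.0, scale, n)


@pytest.fixture()
def toy_counts(design):
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.poisson(50.0, size=(5, 16)),
        index=[f"g{i}" for i in range(5)],
        columns=design.samples,
    )
    from nestedvar import ExpressionMatrix

    return ExpressionMatrix(values, "counts")
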