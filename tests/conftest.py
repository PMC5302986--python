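import numpy as np
import pandas as pd
import pytest

from mirlink.synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_predictions,
    simulate_truth,
)


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter simulation shared across read-only tests."""
    config = SimulationConfig(seed=1)
    truth = simulate_truth(config)
    sim = simulate_expression(truth, config)
    predictions = simulate_predictions(truth, config)
    return config, truth, sim, predictions


@pytest.fixture()
def noiseless_config():
    """Tiny noise-free, bias-free setup with one strong edge."""
    return SimulationConfig(
        seed=7,
        n_mirnas=5,
        n_genes=10,
        n_edges=1,
        cp_noise_sd=0.0,
        expr_noise_sd=0.0,
        cp_bias_amplitude=0.0,
        strength_low=1.0,
        strength_high=1.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_matrix(values, features=None, samples=None) -> pd.DataFrame:
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=features, columns=samples)
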