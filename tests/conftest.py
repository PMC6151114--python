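import numpy as np
import pandas as pd
import pytest

from brtsdm import (
    EnvGrid,
    ResponseRamp,
    TruthSpec,
    make_env_grid,
    make_true_suitability,
)


@pytest.fixture(scope="session")
def small_env() -> EnvGrid:
    """40x40 landscape with two correlated blocks and one independent pair."""
    return make_env_grid(
        40, 40,
        block_spec=[(2, 0.9), (2, 0.9), (2, 0.0)],
        autocorr_range=2.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_truth() -> TruthSpec:
    return TruthSpec(
        response_functions={
            "b0v0": ResponseRamp(location=0.0, steepness=5.0, amplitude=5.0),
            "b1v0": ResponseRamp(location=0.0, steepness=5.0, amplitude=5.0),
        },
        intercept=-7.0,
    )


@pytest.fixture(scope="session")
def small_suitability(small_env, small_truth) -> np.ndarray:
    return make_true_suitability(small_env, small_truth)


def make_binary_dataset(n: int = 300, seed: int = 0, n_noise: int = 2) -> pd.DataFrame:
    """Two informative predictors plus noise columns, Bernoulli labels."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    logit = 1.5 * x1 - 2.0 * (x2 > 0.3) + 0.2
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    data = {"x1": x1, "x2": x2}
    for j in range(n_noise):
        data[f"noise{j}"] = rng.normal(size=n)
    data["label"] = y.astype(int)
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def binary_data() -> pd.DataFrame:
    return make_binary_dataset()
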