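import numpy as np
import pandas as pd
import pytest

from difnet import ExpressionMatrix, SimulationConfig


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """Six genes x six samples, two conditions, hand-set values."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.uniform(1.0, 100.0, size=(6, 6)),
        index=[f"g{i}" for i in range(1, 7)],
        columns=[f"s{i}" for i in range(1, 7)],
    )
    conditions = {f"s{i}": ("ctrl" if i <= 3 else "pert") for i in range(1, 7)}
    return ExpressionMatrix(values=values, conditions=conditions)


@pytest.fixture
def hub_config() -> SimulationConfig:
    """The 200-gene single-hub configuration used across network tests."""
    return SimulationConfig(
        n_genes=200,
        n_samples_per_condition=30,
        n_modules=1,
        module_size=10,
        n_hub_genes=1,
        hub_degree=15,
        rewire_fraction=0.9,
        de_fraction=0.0,
        within_module_corr=0.8,
        noise_sd=0.5,
        seed=1,
    )
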