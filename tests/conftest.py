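import numpy as np
import pandas as pd
import pytest

from seasonet.model import ConditionKey, ExpressionMatrix

C_WET = ConditionKey("cortex", "wet")


def make_matrix(series: dict[str, list[float]], condition: ConditionKey = C_WET) -> ExpressionMatrix:
    """Build a small expression matrix from per-gene series."""
    values = pd.DataFrame.from_dict(series, orient="index", dtype=float)
    values.columns = range(values.shape[1])
    values.index.name = "gene_id"
    return ExpressionMatrix(condition=condition, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-noise synthetic dataset, shared across tests."""
    from seasonet.synthetic import SynthConfig, generate_dataset

    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_dataset():
    from seasonet.synthetic import SynthConfig, generate_dataset

    return generate_dataset(SynthConfig(seed=7, noise_sd=0.0))
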