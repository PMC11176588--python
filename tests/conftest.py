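import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from xtalk.expression import ExpressionDataset
from xtalk.synthetic import SyntheticConfig, generate_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dataset(
    n_genes: int = 6,
    n_per_state: int = 5,
    seed: int = 0,
    dataset_id: str = "TOY",
) -> ExpressionDataset:
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"N{i}" for i in range(n_per_state)] + [f"T{i}" for i in range(n_per_state)]
    states = pd.Series(
        ["normal"] * n_per_state + ["tumor"] * n_per_state, index=samples, name="state"
    )
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, (n_genes, 2 * n_per_state)), index=genes, columns=samples
    )
    return ExpressionDataset(dataset_id, values, states)


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    return make_dataset()


@pytest.fixture(scope="session")
def default_study():
    return generate_study(SyntheticConfig(), seed=11)
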