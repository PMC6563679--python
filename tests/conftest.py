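import numpy as np
import pandas as pd
import pytest

from dcoexnet import simdata


@pytest.fixture(scope="session")
def planted_dataset():
    """Small cohort with one 15-gene block strongly co-expressed in the
    non-invasive group only, DEG effects covering the block."""
    config = simdata.SimConfig(
        n_genes=400,
        planted_modules=[(15, 0.9, 0.1)],
        deg_fraction=0.1,
        fc_effect=1.5,
        seed=42,
    )
    expression, metadata, truth = simdata.generate_expression(config)
    return config, expression, metadata, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Cohort with no planted correlation structure and no DEGs."""
    config = simdata.SimConfig(n_genes=300, seed=7)
    expression, metadata, truth = simdata.generate_expression(config)
    return config, expression, metadata, truth


@pytest.fixture()
def two_group_metadata():
    def make(n_case: int, n_control: int) -> pd.DataFrame:
        samples = [f"A{i}" for i in range(n_case)] + [f"B{i}" for i in range(n_control)]
        return pd.DataFrame(
            {"phenotype": ["invasive"] * n_case + ["non-invasive"] * n_control},
            index=pd.Index(samples, name="sample_id"),
        )

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
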