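import numpy as np
import pytest

from estuarich import model, synthetic_data as sd, trawl_prep


@pytest.fixture(scope="session")
def fg_table():
    return trawl_prep.load_fg_table()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default desk-scale synthetic world (J=10, K=3, 50 trawls/estuary)."""
    return sd.generate_dataset(sd.SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def prepared(synthetic_dataset):
    kept, _ = trawl_prep.qc_filter(synthetic_dataset.records)
    return trawl_prep.transform_covariates(kept, synthetic_dataset.runoff)


@pytest.fixture(scope="session")
def model_data(prepared):
    return model.ModelData.from_prepared(prepared, "pelagic")


@pytest.fixture(scope="session")
def self_consistency_fit(model_data):
    """The shared 4-chain fit to self-simulated data used by the
    acceptance PPC and convergence checks."""
    return model.fit(
        model_data, n_chains=4, n_iter=1250, n_warmup=1250, seed=1
    )
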