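import numpy as np
import pandas as pd
import pytest

from dptscope import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scrna_truth():
    return synthetic.make_scrna_truth(seed=0)


@pytest.fixture(scope="session")
def scrna_adata(scrna_truth):
    return synthetic.gen_scrna(scrna_truth, 2000, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synthetic.default_cohort_config(n_patients=6, cells_per_sample=1200, seed=3)
    return synthetic.gen_cytof_cohort(cfg)


@pytest.fixture
def toy_clonotypes():
    # clones: A spans K1/K2, B confined to K1, C confined to K2
    return pd.DataFrame(
        {
            "clonotype_id": ["A", "A", "A", "B", "B", "C"],
            "cluster": ["K1", "K2", "K2", "K1", "K1", "K2"],
            "compartment": ["TDPT", "TCD8T", "TCD8T", "TDPT", "TDPT", "TCD8T"],
        }
    )
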