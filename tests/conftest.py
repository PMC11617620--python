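import numpy as np
import pandas as pd
import pytest

from canopylna.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact seeded dataset shared by read-only tests."""
    config = SynthConfig(n_plots=12, seed=42,
                         vi_names=("NDRE", "RERI_730", "EVI", "gNDVI"))
    return generate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_vi_table(rows):
    """Helper: long VI table from (plot, stage, vza, vi_name, value) tuples."""
    return pd.DataFrame(rows, columns=["plot_id", "stage", "vza",
                                       "vi_name", "value"])
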