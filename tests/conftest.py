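import warnings

import numpy as np
import pandas as pd
import pytest

from gbfs.featurize import DescriptorBlockSpec, clean_features, featurize_table
from gbfs.fixtures import FixtureSpec, generate_molecules

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)

SMALL_BLOCKS = (
    DescriptorBlockSpec("morgan_counts", {"radius": 2, "n_bits": 256}),
    DescriptorBlockSpec("physchem_descriptors"),
)


@pytest.fixture(scope="session")
def molecules_200():
    """200 synthetic grammar molecules (session-cached)."""
    return generate_molecules(FixtureSpec(n_molecules=200, seed=7))


@pytest.fixture(scope="session")
def small_features(molecules_200):
    """Cleaned small descriptor matrix for the 200 molecules."""
    X = featurize_table(molecules_200, SMALL_BLOCKS)
    Xc, _ = clean_features(X)
    return Xc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def linear_toy(rng):
    """y depends only on x0; 20 standard-normal noise columns."""
    X = pd.DataFrame(
        rng.normal(size=(500, 21)), columns=[f"x{i}" for i in range(21)]
    )
    y = X["x0"].to_numpy().copy()
    return X, y
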