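"""Bundled example data.

``load_logd_examples`` returns 60 drug-like molecules with experimental
octanol-water distribution coefficients (log D at pH 7.4) and the
corresponding model predictions from a published lipophilicity study,
usable as a worked example and as a regression-metric fixture.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_logd_examples() -> pd.DataFrame:
    """60 (formula, SMILES, experimental log D, predicted log D) rows."""
    path = resources.files("gbfs").joinpath("resources/logd_examples.csv")
    with path.open() as f:
        return pd.read_csv(f)
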