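"""Descriptor block generation, concatenation and cleaning."""

import numpy as np
import pandas as pd
import pytest

from gbfs.data import MoleculeTable
from gbfs.featurize import (
    DEFAULT_BLOCKS,
    DescriptorBlockSpec,
    FeatureCleaner,
    clean_features,
    concat_blocks,
    element_property_stats,
    featurize_block,
    featurize_table,
)


def _spec(name, **params):
    return DescriptorBlockSpec(name, params)


class TestBlocks:
    def test_morgan_counts_nonnegative_integers(self):
        X = featurize_block(["CCO"], _spec("morgan_counts", radius=3, n_bits=512))
        v = X.to_numpy()
        assert (v >= 0).all() and np.allclose(v, np.round(v))
        assert list(X.columns)[:2] == ["fm3-0", "fm3-1"]

    def test_bit_blocks_are_binary(self):
        for name in ("ecfp_bits", "path_fingerprint", "maccs_keys"):
            X = featurize_block(["CCO", "c1ccccc1"], _spec(name))
            assert set(np.unique(X.to_numpy())) <= {0.0, 1.0}

    def test_element_fractions_from_molecular_formula(self):
        X = featurize_block(["CCO"], _spec("element_fractions"))
        # C2H6O: 9 atoms with implicit hydrogens
        assert X["frac-C"].iloc[0] == pytest.approx(2 / 9)
        assert X["frac-H"].iloc[0] == pytest.approx(6 / 9)
        assert X["frac-O"].iloc[0] == pytest.approx(1 / 9)
        assert X["frac-N"].iloc[0] == 0.0

    def test_carboxylic_acid_count_descriptor(self):
        X = featurize_block(["CC(=O)O"], _spec("physchem_descriptors"))
        assert X["fr-COO"].iloc[0] == 1

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError):
            featurize_block(["CCO"], _spec("quantum_descriptors"))


class TestElementPropertyStats:
    def test_water_mean_group_number(self):
        X = element_property_stats(["O"])  # H2O with implicit hydrogens
        assert X["mean group number"].iloc[0] == pytest.approx((1 + 1 + 16) / 3)

    def test_methane_mean_group_number(self):
        X = element_property_stats(["C"])  # CH4
        assert X["mean group number"].iloc[0] == pytest.approx(3.6)

    def test_single_element_zero_std(self):
        X = element_property_stats(["[H][H]"])
        std_cols = [c for c in X.columns if c.startswith("std")]
        assert (X[std_cols].iloc[0] == 0).all()

    def test_unknown_element_becomes_missing(self):
        X = element_property_stats(["O"], property_table={"H": (13.99, 1, 1, 1.0, 2.2)})
        assert X.isna().all(axis=None)


class TestConcat:
    def test_width_additivity_and_order(self):
        a = featurize_block(["CCO", "CC"], _spec("maccs_keys"))
        b = featurize_block(["CCO", "CC"], _spec("element_fractions"))
        X = concat_blocks([a, b])
        assert X.shape[1] == a.shape[1] + b.shape[1]
        assert list(X.columns[: a.shape[1]]) == list(a.columns)

    def test_duplicate_names_repaired(self):
        a = pd.DataFrame({"x": [1.0]})
        b = pd.DataFrame({"x": [2.0]})
        b.attrs["block_name"] = "blk"
        X = concat_blocks([a, b])
        assert list(X.columns) == ["x", "blk.x"]

    def test_row_mismatch_rejected(self):
        a = pd.DataFrame({"x": [1.0, 2.0]})
        b = pd.DataFrame({"y": [1.0]})
        with pytest.raises(ValueError):
            concat_blocks([a, b])

    def test_default_block_set_reaches_expected_scale(self):
        X = featurize_table(["CCO", "CC(=O)Nc1ccc(O)cc1", "c1ccsc1"], DEFAULT_BLOCKS)
        assert 9_000 <= X.shape[1] <= 13_000


class TestCleanFeatures:
    def test_constant_and_missing_columns_dropped(self):
        X = pd.DataFrame(
            {
                "const": [1.0, 1.0, 1.0, 1.0],
                "allnan": [np.nan] * 4,
                "mostnan": [1.0, np.nan, np.nan, np.nan],
                "ok": [1.0, 2.0, np.nan, 4.0],
            }
        )
        out, report = clean_features(X, max_missing_fraction=0.3)
        assert list(out.columns) == ["ok"]
        assert report["zero_variance"] == ["const"]
        assert report["all_missing"] == ["allnan"]
        assert report["too_missing"] == ["mostnan"]
        assert out["ok"].iloc[2] == pytest.approx(2.0)  # median imputed

    def test_infinities_treated_as_missing(self):
        X = pd.DataFrame({"a": [1.0, np.inf, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 5.0]})
        out, _ = clean_features(X, max_missing_fraction=0.5)
        assert np.isfinite(out.to_numpy()).all()

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError):
            clean_features(pd.DataFrame({"c": [1.0, 1.0]}))

    def test_cleaner_is_leak_free(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [0, 1, 0, 1.0]})
        cleaner = FeatureCleaner().fit(train)
        test = pd.DataFrame({"a": [np.nan, 10.0], "b": [np.nan, 0.0]})
        out = cleaner.transform(test)
        assert out["a"].iloc[0] == pytest.approx(2.5)  # train median, not test


class TestPurity:
    def test_row_permutation_equivariance(self, molecules_200):
        smiles = molecules_200.smiles[:12]
        spec = (_spec("morgan_counts", radius=2, n_bits=128),)
        X = featurize_table(smiles, spec)
        perm = [5, 3, 0, 1, 2, 4, 11, 7, 6, 10, 9, 8]
        Xp = featurize_table([smiles[i] for i in perm], spec)
        assert np.array_equal(X.to_numpy()[perm], Xp.to_numpy())

    def test_refeaturization_bit_identical(self):
        table = MoleculeTable(
            ids=["a", "b"],
            smiles=["CCO", "c1ccccc1"],
            targets=pd.DataFrame(index=[0, 1]),
        )
        spec = (_spec("morgan_counts", radius=2, n_bits=128), _spec("maccs_keys"))
        assert featurize_table(table, spec).equals(featurize_table(table, spec))
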