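"""High-dimensional descriptor generation from SMILES.

Each molecule is assigned a base feature vector of roughly 11,000 named
columns by concatenating descriptor blocks: count-based Morgan
fingerprints, bit-folded ECFP, RDKit path fingerprints, MACCS keys,
atom-pair counts, the full 2D physicochemical descriptor set,
ElemNet-style element fractions, and statistics of elemental properties
over the molecular composition. All blocks are pure functions of the
canonical SMILES; per-molecule descriptor failures become missing values
that :func:`clean_features` handles.

Column naming is deterministic: count-based Morgan columns are
``fm<radius>-<index>``; physicochemical descriptors carry their
conventional names with hyphens (``MolLogP``, ``fr-COO``,
``PEOE-VSA13``, ...).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from ._elements import (
    ELEMENT_FRACTION_SYMBOLS,
    ELEMENT_PROPERTIES,
    PROPERTY_NAMES,
    STAT_NAMES,
)
from .data import MoleculeTable, mol_from_smiles

logger = logging.getLogger(__name__)


@dataclass
class DescriptorBlockSpec:
    """A named descriptor block with its parameters."""

    block_name: str
    params: dict = field(default_factory=dict)


class AlignmentError(ValueError):
    """Raised when feature blocks disagree on row counts."""


def _composition(mol: Chem.Mol) -> Counter:
    """Element counts including implicit hydrogens."""
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    return counts


def _morgan_counts(mols, radius: int = 3, n_bits: int = 2048) -> pd.DataFrame:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = [gen.GetCountFingerprint(m).ToList() for m in mols]
    cols = [f"fm{radius}-{i}" for i in range(n_bits)]
    return pd.DataFrame(np.asarray(rows, dtype=float), columns=cols)


def _ecfp_bits(mols, radius: int = 2, n_bits: int = 2048) -> pd.DataFrame:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = [np.asarray(gen.GetFingerprint(m), dtype=float) for m in mols]
    cols = [f"ecfp{2 * radius}-{i}" for i in range(n_bits)]
    return pd.DataFrame(np.asarray(rows), columns=cols)


def _path_fingerprint(mols, n_bits: int = 2048) -> pd.DataFrame:
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    rows = [np.asarray(gen.GetFingerprint(m), dtype=float) for m in mols]
    cols = [f"rdkfp-{i}" for i in range(n_bits)]
    return pd.DataFrame(np.asarray(rows), columns=cols)


def _maccs_keys(mols) -> pd.DataFrame:
    rows = [np.asarray(MACCSkeys.GenMACCSKeys(m), dtype=float) for m in mols]
    cols = [f"maccs-{i}" for i in range(167)]
    return pd.DataFrame(np.asarray(rows), columns=cols)


def _atom_pair_counts(mols, n_bits: int = 2048) -> pd.DataFrame:
    gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
    rows = [gen.GetCountFingerprint(m).ToList() for m in mols]
    cols = [f"ap-{i}" for i in range(n_bits)]
    return pd.DataFrame(np.asarray(rows, dtype=float), columns=cols)


def _physchem(mols) -> pd.DataFrame:
    names = [name for name, _ in Descriptors._descList]
    rows = np.full((len(mols), len(names)), np.nan)
    RDLogger.DisableLog("rdApp.*")
    try:
        for i, mol in enumerate(mols):
            for j, (name, fn) in enumerate(Descriptors._descList):
                try:
                    rows[i, j] = fn(mol)
                except Exception:  # descriptor failure -> missing value
                    pass
    finally:
        RDLogger.EnableLog("rdApp.*")
    cols = [n.replace("_", "-") for n in names]
    return pd.DataFrame(rows, columns=cols)


def _element_fractions(mols) -> pd.DataFrame:
    rows = np.zeros((len(mols), len(ELEMENT_FRACTION_SYMBOLS)))
    index = {s: j for j, s in enumerate(ELEMENT_FRACTION_SYMBOLS)}
    for i, mol in enumerate(mols):
        comp = _composition(mol)
        total = sum(comp.values())
        for sym, cnt in comp.items():
            if sym in index and total:
                rows[i, index[sym]] = cnt / total
    cols = [f"frac-{s}" for s in ELEMENT_FRACTION_SYMBOLS]
    return pd.DataFrame(rows, columns=cols)


def _element_property_stats(
    mols, property_table: dict | None = None
) -> pd.DataFrame:
    """Statistics of elemental properties over the molecular composition.

    Per molecule and per property: mean, std, min, max and range of the
    property over all atoms (with implicit hydrogens), weighted by the
    composition. Elements missing from the table yield missing values.
    """
    table = property_table if property_table is not None else ELEMENT_PROPERTIES
    cols = [f"{stat} {prop}" for prop in PROPERTY_NAMES for stat in STAT_NAMES]
    rows = np.full((len(mols), len(cols)), np.nan)
    missing_elements: set[str] = set()
    for i, mol in enumerate(mols):
        comp = _composition(mol)
        j = 0
        for p_idx, _prop in enumerate(PROPERTY_NAMES):
            vals, weights = [], []
            ok = True
            for sym, cnt in comp.items():
                if sym not in table:
                    missing_elements.add(sym)
                    ok = False
                    continue
                vals.append(table[sym][p_idx])
                weights.append(cnt)
            if ok and vals:
                v = np.repeat(np.asarray(vals, dtype=float), weights)
                rows[i, j : j + 5] = [
                    v.mean(),
                    v.std(),
                    v.min(),
                    v.max(),
                    v.max() - v.min(),
                ]
            j += 5
    if missing_elements:
        logger.warning(
            "elements absent from property table: %s", sorted(missing_elements)
        )
    return pd.DataFrame(rows, columns=cols)


_BLOCKS: dict[str, Callable] = {
    "morgan_counts": _morgan_counts,
    "ecfp_bits": _ecfp_bits,
    "path_fingerprint": _path_fingerprint,
    "maccs_keys": _maccs_keys,
    "atom_pair_counts": _atom_pair_counts,
    "physchem_descriptors": _physchem,
    "element_fractions": _element_fractions,
    "element_property_stats": _element_property_stats,
}

#: default block composition reaching the ~11,000-column scale
DEFAULT_BLOCKS: tuple[DescriptorBlockSpec, ...] = (
    DescriptorBlockSpec("morgan_counts", {"radius": 3, "n_bits": 4096}),
    DescriptorBlockSpec("ecfp_bits", {"radius": 2, "n_bits": 2048}),
    DescriptorBlockSpec("path_fingerprint", {"n_bits": 2048}),
    DescriptorBlockSpec("maccs_keys"),
    DescriptorBlockSpec("atom_pair_counts", {"n_bits": 2048}),
    DescriptorBlockSpec("physchem_descriptors"),
    DescriptorBlockSpec("element_fractions"),
    DescriptorBlockSpec("element_property_stats"),
)


def featurize_block(
    table: MoleculeTable | Sequence[str], spec: DescriptorBlockSpec
) -> pd.DataFrame:
    """Compute one descriptor block for every molecule in ``table``."""
    if spec.block_name not in _BLOCKS:
        raise ValueError(f"unknown block_name: {spec.block_name!r}")
    smiles = table.smiles if isinstance(table, MoleculeTable) else list(table)
    if not smiles:
        raise ValueError("empty molecule table")
    mols = [mol_from_smiles(s) for s in smiles]
    out = _BLOCKS[spec.block_name](mols, **spec.params)
    out.attrs["block_name"] = spec.block_name
    return out


def element_property_stats(
    table: MoleculeTable | Sequence[str], property_table: dict | None = None
) -> pd.DataFrame:
    """Composition statistics block as a standalone operation."""
    smiles = table.smiles if isinstance(table, MoleculeTable) else list(table)
    mols = [mol_from_smiles(s) for s in smiles]
    return _element_property_stats(mols, property_table)


def concat_blocks(blocks: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate feature blocks column-wise.

    Row counts must agree; duplicate column names across blocks are
    repaired by prefixing the later block's name.
    """
    if not blocks:
        raise ValueError("no blocks to concatenate")
    n = len(blocks[0])
    seen: set[str] = set()
    fixed = []
    for block in blocks:
        if len(block) != n:
            raise AlignmentError("blocks have mismatched row counts")
        rename = {}
        for col in block.columns:
            if col in seen:
                prefix = block.attrs.get("block_name", "block")
                rename[col] = f"{prefix}.{col}"
                logger.warning("renamed duplicate column %r to %r", col, rename[col])
        block = block.rename(columns=rename)
        seen.update(block.columns)
        fixed.append(block)
    return pd.concat(fixed, axis=1)


def featurize_table(
    table: MoleculeTable | Sequence[str],
    blocks: Sequence[DescriptorBlockSpec] = DEFAULT_BLOCKS,
) -> pd.DataFrame:
    """Full base feature matrix: all blocks, concatenated in order."""
    return concat_blocks([featurize_block(table, spec) for spec in blocks])


def clean_features(
    X: pd.DataFrame,
    max_missing_fraction: float = 0.2,
    impute: str = "median",
) -> tuple[pd.DataFrame, dict]:
    """Drop unusable columns and impute the rest.

    Drops all-missing, mostly-missing (fraction > ``max_missing_fraction``)
    and zero-variance columns; imputes remaining missing entries with the
    column median (or mean). Non-finite values count as missing. Returns
    the cleaned matrix and a drop report.
    """
    X = X.replace([np.inf, -np.inf], np.nan)
    report: dict[str, list[str]] = {
        "all_missing": [],
        "too_missing": [],
        "zero_variance": [],
        "imputed": [],
    }
    keep = []
    for col in X.columns:
        v = X[col]
        miss = v.isna().mean()
        if miss == 1.0:
            report["all_missing"].append(col)
            continue
        if miss > max_missing_fraction:
            report["too_missing"].append(col)
            continue
        if v.dropna().nunique() <= 1:
            report["zero_variance"].append(col)
            continue
        keep.append(col)
    if not keep:
        raise ValueError("all feature columns were dropped")
    out = X[keep].copy()
    fill = out.median() if impute == "median" else out.mean()
    imputed_cols = out.columns[out.isna().any()].tolist()
    report["imputed"] = imputed_cols
    out = out.fillna(fill)
    return out, report


class MoleculeFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless SMILES -> descriptor matrix transformer.

    Parameters
    ----------
    blocks : sequence of DescriptorBlockSpec, optional
        Descriptor blocks to concatenate (default: the full ~11,000-column
        set).
    """

    def __init__(self, blocks: Sequence[DescriptorBlockSpec] | None = None):
        self.blocks = blocks

    def fit(self, X, y=None):
        probe = X[:1] if not isinstance(X, MoleculeTable) else X.subset([0])
        self.feature_names_out_ = list(
            featurize_table(probe, self.blocks or DEFAULT_BLOCKS).columns
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        return featurize_table(X, self.blocks or DEFAULT_BLOCKS)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_)


class FeatureCleaner(BaseEstimator, TransformerMixin):
    """Learn column drops and imputation values on the training matrix.

    ``fit`` applies :func:`clean_features` to the training rows and
    memorizes the retained columns and their fill values; ``transform``
    projects any matrix onto those columns and imputes with the training
    fill values (no test-set leakage).
    """

    def __init__(self, max_missing_fraction: float = 0.2, impute: str = "median"):
        self.max_missing_fraction = max_missing_fraction
        self.impute = impute

    def fit(self, X: pd.DataFrame, y=None):
        cleaned, report = clean_features(X, self.max_missing_fraction, self.impute)
        self.columns_ = list(cleaned.columns)
        self.fill_values_ = (
            cleaned.median() if self.impute == "median" else cleaned.mean()
        )
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X[self.columns_].replace([np.inf, -np.inf], np.nan)
        return X.fillna(self.fill_values_)
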