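"""Molecule tables, SMILES canonicalization and train/test splitting.

A :class:`MoleculeTable` is the unit of dataset I/O: an ordered list of
identified molecules (canonical SMILES) with one or more named targets.
Row order is stable and defines the row index of every feature matrix
derived from the table.

Two splitters are provided: a seeded random split and a Bemis-Murcko
scaffold split in which molecules sharing a scaffold (ring systems plus
linkers, side chains removed) never straddle two partitions and the most
prevalent scaffolds go to the training set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

REGRESSION = "regression"
CLASSIFICATION = "classification"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class SchemaError(ValueError):
    """Raised when an input table is missing required columns."""


def canonicalize_smiles(smiles: str) -> str:
    """Return the unique canonical SMILES for ``smiles``.

    Two encodings of the same molecule map to the same string; the
    function is idempotent. Raises :class:`SmilesParseError` on invalid
    input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES: ring systems plus linkers.

    Acyclic molecules return the empty string (the standard convention);
    molecules sharing a scaffold return identical strings.
    """
    mol = mol_from_smiles(smiles)
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


@dataclass
class MoleculeTable:
    """Ordered molecules with targets.

    Parameters
    ----------
    ids : list of str
        Unique opaque identifiers.
    smiles : list of str
        Canonical SMILES, aligned to ``ids``.
    targets : pandas.DataFrame
        One column per target, rows aligned to ``ids``. Missing
        classification labels are NaN and excluded per-task downstream.
    task_type : {"regression", "classification"}
    """

    ids: list[str]
    smiles: list[str]
    targets: pd.DataFrame
    task_type: str = REGRESSION

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.smiles):
            raise ValueError("ids and smiles must have equal length")
        if len(self.targets) != len(self.ids):
            raise ValueError("targets must align with molecules")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("molecule ids must be unique")
        if self.task_type not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task_type: {self.task_type!r}")
        self.targets = self.targets.reset_index(drop=True)

    @property
    def target_names(self) -> list[str]:
        return list(self.targets.columns)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: Sequence[int]) -> "MoleculeTable":
        idx = list(indices)
        return MoleculeTable(
            ids=[self.ids[i] for i in idx],
            smiles=[self.smiles[i] for i in idx],
            targets=self.targets.iloc[idx].reset_index(drop=True),
            task_type=self.task_type,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "smiles": self.smiles})
        return pd.concat([out, self.targets.reset_index(drop=True)], axis=1)


def read_molecule_table(
    path: str | Path,
    smiles_column: str = "smiles",
    target_columns: Sequence[str] | None = None,
    task_type: str = REGRESSION,
    id_column: str | None = None,
    sheet: int | str = 0,
) -> MoleculeTable:
    """Read a CSV or XLSX molecule table, canonicalizing SMILES.

    Rows whose SMILES does not parse are dropped and counted in the log;
    row order is otherwise preserved. Raises ``FileNotFoundError`` for a
    missing file, :class:`SchemaError` for missing columns, and
    ``ValueError`` if no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise SchemaError(f"missing SMILES column {smiles_column!r}")
    if target_columns is None:
        target_columns = [c for c in df.columns if c not in (smiles_column, id_column)]
    missing = [c for c in target_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing target columns: {missing}")

    RDLogger.DisableLog("rdApp.error")
    try:
        ids, smiles, keep_rows = [], [], []
        n_dropped = 0
        for pos, (row_idx, raw) in enumerate(df[smiles_column].items()):
            try:
                can = canonicalize_smiles(str(raw))
            except SmilesParseError:
                n_dropped += 1
                continue
            ids.append(
                str(df[id_column].iloc[pos]) if id_column else f"mol{pos}"
            )
            smiles.append(can)
            keep_rows.append(pos)
    finally:
        RDLogger.EnableLog("rdApp.error")
    if n_dropped:
        logger.warning("dropped %d rows with unparseable SMILES", n_dropped)
    if not smiles:
        raise ValueError("no valid SMILES rows in table")
    targets = df.iloc[keep_rows][list(target_columns)].apply(
        pd.to_numeric, errors="coerce"
    )
    return MoleculeTable(ids=ids, smiles=smiles, targets=targets, task_type=task_type)


@dataclass
class SplitIndex:
    """Disjoint train/validation/test row-index sets with a test access guard.

    Reading the ``test`` property increments ``test_access_count`` so a
    workflow can assert that the held-out partition was touched exactly
    once (by the final evaluation).
    """

    train: np.ndarray
    validation: np.ndarray
    _test: np.ndarray
    test_access_count: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.validation = np.asarray(self.validation, dtype=int)
        self._test = np.asarray(self._test, dtype=int)
        all_idx = np.concatenate([self.train, self.validation, self._test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split partitions must be pairwise disjoint")

    @property
    def test(self) -> np.ndarray:
        self.test_access_count += 1
        return self._test

    def peek_test_size(self) -> int:
        return len(self._test)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "train": self.train.tolist(),
                "validation": self.validation.tolist(),
                "test": self._test.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str | Path) -> "SplitIndex":
        if isinstance(payload, Path) or (
            isinstance(payload, str) and not payload.lstrip().startswith("{")
        ):
            payload = Path(payload).read_text()
        d = json.loads(payload)
        return cls(
            train=np.array(d["train"], dtype=int),
            validation=np.array(d["validation"], dtype=int),
            _test=np.array(d["test"], dtype=int),
        )


def random_split(
    table: MoleculeTable | int,
    test_fraction: float,
    validation_fraction: float = 0.0,
    seed: int = 0,
) -> SplitIndex:
    """Seeded uniform split; ``|test| = round(n * test_fraction)``."""
    n = table if isinstance(table, int) else len(table)
    if not 0 < test_fraction < 1 or validation_fraction < 0:
        raise ValueError("fractions out of range")
    if test_fraction + validation_fraction >= 1:
        raise ValueError("fractions must sum to less than 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    n_val = int(round(n * validation_fraction))
    return SplitIndex(
        train=np.sort(perm[n_test + n_val :]),
        validation=np.sort(perm[n_test : n_test + n_val]),
        _test=np.sort(perm[:n_test]),
    )


def scaffold_split(
    table: MoleculeTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SplitIndex:
    """Bemis-Murcko scaffold split, largest scaffold groups to train first.

    All acyclic molecules (empty scaffold) form one shared group.
    Molecules sharing a scaffold never straddle two partitions. Emits a
    warning (not an error) if any partition ends up empty.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    groups: dict[str, list[int]] = {}
    for i, smi in enumerate(table.smiles):
        groups.setdefault(murcko_scaffold(smi), []).append(i)
    # largest first; ties broken by first occurrence for determinism
    ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0]))
    n = len(table)
    n_train = fractions[0] * n
    n_val = fractions[1] * n
    train: list[int] = []
    val: list[int] = []
    test: list[int] = []
    for group in ordered:
        if len(train) < n_train:
            train.extend(group)
        elif len(val) < n_val:
            val.extend(group)
        else:
            test.extend(group)
    for name, part in (("train", train), ("validation", val), ("test", test)):
        if not part:
            warnings.warn(f"scaffold split produced an empty {name} set")
    return SplitIndex(
        train=np.sort(train), validation=np.sort(val), _test=np.sort(test)
    )
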