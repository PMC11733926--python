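"""Synthetic molecules with planted structure-property relationships.

A small fragment grammar (alkyl chains, benzene rings, heteroatom
linkers, carboxylic acid / hydroxyl / amine / halogen terminals)
assembles valid drug-like SMILES, and targets are planted as linear
combinations of standardized descriptor columns plus Gaussian noise —
so every workflow stage can be exercised, and feature-recovery claims
checked against known ground truth, without any download. Fixtures test
mechanics, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .data import REGRESSION, CLASSIFICATION, MoleculeTable

# grammar pieces: (prefix, chain_a, middle, chain_b, terminal)
_PREFIXES = ("", "O", "N", "OC(=O)")
_MIDDLES = ("", "c1ccccc1", "O", "N", "S", "C(C)C")
_TERMINALS = ("", "C(=O)O", "O", "N", "F", "Cl", "Br", "C(=O)N", "C#N")
_CHAIN_MAX = 8


@dataclass
class FixtureSpec:
    """Parameters of the synthetic molecule generator."""

    n_molecules: int = 100
    seed: int = 0
    informative_features: list[tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 0.1
    max_attempts_factor: int = 200


def _assemble(rng: np.random.Generator) -> str:
    a = int(rng.integers(0, _CHAIN_MAX + 1))
    b = int(rng.integers(0, _CHAIN_MAX + 1))
    return (
        _PREFIXES[rng.integers(len(_PREFIXES))]
        + "C" * a
        + _MIDDLES[rng.integers(len(_MIDDLES))]
        + "C" * b
        + _TERMINALS[rng.integers(len(_TERMINALS))]
    )


def generate_molecules(spec: FixtureSpec) -> MoleculeTable:
    """Generate ``n_molecules`` unique, valid, canonical SMILES."""
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    limit = spec.n_molecules * spec.max_attempts_factor
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > limit:
            raise RuntimeError(
                "fragment grammar exhausted before reaching the requested "
                "molecule count; enlarge the grammar or lower n_molecules"
            )
        candidate = _assemble(rng)
        mol = Chem.MolFromSmiles(candidate)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        out.append(can)
    ids = [f"syn{i}" for i in range(len(out))]
    return MoleculeTable(
        ids=ids, smiles=out, targets=pd.DataFrame(index=range(len(out)))
    )


def _standardized_signal(
    X: pd.DataFrame, informative: Sequence[tuple[str, float]]
) -> np.ndarray:
    missing = [n for n, _ in informative if n not in X.columns]
    if missing:
        raise KeyError(f"informative features absent from matrix: {missing}")
    signal = np.zeros(len(X))
    for name, beta in informative:
        v = X[name].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"informative feature {name!r} is constant")
        signal += beta * (v - v.mean()) / sd
    return signal


def plant_regression_target(
    table: MoleculeTable,
    X: pd.DataFrame,
    informative: Sequence[tuple[str, float]],
    noise_sd: float = 0.1,
    seed: int = 0,
    target_name: str = "y",
) -> tuple[MoleculeTable, dict]:
    """Plant ``y = sum beta_j standardized(x_j) + Normal(0, noise_sd)``.

    Returns the table with the target attached and a ground-truth record
    (signal, noise draw, coefficients) for recovery tests.
    """
    rng = np.random.default_rng(seed)
    signal = _standardized_signal(X, informative)
    noise = rng.normal(0.0, noise_sd, size=len(X)) if noise_sd > 0 else np.zeros(len(X))
    y = signal + noise
    out = MoleculeTable(
        ids=list(table.ids),
        smiles=list(table.smiles),
        targets=pd.DataFrame({target_name: y}),
        task_type=REGRESSION,
    )
    truth = {
        "informative": list(informative),
        "noise_sd": noise_sd,
        "signal_sd": float(signal.std()),
        "signal": signal,
        "noise": noise,
        "seed": seed,
    }
    return out, truth


def plant_classification_target(
    table: MoleculeTable,
    X: pd.DataFrame,
    informative: Sequence[tuple[str, float]],
    intercept: float = 0.0,
    seed: int = 0,
    target_name: str = "label",
) -> tuple[MoleculeTable, dict]:
    """Plant Bernoulli labels through a logistic link on the linear score."""
    rng = np.random.default_rng(seed)
    score = _standardized_signal(X, informative) + intercept
    p = 1.0 / (1.0 + np.exp(-score))
    labels = (rng.random(len(p)) < p).astype(int)
    out = MoleculeTable(
        ids=list(table.ids),
        smiles=list(table.smiles),
        targets=pd.DataFrame({target_name: labels}),
        task_type=CLASSIFICATION,
    )
    truth = {
        "informative": list(informative),
        "intercept": intercept,
        "score": score,
        "positive_rate": float(labels.mean()),
        "seed": seed,
    }
    return out, truth
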