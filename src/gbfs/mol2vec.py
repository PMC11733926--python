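"""Substructure vector embeddings (Mol2Vec).

A molecule is read as a "sentence" of Morgan substructure identifiers:
for every heavy atom, in canonical atom order, one hashed identifier per
radius 0..max_radius for which a circular environment exists. Sentences
are fed to a skip-gram word2vec model with negative sampling; a
molecule's embedding is the sum of its substructure vectors.
Out-of-vocabulary substructures map to an UNK vector (the mean of all
trained vectors) so rare chemistry still carries signal.

The trainer is a compact, single-worker, fully seeded numpy
implementation of the skip-gram objective, which keeps training
reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .data import MoleculeTable, mol_from_smiles

logger = logging.getLogger(__name__)


def molecule_sentence(smiles: str, max_radius: int = 1) -> list[str]:
    """Substructure-identifier sentence for one molecule.

    For each heavy atom (canonical order) one identifier per radius
    0..max_radius for which a circular environment exists. Identifiers
    are the stable Morgan environment hashes.
    """
    if not 0 <= max_radius <= 3:
        raise ValueError("max_radius must be in 0..3")
    mol = mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=max_radius)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    info = ao.GetBitInfoMap()
    per_atom: dict[tuple[int, int], str] = {}
    for identifier, hits in info.items():
        for atom_idx, radius in hits:
            per_atom[(atom_idx, radius)] = str(identifier)
    sentence = []
    for atom_idx in range(mol.GetNumAtoms()):
        for radius in range(max_radius + 1):
            token = per_atom.get((atom_idx, radius))
            if token is not None:
                sentence.append(token)
    return sentence


@dataclass
class EmbeddingModel:
    """Trained substructure embeddings: identifier -> vector plus UNK."""

    dimension: int
    vocabulary: dict[str, np.ndarray]
    unk_vector: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def vector(self, token: str) -> np.ndarray:
        return self.vocabulary.get(token, self.unk_vector)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"dimension": self.dimension, "training_meta": self.training_meta}
        (directory / "embedding_meta.json").write_text(json.dumps(meta))
        tokens = list(self.vocabulary)
        mat = np.vstack([self.vocabulary[t] for t in tokens] + [self.unk_vector])
        df = pd.DataFrame(mat, index=tokens + ["<UNK>"])
        df.to_csv(directory / "embedding_vectors.csv")

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingModel":
        directory = Path(directory)
        meta = json.loads((directory / "embedding_meta.json").read_text())
        df = pd.read_csv(directory / "embedding_vectors.csv", index_col=0)
        vocab = {
            str(tok): df.loc[tok].to_numpy(float)
            for tok in df.index
            if tok != "<UNK>"
        }
        return cls(
            dimension=meta["dimension"],
            vocabulary=vocab,
            unk_vector=df.loc["<UNK>"].to_numpy(float),
            training_meta=meta["training_meta"],
        )


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(
    corpus: Sequence[Sequence[str]],
    dimension: int = 300,
    window: int = 10,
    min_count: int = 3,
    epochs: int = 5,
    seed: int = 0,
    negative: int = 5,
    alpha: float = 0.025,
) -> EmbeddingModel:
    """Train skip-gram embeddings with negative sampling over sentences.

    Identifiers occurring fewer than ``min_count`` times are excluded
    from the vocabulary. The UNK vector is the mean of all trained
    vectors. Single-worker and fully seeded, so training is reproducible.
    """
    if not corpus:
        raise ValueError("empty corpus")
    counts = Counter(tok for sent in corpus for tok in sent)
    vocab = [t for t, c in sorted(counts.items()) if c >= min_count]
    if not vocab:
        raise ValueError(
            "vocabulary empty after min_count filter; lower min_count"
        )
    index = {t: i for i, t in enumerate(vocab)}
    rng = np.random.default_rng(seed)
    n = len(vocab)
    syn0 = (rng.random((n, dimension)) - 0.5) / dimension
    syn1 = np.zeros((n, dimension))
    # unigram^0.75 negative-sampling distribution
    freqs = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    neg_probs = freqs / freqs.sum()
    encoded = [
        np.array([index[t] for t in sent if t in index], dtype=int)
        for sent in corpus
    ]
    encoded = [s for s in encoded if len(s) > 1]
    for epoch in range(epochs):
        lr = alpha * (1 - epoch / max(epochs, 1)) + 1e-4
        for sent in encoded:
            L = len(sent)
            spans = rng.integers(1, window + 1, size=L)
            for pos in range(L):
                center = sent[pos]
                lo, hi = max(0, pos - spans[pos]), min(L, pos + spans[pos] + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    context = sent[ctx_pos]
                    targets = np.empty(negative + 1, dtype=int)
                    targets[0] = context
                    targets[1:] = rng.choice(n, size=negative, p=neg_probs)
                    labels = np.zeros(negative + 1)
                    labels[0] = 1.0
                    v = syn0[center]
                    out = _sigmoid(syn1[targets] @ v)
                    g = (labels - out) * lr
                    syn0[center] = v + g @ syn1[targets]
                    syn1[targets] += np.outer(g, v)
    vocabulary = {t: syn0[i].copy() for t, i in index.items()}
    unk = syn0.mean(axis=0)
    return EmbeddingModel(
        dimension=dimension,
        vocabulary=vocabulary,
        unk_vector=unk,
        training_meta={
            "window": window,
            "min_count": min_count,
            "epochs": epochs,
            "seed": seed,
            "negative": negative,
        },
    )


def molecule_vector(model: EmbeddingModel, sentence: Sequence[str]) -> np.ndarray:
    """Sum of substructure vectors (UNK for out-of-vocabulary tokens)."""
    if not sentence:
        warnings.warn("empty substructure sentence; returning zero vector")
        return np.zeros(model.dimension)
    return np.sum([model.vector(t) for t in sentence], axis=0)


def embed_table(
    model: EmbeddingModel,
    table: MoleculeTable | Sequence[str],
    max_radius: int = 1,
) -> pd.DataFrame:
    """Per-molecule embedding matrix with columns ``Mol2Vec-0..d-1``."""
    smiles = table.smiles if isinstance(table, MoleculeTable) else list(table)
    rows = np.zeros((len(smiles), model.dimension))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, smi in enumerate(smiles):
            rows[i] = molecule_vector(model, molecule_sentence(smi, max_radius))
    cols = [f"Mol2Vec-{i}" for i in range(model.dimension)]
    return pd.DataFrame(rows, columns=cols)


class Mol2VecVectorizer(BaseEstimator, TransformerMixin):
    """SMILES -> Mol2Vec embedding matrix, sklearn-transformer shaped.

    ``fit`` trains the skip-gram model on the training molecules only
    (no test-set leakage into the corpus); ``transform`` embeds any
    molecule, mapping unseen substructures to the UNK vector.
    """

    def __init__(
        self,
        dimension: int = 300,
        window: int = 10,
        min_count: int = 3,
        epochs: int = 5,
        max_radius: int = 1,
        seed: int = 0,
    ):
        self.dimension = dimension
        self.window = window
        self.min_count = min_count
        self.epochs = epochs
        self.max_radius = max_radius
        self.seed = seed

    def _smiles(self, X) -> list[str]:
        return X.smiles if isinstance(X, MoleculeTable) else list(X)

    def fit(self, X, y=None):
        corpus = [molecule_sentence(s, self.max_radius) for s in self._smiles(X)]
        self.model_ = train_embeddings(
            corpus,
            dimension=self.dimension,
            window=self.window,
            min_count=self.min_count,
            epochs=self.epochs,
            seed=self.seed,
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        return embed_table(self.model_, self._smiles(X), self.max_radius)

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"Mol2Vec-{i}" for i in range(self.dimension)])
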