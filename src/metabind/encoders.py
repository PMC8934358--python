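"""Fixed-length embeddings for proteins and drugs, and derived similarities.

Proteins: ProtVec-style 3-gram "biological word" embeddings.  The training
corpus for the skip-gram model is built by splitting every sequence into
three lists of shifted non-overlapping 3-grams; a protein's embedding is
then the sum of the vectors of ALL overlapping 3-grams in its sequence.

Drugs: a pluggable encoder contract (``fit_corpus`` / ``encode``).  The
default is a deterministic hashed character n-gram encoder with a seeded
random projection; a trainable GRU sequence-autoencoder is also provided.

Both sides expose sklearn-style transformers so they can sit inside
pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .gru import GruSeq2Seq
from .io import SequenceRecord, SimilarityMatrix
from .graph import minmax_normalize
from .word2vec import SkipGramModel, train_skipgram

__all__ = [
    "EmbeddingMatrix",
    "KmerVocabulary",
    "build_shifted_corpus",
    "train_kmer_embeddings",
    "embed_protein",
    "ProteinKmerEmbedder",
    "tokenize_smiles",
    "HashedSmilesEncoder",
    "GruSmilesAutoencoder",
    "embed_drug",
    "cosine_similarity_matrix",
    "tanimoto_ngram_similarity",
]


@dataclass
class EmbeddingMatrix:
    """Per-entity fixed-length feature vectors."""

    entity_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(self.entity_ids) != self.vectors.shape[0]:
            raise ValueError("one vector per entity required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding values")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, entity_id: str) -> np.ndarray:
        try:
            idx = self.entity_ids.index(entity_id)
        except ValueError:
            raise KeyError(f"entity {entity_id!r} has no embedding") from None
        return self.vectors[idx]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.vectors, index=self.entity_ids, columns=[f"e{i}" for i in range(self.dim)]
        )


# ---------------------------------------------------------------------------
# protein side
# ---------------------------------------------------------------------------


def build_shifted_corpus(seq: str, k: int = 3) -> tuple[list[str], ...]:
    """Split ``seq`` into k lists of shifted non-overlapping k-mers.

    List s (s = 0..k-1) contains seq[s:s+k], seq[s+k:s+2k], ...; trailing
    fragments shorter than k are dropped.  Concatenating list s reproduces
    seq[s : s + k*floor((len(seq)-s)/k)].
    """
    if len(seq) < k:
        warnings.warn(f"sequence shorter than k={k}; returning empty token lists")
        return tuple([] for _ in range(k))
    out = []
    for s in range(k):
        out.append([seq[i : i + k] for i in range(s, len(seq) - k + 1, k)])
    return tuple(out)


@dataclass
class KmerVocabulary:
    """Token -> vector map over length-k amino-acid words."""

    k: int
    model: SkipGramModel

    @property
    def dim(self) -> int:
        return self.model.dim

    def __contains__(self, token: str) -> bool:
        return token in self.model

    def vector(self, token: str) -> np.ndarray:
        if len(token) != self.k:
            raise ValueError(f"token {token!r} is not length {self.k}")
        return self.model[token]

    def get(self, token: str) -> np.ndarray | None:
        return self.model.get(token)

    def save(self, path) -> None:
        self.model.save_word2vec_text(path)

    @classmethod
    def load(cls, path, k: int = 3) -> "KmerVocabulary":
        return cls(k=k, model=SkipGramModel.load_word2vec_text(path))


def train_kmer_embeddings(
    corpus: Sequence[Sequence[str]],
    dim: int = 100,
    k: int = 3,
    seed: int = 0,
    window: int = 5,
    min_count: int = 1,
    epochs: int = 10,
) -> KmerVocabulary:
    """Train skip-gram k-mer embeddings on a corpus of token sentences."""
    if not any(len(s) for s in corpus):
        raise ValueError("empty corpus")
    model = train_skipgram(
        corpus, dim=dim, window=window, min_count=min_count, epochs=epochs, seed=seed
    )
    return KmerVocabulary(k=k, model=model)


def embed_protein(
    seq: str, vocab: KmerVocabulary, average: bool = False
) -> tuple[np.ndarray, float]:
    """Sum vectors of all overlapping k-mers; returns (vector, coverage).

    Unknown k-mers contribute zero and lower the coverage statistic.
    With ``average=True`` the sum is divided by the window count.
    """
    k = vocab.k
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    total = np.zeros(vocab.dim)
    n_windows = len(seq) - k + 1
    known = 0
    for i in range(n_windows):
        v = vocab.get(seq[i : i + k])
        if v is not None:
            total += v
            known += 1
    if average and n_windows:
        total = total / n_windows
    return total, known / n_windows


class ProteinKmerEmbedder(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: protein sequences -> k-mer sum embeddings.

    ``fit`` builds the shifted non-overlapping corpus from the training
    sequences and trains the skip-gram vocabulary (or adopts a pretrained
    one passed as ``vocabulary``); ``transform`` sums overlapping k-mer
    vectors per sequence.
    """

    def __init__(
        self,
        dim: int = 100,
        k: int = 3,
        window: int = 5,
        min_count: int = 1,
        epochs: int = 10,
        average: bool = False,
        seed: int = 0,
        vocabulary: KmerVocabulary | None = None,
    ):
        self.dim = dim
        self.k = k
        self.window = window
        self.min_count = min_count
        self.epochs = epochs
        self.average = average
        self.seed = seed
        self.vocabulary = vocabulary

    def fit(self, sequences: Sequence[str], y=None):
        if self.vocabulary is not None:
            self.vocab_ = self.vocabulary
        else:
            corpus: list[list[str]] = []
            for seq in sequences:
                corpus.extend(build_shifted_corpus(seq, self.k))
            self.vocab_ = train_kmer_embeddings(
                corpus,
                dim=self.dim,
                k=self.k,
                seed=self.seed,
                window=self.window,
                min_count=self.min_count,
                epochs=self.epochs,
            )
        return self

    def transform(self, sequences: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "vocab_"):
            raise RuntimeError("ProteinKmerEmbedder is not fitted")
        vecs = np.empty((len(sequences), self.vocab_.dim))
        self.coverage_ = np.empty(len(sequences))
        for i, seq in enumerate(sequences):
            vecs[i], self.coverage_[i] = embed_protein(seq, self.vocab_, self.average)
        return vecs

    def embed_records(self, records: Sequence[SequenceRecord]) -> EmbeddingMatrix:
        vecs = self.transform([r.sequence for r in records])
        return EmbeddingMatrix([r.id for r in records], vecs)


# ---------------------------------------------------------------------------
# drug side
# ---------------------------------------------------------------------------

_TWO_CHAR = ("Cl", "Br")


def tokenize_smiles(smiles: str) -> list[str]:
    """Character-level SMILES tokens, keeping Cl/Br and [...] atoms atomic."""
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens: list[str] = []
    i = 0
    while i < len(smiles):
        if smiles[i] == "[":
            j = smiles.find("]", i)
            if j == -1:
                tokens.append(smiles[i:])
                break
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif smiles[i : i + 2] in _TWO_CHAR:
            tokens.append(smiles[i : i + 2])
            i += 2
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


@runtime_checkable
class DrugEncoder(Protocol):
    """Contract every SMILES encoder fulfils."""

    dim: int

    def fit_corpus(self, smiles_list: Sequence[str]) -> "DrugEncoder": ...

    def encode(self, smiles: str) -> np.ndarray: ...


def _ngram_counts(tokens: list[str], n_lo: int = 1, n_hi: int = 3) -> dict[str, int]:
    counts: dict[str, int] = {}
    for n in range(n_lo, n_hi + 1):
        for i in range(len(tokens) - n + 1):
            key = "\x00".join(tokens[i : i + n])
            counts[key] = counts.get(key, 0) + 1
    return counts


def _stable_hash(s: str, buckets: int) -> int:
    # FNV-1a, stable across processes (unlike builtin hash)
    h = 0xCBF29CE484222325
    for ch in s.encode():
        h = ((h ^ ch) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h % buckets


class HashedSmilesEncoder(BaseEstimator, TransformerMixin):
    """Deterministic default drug encoder.

    Counts hashed token n-grams (n = 1..3) of the SMILES token stream into
    ``n_buckets`` bins, then projects to ``dim`` with a seeded Gaussian
    random projection.  Stateless apart from the fixed projection, so
    ``fit_corpus`` is a no-op that exists to satisfy the encoder contract.
    """

    def __init__(self, dim: int = 128, n_buckets: int = 4096, seed: int = 0):
        self.dim = dim
        self.n_buckets = n_buckets
        self.seed = seed

    def _projection(self) -> np.ndarray:
        if not hasattr(self, "_proj"):
            rng = np.random.default_rng(self.seed)
            self._proj = rng.standard_normal((self.n_buckets, self.dim)) / np.sqrt(self.dim)
        return self._proj

    def fit_corpus(self, smiles_list: Sequence[str]) -> "HashedSmilesEncoder":
        return self

    def fit(self, X, y=None):
        return self

    def encode(self, smiles: str) -> np.ndarray:
        tokens = tokenize_smiles(smiles)
        bucketed = np.zeros(self.n_buckets)
        for key, c in _ngram_counts(tokens).items():
            bucketed[_stable_hash(key, self.n_buckets)] += c
        return bucketed @ self._projection()

    def transform(self, smiles_list: Sequence[str]) -> np.ndarray:
        return np.vstack([self.encode(s) for s in smiles_list])


class GruSmilesAutoencoder(BaseEstimator, TransformerMixin):
    """Trainable seq2seq fingerprint encoder (GRU bottleneck)."""

    def __init__(
        self,
        dim: int = 128,
        n_layers: int = 2,
        learning_rate: float = 0.01,
        dropout: float = 0.1,
        epochs: int = 100,
        seed: int = 0,
    ):
        self.dim = dim
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.epochs = epochs
        self.seed = seed

    def fit_corpus(self, smiles_list: Sequence[str]) -> "GruSmilesAutoencoder":
        self.model_ = GruSeq2Seq(
            fv_length=self.dim,
            n_layers=self.n_layers,
            learning_rate=self.learning_rate,
            dropout=self.dropout,
            epochs=self.epochs,
            seed=self.seed,
        )
        self.model_.fit([tokenize_smiles(s) for s in smiles_list])
        return self

    def fit(self, X, y=None):
        return self.fit_corpus(X)

    def encode(self, smiles: str) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("GruSmilesAutoencoder is not fitted")
        return self.model_.encode(tokenize_smiles(smiles))

    def transform(self, smiles_list: Sequence[str]) -> np.ndarray:
        return np.vstack([self.encode(s) for s in smiles_list])

    def reconstruction_accuracy(self, smiles_list: Sequence[str]) -> float:
        return self.model_.reconstruction_accuracy([tokenize_smiles(s) for s in smiles_list])


def embed_drug(smiles: str, encoder: DrugEncoder) -> np.ndarray:
    """Encode a single SMILES with any encoder fulfilling the contract."""
    if not smiles:
        raise ValueError("empty SMILES string")
    vec = np.asarray(encoder.encode(smiles), dtype=float)
    if vec.shape != (encoder.dim,):
        raise ValueError(f"encoder returned shape {vec.shape}, declared dim {encoder.dim}")
    return vec


def embed_drug_records(
    records: Sequence[SequenceRecord], encoder: DrugEncoder
) -> EmbeddingMatrix:
    encoder.fit_corpus([r.sequence for r in records])
    return EmbeddingMatrix([r.id for r in records], np.vstack([embed_drug(r.sequence, encoder) for r in records]))


# ---------------------------------------------------------------------------
# similarities
# ---------------------------------------------------------------------------


def cosine_similarity_matrix(emb: EmbeddingMatrix, normalize: bool = True) -> SimilarityMatrix:
    """Pairwise cosine similarity of embedding rows, then min-max to [0,1].

    All-zero rows get similarity 0 to everything (with a warning) since
    their cosine is undefined.
    """
    X = emb.vectors
    norms = np.linalg.norm(X, axis=1)
    zero_rows = norms == 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} all-zero embedding rows; similarities set to 0")
    safe = np.where(zero_rows, 1.0, norms)
    unit = X / safe[:, None]
    sim = unit @ unit.T
    sim[zero_rows, :] = 0.0
    sim[:, zero_rows] = 0.0
    sim = (sim + sim.T) / 2.0
    if normalize:
        sim = minmax_normalize(sim)
        sim = (sim + sim.T) / 2.0
    return SimilarityMatrix(entity_ids=list(emb.entity_ids), values=sim)


def tanimoto_ngram_similarity(records: Sequence[SequenceRecord], n_buckets: int = 2048) -> SimilarityMatrix:
    """Tanimoto similarity over hashed token n-gram sets of SMILES.

    A lightweight stand-in for 2D-structure similarity so the pipeline can
    run without precomputed matrices; operates on token n-gram presence
    sets, so it accepts synthetic (chemically invalid) SMILES too.
    """
    sets = []
    for rec in records:
        keys = _ngram_counts(tokenize_smiles(rec.sequence)).keys()
        sets.append({_stable_hash(k, n_buckets) for k in keys})
    k = len(sets)
    values = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            values[i, j] = values[j, i] = inter / union if union else 0.0
    return SimilarityMatrix(entity_ids=[r.id for r in records], values=values)
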