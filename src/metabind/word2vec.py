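"""Minimal seeded skip-gram-with-negative-sampling (SGNS) word embeddings.

Single-threaded numpy implementation sufficient for k-mer "biological word"
corpora: a vocabulary over the tokens, input/output vector tables, SGD with
a linearly decaying learning rate and unigram^0.75 negative sampling.
Deterministic given the seed.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SkipGramModel", "train_skipgram"]


class SkipGramModel:
    """Trained token -> vector map (the SGNS input vectors)."""

    def __init__(self, vocab: dict[str, int], vectors: np.ndarray):
        self.vocab = vocab
        self.vectors = vectors

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    def __getitem__(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.vocab[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def get(self, token: str) -> np.ndarray | None:
        idx = self.vocab.get(token)
        return None if idx is None else self.vectors[idx]

    def save_word2vec_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.vocab)} {self.dim}\n")
            for token, idx in self.vocab.items():
                vec = " ".join(repr(float(x)) for x in self.vectors[idx])
                fh.write(f"{token} {vec}\n")

    @classmethod
    def load_word2vec_text(cls, path) -> "SkipGramModel":
        with open(path) as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            vocab: dict[str, int] = {}
            vectors = np.empty((n, dim))
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                vocab[parts[0]] = i
                vectors[i] = [float(x) for x in parts[1 : dim + 1]]
        if len(vocab) != n:
            raise ValueError(f"{path}: expected {n} vectors, found {len(vocab)}")
        return cls(vocab, vectors)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_skipgram(
    corpus: Sequence[Sequence[str]],
    dim: int = 100,
    window: int = 5,
    min_count: int = 1,
    epochs: int = 10,
    negative: int = 5,
    lr: float = 0.025,
    min_lr: float = 1e-4,
    seed: int = 0,
) -> SkipGramModel:
    """Train SGNS embeddings on a corpus of token sentences.

    Tokens appearing fewer than ``min_count`` times are dropped.  Context
    windows are symmetric of radius ``window``; negatives are drawn from
    the unigram distribution raised to 3/4.
    """
    sentences = [list(s) for s in corpus if s]
    if not sentences:
        raise ValueError("empty corpus")
    counts = Counter(t for s in sentences for t in s)
    vocab = {t: i for i, (t, c) in enumerate(sorted(counts.items())) if c >= min_count}
    if not vocab:
        raise ValueError(f"no token reaches min_count={min_count}")
    rng = np.random.default_rng(seed)
    n_vocab = len(vocab)
    w_in = (rng.random((n_vocab, dim)) - 0.5) / dim
    w_out = np.zeros((n_vocab, dim))

    freq = np.zeros(n_vocab)
    for t, c in counts.items():
        if t in vocab:
            freq[vocab[t]] = c
    noise = freq**0.75
    noise /= noise.sum()

    encoded = [np.array([vocab[t] for t in s if t in vocab], dtype=np.int64) for s in sentences]
    encoded = [s for s in encoded if s.size > 1]
    if not encoded:
        # single-token sentences only: vectors stay at their init
        return SkipGramModel(vocab, w_in)

    total_steps = epochs * len(encoded)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(encoded))
        for si in order:
            sent = encoded[si]
            alpha = max(min_lr, lr * (1.0 - step / total_steps))
            step += 1
            reduced = rng.integers(0, window, size=sent.size)
            for pos, center in enumerate(sent):
                w = window - reduced[pos]
                lo, hi = max(0, pos - w), min(sent.size, pos + w + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    ctx = sent[cpos]
                    targets = np.empty(negative + 1, dtype=np.int64)
                    targets[0] = ctx
                    targets[1:] = rng.choice(n_vocab, size=negative, p=noise)
                    labels = np.zeros(negative + 1)
                    labels[0] = 1.0
                    v = w_in[center]
                    out = w_out[targets]
                    g = (labels - _sigmoid(out @ v)) * alpha
                    grad_v = g @ out
                    w_out[targets] += np.outer(g, v)
                    w_in[center] += grad_v
    return SkipGramModel(vocab, w_in)
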