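"""Assembly of the three feature variants and the normalization protocol.

PSCORE: meta-path sum/max scores (12 or 24 columns).
EMBED: concatenated drug and protein embeddings (d + k columns).
HYBRID: PSCORE columns followed by EMBED columns.

Pairs with masked (unobserved) labels are excluded from X and Y at
assembly time and never imputed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoders import EmbeddingMatrix
from .io import pair_id
from .metapath import MetaPathFeatureSet

__all__ = [
    "Variant",
    "NormalizationMode",
    "FeatureMatrix",
    "build_embed_features",
    "build_hybrid_features",
    "normalize_train_test",
]


class Variant(enum.Enum):
    PSCORE = "pscore"
    EMBED = "embed"
    HYBRID = "hybrid"


class NormalizationMode(enum.Enum):
    """FIT_ON_TRAIN applies train min/max to both sets (test clipped to
    [0,1]); INDEPENDENT normalizes each set with its own min/max."""

    FIT_ON_TRAIN = "fit_on_train"
    INDEPENDENT = "independent"


@dataclass
class FeatureMatrix:
    pairs: np.ndarray  # (N, 2) positional index pairs
    values: np.ndarray  # (N, p)
    columns: list[str]
    variant: Variant

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.pairs.shape[0]:
            raise ValueError("values must be (n_pairs, p)")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names do not match value width")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def to_frame(self, drug_ids: Sequence[str], target_ids: Sequence[str]) -> pd.DataFrame:
        idx = [pair_id(drug_ids[i], target_ids[j]) for i, j in self.pairs]
        return pd.DataFrame(self.values, index=idx, columns=self.columns)

    def write(self, path: str | Path, drug_ids: Sequence[str], target_ids: Sequence[str]) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# variant={self.variant.value}\n")
            self.to_frame(drug_ids, target_ids).to_csv(fh, sep="\t", index_label="pair")


def build_embed_features(
    drug_emb: EmbeddingMatrix,
    prot_emb: EmbeddingMatrix,
    pairs: Sequence[tuple[int, int]] | np.ndarray,
) -> FeatureMatrix:
    """Row per pair = drug vector followed by protein vector (d + k columns)."""
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
    if pairs.shape[0]:
        if pairs[:, 0].max() >= len(drug_emb.entity_ids):
            raise ValueError(f"drug index {pairs[:, 0].max()} has no embedding")
        if pairs[:, 1].max() >= len(prot_emb.entity_ids):
            raise ValueError(f"target index {pairs[:, 1].max()} has no embedding")
        values = np.hstack([drug_emb.vectors[pairs[:, 0]], prot_emb.vectors[pairs[:, 1]]])
    else:
        values = np.empty((0, drug_emb.dim + prot_emb.dim))
    columns = [f"drug_e{i}" for i in range(drug_emb.dim)] + [
        f"prot_e{i}" for i in range(prot_emb.dim)
    ]
    return FeatureMatrix(pairs=pairs, values=values, columns=columns, variant=Variant.EMBED)


def build_hybrid_features(pscore: MetaPathFeatureSet, embed: FeatureMatrix) -> FeatureMatrix:
    """PSCORE columns then EMBED columns; pair orderings must match."""
    if pscore.pairs.shape != embed.pairs.shape or np.any(pscore.pairs != embed.pairs):
        raise ValueError("meta-path and embedding feature sets index different pairs")
    return FeatureMatrix(
        pairs=embed.pairs,
        values=np.hstack([pscore.values, embed.values]),
        columns=list(pscore.columns) + list(embed.columns),
        variant=Variant.HYBRID,
    )


def pscore_matrix(pscore: MetaPathFeatureSet) -> FeatureMatrix:
    return FeatureMatrix(
        pairs=pscore.pairs,
        values=pscore.values,
        columns=list(pscore.columns),
        variant=Variant.PSCORE,
    )


def normalize_train_test(
    train: FeatureMatrix,
    test: FeatureMatrix,
    mode: NormalizationMode = NormalizationMode.INDEPENDENT,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Column-wise min-max normalization of train and test feature blocks.

    INDEPENDENT scales each block with its own per-column min/max (constant
    columns map to zero).  FIT_ON_TRAIN scales both with the train min/max
    and clips the test block to [0, 1]; this is the leakage-safe protocol
    recommended for real use.
    """
    if train.columns != test.columns:
        raise ValueError("train and test feature columns differ")

    def _scale(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = hi - lo
        out = np.zeros_like(values)
        ok = span > 0
        out[:, ok] = (values[:, ok] - lo[ok]) / span[ok]
        return out

    if mode is NormalizationMode.INDEPENDENT:
        blocks = []
        for fm in (train, test):
            if fm.values.shape[0]:
                lo, hi = fm.values.min(axis=0), fm.values.max(axis=0)
                vals = _scale(fm.values, lo, hi)
            else:
                vals = fm.values.copy()
            blocks.append(FeatureMatrix(fm.pairs, vals, list(fm.columns), fm.variant))
        return blocks[0], blocks[1]

    lo, hi = train.values.min(axis=0), train.values.max(axis=0)
    train_vals = _scale(train.values, lo, hi)
    test_vals = np.clip(_scale(test.values, lo, hi), 0.0, 1.0)
    return (
        FeatureMatrix(train.pairs, train_vals, list(train.columns), train.variant),
        FeatureMatrix(test.pairs, test_vals, list(test.columns), test.variant),
    )
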