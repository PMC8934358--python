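"""Weighted heterogeneous drug-target graph construction.

The graph has three edge classes: drug-drug similarity (thresholded),
target-target similarity (thresholded), and drug-target affinity edges
whose raw values are mapped into [0, 1] "binding strength" weights so that
a larger weight always means a stronger binder, matching the similarity
semantics of the other two edge classes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .io import AffinityDataset, Orientation

__all__ = [
    "AffinityTransform",
    "TransformConfig",
    "WeightedHeteroGraph",
    "transform_pkd",
    "minmax_normalize",
    "filter_similarity",
    "transform_affinity_exponential",
    "transform_affinity_softmax",
    "assemble_graph",
]


class AffinityTransform(enum.Enum):
    EXPONENTIAL = "exponential"
    SOFTMAX = "softmax"


@dataclass(frozen=True)
class TransformConfig:
    """How raw affinities become [0,1] edge weights, plus similarity cutoffs.

    ``alpha`` is the exponential decay rate of the EXPONENTIAL transform
    applied to the distance-like affinity; ``drug_threshold`` and
    ``target_threshold`` zero out similarity edges below the cutoff
    (defaults follow the Davis-style settings 0.3 and 0.04).
    """

    method: AffinityTransform = AffinityTransform.EXPONENTIAL
    alpha: float = 1.0
    drug_threshold: float = 0.3
    target_threshold: float = 0.04

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        for name in ("drug_threshold", "target_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class WeightedHeteroGraph:
    """Block representation of the heterogeneous graph.

    ``dd`` (n x n) and ``tt`` (m x m) are symmetric with zero diagonals;
    ``dt`` (n x m) holds transformed affinity weights and is zero wherever
    ``edge_mask`` is False (missing or held-out pairs).
    """

    dd: np.ndarray
    tt: np.ndarray
    dt: np.ndarray
    edge_mask: np.ndarray

    def __post_init__(self) -> None:
        self.dd = np.asarray(self.dd, dtype=float)
        self.tt = np.asarray(self.tt, dtype=float)
        self.dt = np.asarray(self.dt, dtype=float)
        self.edge_mask = np.asarray(self.edge_mask, dtype=bool)
        n, m = self.dt.shape
        if self.dd.shape != (n, n) or self.tt.shape != (m, m):
            raise ValueError("block shapes inconsistent")
        if self.edge_mask.shape != (n, m):
            raise ValueError("edge_mask shape mismatch")
        for name, block in (("dd", self.dd), ("tt", self.tt)):
            if np.abs(block - block.T).max(initial=0.0) > 1e-9:
                raise ValueError(f"{name} block not symmetric")
            if np.abs(np.diagonal(block)).max(initial=0.0) != 0.0:
                raise ValueError(f"{name} diagonal must be zero")
        for name, block in (("dd", self.dd), ("tt", self.tt), ("dt", self.dt)):
            if block.size and (block.min() < 0.0 or block.max() > 1.0):
                raise ValueError(f"{name} weights must lie in [0, 1]")
        if np.any(self.dt[~self.edge_mask] != 0.0):
            raise ValueError("dt must be zero where edge_mask is False")

    @property
    def n_drugs(self) -> int:
        return self.dd.shape[0]

    @property
    def n_targets(self) -> int:
        return self.tt.shape[0]


def transform_pkd(kd_nM: float | np.ndarray) -> float | np.ndarray:
    """Map a dissociation constant in nanomolar to pKd = -log10(Kd / 1e9)."""
    arr = np.asarray(kd_nM, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("Kd must be strictly positive (nanomolar)")
    out = -np.log10(arr / 1e9)
    return float(out) if np.isscalar(kd_nM) else out


def minmax_normalize(values: np.ndarray, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Affine map onto [0,1]; a constant input maps to all-zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    lo = float(np.min(values)) if lo is None else float(lo)
    hi = float(np.max(values)) if hi is None else float(hi)
    if hi <= lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def filter_similarity(values: np.ndarray, threshold: float) -> np.ndarray:
    """Zero out entries below ``threshold`` and force the diagonal to zero.

    The zero diagonal means a node never transitions to itself inside a
    meta-path.  Idempotent.
    """
    values = np.asarray(values, dtype=float)
    out = np.where(values >= threshold, values, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def transform_affinity_exponential(values: np.ndarray, alpha: float) -> np.ndarray:
    """Elementwise exp(-alpha * z): strictly decreasing, (0,1] for z >= 0."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return np.exp(-alpha * np.asarray(values, dtype=float))


def transform_affinity_softmax(values: np.ndarray) -> np.ndarray:
    """Max-shifted softmax over the full value vector; sums to one."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("softmax over an empty vector")
    shifted = values - values.max()
    e = np.exp(shifted)
    return e / e.sum()


def _distance_oriented(values: np.ndarray, orientation: Orientation) -> np.ndarray:
    """Return a quantity where smaller = stronger binding.

    LOWER_IS_STRONGER values (raw Kd, raw KIBA) already are distances;
    HIGHER_IS_STRONGER scales (pKd) are flipped as max - value.
    """
    if orientation is Orientation.LOWER_IS_STRONGER:
        return values
    return values.max() - values


def assemble_graph(
    dd: np.ndarray,
    tt: np.ndarray,
    dataset: AffinityDataset,
    cfg: TransformConfig = TransformConfig(),
    holdout_pairs: set[tuple[int, int]] | None = None,
) -> WeightedHeteroGraph:
    """Build the heterogeneous graph, masking held-out affinity edges.

    ``dd`` / ``tt`` must already be normalized to [0,1] and thresholded.
    The affinity transform is computed over observed *training* edges only
    (held-out edges contribute nothing, not even to the softmax
    normalizer), so no test information leaks into any edge weight.
    """
    holdout_pairs = holdout_pairs or set()
    observed = dataset.observed.copy()
    for (i, j) in holdout_pairs:
        if not dataset.observed[i, j]:
            raise ValueError(f"holdout pair ({i}, {j}) is not an observed entry")
    edge_mask = observed.copy()
    if holdout_pairs:
        hi, hj = zip(*holdout_pairs)
        edge_mask[list(hi), list(hj)] = False

    dt = np.zeros_like(dataset.affinities, dtype=float)
    idx = np.argwhere(edge_mask)
    if idx.size:
        raw = dataset.affinities[idx[:, 0], idx[:, 1]]
        dist = _distance_oriented(raw, dataset.orientation)
        if cfg.method is AffinityTransform.EXPONENTIAL:
            weights = transform_affinity_exponential(dist, cfg.alpha)
        else:
            # softmax of the negated distance: strongest binder gets the
            # largest probability mass; rescale so the strongest edge gets
            # weight 1 and D-T weights stay comparable to similarity edges
            weights = transform_affinity_softmax(-dist)
            top = weights.max()
            if top > 0:
                weights = weights / top
        dt[idx[:, 0], idx[:, 1]] = weights
    return WeightedHeteroGraph(dd=dd, tt=tt, dt=dt, edge_mask=edge_mask)
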