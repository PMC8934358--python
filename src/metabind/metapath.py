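"""Meta-path score features over the weighted heterogeneous graph.

For every drug-target pair and each of the six path structures
C1: D-D-T, C2: D-T-T, C3: D-D-D-T, C4: D-T-T-T, C5: D-D-T-T, C6: D-T-D-T
(all drug-to-target type sequences of 2 or 3 edges), the score of a path
is the product of its edge weights; the features are the sum and the max
of these products over all paths of that structure.

Sums are computed with ordinary matrix products (commuting matrices) and
maxima with (max, *) semiring products.  Matrix products count *walks*;
under the default simple-path semantics the closed-form revisit terms are
subtracted (sums) or the offending candidates excluded (maxima):

* C3 walks d_i -> d_k -> d_i -> t_j contribute diag(DD^2)_i * A_ij;
* C4 walks d_i -> t_j -> t_l -> t_j contribute A_ij * diag(TT^2)_j;
* C6 walks revisiting d_i or t_j contribute
  A_ij * diag(A A^T)_i + A_ij * diag(A^T A)_j - A_ij^3
  (inclusion-exclusion for the doubly-degenerate walk d_i->t_j->d_i->t_j).

Zero diagonals on DD/TT (enforced by the graph builder) remove every other
self-transition.  A brute-force simple-path enumeration oracle is provided
for verification on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .graph import WeightedHeteroGraph

__all__ = [
    "STRUCTURES",
    "enumerate_structures",
    "sum_scores",
    "max_scores",
    "enumerate_path_scores",
    "MetaPathFeatureSet",
    "pair_features",
    "MetaPathFeaturizer",
]

#: the six drug-to-target type sequences with 2 or 3 edges
STRUCTURES: tuple[str, ...] = ("DDT", "DTT", "DDDT", "DTTT", "DDTT", "DTDT")
STRUCTURE_LABELS: tuple[str, ...] = tuple(f"C{i + 1}" for i in range(6))

Semantics = Literal["simple", "walk"]


def enumerate_structures(max_len: int = 3) -> list[str]:
    """All D...T type sequences of 2..max_len edges joinable by D-D, T-T, D-T edges.

    Consecutive equal types use a similarity edge; a D,T or T,D step uses an
    affinity edge, so every type sequence over {D, T} starting with D and
    ending with T is realizable.  Single-edge (direct D-T) paths are
    excluded by the 2-edge minimum.
    """
    if max_len not in (2, 3):
        raise ValueError("max_len must be 2 or 3")
    out: list[str] = []
    for n_edges in range(2, max_len + 1):
        # interior type choices; first node D, last node T
        n_interior = n_edges - 1
        for mask in range(2**n_interior):
            interior = ["D" if (mask >> b) & 1 == 0 else "T" for b in range(n_interior)]
            out.append("D" + "".join(interior) + "T")
    order = {s: i for i, s in enumerate(STRUCTURES)}
    return sorted(out, key=lambda s: order.get(s, len(order)))


def _maxprod(a: np.ndarray, b: np.ndarray, chunk: int = 256) -> np.ndarray:
    """(max, *) semiring matrix product."""
    out = np.empty((a.shape[0], b.shape[1]))
    for lo in range(0, a.shape[0], chunk):
        hi = min(lo + chunk, a.shape[0])
        out[lo:hi] = np.max(a[lo:hi, :, None] * b[None, :, :], axis=1)
    return out


def sum_scores(g: WeightedHeteroGraph, semantics: Semantics = "simple") -> np.ndarray:
    """SumScore_h(i, j) for h = 1..6, shape (n_drugs, n_targets, 6)."""
    dd, tt, a = g.dd, g.tt, g.dt
    c1 = dd @ a
    c2 = a @ tt
    dd2 = dd @ dd
    tt2 = tt @ tt
    c3 = dd2 @ a
    c4 = a @ tt2
    c5 = dd @ a @ tt
    c6 = a @ a.T @ a
    if semantics == "simple":
        c3 = c3 - np.diagonal(dd2)[:, None] * a
        c4 = c4 - a * np.diagonal(tt2)[None, :]
        row = np.einsum("ij,ij->i", a, a)  # diag(A A^T)
        col = np.einsum("ij,ij->j", a, a)  # diag(A^T A)
        c6 = c6 - a * row[:, None] - a * col[None, :] + a**3
    out = np.stack([c1, c2, c3, c4, c5, c6], axis=-1)
    # float cancellation in the corrections can leave tiny negatives
    np.clip(out, 0.0, None, out=out)
    return out


def max_scores(g: WeightedHeteroGraph, semantics: Semantics = "simple") -> np.ndarray:
    """MaxScore_h(i, j) for h = 1..6, shape (n_drugs, n_targets, 6)."""
    dd, tt, a = g.dd, g.tt, g.dt
    c1 = _maxprod(dd, a)
    c2 = _maxprod(a, tt)
    c5 = _maxprod(_maxprod(dd, a), tt)
    m_dd = _maxprod(dd, dd)
    m_tt = _maxprod(tt, tt)
    if semantics == "simple":
        np.fill_diagonal(m_dd, 0.0)  # kills d_i -> d_k -> d_i revisits
        np.fill_diagonal(m_tt, 0.0)  # kills t_j -> t_l -> t_j revisits
        c6 = _max_c6_simple(a)
    else:
        c6 = _maxprod(_maxprod(a, a.T), a)
    c3 = _maxprod(m_dd, a)
    c4 = _maxprod(a, m_tt)
    return np.stack([c1, c2, c3, c4, c5, c6], axis=-1)


def _max_c6_simple(a: np.ndarray) -> np.ndarray:
    """Max over D-T-D-T paths d_i -> t_k -> d_l -> t_j with l != i, k != j.

    Uses a top-2 trick: for each (i, l) keep the best and second-best
    intermediate target k of A_ik * A_lk, so the k == j exclusion can fall
    back to the runner-up.
    """
    n, m = a.shape
    prod = a[:, None, :] * a[None, :, :]  # (i, l, k) -> A_ik * A_lk
    k1 = np.argmax(prod, axis=2)
    b1 = np.take_along_axis(prod, k1[:, :, None], axis=2)[:, :, 0]
    prod2 = prod.copy()
    np.put_along_axis(prod2, k1[:, :, None], -np.inf, axis=2)
    b2 = np.max(prod2, axis=2) if m > 1 else np.zeros((n, n))
    b2 = np.where(np.isfinite(b2), b2, 0.0)
    out = np.empty((n, m))
    for j in range(m):
        cand = np.where(k1 == j, b2, b1)  # (i, l) with k != j enforced
        np.fill_diagonal(cand, 0.0)  # exclude l == i
        scored = cand * a[:, j][None, :]  # times A_lj, l runs over columns
        out[:, j] = scored.max(axis=1, initial=0.0)
    return np.clip(out, 0.0, None)


def enumerate_path_scores(
    g: WeightedHeteroGraph, semantics: Semantics = "simple"
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force (sum, max) over explicit path enumeration; small graphs only.

    Returns two (n, m, 6) arrays.  Under ``simple`` semantics no node may
    repeat within a path; ``walk`` allows revisits (matching raw matrix
    products with zero-diagonal DD/TT).
    """
    dd, tt, a = g.dd, g.tt, g.dt
    n, m = a.shape

    def edge(t1: str, i: int, t2: str, j: int) -> float:
        if t1 == "D" and t2 == "D":
            return dd[i, j]
        if t1 == "T" and t2 == "T":
            return tt[i, j]
        if t1 == "D" and t2 == "T":
            return a[i, j]
        return a[j, i]

    sums = np.zeros((n, m, 6))
    maxs = np.zeros((n, m, 6))
    for h, struct in enumerate(STRUCTURES):
        interior_types = struct[1:-1]
        for i in range(n):
            for j in range(m):
                total = 0.0
                best = 0.0
                ranges = [range(n) if t == "D" else range(m) for t in interior_types]
                stack: list[tuple[int, ...]] = [()]
                for r in ranges:
                    stack = [s + (k,) for s in stack for k in r]
                for interior in stack:
                    nodes = [("D", i)] + [
                        (t, k) for t, k in zip(interior_types, interior)
                    ] + [("T", j)]
                    if semantics == "simple" and len(set(nodes)) != len(nodes):
                        continue
                    w = 1.0
                    for (t1, u), (t2, v) in zip(nodes, nodes[1:]):
                        w *= edge(t1, u, t2, v)
                        if w == 0.0:
                            break
                    total += w
                    best = max(best, w)
                sums[i, j, h] = total
                maxs[i, j, h] = best
    return sums, maxs


@dataclass
class MetaPathFeatureSet:
    """Per-pair meta-path features: 12 columns per source graph."""

    pairs: np.ndarray  # (N, 2) drug/target index pairs
    values: np.ndarray  # (N, 12) or (N, 24)
    columns: list[str]

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.values = np.asarray(self.values, dtype=float).reshape(
            self.pairs.shape[0], -1 if self.pairs.shape[0] else len(self.columns)
        )
        if self.pairs.shape[0] and self.values.shape[1] != len(self.columns):
            raise ValueError("column names do not match value width")

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def _graph_feature_block(g: WeightedHeteroGraph, pairs: np.ndarray, semantics: Semantics) -> np.ndarray:
    s = sum_scores(g, semantics)
    x = max_scores(g, semantics)
    di, tj = pairs[:, 0], pairs[:, 1]
    return np.hstack([s[di, tj, :], x[di, tj, :]])


def pair_features(
    g1: WeightedHeteroGraph,
    g2: WeightedHeteroGraph | None = None,
    pairs: Sequence[tuple[int, int]] | np.ndarray = (),
    semantics: Semantics = "simple",
) -> MetaPathFeatureSet:
    """12 features per pair per graph: (Sum_C1..C6, Max_C1..C6), g1 then g2."""
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
    graphs = [("G1", g1)] + ([("G2", g2)] if g2 is not None else [])
    columns: list[str] = []
    for gname, g in graphs:
        if g.dd.shape != g1.dd.shape or g.tt.shape != g1.tt.shape:
            raise ValueError("graphs must share entity orderings")
        columns += [f"{gname}_Sum_{c}" for c in STRUCTURE_LABELS]
        columns += [f"{gname}_Max_{c}" for c in STRUCTURE_LABELS]
    if pairs.shape[0] == 0:
        return MetaPathFeatureSet(
            pairs=np.empty((0, 2), dtype=int),
            values=np.empty((0, len(columns))),
            columns=columns,
        )
    if pairs[:, 0].max() >= g1.n_drugs or pairs[:, 1].max() >= g1.n_targets:
        raise ValueError("pair index outside graph entity range")
    blocks = [_graph_feature_block(g, pairs, semantics) for _, g in graphs]
    return MetaPathFeatureSet(pairs=pairs, values=np.hstack(blocks), columns=columns)


class MetaPathFeaturizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: (drug, target) index pairs -> path scores.

    The graph context (g1 and optionally g2) is bound at ``fit`` time;
    ``transform`` takes an (N, 2) array of index pairs and returns the
    12- or 24-column score matrix.
    """

    def __init__(self, semantics: Semantics = "simple"):
        self.semantics = semantics

    def fit(self, graphs: WeightedHeteroGraph | Sequence[WeightedHeteroGraph], y=None):
        if isinstance(graphs, WeightedHeteroGraph):
            graphs = [graphs]
        if not 1 <= len(graphs) <= 2:
            raise ValueError("expect one or two graphs")
        self.graphs_ = list(graphs)
        self.sum_scores_ = [sum_scores(g, self.semantics) for g in self.graphs_]
        self.max_scores_ = [max_scores(g, self.semantics) for g in self.graphs_]
        self.columns_ = []
        for idx in range(len(self.graphs_)):
            gname = f"G{idx + 1}"
            self.columns_ += [f"{gname}_Sum_{c}" for c in STRUCTURE_LABELS]
            self.columns_ += [f"{gname}_Max_{c}" for c in STRUCTURE_LABELS]
        return self

    def transform(self, pairs: np.ndarray) -> np.ndarray:
        if not hasattr(self, "graphs_"):
            raise RuntimeError("MetaPathFeaturizer is not fitted")
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        if pairs.shape[0] == 0:
            return np.empty((0, len(self.columns_)))
        di, tj = pairs[:, 0], pairs[:, 1]
        blocks = []
        for s, x in zip(self.sum_scores_, self.max_scores_):
            blocks.append(np.hstack([s[di, tj, :], x[di, tj, :]]))
        return np.hstack(blocks)
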