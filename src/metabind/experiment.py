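"""End-to-end runs: splits, leakage-safe per-fold graph rebuilds, reports.

Setting 1 is a nested cross-validation: the labelled pairs are randomly
partitioned into six near-equal sets; one is the hold-out, the other five
act as inner CV folds.  For every inner fold the heterogeneous graph is
rebuilt with that fold's AND the hold-out's affinity edges removed, the
regressor is trained on the remaining labelled pairs, and the hold-out is
scored.  Reported hold-out metrics are (by default) the average of the
five models' metric values; metrics of the averaged prediction vector are
available as an alternate aggregation.

Setting 2 is a time-based split keyed by a per-pair year map.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoders import (
    EmbeddingMatrix,
    HashedSmilesEncoder,
    ProteinKmerEmbedder,
    cosine_similarity_matrix,
    embed_drug_records,
)
from .evaluation import EvalReport, PositiveRule, evaluate
from .features import (
    FeatureMatrix,
    NormalizationMode,
    Variant,
    build_embed_features,
    build_hybrid_features,
    normalize_train_test,
    pscore_matrix,
)
from .graph import TransformConfig, WeightedHeteroGraph, assemble_graph, filter_similarity, minmax_normalize
from .io import AffinityDataset, SequenceRecord, SimilarityMatrix
from .metapath import pair_features
from .regressor import AffinityBoostRegressor, BoostParams, tune

__all__ = [
    "SplitScheme",
    "SplitSpec",
    "GraphSource",
    "RunConfig",
    "PipelineData",
    "make_nested_cv_splits",
    "make_time_split",
    "run_pipeline",
]

log = logging.getLogger("metabind")


class SplitScheme(enum.Enum):
    NESTED_CV = "nested_cv"
    TIME_BASED = "time_based"


class GraphSource(enum.Enum):
    G1 = "g1"  # provided similarity matrices
    G2 = "g2"  # cosine similarities of learned embeddings
    G1G2 = "g1g2"


@dataclass(frozen=True)
class SplitSpec:
    scheme: SplitScheme = SplitScheme.NESTED_CV
    n_partitions: int = 6
    inner_folds: int = 5
    train_max_year: int = 2011
    valid_year: int = 2012
    test_min_year: int = 2013
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_partitions != self.inner_folds + 1:
            raise ValueError("n_partitions must equal inner_folds + 1")


@dataclass
class RunConfig:
    transform: TransformConfig = field(default_factory=TransformConfig)
    variant: Variant = Variant.PSCORE
    graph_source: GraphSource = GraphSource.G1
    params: BoostParams = field(default_factory=lambda: BoostParams(n_trees=300, max_depth=5))
    tune_grid: Sequence[BoostParams] | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    normalization: NormalizationMode = NormalizationMode.FIT_ON_TRAIN
    aggregate_predictions: bool = True  # metrics of the bagged (averaged) predictions
    aupr_thresholds: tuple[float, ...] = ()
    positive_rule: PositiveRule = PositiveRule.GE
    drug_embed_dim: int = 64
    protein_embed_dim: int = 32
    protein_embed_epochs: int = 3
    semantics: str = "simple"
    seed: int = 0

    def child_seed(self, stream: int) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        ss = np.random.SeedSequence([self.seed, stream])
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineData:
    """In-memory bundle of everything a run needs."""

    dataset: AffinityDataset
    drug_similarity: SimilarityMatrix | None = None
    target_similarity: SimilarityMatrix | None = None
    smiles: list[SequenceRecord] | None = None
    proteins: list[SequenceRecord] | None = None


def make_nested_cv_splits(
    pairs: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Seeded partition into ``n_partitions`` near-equal sets.

    Returns (holdout_pairs, [fold_pairs x inner_folds]); sizes differ by
    at most one.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.shape[0] < spec.n_partitions:
        raise ValueError(
            f"{pairs.shape[0]} labelled pairs cannot fill {spec.n_partitions} partitions"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(pairs.shape[0])
    parts = np.array_split(order, spec.n_partitions)
    holdout = pairs[parts[0]]
    folds = [pairs[p] for p in parts[1:]]
    return holdout, folds


def make_time_split(
    pairs: np.ndarray,
    year_map: dict[tuple[int, int], int],
    spec: SplitSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split pairs by year: train <= train_max_year, valid == valid_year,
    test >= test_min_year; pairs between ranges are dropped with a log line."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    years = []
    for i, j in pairs:
        key = (int(i), int(j))
        if key not in year_map:
            raise ValueError(f"pair {key} has no year")
        years.append(year_map[key])
    years = np.array(years)
    train = pairs[years <= spec.train_max_year]
    valid = pairs[years == spec.valid_year]
    test = pairs[years >= spec.test_min_year]
    dropped = pairs.shape[0] - train.shape[0] - valid.shape[0] - test.shape[0]
    if dropped:
        log.info("time split dropped %d pairs outside all year ranges", dropped)
    if valid.shape[0] == 0 or test.shape[0] == 0:
        raise ValueError("time split produced an empty validation or test set")
    return train, valid, test


def _prepare_similarity(sim: SimilarityMatrix, threshold: float) -> np.ndarray:
    values = minmax_normalize(sim.values)
    values = (values + values.T) / 2.0
    return filter_similarity(values, threshold)


def _build_embeddings(data: PipelineData, cfg: RunConfig) -> tuple[EmbeddingMatrix, EmbeddingMatrix]:
    if data.smiles is None or data.proteins is None:
        raise ValueError("SMILES and protein records required for embeddings")
    drug_enc = HashedSmilesEncoder(dim=cfg.drug_embed_dim, seed=cfg.child_seed(1))
    drug_emb = embed_drug_records(data.smiles, drug_enc)
    prot = ProteinKmerEmbedder(
        dim=cfg.protein_embed_dim,
        epochs=cfg.protein_embed_epochs,
        seed=cfg.child_seed(2),
    ).fit([r.sequence for r in data.proteins])
    prot_emb = prot.embed_records(data.proteins)
    return drug_emb, prot_emb


def _similarity_blocks(
    data: PipelineData,
    cfg: RunConfig,
    embeddings: tuple[EmbeddingMatrix, EmbeddingMatrix] | None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalized + thresholded (dd, tt) blocks for each requested graph."""
    blocks = []
    if cfg.graph_source in (GraphSource.G1, GraphSource.G1G2):
        if data.drug_similarity is None or data.target_similarity is None:
            raise ValueError("G1 requires provided similarity matrices")
        blocks.append(
            (
                _prepare_similarity(data.drug_similarity, cfg.transform.drug_threshold),
                _prepare_similarity(data.target_similarity, cfg.transform.target_threshold),
            )
        )
    if cfg.graph_source in (GraphSource.G2, GraphSource.G1G2):
        if embeddings is None:
            raise ValueError("G2 requires embeddings")
        drug_emb, prot_emb = embeddings
        dd2 = cosine_similarity_matrix(drug_emb)
        tt2 = cosine_similarity_matrix(prot_emb)
        blocks.append(
            (
                filter_similarity(dd2.values, cfg.transform.drug_threshold),
                filter_similarity(tt2.values, cfg.transform.target_threshold),
            )
        )
    return blocks


def _fold_features(
    data: PipelineData,
    cfg: RunConfig,
    sim_blocks: list[tuple[np.ndarray, np.ndarray]],
    embeddings: tuple[EmbeddingMatrix, EmbeddingMatrix] | None,
    masked_pairs: set[tuple[int, int]],
    train_pairs: np.ndarray,
    eval_pairs: np.ndarray,
) -> tuple[FeatureMatrix, FeatureMatrix, list[WeightedHeteroGraph]]:
    """Features for one fold with ``masked_pairs`` removed from every graph."""
    graphs = [
        assemble_graph(dd, tt, data.dataset, cfg.transform, holdout_pairs=masked_pairs)
        for dd, tt in sim_blocks
    ]
    for g in graphs:
        for (i, j) in masked_pairs:
            assert not g.edge_mask[i, j], "masked affinity edge leaked into a graph"

    def _variant_features(pairs: np.ndarray) -> FeatureMatrix:
        if cfg.variant in (Variant.PSCORE, Variant.HYBRID):
            ps = pair_features(
                graphs[0],
                graphs[1] if len(graphs) > 1 else None,
                pairs,
                semantics=cfg.semantics,
            )
        if cfg.variant is Variant.PSCORE:
            return pscore_matrix(ps)
        drug_emb, prot_emb = embeddings
        emb = build_embed_features(drug_emb, prot_emb, pairs)
        if cfg.variant is Variant.EMBED:
            return emb
        return build_hybrid_features(ps, emb)

    train_fm = _variant_features(train_pairs)
    eval_fm = _variant_features(eval_pairs)
    train_fm, eval_fm = normalize_train_test(train_fm, eval_fm, cfg.normalization)
    return train_fm, eval_fm, graphs


def run_pipeline(data: PipelineData, cfg: RunConfig) -> dict:
    """Nested-CV pipeline; returns the aggregate report and per-fold detail.

    The returned dict has keys ``report`` (EvalReport), ``fold_reports``
    (list of EvalReport), ``holdout_pairs``, ``params`` and
    ``feature_dimension``.
    """
    t0 = time.perf_counter()
    dataset = data.dataset
    pairs = dataset.observed_pairs()
    split = dataclasses.replace(cfg.split, seed=cfg.child_seed(0))
    holdout, folds = make_nested_cv_splits(pairs, split)
    holdout_set = {(int(i), int(j)) for i, j in holdout}

    needs_embeddings = cfg.variant in (Variant.EMBED, Variant.HYBRID) or cfg.graph_source in (
        GraphSource.G2,
        GraphSource.G1G2,
    )
    embeddings = _build_embeddings(data, cfg) if needs_embeddings else None
    sim_blocks = _similarity_blocks(data, cfg, embeddings)
    log.info(
        "pipeline start: %d drugs x %d targets, %d labelled pairs, variant=%s, graphs=%s",
        dataset.n_drugs,
        dataset.n_targets,
        pairs.shape[0],
        cfg.variant.value,
        cfg.graph_source.value,
    )

    y_holdout = dataset.labels(holdout)
    fold_reports: list[EvalReport] = []
    predictions = []
    params = cfg.params
    for k, fold in enumerate(folds):
        fold_set = {(int(i), int(j)) for i, j in fold}
        masked = holdout_set | fold_set
        train_pairs = np.array(
            [p for p in pairs if (int(p[0]), int(p[1])) not in masked], dtype=int
        )
        train_fm, hold_fm, _ = _fold_features(
            data, cfg, sim_blocks, embeddings, masked, train_pairs, holdout
        )
        y_train = dataset.labels(train_pairs)
        if cfg.tune_grid is not None and k == 0:
            params, _ = tune(
                train_fm.values, y_train, cfg.tune_grid, folds=split.inner_folds, seed=cfg.child_seed(3)
            )
            log.info("tuned params: %s", params)
        model = AffinityBoostRegressor.from_params(
            dataclasses.replace(params, seed=cfg.child_seed(10 + k))
        ).fit(train_fm.values, y_train)
        pred = model.predict(hold_fm.values)
        predictions.append(pred)
        fold_reports.append(
            evaluate(pred, y_holdout, cfg.aupr_thresholds, cfg.positive_rule)
        )
        log.info(
            "fold %d: train=%d, holdout mse=%.4f ci=%.4f",
            k,
            train_pairs.shape[0],
            fold_reports[-1].mse,
            fold_reports[-1].ci,
        )

    if cfg.aggregate_predictions:
        mean_pred = np.mean(predictions, axis=0)
        report = evaluate(mean_pred, y_holdout, cfg.aupr_thresholds, cfg.positive_rule)
    else:
        report = _average_reports(fold_reports)
    log.info("pipeline done in %.1fs: mse=%.4f ci=%.4f", time.perf_counter() - t0, report.mse, report.ci)
    return {
        "report": report,
        "fold_reports": fold_reports,
        "holdout_pairs": holdout,
        "predictions": np.asarray(predictions),
        "params": params,
        "feature_dimension": _feature_dimension(cfg),
    }


def _average_reports(reports: list[EvalReport]) -> EvalReport:
    def avg(attr):
        return float(np.mean([getattr(r, attr) for r in reports]))

    thresholds = reports[0].aupr_per_threshold.keys()
    per = {
        t: float(np.mean([r.aupr_per_threshold[t] for r in reports])) for t in thresholds
    }
    return EvalReport(
        mse=avg("mse"),
        rmse=avg("rmse"),
        ci=avg("ci"),
        r2=avg("r2"),
        r0_2=avg("r0_2"),
        rm2=avg("rm2"),
        aupr_per_threshold=per,
        aupr_mean=avg("aupr_mean") if per else float("nan"),
        n=reports[0].n,
    )


def _feature_dimension(cfg: RunConfig) -> int:
    n_graphs = 2 if cfg.graph_source is GraphSource.G1G2 else 1
    pscore = 12 * n_graphs
    embed = cfg.drug_embed_dim + cfg.protein_embed_dim
    if cfg.variant is Variant.PSCORE:
        return pscore
    if cfg.variant is Variant.EMBED:
        return embed
    return pscore + embed


def run_time_split(
    data: PipelineData,
    cfg: RunConfig,
    year_map: dict[tuple[int, int], int],
) -> dict:
    """Setting-2: train on early years, validate mid, test late."""
    dataset = data.dataset
    pairs = dataset.observed_pairs()
    train, valid, test = make_time_split(pairs, year_map, cfg.split)
    needs_embeddings = cfg.variant in (Variant.EMBED, Variant.HYBRID) or cfg.graph_source in (
        GraphSource.G2,
        GraphSource.G1G2,
    )
    embeddings = _build_embeddings(data, cfg) if needs_embeddings else None
    sim_blocks = _similarity_blocks(data, cfg, embeddings)
    masked = {(int(i), int(j)) for i, j in np.vstack([valid, test])}
    train_fm, test_fm, _ = _fold_features(
        data, cfg, sim_blocks, embeddings, masked, train, test
    )
    _, valid_fm, _ = _fold_features(data, cfg, sim_blocks, embeddings, masked, train, valid)
    y_train = dataset.labels(train)
    model = AffinityBoostRegressor.from_params(
        dataclasses.replace(cfg.params, seed=cfg.child_seed(20))
    ).fit(train_fm.values, y_train)
    report = evaluate(
        model.predict(test_fm.values), dataset.labels(test), cfg.aupr_thresholds, cfg.positive_rule
    )
    valid_report = evaluate(
        model.predict(valid_fm.values), dataset.labels(valid), cfg.aupr_thresholds, cfg.positive_rule
    )
    return {"report": report, "valid_report": valid_report, "sizes": (len(train), len(valid), len(test))}
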