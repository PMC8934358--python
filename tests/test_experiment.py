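import json

import numpy as np
import pytest

import metabind as mb
from metabind.experiment import _feature_dimension
from metabind.features import Variant
from metabind.regressor import BoostParams


def _pairs(n):
    return np.array([(i // 10, i % 10) for i in range(n)])


class TestNestedCvSplits:
    def test_600_pairs_split_into_six_hundreds(self):
        hold, folds = mb.make_nested_cv_splits(_pairs(600), mb.SplitSpec(seed=0))
        assert len(hold) == 100
        assert [len(f) for f in folds] == [100] * 5

    def test_uneven_sizes_differ_by_at_most_one(self):
        hold, folds = mb.make_nested_cv_splits(_pairs(601), mb.SplitSpec(seed=0))
        sizes = [len(hold)] + [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 601

    def test_partitions_disjoint_and_cover(self):
        pairs = _pairs(97)
        hold, folds = mb.make_nested_cv_splits(pairs, mb.SplitSpec(seed=1))
        seen = {tuple(p) for p in hold}
        for f in folds:
            fs = {tuple(p) for p in f}
            assert not seen & fs
            seen |= fs
        assert seen == {tuple(p) for p in pairs}

    def test_deterministic_given_seed(self):
        a = mb.make_nested_cv_splits(_pairs(60), mb.SplitSpec(seed=5))
        b = mb.make_nested_cv_splits(_pairs(60), mb.SplitSpec(seed=5))
        np.testing.assert_array_equal(a[0], b[0])
        for fa, fb in zip(a[1], b[1]):
            np.testing.assert_array_equal(fa, fb)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            mb.make_nested_cv_splits(_pairs(3), mb.SplitSpec())


class TestTimeSplit:
    def _year_map(self, pairs, years):
        return {(int(i), int(j)): y for (i, j), y in zip(pairs, years)}

    def test_boundary_years_follow_protocol(self):
        pairs = _pairs(10)
        years = [2010] * 5 + [2012] * 2 + [2014] * 3
        spec = mb.SplitSpec(scheme=mb.SplitScheme.TIME_BASED)
        train, valid, test = mb.make_time_split(pairs, self._year_map(pairs, years), spec)
        assert (len(train), len(valid), len(test)) == (5, 2, 3)

    def test_2011_trains_2013_tests(self):
        pairs = _pairs(4)
        years = [2011, 2012, 2013, 2020]
        train, valid, test = mb.make_time_split(
            pairs, self._year_map(pairs, years), mb.SplitSpec()
        )
        assert len(train) == 1 and len(valid) == 1 and len(test) == 2

    def test_all_pre2011_rejected(self):
        pairs = _pairs(6)
        with pytest.raises(ValueError):
            mb.make_time_split(pairs, self._year_map(pairs, [2009] * 6), mb.SplitSpec())

    def test_missing_year_rejected(self):
        pairs = _pairs(3)
        ym = self._year_map(pairs[:2], [2010, 2012])
        with pytest.raises(ValueError, match="no year"):
            mb.make_time_split(pairs, ym, mb.SplitSpec())


class TestFeatureDimension:
    @pytest.mark.parametrize(
        "variant, source, d, k, expected",
        [
            (Variant.PSCORE, mb.GraphSource.G1, 128, 100, 12),
            (Variant.PSCORE, mb.GraphSource.G1G2, 128, 100, 24),
            (Variant.EMBED, mb.GraphSource.G1, 128, 100, 228),
            (Variant.HYBRID, mb.GraphSource.G1, 128, 100, 240),
            (Variant.HYBRID, mb.GraphSource.G1G2, 128, 100, 252),
            (Variant.HYBRID, mb.GraphSource.G1, 256, 100, 368),
        ],
    )
    def test_variant_arithmetic(self, variant, source, d, k, expected):
        cfg = mb.RunConfig(
            variant=variant, graph_source=source, drug_embed_dim=d, protein_embed_dim=k
        )
        assert _feature_dimension(cfg) == expected


class TestRunPipeline:
    def test_pscore_recovers_signal(self, pipeline_data):
        cfg = mb.RunConfig(seed=3, params=BoostParams(n_trees=150, max_depth=4))
        out = mb.run_pipeline(pipeline_data, cfg)
        r = out["report"]
        y = pipeline_data.dataset.labels(pipeline_data.dataset.observed_pairs())
        assert r.ci > 0.5
        assert r.mse < np.var(y)  # beats the mean predictor

    def test_reports_reproducible_given_seed(self, pipeline_data):
        cfg = mb.RunConfig(seed=11, params=BoostParams(n_trees=60, max_depth=3))
        r1 = mb.run_pipeline(pipeline_data, cfg)["report"]
        r2 = mb.run_pipeline(pipeline_data, cfg)["report"]
        assert r1.to_json() == r2.to_json()

    def test_embed_and_hybrid_variants_run(self, pipeline_data):
        for variant in (Variant.EMBED, Variant.HYBRID):
            cfg = mb.RunConfig(
                seed=2,
                variant=variant,
                params=BoostParams(n_trees=40, max_depth=3),
                drug_embed_dim=16,
                protein_embed_dim=8,
                protein_embed_epochs=1,
            )
            r = mb.run_pipeline(pipeline_data, cfg)["report"]
            assert np.isfinite(r.mse)

    def test_g2_graph_source_runs(self, pipeline_data):
        cfg = mb.RunConfig(
            seed=2,
            graph_source=mb.GraphSource.G2,
            params=BoostParams(n_trees=40, max_depth=3),
            drug_embed_dim=16,
            protein_embed_dim=8,
            protein_embed_epochs=1,
        )
        r = mb.run_pipeline(pipeline_data, cfg)["report"]
        assert np.isfinite(r.mse)

    def test_no_holdout_edge_in_any_fold_graph(self, pipeline_data):
        """Leakage guard: perturbing a hold-out pair's affinity leaves all
        training-fold features bit-identical."""
        ds = pipeline_data.dataset
        cfg = mb.RunConfig(seed=4)
        pairs = ds.observed_pairs()
        import dataclasses

        split = dataclasses.replace(cfg.split, seed=cfg.child_seed(0))
        hold, folds = mb.make_nested_cv_splits(pairs, split)
        hi, hj = map(int, hold[0])
        from metabind.experiment import _fold_features, _similarity_blocks

        blocks = _similarity_blocks(pipeline_data, cfg, None)
        fold_set = {(int(i), int(j)) for i, j in folds[0]}
        hold_set = {(int(i), int(j)) for i, j in hold}
        masked = fold_set | hold_set
        train_pairs = np.array(
            [p for p in pairs if (int(p[0]), int(p[1])) not in masked]
        )
        f1, _, _ = _fold_features(
            pipeline_data, cfg, blocks, None, masked, train_pairs, hold
        )
        perturbed = ds.affinities.copy()
        perturbed[hi, hj] += 3.21
        ds2 = mb.AffinityDataset(
            ds.drug_ids, ds.target_ids, perturbed, ds.observed, ds.orientation
        )
        data2 = mb.PipelineData(
            dataset=ds2,
            drug_similarity=pipeline_data.drug_similarity,
            target_similarity=pipeline_data.target_similarity,
        )
        f2, _, _ = _fold_features(data2, cfg, blocks, None, masked, train_pairs, hold)
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_metric_averaging_mode(self, pipeline_data):
        cfg = mb.RunConfig(
            seed=5, aggregate_predictions=False, params=BoostParams(n_trees=40, max_depth=3)
        )
        out = mb.run_pipeline(pipeline_data, cfg)
        expected_ci = float(np.mean([r.ci for r in out["fold_reports"]]))
        assert out["report"].ci == pytest.approx(expected_ci)


class TestTimeSplitPipeline:
    def test_runs_and_scores(self, pipeline_data):
        ds = pipeline_data.dataset
        pairs = ds.observed_pairs()
        rng = np.random.default_rng(0)
        years = rng.choice([2009, 2010, 2011, 2012, 2013, 2015], size=len(pairs))
        ym = {(int(i), int(j)): int(y) for (i, j), y in zip(pairs, years)}
        cfg = mb.RunConfig(seed=1, params=BoostParams(n_trees=40, max_depth=3))
        out = mb.run_time_split(pipeline_data, cfg, ym)
        assert np.isfinite(out["report"].mse)
        tr, va, te = out["sizes"]
        assert tr + va + te == len(pairs)
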