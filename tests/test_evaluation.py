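import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metabind as mb
from metabind.evaluation import PositiveRule


class TestMse:
    def test_identical_vectors_zero(self):
        assert mb.mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_half(self):
        assert mb.mse([1.0, 2.0], [0.0, 2.0]) == 0.5

    def test_residual_scaling_quadratic(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(50)
        p = a + rng.standard_normal(50)
        base = mb.mse(p, a)
        scaled = mb.mse(a + 3 * (p - a), a)
        assert scaled == pytest.approx(9 * base)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mb.mse([1.0], [1.0, 2.0])

    def test_rmse_is_sqrt(self):
        assert mb.rmse([1.0, 2.0], [0.0, 2.0]) == pytest.approx(np.sqrt(0.5))


class TestConcordanceIndex:
    def test_perfect_ranking(self):
        assert mb.concordance_index([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_reversed_ranking(self):
        assert mb.concordance_index([4, 3, 2, 1], [10, 20, 30, 40]) == 0.0

    def test_all_tied_predictions_give_half(self):
        assert mb.concordance_index([5, 5, 5], [1, 2, 3]) == 0.5

    def test_two_thirds_example(self):
        assert mb.concordance_index([1, 3, 2], [1, 2, 3]) == pytest.approx(2 / 3)

    def test_all_tied_actuals_rejected(self):
        with pytest.raises(ValueError):
            mb.concordance_index([1, 2], [5, 5])

    def test_fast_equals_quadratic_oracle_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            actual = rng.integers(0, 6, n).astype(float)  # many ties
            if np.all(actual == actual[0]):
                continue
            pred = np.round(rng.standard_normal(n), 1)  # tied predictions too
            assert mb.concordance_index(pred, actual) == mb.concordance_index_slow(
                pred, actual
            )

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=15))
    @settings(derandomize=True, max_examples=40)
    def test_invariant_to_monotone_transform_of_predictions(self, preds):
        actual = np.arange(len(preds), dtype=float)
        # half-integer grid keeps the affine transform exact in floats
        p = np.round(np.array(preds) * 2) / 2
        a = mb.concordance_index(p, actual)
        b = mb.concordance_index(2.0 * p + 1.0, actual)
        assert a == pytest.approx(b)

    def test_invariant_to_joint_permutation(self):
        rng = np.random.default_rng(4)
        p, a = rng.standard_normal(30), rng.standard_normal(30)
        perm = rng.permutation(30)
        assert mb.concordance_index(p, a) == pytest.approx(
            mb.concordance_index(p[perm], a[perm])
        )


class TestRm2:
    def test_perfect_predictions(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r2, r0_2, rm_2 = mb.rm2(x, x)
        assert r2 == pytest.approx(1.0) and r0_2 == pytest.approx(1.0)
        assert rm_2 == pytest.approx(1.0)

    def test_closed_form_arithmetic(self):
        # with r2=0.8 and r0_2=0.64: rm2 = 0.8 * (1 - sqrt(0.16)) = 0.48
        r2, r0_2 = 0.8, 0.64
        assert r2 * (1 - np.sqrt(r2 - r0_2)) == pytest.approx(0.48)
        # the implementation reproduces the identity on data engineered so
        # that the through-origin fit is poorer than the centered fit
        rng = np.random.default_rng(0)
        a = rng.standard_normal(200) + 10
        p = 0.5 * a + rng.standard_normal(200) * 0.5 - 8
        r2_hat, r0_2_hat, rm_2_hat = mb.rm2(p, a)
        assert rm_2_hat == pytest.approx(
            r2_hat * (1 - np.sqrt(max(r2_hat - r0_2_hat, 0.0)))
        )
        assert rm_2_hat <= r2_hat

    def test_uncorrelated_noise_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(20):
            a = rng.standard_normal(300)
            p = rng.standard_normal(300)
            vals.append(mb.rm2(p, a)[2])
        assert abs(float(np.median(vals))) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mb.rm2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p, a = rng.standard_normal(40), rng.standard_normal(40)
        perm = rng.permutation(40)
        assert mb.rm2(p, a) == pytest.approx(mb.rm2(p[perm], a[perm]))


class TestThresholdedAupr:
    def test_perfect_separation_gives_one(self):
        a = np.array([5.0, 6.0, 8.0, 9.0])
        per, mean = mb.thresholded_aupr(a, a, [7.0])
        assert per[7.0] == 1.0 and mean == 1.0

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(0)
        n = 10_000
        actual = np.concatenate([np.full(n // 2, 5.0), np.full(n // 2, 9.0)])
        pred = rng.random(n)
        per, _ = mb.thresholded_aupr(pred, actual, [7.0])
        assert per[7.0] == pytest.approx(0.5, abs=0.02)

    def test_mean_over_three_thresholds(self):
        rng = np.random.default_rng(1)
        actual = rng.uniform(4, 12, 500)
        pred = actual + rng.normal(0, 1, 500)
        per, mean = mb.thresholded_aupr(pred, actual, [6.0, 7.0, 10.0])
        assert len(per) == 3
        assert mean == pytest.approx(np.mean(list(per.values())))

    def test_le_positive_rule_orients_scores(self):
        # lower affinity = binder; perfect predictions must still give 1.0
        a = np.array([1.0, 2.0, 10.0, 12.0])
        per, _ = mb.thresholded_aupr(a, a, [5.0], positive_rule=PositiveRule.LE)
        assert per[5.0] == 1.0

    def test_single_class_threshold_excluded_with_warning(self):
        a = np.array([5.0, 6.0, 8.0])
        with pytest.warns(UserWarning):
            per, mean = mb.thresholded_aupr(a, a, [0.0, 7.0])
        assert np.isnan(per[0.0]) and mean == per[7.0]

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            mb.thresholded_aupr([1.0], [1.0], [])


class _Ridge:
    """tiny deterministic stand-in model for Y-randomization tests"""

    def fit(self, X, y):
        from sklearn.linear_model import Ridge

        self.m = Ridge(alpha=1.0).fit(X, y)
        return self

    def predict(self, X):
        return self.m.predict(X)


class TestYRandomization:
    def _data(self, signal: bool, seed=0, n=200, p=5):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        y = X @ beta + 0.1 * rng.standard_normal(n) if signal else rng.standard_normal(n)
        return X[: n // 2], y[: n // 2], X[n // 2 :], y[n // 2 :]

    def test_signal_labels_beat_every_permutation(self):
        Xtr, ytr, Xte, yte = self._data(signal=True)
        out = mb.y_randomization(Xtr, ytr, Xte, yte, _Ridge, n_iter=50, seed=0)
        assert out["p_value_empirical"] <= 1 / 51
        assert out["observed_r2"] > 0.9

    def test_noise_labels_rank_centrally(self):
        Xtr, ytr, Xte, yte = self._data(signal=False)
        out = mb.y_randomization(Xtr, ytr, Xte, yte, _Ridge, n_iter=50, seed=1)
        assert 0.05 < out["p_value_empirical"] < 0.99

    def test_permuted_r2_typically_nonpositive(self):
        Xtr, ytr, Xte, yte = self._data(signal=True, seed=3)
        out = mb.y_randomization(Xtr, ytr, Xte, yte, _Ridge, n_iter=30, seed=2)
        assert float(np.median(out["permuted_r2"])) < 0.05

    def test_too_few_iterations_rejected(self):
        Xtr, ytr, Xte, yte = self._data(signal=True)
        with pytest.raises(ValueError):
            mb.y_randomization(Xtr, ytr, Xte, yte, _Ridge, n_iter=5)


def test_evaluate_bundles_all_metrics():
    rng = np.random.default_rng(0)
    a = rng.uniform(5, 11, 200)
    p = a + rng.normal(0, 0.5, 200)
    report = mb.evaluate(p, a, thresholds=[7.0])
    assert report.rmse == pytest.approx(np.sqrt(report.mse))
    assert 0 <= report.ci <= 1
    assert report.n == 200
    assert report.rm2 <= report.r2 or report.r2 < report.r0_2
    parsed = __import__("json").loads(report.to_json())
    assert "aupr_per_threshold" in parsed
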