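"""Logistic fit, jackknife, AUC/ROC, balanced resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varstab.classifier import (
    auc,
    balanced_auc,
    compare_predictors,
    fit_logistic,
    jackknife,
    roc_points,
)
from varstab.synthetic import GeneratorSpec, make_synthetic_variant_table
from varstab.variants import VariantRecord, VariantTable


def brute_force_auc(scores, labels):
    """P(s+ > s-) + 0.5 P(tie) over all positive-negative pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        X = np.zeros((10, 2))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        model = fit_logistic(X, y)
        prevalence = 0.3
        assert model.intercept == pytest.approx(np.log(prevalence / (1 - prevalence)))
        assert np.allclose(model.weights, 0.0, atol=1e-8)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            fit_logistic(np.random.default_rng(0).normal(size=(5, 2)), [1] * 5)

    def test_separation_flagged_not_diverged(self):
        X = np.array([[-2.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_logistic(X, y)
        assert model.separation
        assert np.all(np.isfinite(model.weights))
        assert np.max(np.abs(model.weights)) <= 1e3

    def test_matches_sklearn_unregularized(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(300, 2))
        z = 0.8 * X[:, 0] - 1.2 * X[:, 1] + 0.3
        y = (rng.random(300) < 1 / (1 + np.exp(-z))).astype(int)
        ours = fit_logistic(X, y)
        ref = LogisticRegression(C=1e10, tol=1e-10, max_iter=5000).fit(X, y)
        assert ours.converged
        assert np.allclose(ours.weights, ref.coef_[0], atol=1e-4)
        assert ours.intercept == pytest.approx(ref.intercept_[0], abs=1e-4)

    def test_gradient_at_optimum(self, rng):
        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < 0.5).astype(int)
        model = fit_logistic(X, y)
        assert model.converged
        Xd = np.hstack([X, np.ones((200, 1))])
        beta = np.append(model.weights, model.intercept)
        p = 1 / (1 + np.exp(-(Xd @ beta)))
        assert np.max(np.abs(Xd.T @ (y - p))) < 1e-6


class TestJackknife:
    def test_separable_high_accuracy(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y * 6.0 + rng.normal(0, 1, n), rng.normal(0, 1, n)])
        assert jackknife(X, y).accuracy >= 0.95

    def test_permuted_labels_near_chance(self, rng):
        n = 200
        X = rng.normal(size=(n, 2))
        y = np.repeat([0, 1], n // 2)  # independent of X
        acc = jackknife(X, y).accuracy
        assert abs(acc - 0.5) < 0.15  # binomial noise band

    def test_three_point_bookkeeping(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        y = np.array([0, 0, 1])
        with pytest.warns(UserWarning, match="single-class"):
            res = jackknife(X, y)
        assert len(res.categories) == 3
        # leaving out the lone positive gives a single-class training set:
        # that point is marked unclassifiable, the other two are categorized
        n_unclassifiable = sum(c is None for c in res.categories)
        assert sum(res.counts().values()) + n_unclassifiable == 3
        assert n_unclassifiable == 1


class TestAuc:
    def test_examples(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
        assert auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert auc([0.5] * 6, [0, 1] * 3) == 0.5

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 50))
    def test_equals_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.25, 0.5, 0.7], size=n)  # force ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.4).astype(int)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_monotone_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(auc(np.exp(scores), labels))


class TestRocPoints:
    def test_perfect_separator(self):
        res = roc_points([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.points == [(0.0, 0.0), (0.0, 0.5), (0.0, 1.0), (0.5, 1.0), (1.0, 1.0)]
        assert res.auc == 1.0

    def test_all_tied(self):
        res = roc_points([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert res.points == [(0.0, 0.0), (1.0, 1.0)]
        assert res.auc == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_area_equals_rank_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        res = roc_points(scores, labels)
        fpr = np.array([p[0] for p in res.points])
        tpr = np.array([p[1] for p in res.points])
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert np.trapezoid(tpr, fpr) == pytest.approx(res.auc, abs=1e-12)


class TestBalancedAuc:
    def test_balanced_input_zero_std(self, rng):
        scores = rng.normal(size=20)
        labels = np.repeat([0, 1], 10)
        mean, std = balanced_auc(scores, labels, n_resamples=50, seed=3)
        assert std == 0.0
        assert mean == pytest.approx(auc(scores, labels))

    def test_perfect_separator_any_imbalance(self, rng):
        labels = np.array([1] * 5 + [0] * 45)
        scores = labels + rng.random(50) * 0.1
        mean, std = balanced_auc(scores, labels, n_resamples=30, seed=0)
        assert (mean, std) == (1.0, 0.0)

    def test_seed_determinism(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.3).astype(int)
        labels[:2] = [0, 1]
        a = balanced_auc(scores, labels, n_resamples=40, seed=7)
        b = balanced_auc(scores, labels, n_resamples=40, seed=7)
        assert a == b


class TestComparePredictors:
    def _table(self, scores_a, scores_b, labels):
        records = []
        for i, (a, b, y) in enumerate(zip(scores_a, scores_b, labels)):
            records.append(
                VariantRecord(
                    position=i + 1,
                    wt_aa="A",
                    mut_aa="C",
                    clinvar_class="likely_pathogenic" if y else "likely_benign",
                    extras={"m1": str(a), "m2": str(b)},
                )
            )
        return VariantTable(records)

    def test_identical_columns_identical_auc(self, rng):
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        res = compare_predictors(self._table(s, s, y), ["m1", "m2"], n_resamples=20, seed=1)
        assert res["m1"].auc == res["m2"].auc

    def test_negated_column_antisymmetry(self, rng):
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        res = compare_predictors(self._table(s, -s, y), ["m1", "m2"], n_resamples=20, seed=1)
        assert res["m1"].auc == pytest.approx(1.0 - res["m2"].auc)

    def test_true_latent_beats_noisy_copy(self):
        rng = np.random.default_rng(5)
        latent = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-2 * latent))).astype(int)
        noisy = latent + rng.normal(0, 2.0, size=200)
        res = compare_predictors(self._table(latent, noisy, y), ["m1", "m2"],
                                 n_resamples=20, seed=2)
        assert res["m1"].auc >= res["m2"].auc

    def test_unknown_column_error_lists_available(self, rng):
        table = self._table([1.0], [2.0], [1])
        # need both classes for the valid methods, but the error fires first
        with pytest.raises(KeyError, match="m1"):
            compare_predictors(table, ["nope"], n_resamples=5, seed=0)
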