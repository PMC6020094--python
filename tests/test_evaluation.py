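"""Metric implementations against independent brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

import admetkit as ak
from admetkit.evaluation import (
    UndefinedMetricError,
    auc_score,
    classification_metrics,
    cohens_kappa,
    cross_validate,
    fold_error_rates,
    make_folds,
    regression_metrics,
)
from admetkit.modeling import ModelConfig, predict, train
from admetkit.synthetic import SyntheticSpec


def brute_force_auc(y, s):
    """Concordant-pair count (+1/2 for ties) over positive x negative pairs."""
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        r2, rmse = regression_metrics([1, 2, 3], [1, 2, 3])
        assert r2 == 1.0 and rmse == 0.0

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, _ = regression_metrics(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        r2, rmse = regression_metrics([1, 2, 3], [1, 2, 4], ybar_reference=2)
        assert rmse == pytest.approx(np.sqrt(1 / 3))
        assert r2 == pytest.approx(0.5)

    def test_undefined_r2(self):
        with pytest.raises(UndefinedMetricError):
            regression_metrics([2.0, 2.0], [1.0, 3.0])

    def test_training_mean_reference_contract(self):
        # test-set R^2 uses the training-set mean, not the test-set mean
        y_test = np.array([10.0, 11.0, 12.0])
        yhat = np.array([10.5, 11.0, 11.5])
        naive, _ = regression_metrics(y_test, yhat)
        shifted, _ = regression_metrics(y_test, yhat, ybar_reference=0.0)
        assert shifted > naive

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 100)
            y = rng.normal(size=n)
            yhat = rng.normal(size=n)
            ybar = rng.normal()
            r2, rmse = regression_metrics(y, yhat, ybar_reference=ybar)
            ss_tot = sum((yi - ybar) ** 2 for yi in y)
            if ss_tot == 0:
                continue
            r2_oracle = 1 - sum((a - b) ** 2 for a, b in zip(yhat, y)) / ss_tot
            rmse_oracle = (sum((a - b) ** 2 for a, b in zip(y, yhat)) / n) ** 0.5
            assert abs(r2 - r2_oracle) < 1e-10
            assert abs(rmse - rmse_oracle) < 1e-10


class TestClassificationMetrics:
    def test_direct_substitution(self):
        # TP=8, TN=6, FP=2, FN=4
        y = np.array([1] * 12 + [0] * 8)
        s = np.array([0.9] * 8 + [0.1] * 4 + [0.9] * 2 + [0.1] * 6)
        ce = classification_metrics(y, s)
        assert ce.ACC == pytest.approx(0.70)
        assert ce.SE == pytest.approx(8 / 12)
        assert ce.SP == pytest.approx(0.75)
        assert ce.counts.n == 20

    def test_perfect_separation_auc(self):
        y = np.array([0, 0, 1, 1])
        assert auc_score(y, [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            classification_metrics([1, 1, 1], [0.2, 0.8, 0.9])

    def test_auc_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = rng.integers(4, 50)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            assert abs(auc_score(y, s) - brute_force_auc(y, s)) < 1e-10

    def test_auc_matches_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            y = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            s = rng.random(40)
            assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_chance_agreement_zero(self):
        # p_o equals p_e when prediction is independent with matched marginals
        y = [1, 1, 0, 0]
        p = [1, 0, 1, 0]
        assert cohens_kappa(y, p) == pytest.approx(0.0)

    def test_hand_contingency(self):
        # (a,b,c,d) = (20,5,10,15): both-1, true1-pred0, true0-pred1, both-0
        y = [1] * 25 + [0] * 25
        p = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 15
        n = 50
        p_o = (20 + 15) / n
        p_e = (25 / n) * (30 / n) + (25 / n) * (20 / n)
        expected = (p_o - p_e) / (1 - p_e)
        assert cohens_kappa(y, p) == pytest.approx(expected, abs=1e-12)

    def test_constant_equal_raters_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert cohens_kappa([1, 1], [1, 1]) == 0.0

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            if ((y == 1).mean() * (p == 1).mean() + (y == 0).mean() * (p == 0).mean()) == 1:
                continue
            assert cohens_kappa(y, p) == pytest.approx(cohen_kappa_score(y, p), abs=1e-10)


class TestFoldError:
    def test_perfect_predictor(self):
        fe = fold_error_rates([1.0, 2.0], [1.0, 2.0])
        assert np.all(fe.folds == 1.0)
        assert fe.within_2fold == 1.0 and fe.average_fold == 1.0

    @pytest.mark.parametrize("yhat,fold,in2,in3", [(15.0, 1.5, 1.0, 1.0), (25.0, 2.5, 0.0, 1.0)])
    def test_printed_formula(self, yhat, fold, in2, in3):
        fe = fold_error_rates([10.0], [yhat])
        assert fe.folds[0] == pytest.approx(fold)
        assert fe.within_2fold == in2 and fe.within_3fold == in3

    def test_zero_and_negative_truth_error(self):
        with pytest.raises(ValueError):
            fold_error_rates([0.0], [1.0])
        with pytest.raises(ValueError):
            fold_error_rates([-1.0], [1.0])

    def test_monotone_in_error_factor(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(1, 10, 50)
        prev = 1.1
        rates = []
        for factor in (1.0, 1.5, 2.0, 3.0, 5.0):
            rates.append(fold_error_rates(y, y * factor).within_2fold)
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_within2_le_within3(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(1, 10, 30)
        yhat = y * rng.uniform(0.5, 4, 30)
        fe = fold_error_rates(y, yhat)
        assert fe.within_2fold <= fe.within_3fold


class TestCrossValidate:
    def test_fold_sizes(self):
        folds = make_folds(10, 5, seed=0)
        assert sorted(len(f) for f in folds) == [2] * 5
        folds = make_folds(11, 5, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_same_folds(self):
        a = make_folds(20, 5, seed=7)
        b = make_folds(20, 5, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_greater_than_n_errors(self):
        with pytest.raises(ValueError):
            make_folds(3, 5, seed=0)

    def test_loo_matches_brute_force(self):
        """Leave-one-out CV equals an explicit refit-per-sample loop."""
        spec = SyntheticSpec(n=8, n_features=3, n_informative=2, noise_sigma=0.3, seed=6)
        ds, _ = ak.generate_qsar_dataset(spec)
        cfg = ModelConfig("cart_regression", "regression", seed=0)
        q2, rmse = cross_validate(ds, cfg, k=8, seed=0)
        # brute force: refit excluding each sample once
        ids = ds.features.row_ids
        oof = np.empty(8)
        for i in range(8):
            train_ids = [x for j, x in enumerate(ids) if j != i]
            model = train(ds.subset(train_ids), cfg)
            oof[i] = predict(model, ds.features.subset_rows([ids[i]]))["value"][0]
        q2_oracle, rmse_oracle = regression_metrics(ds.y, oof, ybar_reference=float(ds.y.mean()))
        assert q2 == pytest.approx(q2_oracle, abs=1e-10)
        assert rmse == pytest.approx(rmse_oracle, abs=1e-10)

    def test_q2_not_above_fit_r2_on_average(self):
        """Out-of-fold error exceeds fit error in expectation."""
        gaps = []
        for seed in range(20):
            spec = SyntheticSpec(n=60, n_features=5, n_informative=2, noise_sigma=1.0, seed=seed)
            ds, _ = ak.generate_qsar_dataset(spec)
            cfg = ModelConfig("rf", "regression", {"estimators": 30}, seed=seed)
            model = train(ds, cfg)
            r2_f, _ = regression_metrics(ds.y, predict(model, ds.features)["value"])
            q2, _ = cross_validate(ds, cfg, k=5, seed=seed)
            gaps.append(r2_f - q2)
        assert np.mean(gaps) > 0
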