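import numpy as np
import pandas as pd
import pytest

import admetkit as ak
from admetkit.features import FeatureMatrix
from admetkit.dataprep import LabeledDataset
from admetkit.modeling import (
    ConsensusModel,
    ModelConfig,
    coverage_tree_count,
    grid_search_pls,
    grid_search_rf,
    grid_search_svm,
    pls_component_grid,
    predict,
    rf_stage1_mtry_grid,
    rf_stage2_mtry_grid,
    sigma_to_gamma,
    svm_stage1_exponents,
    svm_stage2_exponents,
    train,
    train_balanced_rf,
    train_resampling_consensus,
)
from admetkit.synthetic import SyntheticSpec


def _separable_dataset(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x0 = np.concatenate([rng.normal(-3, 0.5, n // 2), rng.normal(3, 0.5, n // 2)])
    x1 = rng.normal(size=n)
    y = np.array([0.0] * (n // 2) + [1.0] * (n // 2))
    df = pd.DataFrame({"x0": x0, "x1": x1}, index=[f"m{i}" for i in range(n)])
    fm = FeatureMatrix(df, "descriptor", pd.Series({"x0": "t", "x1": "t"}))
    return LabeledDataset(fm, y, task="classification")


class TestTrain:
    def test_separable_training_accuracy(self):
        ds = _separable_dataset()
        model = train(ds, ModelConfig("rf", "classification", {"estimators": 50}, seed=0))
        preds = predict(model, ds.features)
        assert (preds["label"] == ds.y).mean() == 1.0
        assert np.all((preds["probability"] >= 0) & (preds["probability"] <= 1))

    def test_incompatible_algorithm_task(self):
        with pytest.raises(ValueError):
            ModelConfig("naive_bayes", "regression")
        with pytest.raises(ValueError):
            ModelConfig("pls", "classification")

    def test_deterministic_given_seed(self, regression_dataset):
        ds, _ = regression_dataset
        a = train(ds, ModelConfig("rf", "regression", {"estimators": 50}, seed=9))
        b = train(ds, ModelConfig("rf", "regression", {"estimators": 50}, seed=9))
        assert np.array_equal(predict(a, ds.features)["value"], predict(b, ds.features)["value"])

    @pytest.mark.parametrize("algo", ["rf", "svm_rbf", "pls", "cart_regression"])
    def test_regression_algorithms_fit(self, algo, regression_dataset):
        ds, _ = regression_dataset
        model = train(ds, ModelConfig(algo, "regression", seed=0))
        assert predict(model, ds.features)["value"].shape == (ds.n,)

    @pytest.mark.parametrize("algo", ["rf", "svm_rbf", "naive_bayes", "decision_tree"])
    def test_classification_algorithms_fit(self, algo):
        ds = _separable_dataset()
        model = train(ds, ModelConfig(algo, "classification", seed=0))
        p = predict(model, ds.features)["probability"]
        assert np.all((p >= 0) & (p <= 1))

    def test_feature_mismatch_errors(self, regression_dataset):
        ds, _ = regression_dataset
        model = train(ds, ModelConfig("cart_regression", "regression", seed=0))
        wrong = ds.features.subset_columns(ds.features.columns[:-1])
        with pytest.raises(ValueError, match="mismatch"):
            predict(model, wrong)


class TestGridConstruction:
    def test_rf_stage1_mtry_ladder(self):
        assert rf_stage1_mtry_grid(100) == [1, 21, 41, 61, 81]

    def test_rf_stage2_window(self):
        grid = rf_stage2_mtry_grid(61, 200)
        assert grid[0] == 11 and grid[-1] == 111 and grid[1] - grid[0] == 2

    def test_rf_stage2_clipping(self):
        assert rf_stage2_mtry_grid(10, 40) == list(range(2, 41, 2))

    def test_svm_stage1_ladders(self):
        c_exp, s_exp = svm_stage1_exponents()
        assert c_exp == [float(e) for e in range(-5, 16, 2)] and len(c_exp) == 11
        assert s_exp == [float(e) for e in range(-15, 4, 2)] and len(s_exp) == 10

    def test_svm_stage2_quarter_steps(self):
        exps = svm_stage2_exponents(3.0)
        assert exps[0] == 1.0 and exps[-1] == 5.0
        assert exps[1] - exps[0] == pytest.approx(0.25)
        assert len(exps) == 17

    def test_pls_component_grids(self):
        assert pls_component_grid(5, 50) == [1, 2, 3, 4, 5]
        assert pls_component_grid(300, 300) == list(range(1, 101))

    def test_sigma_parameterization(self):
        # kernel exp(-||x-z||^2 / (2 Sigma^2)) => gamma = 1/(2 Sigma^2)
        assert sigma_to_gamma(1.0) == 0.5
        assert sigma_to_gamma(2.0) == 0.125


class TestGridSearch:
    def test_rf_grid_search_best_in_stage2(self, regression_dataset):
        ds, _ = regression_dataset
        result = grid_search_rf(ds, cv_folds=3, seed=0, estimators_grid=(30,))
        assert result.final_best in result.stage2_grid
        assert 1 <= result.final_best["mtry"] <= ds.features.p

    def test_pls_grid_search(self, regression_dataset):
        ds, _ = regression_dataset
        result = grid_search_pls(ds, cv_folds=3, seed=0)
        assert result.final_best["n_components"] in range(1, ds.features.p + 1)

    def test_svm_window_arithmetic_only(self):
        # full SVM grid search is exercised through its window functions plus
        # a minimal end-to-end run on a tiny set
        ds = _separable_dataset(n=24, seed=3)
        result = grid_search_svm(ds, cv_folds=3, seed=0)
        assert {"C", "Sigma"} <= set(result.final_best)
        assert len(result.stage1_grid) == 110


class TestBalancedRf:
    def test_per_tree_class_counts(self):
        spec = SyntheticSpec(n=300, task="classification", n_features=6,
                             n_informative=3, class_balance=0.2, seed=0)
        ds, _ = ak.generate_qsar_dataset(spec)
        model = train_balanced_rf(ds, samplesize=30, estimators=50, seed=0)
        assert all(c == (30, 30) for c in model.training_summary["per_tree_class_counts"])

    def test_samplesize_exceeding_minority_errors(self):
        spec = SyntheticSpec(n=100, task="classification", n_features=4,
                             n_informative=2, class_balance=0.1, seed=1)
        ds, _ = ak.generate_qsar_dataset(spec)
        with pytest.raises(ValueError, match="samplesize"):
            train_balanced_rf(ds, samplesize=50, replacement=False)

    def test_single_class_errors(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=20)}, index=[f"m{i}" for i in range(20)])
        fm = FeatureMatrix(df, "descriptor", pd.Series({"x": "t"}))
        ds = LabeledDataset(fm, np.ones(20), task="classification")
        with pytest.raises(ValueError):
            train_balanced_rf(ds)

    def test_coverage_rule(self):
        assert coverage_tree_count(100, 100) == 1
        # 900-compound class sampled 100 per tree: (8/9)^T <= 0.01
        t = coverage_tree_count(100, 900)
        assert (1 - 100 / 900) ** t <= 0.01 < (1 - 100 / 900) ** (t - 1)

    def test_low_tree_count_warns(self):
        spec = SyntheticSpec(n=600, task="classification", n_features=4,
                             n_informative=2, class_balance=0.1, seed=2)
        ds, _ = ak.generate_qsar_dataset(spec)
        with pytest.warns(UserWarning, match="coverage"):
            train_balanced_rf(ds, samplesize=20, estimators=5, seed=0)


class TestConsensus:
    def test_member_count_and_training_sizes(self):
        spec = SyntheticSpec(n=500, task="classification", n_features=6,
                             n_informative=3, class_balance=0.1, seed=3)
        ds, _ = ak.generate_qsar_dataset(spec)
        model = train_resampling_consensus(ds, n_members=10, seed=0)
        assert len(model.members) == 10
        n_min = int(min(ds.y.sum(), (1 - ds.y).sum()))
        assert all(m.training_summary["n"] == 2 * n_min for m in model.members)

    def test_consensus_probability_is_mean(self):
        spec = SyntheticSpec(n=300, task="classification", n_features=6,
                             n_informative=3, class_balance=0.2, seed=4)
        ds, _ = ak.generate_qsar_dataset(spec)
        model = train_resampling_consensus(ds, n_members=5, seed=1)
        probe = ds.features.subset_rows(ds.features.row_ids[:10])
        member_probs = np.array([predict(m, probe)["probability"] for m in model.members])
        consensus = predict(model, probe)["probability"]
        assert np.allclose(consensus, member_probs.mean(axis=0), atol=1e-12)

    def test_balanced_input_warns(self):
        ds = _separable_dataset(n=40)
        with pytest.warns(UserWarning, match="balanced"):
            train_resampling_consensus(ds, n_members=3, seed=0)

    def test_mismatched_members_rejected(self):
        ds = _separable_dataset(n=30)
        m1 = train(ds, ModelConfig("rf", "classification", {"estimators": 10}, seed=0))
        sub = LabeledDataset(ds.features.subset_columns(["x0"]), ds.y, task="classification")
        m2 = train(sub, ModelConfig("rf", "classification", {"estimators": 10}, seed=0))
        with pytest.raises(ValueError):
            ConsensusModel([m1, m2])
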