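"""Model training: six algorithms, two-stage grid searches, and two
imbalance-handling strategies.

Regression uses random forest, RBF-kernel SVM, recursive-partitioning (CART)
trees and PLS; classification uses random forest, RBF SVM, naive Bayes and
CART decision trees. Hyperparameters follow the platform's two-stage grids:
RF crosses estimators {500, 1000} with an mtry ladder of step 20 over
(1, n_features), then rescans mtry' +/- 50 at step 2; the SVM coarse grid is
C = 2^-5..2^15 and Sigma = 2^-15..2^3 in steps of 2^2 with a finer 2^0.25
scan around the winner; PLS components run 1..100 capped by p and n.

Sigma parameterizes the RBF kernel as exp(-||x - z||^2 / (2 Sigma^2)), so
the scikit-learn gamma is 1 / (2 Sigma^2); features are z-scored inside the
SVM pipeline with training-fold statistics.

For imbalanced endpoints, ``train_balanced_rf`` grows every tree on exactly
``samplesize`` positives plus ``samplesize`` negatives, and
``train_resampling_consensus`` averages 10 models each trained on all
minority compounds plus an equal-size majority subsample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .dataprep import LabeledDataset
from .features import FeatureMatrix

REGRESSION_ALGORITHMS = {"rf", "svm_rbf", "pls", "cart_regression"}
CLASSIFICATION_ALGORITHMS = {"rf", "svm_rbf", "naive_bayes", "decision_tree"}


@dataclass
class ModelConfig:
    algorithm: str
    task: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        allowed = REGRESSION_ALGORITHMS if self.task == "regression" else CLASSIFICATION_ALGORITHMS
        if self.task not in {"regression", "classification"}:
            raise ValueError(f"unknown task {self.task!r}")
        if self.algorithm not in allowed:
            raise ValueError(
                f"algorithm {self.algorithm!r} is not valid for {self.task} "
                f"(choose from {sorted(allowed)})"
            )


@dataclass
class TrainedModel:
    config: ModelConfig
    feature_names: list[str]
    fitted_state: object
    training_summary: dict = field(default_factory=dict)

    @property
    def task(self) -> str:
        return self.config.task


@dataclass
class ConsensusModel:
    """Ensemble whose probability is the arithmetic mean of member
    probabilities; label at 0.5."""

    members: list[TrainedModel]

    def __post_init__(self):
        names = {tuple(m.feature_names) for m in self.members}
        tasks = {m.task for m in self.members}
        if len(names) > 1 or len(tasks) > 1:
            raise ValueError("consensus members must share feature names and task")

    @property
    def feature_names(self) -> list[str]:
        return self.members[0].feature_names

    @property
    def task(self) -> str:
        return self.members[0].task


@dataclass
class GridResult:
    stage1_grid: list[dict]
    stage2_grid: list[dict]
    stage1_best: dict
    final_best: dict
    cv_scores: dict


def sigma_to_gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma * sigma)


def _mtry_default(p: int) -> int:
    return max(1, int(math.isqrt(p)))


def _build_estimator(config: ModelConfig, p: int, feature_kind: str):
    hp = config.hyperparameters
    algo, task, seed = config.algorithm, config.task, config.seed
    if algo == "rf":
        mtry = int(hp.get("mtry", _mtry_default(p)))
        est = int(hp.get("estimators", 500))
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(n_estimators=est, max_features=min(mtry, p), random_state=seed, n_jobs=1)
    if algo == "svm_rbf":
        C = float(hp.get("C", 1.0))
        sigma = float(hp.get("Sigma", 1.0))
        gamma = sigma_to_gamma(sigma)
        svm = (
            SVR(C=C, gamma=gamma)
            if task == "regression"
            else SVC(C=C, gamma=gamma, probability=True, random_state=seed)
        )
        return Pipeline([("scale", StandardScaler()), ("svm", svm)])
    if algo == "pls":
        return PLSRegression(n_components=int(hp.get("n_components", 2)))
    if algo == "cart_regression":
        return DecisionTreeRegressor(random_state=seed, **{k: hp[k] for k in ("max_depth",) if k in hp})
    if algo == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **{k: hp[k] for k in ("max_depth",) if k in hp})
    if algo == "naive_bayes":
        return BernoulliNB() if feature_kind == "fingerprint" else GaussianNB()
    raise ValueError(f"unknown algorithm {algo!r}")


def train(dataset: LabeledDataset, config: ModelConfig) -> TrainedModel:
    """Fit one model; deterministic given the config seed."""
    if config.task != dataset.task:
        raise ValueError(f"config task {config.task!r} != dataset task {dataset.task!r}")
    X = dataset.features.values.astype(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    est = _build_estimator(config, dataset.features.p, dataset.features.kind)
    est.fit(X, dataset.y)
    summary: dict = {"n": dataset.n, "p": dataset.features.p}
    return TrainedModel(config, dataset.features.columns, est, summary)


def _proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    est = model.fitted_state
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        classes = getattr(est, "classes_", None)
        if classes is None:  # pipeline
            classes = est.steps[-1][1].classes_
        col = int(np.where(np.asarray(classes) == 1)[0][0]) if 1 in list(classes) else proba.shape[1] - 1
        return proba[:, col]
    raise ValueError("estimator exposes no probabilities")


def predict(model: TrainedModel | ConsensusModel, features: FeatureMatrix) -> dict:
    """Predict for every row; classification returns label + probability."""
    expected = list(model.feature_names)
    got = features.columns
    if got != expected:
        missing = [c for c in expected if c not in got]
        extra = [c for c in got if c not in expected]
        if missing or extra:
            raise ValueError(f"feature mismatch: missing={missing[:5]}, extra={extra[:5]}")
        features = features.subset_columns(expected)  # same names, wrong order
    X = features.values.astype(float)
    if isinstance(model, ConsensusModel):
        probs = np.mean([_proba(m, X) for m in model.members], axis=0)
        return {"probability": probs, "label": (probs >= 0.5).astype(float)}
    if model.task == "regression":
        vals = np.asarray(model.fitted_state.predict(X), dtype=float).ravel()
        return {"value": vals}
    probs = _proba(model, X)
    return {"probability": probs, "label": (probs >= 0.5).astype(float)}


# ---------------------------------------------------------------------------
# grid searches


def _cv_score(dataset: LabeledDataset, config: ModelConfig, cv_folds: int, seed: int) -> float:
    """Mean-CV quality: Q^2 for regression, ACC for classification.

    A degenerate single-class training fold triggers a refold with a shifted
    seed, erroring after 3 attempts.
    """
    from .evaluation import cross_validate

    for attempt in range(3):
        try:
            out = cross_validate(dataset, config, k=cv_folds, seed=seed + attempt)
        except ValueError as exc:
            if "class" in str(exc).lower() and attempt < 2:
                continue
            raise
        return out[0] if dataset.task == "regression" else out.ACC
    raise RuntimeError("cross-validation failed after 3 refold attempts")


def rf_stage1_mtry_grid(p: int) -> list[int]:
    return list(range(1, p + 1, 20))


def rf_stage2_mtry_grid(mtry_best: int, p: int) -> list[int]:
    ladder = range(mtry_best - 50, mtry_best + 50 + 1, 2)
    grid = [m for m in ladder if 1 <= m <= p]
    return grid or [max(1, min(mtry_best, p))]


def svm_stage1_exponents() -> tuple[list[float], list[float]]:
    c_exp = [float(e) for e in range(-5, 16, 2)]
    sigma_exp = [float(e) for e in range(-15, 4, 2)]
    return c_exp, sigma_exp


def svm_stage2_exponents(best_exp: float, step: float = 0.25, half_width: float = 2.0) -> list[float]:
    n = int(round(2 * half_width / step)) + 1
    return [best_exp - half_width + i * step for i in range(n)]


def pls_component_grid(p: int, n: int) -> list[int]:
    return list(range(1, min(100, p, n - 2) + 1))


def grid_search_rf(dataset: LabeledDataset, cv_folds: int = 5, seed: int = 0,
                   estimators_grid: tuple[int, ...] = (500, 1000)) -> GridResult:
    """Two-stage RF grid: estimators x mtry ladder (step 20), then a step-2
    rescan of mtry' +/- 50 clipped to [1, p]."""
    p = dataset.features.p
    if p < 2:
        raise ValueError("need p >= 2")
    stage1 = [{"estimators": e, "mtry": m} for e in estimators_grid for m in rf_stage1_mtry_grid(p)]
    scores: dict = {}

    def score(params: dict) -> float:
        key = tuple(sorted(params.items()))
        if key not in scores:
            cfg = ModelConfig("rf", dataset.task, dict(params), seed=seed)
            scores[key] = _cv_score(dataset, cfg, cv_folds, seed)
        return scores[key]

    stage1_best = max(stage1, key=lambda g: (score(g), -g["mtry"], -g["estimators"]))
    stage2 = [
        {"estimators": stage1_best["estimators"], "mtry": m}
        for m in rf_stage2_mtry_grid(stage1_best["mtry"], p)
    ]
    final_best = max(stage2, key=lambda g: (score(g), -g["mtry"]))
    return GridResult(stage1, stage2, stage1_best, final_best, dict(scores))


def grid_search_svm(dataset: LabeledDataset, cv_folds: int = 5, seed: int = 0) -> GridResult:
    """Two-stage RBF SVM grid over (C, Sigma) exponent ladders."""
    c_exp, s_exp = svm_stage1_exponents()
    stage1 = [{"C_exp": c, "Sigma_exp": s} for c in c_exp for s in s_exp]
    scores: dict = {}

    def score(params: dict) -> float:
        key = (params["C_exp"], params["Sigma_exp"])
        if key not in scores:
            cfg = ModelConfig(
                "svm_rbf",
                dataset.task,
                {"C": 2.0 ** params["C_exp"], "Sigma": 2.0 ** params["Sigma_exp"]},
                seed=seed,
            )
            scores[key] = _cv_score(dataset, cfg, cv_folds, seed)
        return scores[key]

    stage1_best = max(stage1, key=lambda g: (score(g), -g["C_exp"], -g["Sigma_exp"]))
    stage2 = [
        {"C_exp": c, "Sigma_exp": s}
        for c in svm_stage2_exponents(stage1_best["C_exp"])
        for s in svm_stage2_exponents(stage1_best["Sigma_exp"])
    ]
    final_best = max(stage2, key=lambda g: (score(g), -g["C_exp"], -g["Sigma_exp"]))
    final = {
        "C": 2.0 ** final_best["C_exp"],
        "Sigma": 2.0 ** final_best["Sigma_exp"],
        **final_best,
    }
    return GridResult(stage1, stage2, stage1_best, final, {str(k): v for k, v in scores.items()})


def grid_search_pls(dataset: LabeledDataset, cv_folds: int = 5, seed: int = 0) -> GridResult:
    """PLS n_components grid 1..min(100, p, n-2), best by Q^2 (ties toward
    fewer components)."""
    if dataset.task != "regression":
        raise ValueError("PLS grid search is regression-only")
    p, n = dataset.features.p, dataset.n
    if p == 0:
        raise ValueError("need p >= 1")
    grid = [{"n_components": c} for c in pls_component_grid(p, n)]
    scores = {}
    for g in grid:
        cfg = ModelConfig("pls", "regression", dict(g), seed=seed)
        scores[g["n_components"]] = _cv_score(dataset, cfg, cv_folds, seed)
    best = max(grid, key=lambda g: (scores[g["n_components"]], -g["n_components"]))
    return GridResult(grid, [], best, best, scores)


# ---------------------------------------------------------------------------
# imbalance strategies


class _BalancedForest:
    """Forest of CART trees, each grown on samplesize positives +
    samplesize negatives drawn without replacement within class."""

    def __init__(self, trees, tree_samples):
        self.trees = trees
        self.tree_samples = tree_samples  # list of (pos_idx, neg_idx)
        self.classes_ = np.array([0.0, 1.0])

    def predict_proba(self, X):
        votes = np.mean([t.predict(X) for t in self.trees], axis=0)
        return np.column_stack([1 - votes, votes])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)


def coverage_tree_count(samplesize: int, class_size: int, target: float = 0.99) -> int:
    """Trees needed so each compound of a class of *class_size* enters at
    least one per-tree sample with probability >= *target*."""
    if samplesize >= class_size:
        return 1
    miss = 1.0 - samplesize / class_size
    return int(math.ceil(math.log(1.0 - target) / math.log(miss)))


def train_balanced_rf(
    dataset: LabeledDataset,
    samplesize: int | None = None,
    estimators: int | None = None,
    seed: int = 0,
    replacement: bool = False,
) -> TrainedModel:
    """Balanced random forest via the samplesize strategy.

    Each tree sees exactly ``samplesize`` positives and ``samplesize``
    negatives. The default tree count is derived from the coverage rule:
    every training compound appears in at least one tree's sample with
    probability >= 0.99 (warned otherwise).
    """
    if dataset.task != "classification":
        raise ValueError("balanced RF is classification-only")
    y = dataset.y
    pos_idx = np.where(y == 1)[0]
    neg_idx = np.where(y == 0)[0]
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise ValueError("both classes need >= 2 members")
    min_class = min(len(pos_idx), len(neg_idx))
    if samplesize is None:
        samplesize = min(100, min_class)
    if samplesize > min_class and not replacement:
        raise ValueError(
            f"samplesize {samplesize} exceeds minority class size {min_class} "
            "without replacement"
        )
    needed = max(
        coverage_tree_count(samplesize, len(pos_idx)),
        coverage_tree_count(samplesize, len(neg_idx)),
    )
    if estimators is None:
        estimators = max(100, needed)
    elif estimators < needed:
        warnings.warn(
            f"{estimators} trees give per-compound coverage probability below "
            f"0.99 (need >= {needed})"
        )
    rng = np.random.default_rng(seed)
    X = dataset.features.values.astype(float)
    trees, tree_samples = [], []
    for t in range(estimators):
        ps = rng.choice(pos_idx, size=samplesize, replace=replacement)
        ns = rng.choice(neg_idx, size=samplesize, replace=replacement)
        idx = np.concatenate([ps, ns])
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        tree_samples.append((ps, ns))
    forest = _BalancedForest(trees, tree_samples)
    cfg = ModelConfig(
        "rf", "classification", {"samplesize": samplesize, "estimators": estimators}, seed=seed
    )
    summary = {
        "n": dataset.n,
        "p": dataset.features.p,
        "per_tree_class_counts": [(len(p_), len(n_)) for p_, n_ in tree_samples],
    }
    return TrainedModel(cfg, dataset.features.columns, forest, summary)


def train_resampling_consensus(
    dataset: LabeledDataset,
    n_members: int = 10,
    seed: int = 0,
    member_estimators: int = 100,
) -> ConsensusModel:
    """Resampling consensus for imbalanced data.

    Each of ``n_members`` models trains on all minority-class compounds plus
    a without-replacement majority subsample of equal size; the consensus
    probability is the mean over members.
    """
    if dataset.task != "classification":
        raise ValueError("resampling consensus is classification-only")
    y = dataset.y
    pos_idx = np.where(y == 1)[0]
    neg_idx = np.where(y == 0)[0]
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be present")
    minority, majority = (pos_idx, neg_idx) if len(pos_idx) <= len(neg_idx) else (neg_idx, pos_idx)
    ratio = len(majority) / len(minority)
    if ratio < 1.2:
        warnings.warn(f"classes nearly balanced (ratio {ratio:.2f}); consensus proceeds anyway")
    rng = np.random.default_rng(seed)
    ids = np.array(dataset.features.row_ids)
    members = []
    for m in range(n_members):
        sub = rng.choice(majority, size=len(minority), replace=False)
        idx = np.sort(np.concatenate([minority, sub]))
        subset = dataset.subset(list(ids[idx]))
        cfg = ModelConfig(
            "rf",
            "classification",
            {"estimators": member_estimators},
            seed=int(rng.integers(2**31 - 1)),
        )
        members.append(train(subset, cfg))
    return ConsensusModel(members)
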