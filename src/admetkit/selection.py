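"""Descriptor pre-filtering and RF-importance recursive feature elimination.

The pre-filter applies three rules in order: (1) drop zero / near-zero
variance columns, (2) drop columns where more than 95% of values are
identical (modal frequency), (3) for column pairs with |Pearson r| > 0.95,
drop one member of each pair (random under a seed, otherwise the
lexicographically later name).

The recursive elimination fits a random forest (1000 trees by default,
mtry = floor(sqrt(p))), ranks features by impurity importance, scores the
current set by 5-fold CV (Q^2 for regression, ACC for classification),
removes the two least important features and repeats down to 2 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .dataprep import LabeledDataset
from .evaluation import classification_metrics, make_folds, regression_metrics
from .features import FeatureMatrix


@dataclass
class PrefilterReport:
    removed_zero_variance: list[str] = field(default_factory=list)
    removed_high_identity: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    surviving: list[str] = field(default_factory=list)


@dataclass
class RfePath:
    steps: list[dict]  # n_features, features, cv_score, importance_ranking
    best_index: int

    @property
    def best_features(self) -> list[str]:
        return list(self.steps[self.best_index]["features"])


def prefilter(
    matrix: FeatureMatrix,
    var_eps: float = 1e-8,
    identity_threshold: float = 0.95,
    corr_threshold: float = 0.95,
    seed: int | None = None,
) -> tuple[FeatureMatrix, PrefilterReport]:
    """Apply the three pre-selection rules in order; idempotent."""
    report = PrefilterReport()
    df = matrix.df
    X = df.to_numpy(dtype=float)
    cols = list(df.columns)

    # rule 1: zero / near-zero variance on standardized columns
    std = X.std(axis=0)
    scale = np.where(std > 0, std, 1.0)
    var_std = ((X - X.mean(axis=0)) / scale).var(axis=0)
    keep = []
    for j, c in enumerate(cols):
        if std[j] == 0 or var_std[j] <= var_eps:
            report.removed_zero_variance.append(c)
        else:
            keep.append(j)

    # rule 2: modal value frequency > identity_threshold
    keep2 = []
    n = X.shape[0]
    for j in keep:
        _, counts = np.unique(X[:, j], return_counts=True)
        if counts.max() / n > identity_threshold:
            report.removed_high_identity.append(cols[j])
        else:
            keep2.append(j)

    # rule 3: |r| > corr_threshold, remove one member of each pair
    order = sorted(keep2, key=lambda j: cols[j])
    rng = np.random.default_rng(seed) if seed is not None else None
    removed: set[int] = set()
    if len(order) > 1:
        sub = X[:, order]
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(sub, rowvar=False)
        for a in range(len(order)):
            if order[a] in removed:
                continue
            for b in range(a + 1, len(order)):
                if order[b] in removed:
                    continue
                rv = r[a, b]
                if np.isfinite(rv) and abs(rv) > corr_threshold:
                    if rng is not None and rng.random() < 0.5:
                        drop, kept = order[a], order[b]
                    else:
                        drop, kept = order[b], order[a]
                    report.removed_correlated.append((cols[kept], cols[drop], float(rv)))
                    removed.add(drop)
                    if drop == order[a]:
                        break

    surviving = [cols[j] for j in keep2 if j not in removed]
    if not surviving:
        raise ValueError("no informative descriptors remain after pre-filtering")
    report.surviving = surviving
    return matrix.subset_columns(surviving), report


def _fit_forest(X, y, task: str, estimators: int, seed: int):
    mtry = max(1, int(np.sqrt(X.shape[1])))
    cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
    forest = cls(n_estimators=estimators, max_features=mtry, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return forest


def _cv_score(X, y, task: str, estimators: int, cv_folds: int, seed: int) -> float:
    folds = make_folds(len(y), cv_folds, seed)
    oof = np.full(len(y), np.nan)
    for f, idx in enumerate(folds):
        mask = np.ones(len(y), dtype=bool)
        mask[idx] = False
        forest = _fit_forest(X[mask], y[mask], task, estimators, seed + f)
        if task == "regression":
            oof[idx] = forest.predict(X[idx])
        else:
            col = int(np.where(forest.classes_ == 1)[0][0])
            oof[idx] = forest.predict_proba(X[idx])[:, col]
    if task == "regression":
        q2, _ = regression_metrics(y, oof, ybar_reference=float(np.mean(y)))
        return q2
    return classification_metrics(y, oof).ACC


def rf_rfe(
    dataset: LabeledDataset,
    cv_folds: int = 5,
    step: int = 2,
    estimators: int = 1000,
    seed: int = 0,
) -> RfePath:
    """Recursive elimination by random-forest importance.

    Each step fits a forest on the current feature set, records the 5-fold
    CV score and the importance ranking, then removes the *step* least
    important features; the path ends at 2 features (a single step when
    p < 4). Fold assignment folds the step index into the seed so the whole
    path is reproducible.
    """
    y = dataset.y
    task = dataset.task
    current = list(dataset.features.columns)
    df = dataset.features.df
    steps: list[dict] = []
    step_idx = 0
    while True:
        X = df[current].to_numpy(dtype=float)
        forest = _fit_forest(X, y, task, estimators, seed + 1000 * step_idx)
        importances = np.asarray(forest.feature_importances_, dtype=float)
        if not np.all(np.isfinite(importances)):
            raise ValueError("non-finite feature importance")
        cv = _cv_score(X, y, task, estimators, cv_folds, seed + 1000 * step_idx)
        ranking = [current[j] for j in np.argsort(importances)[::-1]]
        steps.append(
            {
                "n_features": len(current),
                "features": list(current),
                "cv_score": cv,
                "importance_ranking": ranking,
            }
        )
        if len(current) <= 2 or len(dataset.features.columns) < 4:
            break  # 2-feature floor; p < 4 gives a single-step path
        n_drop = min(step, len(current) - 2)
        drop = set(ranking[-n_drop:])
        current = [c for c in current if c not in drop]
        step_idx += 1
    best = select_best_index(steps)
    return RfePath(steps=steps, best_index=best)


def select_best_index(steps: Sequence[dict]) -> int:
    """Argmax of cv_score; ties broken toward fewer features."""
    if not steps:
        raise ValueError("empty path")
    return max(range(len(steps)), key=lambda i: (steps[i]["cv_score"], -steps[i]["n_features"]))


def select_best(path: RfePath) -> list[str]:
    """Feature set of the best step (maximal CV score, ties toward fewer)."""
    return list(path.steps[select_best_index(path.steps)]["features"])
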