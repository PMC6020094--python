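"""Train a grid-searched random forest regressor and report the six-number
regression evaluation (fit / cross-validation / test)."""

import numpy as np

import admetkit as ak
from admetkit.modeling import ModelConfig, grid_search_rf, predict, train
from admetkit.synthetic import SyntheticSpec

spec = SyntheticSpec(n=150, n_features=12, n_informative=4, noise_sigma=0.5, seed=3)
ds, _ = ak.generate_qsar_dataset(spec)
ids = ds.features.row_ids
train_ds, test_ds = ds.subset(ids[:110]), ds.subset(ids[110:])

grid = grid_search_rf(train_ds, cv_folds=5, seed=3, estimators_grid=(100,))
print(f"grid-searched mtry = {grid.final_best['mtry']}")

config = ModelConfig("rf", "regression", grid.final_best, seed=3)
model = train(train_ds, config)

ybar = float(np.mean(train_ds.y))
r2_f, rmse_f = ak.regression_metrics(train_ds.y, predict(model, train_ds.features)["value"])
q2, rmse_cv = ak.cross_validate(train_ds, config, k=5, seed=3)
r2_t, rmse_t = ak.regression_metrics(
    test_ds.y, predict(model, test_ds.features)["value"], ybar_reference=ybar
)
print(f"R2_F={r2_f:.3f} RMSE_F={rmse_f:.3f}  Q2={q2:.3f} RMSE_cv={rmse_cv:.3f}  "
      f"R2_T={r2_t:.3f} RMSE_T={rmse_t:.3f}")
# R2_T uses the TRAINING-set mean as its reference, and Q2 comes from pooled
# out-of-fold predictions; expect R2_F > Q2 (fit beats cross-validation).

fe = ak.fold_error_rates(np.abs(test_ds.y) + 5, np.abs(predict(model, test_ds.features)["value"]) + 5)
print(f"fold errors on shifted-positive scale: average {fe.average_fold:.2f}, "
      f"within 2-fold {fe.within_2fold:.0%}, within 3-fold {fe.within_3fold:.0%}")
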