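# admetkit

A toolkit for building and evaluating QSAR models of ADMET endpoints
(absorption, distribution, metabolism, excretion, toxicity), for medicinal
and computational chemists who want the full pipeline — from raw SMILES/SDF
to an evaluated, serialized model — as an importable Python library with a
thin `admetkit` command-line wrapper.

## What it does

- **Molecule I/O and washing** (`admetkit.chem_io`): read SMILES/SDF/CSV,
  disconnect simple metal salts, keep the largest fragment, normalize
  hydrogens; every removal is logged, never silent.
- **Featurization** (`admetkit.features`): eleven continuous descriptor
  families (constitution, topology, connectivity, E-state, kappa, Basak
  information indices, Burden/BCUT, autocorrelation, charge, property,
  MOE-type surface areas) and five fingerprints — FP2 (hashed linear paths
  up to 7 atoms, 2048 bits), MACCS (167 keys), ECFP2/4/6 (circular, folded
  to 2048 bits).
- **Dataset preparation** (`admetkit.dataprep`): duplicate handling for
  classification (conflicting labels dropped) and regression (arithmetic
  mean within a relative-spread limit), and a diverse 75/25 train/test
  split by max-min Tanimoto picking over ECFP4.
- **Feature selection** (`admetkit.selection`): the three-rule pre-filter
  (zero variance; >95% identical values; pairwise |r| > 0.95) and recursive
  feature elimination driven by random-forest importance, two features per
  step, scored by 5-fold cross-validation.
- **Modeling** (`admetkit.modeling`): random forest, RBF-kernel SVM, PLS
  and CART for regression; random forest, RBF SVM, naive Bayes and CART for
  classification. Two-stage grid searches (RF: estimators {500, 1000} x an
  mtry ladder of step 20, then a step-2 rescan of mtry' ± 50; SVM:
  C = 2⁻⁵…2¹⁵, Sigma = 2⁻¹⁵…2³ in steps of 2², then a 2^0.25 fine scan;
  PLS: 1–100 components). Two imbalance strategies: balanced trees grown on
  *samplesize* positives + *samplesize* negatives each, and a 10-member
  resampling consensus averaging member probabilities.
- **Evaluation** (`admetkit.evaluation`): R²_F/RMSE_F, Q²/RMSE_cv (pooled
  out-of-fold), R²_T/RMSE_T — all against the training-set mean ȳ — plus
  ACC, SP, SE, rank-statistic AUC, Cohen's kappa, and the fold-error metric
  fold = 1 + |ŷ − y|/y with within-2-fold / within-3-fold rates.
- **Drug-likeness** (`admetkit.druglikeness`): Lipinski, Ghose, Oprea,
  Veber and Varma rule batteries with overridable thresholds.
- **Search and profiling** (`admetkit.search_profile`): a local ADMET
  record store (CSV) with accurate (SMILES/CAS/IUPAC), range
  (MW/AlogP/HBA/HBD) and similarity search (five fingerprints × Tanimoto or
  Dice), and per-molecule profiles mapping probabilities to `+`/`−` symbol
  runs.
- **Synthetic data** (`admetkit.synthetic`): molecule corpora from a
  fragment grammar and feature/label datasets with known informative
  features, so the whole pipeline is testable without external data.

## Worked example

`examples/04_imbalanced_endpoints.py` trains the two imbalance strategies
against a standard random forest on a synthetic 9:1 endpoint (n = 1000,
10 features, 5 informative) and evaluates on 200 held-out compounds:

```
standard rf: SE=0.118 SP=0.995 |SE-SP|=0.877 kappa=0.179
balanced rf: SE=0.706 SP=0.913 |SE-SP|=0.207 kappa=0.478
consensus  : SE=0.882 SP=0.907 |SE-SP|=0.025 kappa=0.564
```

The standard forest all but ignores the minority class (sensitivity 0.12 at
specificity 1.00). Growing every tree on a balanced per-class sample, or
averaging ten models each trained on all minority compounds plus an
equal-size majority subsample, brings SE and SP close together and roughly
triples kappa. The other examples (`examples/01`–`06`) cover washing and
featurization, the diverse split and feature elimination, grid-searched
regression with the six-number evaluation, rule screening and profiling,
and record-store search.

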