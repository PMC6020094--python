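# Methods

This note documents the models and procedures admetkit implements, the
defaults and why, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## Molecule washing

Washing standardizes an input structure in three steps, in order:

1. **Salt disconnection.** Bonds between alkali / alkaline-earth metals
   (Li, Na, K, Rb, Cs, Be, Mg, Ca, Sr, Ba) and O/N/S are cleaved
   heterolytically, charging the metal +1 and the heteroatom −1. This
   approximates the behavior of commercial washing tools for "simple
   salts"; no claim of bit-compatibility with any particular salt
   dictionary is made, and tautomer/charge standardization beyond this is
   out of scope.
2. **Largest fragment.** The fragment with the most heavy atoms is kept;
   ties break by molecular weight, then lexicographic canonical SMILES, so
   the output is deterministic.
3. **Hydrogen normalization.** The stored structure carries explicit
   hydrogens; the stored canonical SMILES is written from the implicit-H
   form. A structure left without heavy atoms becomes an
   `EMPTY_AFTER_WASH` removal.

Washing is idempotent, which the tests verify over a salted synthetic
corpus.

## Descriptors and fingerprints

Descriptor families are computed with RDKit. The family manifest
(`features.family_manifest()`) is the membership contract; column counts
per family are fixed across molecules but differ from the conventional
counts of other toolkits where RDKit's coverage differs (e.g. the kappa
family here is Kappa1–3, Hall–Kier alpha and the Kier flexibility index;
Basak-style information indices IC/SIC/CIC at neighborhood orders 0–2 are
implemented in-package since no installed library provides them). The
property family is exactly six columns: LogP, molar refractivity, TPSA,
H-bond donors, H-bond acceptors, molecular weight. Descriptors are computed
on a molecule re-parsed from its canonical SMILES so identical structures
give bit-identical rows; molecules with any non-finite value are excluded
and listed in the failure report, so assembled matrices contain no NaN/∞.

Fingerprints and widths: FP2 2048 bits, MACCS 167, ECFP2/4/6 2048 each.
ECFP2/4/6 use circular radius 1/2/3 folded to 2048 bits. FP2 is an
in-package path fingerprint: all simple linear paths of 2–7 atoms (plus
pure ring cycles up to 7 bonds) are rendered as direction-canonical
element/bond strings and hashed (CRC32) into 2048 bits. Closed ring walks
are canonicalized over all rotations and both directions because the
underlying path enumerator returns one arbitrary rotation per bond set;
walks that revisit an atom without being a pure cycle have no
orientation-free canonical form and are skipped. Bit-level compatibility
with Open Babel's FP2 is explicitly not a goal; the enumeration above is
the definition.

## Dataset pretreatments and the diverse split

Classification duplicates (same canonical SMILES) collapse to one entry
when all labels agree and are dropped (`CONFLICTING_LABELS`) otherwise —
dropping avoids an arbitrary label choice. Regression duplicates merge to
their arithmetic mean when the relative spread (max−min)/|mean| is within
`rel_spread_limit` (default 0.5, configurable; an absolute epsilon of 1e-8
applies when the group mean is exactly 0) and are dropped
(`EXCESS_SPREAD`) otherwise.

The train/test split picks a maximally diverse training set by max-min
(Kennard–Stone-style) selection on Tanimoto distance over ECFP4 bits: the
first pick is the molecule with the highest mean distance to all others;
each subsequent pick maximizes the minimum distance to the picked set.
|train| = round(fraction · n), rounding half up, default fraction 0.75.
The seed only breaks exact distance ties (via an additive jitter of 1e-12,
far below any achievable distance gap). Descriptor matrices passed directly
are binarized at the per-column median for the distance computation only.

## Feature selection

The pre-filter applies, in order: (1) remove columns with zero or
near-zero variance (variance ≤ 1e-8 on standardized columns — "close to
zero" needs a number and this one is scale-free); (2) remove columns whose
modal value frequency exceeds 95% (the identity rule is read as modal
frequency, not pairwise identity); (3) scan column pairs in name order and,
when |Pearson r| > 0.95, remove one member — randomly under a seed,
otherwise the lexicographically later name. The filter is idempotent.

Recursive elimination fits a random forest (default 1000 trees,
mtry = ⌊√p⌋) on the current set, records the impurity-importance ranking
and the 5-fold CV score (Q² for regression, ACC for classification),
removes the two least important features, and repeats to a 2-feature
floor (the final step removes one feature if only one separates the set
from the floor; p < 4 yields a single-step path). Fold assignment folds
the step index into the seed, making the whole path reproducible. The best
step maximizes CV score with ties broken toward fewer features.

## Models and grids

Algorithm/task compatibility is enforced: regression ∈ {rf, svm_rbf, pls,
cart_regression}, classification ∈ {rf, svm_rbf, naive_bayes,
decision_tree}. Naive Bayes uses a Bernoulli event model on fingerprint
matrices and Gaussian on continuous descriptors.

The SVM's `Sigma` parameterizes the RBF kernel as
exp(−‖x−z‖²/(2·Sigma²)), i.e. scikit-learn's gamma = 1/(2·Sigma²).
Features are z-scored inside the SVM pipeline using training-fold
statistics, since RBF kernels are scale-sensitive.

Grid searches score every point by mean 5-fold CV (Q² regression, ACC
classification):

- **RF**: stage 1 crosses estimators {500, 1000} with mtry ∈ {1, 21, 41, …}
  up to p; stage 2 rescans mtry′ ± 50 at step 2. When the ±50 window
  extends past [1, p] it is clipped rather than skipped, so small-p
  problems still get a fine scan.
- **SVM**: stage 1 is the exponent ladder C: −5, −3, …, 15 (11 points) ×
  Sigma: −15, −13, …, 3 (10 points); stage 2 scans both exponents jointly
  over best ± 2 (one coarse step) at step 0.25.
- **PLS**: components 1 .. min(100, p, n−2), ties toward fewer components.

A degenerate single-class CV training fold triggers a refold with a
shifted seed, erroring after three attempts.

### Imbalance strategies

`train_balanced_rf` grows each CART tree on exactly `samplesize` positives
plus `samplesize` negatives drawn without replacement within class
(default samplesize = min(100, minority class size)). The tree count
defaults to the smallest T such that every compound of either class enters
at least one per-tree sample with probability ≥ 0.99 — i.e.
(1 − s/n_class)^T ≤ 0.01 — with a floor of 100; an explicit smaller count
warns. Per-tree class compositions are kept in the fit metadata so the
contract is introspectable.

`train_resampling_consensus` trains 10 members (default), each on all
minority-class compounds plus an equal-size without-replacement majority
subsample; the consensus probability is the arithmetic mean of member
probabilities (mean rather than majority vote, so the output remains a
graded score), label at 0.5. Nearly balanced input (ratio < 1.2) warns and
proceeds.

## Evaluation

R² = 1 − Σ(ŷᵢ−yᵢ)²/Σ(yᵢ−ȳ)² and RMSE = √(Σ(yᵢ−ŷᵢ)²/N), where ȳ is always
the mean of the training-set experimental values — including for test-set
R²_T. This is a deliberate contract: it penalizes a model whose test
predictions are good only relative to a shifted test distribution, and it
can make R²_T differ from implementations that reference the test mean.
Q²/RMSE_cv are computed from pooled out-of-fold predictions of k-fold CV
(shuffled round-robin folds, sizes differing by at most 1; classification
CV is unstratified by default with a stratify flag available).

Classification: SE = TP/(TP+FN), SP = TN/(TN+FP), ACC; labels threshold
probabilities at 0.5 everywhere. AUC uses the Mann–Whitney rank statistic
with tied scores contributing ½. Cohen's kappa is (p_o − p_e)/(1 − p_e)
with chance agreement from the marginal products; when both raters are
constant and equal (p_e = 1) kappa is defined as 0 with a warning.

Fold error: fold = 1 + |ŷ − y|/y per sample (undefined and an error at
y ≤ 0), with within-2-fold and within-3-fold success rates using ≤ (a
prediction exactly at 2-fold counts as within) and the arithmetic mean as
the average fold.

## Drug-likeness rules

The five batteries use their canonical published thresholds — Lipinski
(MW ≤ 500, LogP ≤ 5, HBD ≤ 5, HBA ≤ 10, at most one violation allowed),
Ghose (160 ≤ MW ≤ 480, −0.4 ≤ LogP ≤ 5.6, 40 ≤ MR ≤ 130, 20 ≤ atoms ≤ 70),
Oprea lead-like (MW ≤ 450, LogP ≤ 4.5, rings ≤ 4, RotB ≤ 10, HBD ≤ 5,
HBA ≤ 8), Veber (RotB ≤ 10, TPSA ≤ 140) and Varma (MW ≤ 500, TPSA ≤ 125,
LogP ≤ 5 as a logD proxy; logD modeling itself is out of scope). Several
of these rules exist in multiple published variants, which is exactly why
the thresholds are configuration (overridable via a `rule.descriptor =
bound` text file), not code. Every criterion is evaluated and reported;
a molecule whose descriptors cannot be computed is flagged INCOMPUTABLE,
never passed.

## Record store, search and profiles

The store is a plain CSV; SMILES are canonicalized at load and missing
MW/AlogP/HBA/HBD columns are computed then, so range search always has its
four keys. Range bounds are inclusive on both ends and multiple ranges
conjoin. Similarity uses Tanimoto |A∩B|/|A∪B| or Dice 2|A∩B|/(|A|+|B|) on
bit sets (the two standard binary-set metrics); a query with no bits set
scores 0 everywhere with a warning; hits sort by descending score with
ties by entry id.

Profile symbols map classification probabilities to bands
[0,0.1]→`---`, (0.1,0.3]→`--`, (0.3,0.5]→`-`, (0.5,0.7]→`+`,
(0.7,0.9]→`++`, (0.9,1]→`+++`; the symbol count tracks confidence, and
regression endpoints show a numeric value with its unit from the bundled
endpoint metadata file. The hosted multi-hundred-thousand-entry record
content is not bundled — users point the store at their own CSV.

## Synthetic data

The corpus generator assembles SMILES from a bundled fragment grammar
(12 ring scaffolds, 13 linkers, 15 functional groups, up to three
decorations), parses and canonicalizes each candidate, and enforces
distinctness on canonical SMILES; with `include_salts` 20% of molecules
carry a counter-ion fragment. Generation is deterministic per seed and
raises when 5000 consecutive attempts yield nothing new (grammar
exhaustion).

The dataset generator draws X ~ N(0, 1) i.i.d. and builds
y = Σ βⱼxⱼ + ε, ε ~ N(0, σ); classification thresholds the logistic
transform of the noisy score at its empirical quantile so the class
balance is exact up to ties. Defaults mirror the study conditions the
tests exercise: the feature-recovery benchmark uses n = 300, p = 50,
5 informative features with coefficients 1.0–2.0 and σ = 0.5; the
imbalance benchmark uses n = 1000 at 9:1 balance with 10 features. These
synthetic datasets have independent features, linear signal and Gaussian
noise — none of the correlation structure, activity cliffs, assay noise or
label imbalance mechanisms of real ADMET data — so passing tests
demonstrate algorithmic correctness and qualitative behavior (e.g. that
the imbalance strategies close the SE/SP gap), not real-data performance.
Reproducing published per-endpoint accuracies would require the original
curated datasets, which are not distributed with this package.

## Problem sizes and tree counts

The recursive-elimination benchmark runs with 150 trees per forest rather
than the 1000-tree default: at n = 300, p = 50 the importance ranking and
recovery behavior are insensitive to tree count well below 1000, and the
smaller forest keeps the five-seed benchmark to ~2 minutes on one CPU.
The balanced-RF benchmark uses the coverage-derived tree count described above;
consensus members default to 100-tree forests.

## Known limitations

- Descriptor family counts are RDKit's coverage, not any other toolkit's;
  numeric replication of Chemopy/ChemDes values is a non-goal.
- FP2 is this package's enumeration, not Open Babel's bit layout.
- No applicability-domain estimation, probability calibration beyond the
  consensus mean, stereochemistry normalization, tautomer handling, 3D
  descriptors, or scaffold/temporal splits.
- Model files are Python pickles (with a format-version tag and an
  embedded SHA-256 payload digest): load only files you trust.
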