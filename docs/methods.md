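# Methods

This note records the models, conventions and design choices behind
`dpphqsar`, in the spirit of a package's statistical reference page.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Endpoint and curation model

The modeled endpoint is the DPPH radical-scavenging IC50, transformed to
pIC50 = −log₁₀(IC50 [mol/L]).  The log transform symmetrizes the
concentration scale, which spans roughly 10⁻⁷–10⁻² M; both the raw-IC50 and
pIC50 skewness (adjusted Fisher–Pearson, bias-corrected, right tail
positive) are reported by the curation stage so the effect of the transform
is visible per dataset.

Curation runs in a fixed order: assay-window filter → quantitative filter →
structure standardization → molecular-weight cut → molar conversion and
pIC50 → duplicate reconciliation (InChI pass, then canonical-SMILES pass).
Conventions, where the underlying procedure admits more than one reading:

- **Assay window.** A record survives if its free-text assay description
  contains the keyword (case-insensitive, default "DPPH") and its incubation
  time equals the window (default 30 min) exactly.  Records matching the
  keyword but missing a time are routed to a "needs manual check" list and
  counted separately; the package performs no literature lookup for them.
- **Quantitative filter.** Only exactly valued IC50s survive; "<", ">",
  ratio-style and unparseable values are excluded.  Inline qualifiers in the
  value cell (e.g. `>100`) override the qualifier column.
- **Standardization.** Largest organic fragment (salt/counterion stripping),
  charge neutralization where chemically valid, stereochemistry removal,
  then RDKit canonical SMILES.  Stereo is removed *before* InChI generation
  so both deduplication keys are stereo-free and the two passes are
  consistent.  Purely inorganic structures are excluded; unparseable SMILES
  are dropped with a logged count, never fatally.
- **Molecular weight.** "Small molecule" means MW ≤ 1000 Da, boundary
  inclusive (exactly 1000.0 is kept).
- **Units.** A fixed alias table maps accepted spellings (µM/μM/uM,
  ug/mL ≡ mg/L, …); unknown tokens are errors, never guesses.  Mass-based
  units are converted with the *standardized* structure's molecular weight.
- **Replicates.** The coefficient of variation CV = σ/μ uses the sample
  standard deviation (n−1 denominator) — duplicate groups are tiny samples,
  so this is the conservative estimator.  Groups with CV ≤ 0.1 collapse to
  the unweighted mean of their member IC50s taken on the linear molar scale
  (then re-logged); groups above the cutoff are removed entirely.  Averaging
  on the molar scale, and unweighted across the two passes, is a documented
  package choice, not an inference about any particular upstream dataset.

The curation report satisfies an exact conservation identity: input rows =
output compounds + Σ dropped (per stage) + merged-away rows.  Tests assert
it on manifests with known ground truth.

## Descriptors and scaling

Descriptors are RDKit's 2D set (~210 named numeric descriptors:
constitutional counts, topological/connectivity indices, E-state sums,
logP/TPSA-type properties).  2D-only is the default because 3D descriptors
depend on conformer embedding and would compromise bit-reproducibility; an
opt-in flag embeds a single seeded ETKDGv3 conformer and appends RDKit's 3D
shape descriptors under a documented protocol.  Columns with any non-finite
value are dropped rather than imputed (no defensible imputation rule exists
for failed calculations), as are zero-variance columns, which cannot be
z-scaled.

Scaling is z-scoring with the population (n-denominator) standard
deviation, the StandardScaler convention.  Scaler parameters are fitted on
training rows only and applied unchanged to held-out data; fitting the
scaler before the split would leak test-set location/scale into training.

## Feature selection

Two univariate rankings are intersected:

- **F score**: F = r²(n−2)/(1−r²), r the Pearson correlation of the
  (scaled) descriptor with pIC50.  A perfectly correlated descriptor gets
  +inf and ranks first; this statistic sees linear association only.
- **Mutual information**: the k-nearest-neighbour entropy estimator for a
  continuous target (k = 3, the customary default for this estimator
  family), seeded so the estimator's internal jitter is reproducible.
  Estimates are clipped at zero.

Descriptors in the top-k of *both* rankings are retained, ordered by F-score
rank; ties break by (score descending, name ascending), which also makes the
selection invariant to input column order.  The defaults k_f = k_mi = 300
retain on the order of 10²–all descriptors depending on matrix width; the
appropriate k is dataset-specific and both k values are exposed as
parameters.  Selection is monotone in k (enlarging either k never shrinks
the selected set), a property under test.

## Models and validation

Eleven regression algorithms are supported (extra trees, gradient boosting,
XGBoost, random forest, k-NN, AdaBoost, decision tree, ridge, elastic net,
Bayesian ridge, lasso), instantiated from scikit-learn/xgboost with a shared
seed.  Hyperparameters come from an exhaustive grid search over small
shipped grids (≤ 24 points per algorithm, in `default_grids.json`) scored by
mean k-fold CV R²; ties break toward the earlier grid point, and a grid
point that fails to fit scores −inf with a warning.  The winner is refitted
on the full training set.

Internal validation is 10-fold cross-validation: indices are shuffled once
with the seed, then cut into contiguous chunks whose sizes differ by at most
one; no stratification (continuous target).  The report carries the per-fold
R², their mean and median, and a 95% confidence halfwidth
t(0.975, k−1)·sd(folds)/√k using Student's t.  External validation is a
seeded 80/20 hold-out (test size = ⌈0.2·n⌉, so 1911 records split
1528/383) evaluated with R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)², RMSE and MAE.  R² is
allowed to be negative: for a predictor worse than the training mean on
held-out data that is the mathematically correct value, even though fitted
regressions on their own data stay in [0, 1].

Impurity-based feature importances (tree models only) are normalized to sum
to one.  Importance spreads across collinear descriptors — e.g. RingCount
vs. aromatic-ring counts, MolWt vs. heavy-atom counts — so the consensus
object also exposes the mean of its three members' importances, which damps
single-model dilution.

## Consensus and uncertainty

The integrated model is the unweighted mean of three tree-ensemble members
(extra trees, gradient boosting, XGBoost by default; any trained triple on
the same features and training fingerprint is accepted).  Per compound, the
uncertainty halfwidth is **3 × the sample (n−1) standard deviation of the
three member predictions**, so a report reads pIC50 = mean ± 3·sd; the
plot-level band over an evaluation set is the mean of those per-compound
halfwidths.  This definition yields both a per-compound ± value (the
"31 ± 6 mg/L" reporting style, via the mg/L conversion
10^(−pIC50)·MW·1000) and a single band for correlation plots.  The
halfwidth is invariant under shifting all member predictions and scales
linearly under scaling them; it is zero iff the members agree exactly.

## Applicability domain

Both AD methods operate in the scaled descriptor space of the training set:

- **Bounding box** — in-domain iff every descriptor lies within the
  training [min, max], inclusive.  Every training point is trivially
  in-domain.
- **Centroid** — in-domain iff the Euclidean distance to the per-feature
  training mean is at most a threshold.  The threshold is a quantile of the
  training points' own distances; the default quantile 1.0 (the maximum)
  keeps the whole training set in-domain, and smaller quantiles screen
  strictly more aggressively (the in-domain set is monotone in the
  quantile).

Metrics can be recomputed on the in-domain subset only, with the excluded
count reported alongside.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the pipeline assumes, not
real medicinal-chemistry diversity:

- **Molecules** are sampled from a hand-curated fragment grammar of ~12
  phenolic/flavonoid-like scaffolds × 20 substituents (the chemical space
  of typical DPPH-active antioxidants), standardized-unique, MW ≤ 1000 Da,
  deterministic per seed.
- **Activity** is planted as pIC50 = 4.5 + signal + ε: the signal is a
  weighted sum of five named computed descriptors (TPSA 0.5, MolLogP 0.4,
  NumHDonors 0.4, NumAromaticRings 0.3, after per-descriptor z-scoring)
  plus one interaction term (1.0 · zMolLogP·zTPSA) and one threshold term
  (1.2 · [zMolWt > 0.5]), standardized to unit variance; ε is Gaussian with
  sd 0.35 pIC50 units.  The interaction and threshold terms carry most of
  the signal so the fixture is genuinely nonlinear — linear models face a
  real handicap.  The noise level was chosen once so that an ensemble-tree
  fit attains a cross-validated R² in the 0.6–0.9 band typical of curated
  literature QSAR data (the noiseless ceiling being R² = 1).  Values are
  clipped to the plausible assay window pIC50 ∈ [2, 7].
- **Corruption** re-introduces the dirt curation must remove, each with a
  manifest entry: replicate pairs at controlled CV (m(1±d) pairs, so
  CV = d√2 and the pair mean is *exactly* the planted value), salt-form
  duplicates, "<"/">"/ratio rows, off-window and missing assay times, a
  C₇₂ alkane decoy above 1000 Da, an inorganic salt, and an unparseable
  row.

Because activities derive from computed descriptors, feature-selection and
importance recovery tests are meaningful rather than tautological.  What
passing tests do **not** show: performance on real assay data (real
IC50 noise is not Gaussian in pIC50, inter-laboratory variation is not a
clean CV, and real chemical space is far broader than the grammar), nor
descriptor relevance beyond the planted five.

## Problem sizes and determinism

The test suite and the acceptance script use 300-molecule fixtures for
model-level checks and 30–120-molecule fixtures for unit-level checks —
large enough for stable cross-validation statistics on a single CPU, small
enough for an interactive edit-test loop.  All randomness (molecule
sampling, activity noise, splits, folds, stochastic estimators, MI jitter)
derives from explicit integer seeds, and with a fixed seed the full
generate→curate→featurize→select→train path is bit-reproducible.

## Known limitations

- The descriptor universe is RDKit's 2D set; electrotopological/Geary-type
  descriptors from larger calculators are absent, so selected-feature lists
  are not comparable across calculators.
- Impurity importances remain biased toward correlated, high-cardinality
  features even after consensus averaging; they rank, they do not explain.
- The duplicate-reconciliation CV is undefined for single-measurement
  compounds, which pass through unexamined — a second measurement can later
  overturn them.
- The AD methods describe the descriptor-space envelope only; activity-cliff
  behaviour inside the envelope is not screened.
- No tautomer enumeration or pKa-aware protonation; structures are modeled
  as drawn after neutralization.
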