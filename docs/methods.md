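# Methods

This note records the statistical procedures the package implements, the
modelling choices taken where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real cohorts.

## Data model

A cohort is a list of patient records — a two-level adult diagnosis
(SZ = schizophrenia, MSD = mood spectrum disorder), one binary presence
flag per symptom, and an optional age at onset (years) for present
symptoms — together with a symptom catalog.  The catalog row for each
symptom carries its clinical dimension and the group-wise parameters:
prevalence and onset mean/SD.  Onset ages are validated against the
chart-review window [0, 17] years; violations warn by default and raise
under `strict` (population means sit well inside the window but reported
SDs imply tails, so a hard error would reject plausible records).

The built-in catalog stores prevalences as exact count/group-size
fractions rather than the published rounded percentages, because the
percentages contain at least one internal inconsistency (a count of 10/82
printed as 8.1 %); counts are treated as authoritative.  Two onset cells
are unrecoverable from the source (one typo, one single-patient cell with
no SD) and are stored as absent / zero-SD respectively; the inline
comments in `prodromes/catalog.py` document each case.  Missing presence
cells on file input are coerced to 0 with a warning: in a retrospective
chart review, "not documented" is read as "not observed".

## Univariate battery

Presence × diagnosis is tested per symptom on the 2×2 table:

- **Pearson χ²**, 1 df, *without* Yates continuity correction.  The
  uncorrected statistic reproduces the published p-value column from the
  published counts (57 of the 63 internally consistent exact-p rows to
  within half a unit of the printed last digit, and 11 of 13 printed
  bounds); the corrected statistic does not.  The six non-reproducible
  rows are frozen in `SUSPECT_P_ROWS` with per-row evidence that the
  printed value, not the computation, is at fault (e.g. two rows with
  identical counts but different printed p-values).
- **Fisher's exact test**, two-sided by the point-probability convention:
  the p-value sums hypergeometric probabilities of every table with the
  observed margins whose point probability is at most the observed one
  (relative tolerance 1e−7 for floating-point ties).  Mid-p and
  doubling conventions exist; point-probability is the common default and
  matches the published values.
- **Test choice** follows Cochran's rule — Fisher whenever any expected
  cell count is below 5 — since the original analysis does not state its
  rule; this choice reproduces the published column.
- **Mann-Whitney U** on onset ages among symptom-positive patients, with
  midrank tie handling.  For pooled samples of at most 20 the two-sided
  p-value is exact: enumeration over all C(n+m, n) assignments of the
  pooled midranks, counting assignments whose U deviates from nm/2 at
  least as much as observed (this reduces to the classical exact null
  distribution when there are no ties and remains valid with ties).
  Larger samples use the normal approximation with tie-corrected variance
  and continuity correction.  The comparison is skipped, with a recorded
  reason, when either group has fewer than two recorded onsets.

Significance is flagged at raw p < α = 0.05 per test with **no**
multiple-testing adjustment, mirroring the original analysis; every
rendering of the report carries an explicit note to that effect.  The
standard test computations are delegated to scipy (`chi2_contingency`,
`fisher_exact`, `mannwhitneyu`); the exact small-sample Mann-Whitney
branch is implemented here because scipy's exact method declines tied
data.  The test suite checks all three tests against independent oracles
(algebraic χ² identity, full hypergeometric enumeration, permutation
enumeration).

## CHAID

Implemented from scratch for nominal predictors against the two-level
diagnosis target.

*Merging.*  Starting from the observed categories, while more than two
groups remain, the pair of groups whose 2 × target sub-table has the
largest χ² p-value is merged, provided that p exceeds `alpha_merge`
(default 0.05).  A pair sub-table whose cases are all one class carries no
signal and is treated as maximally mergeable (p = 1).

*Split test.*  The merged r × 2 table's Pearson χ² p-value is multiplied
by Kass's Bonferroni multiplier — the number of partitions of the c
original categories into the r merged groups, the Stirling number
S(c, r), computed by the alternating sum
B = Σᵢ₌₀^{r−1} (−1)ⁱ (r−i)^c / (i!(r−i)!) in exact rational arithmetic —
and capped at 1.  For binary predictors B = 1 and the procedure reduces
to the plain 2×2 χ²; with Bonferroni enabled, depth-1 growth is provably
the argmax of the per-predictor χ², which the tests verify against a
brute-force oracle.

*Growth.*  A node is eligible to split when it holds at least
`min_parent` cases, is not class-pure, and is above `max_depth`.  The
candidate with the smallest adjusted p is selected (ties: larger
statistic, then catalog order) and accepted if its adjusted p ≤
`alpha_split` and every child would hold ≥ `min_child` cases; otherwise
the node stays a leaf.  Growth is fully deterministic: identical cohort
and parameters give byte-identical renderings.

*Defaults.*  `min_parent=20`, `min_child=7`: the published tree reaches
nodes far smaller than SPSS's 100/50 defaults, so permissive values are
used and documented as a guess; both are configurable.  `max_depth=6`,
`alpha_split=alpha_merge=0.05`.

*Prediction and risk.*  A patient routes down the splits to a leaf and
receives the leaf's majority class; leaf ties break toward the parent's
majority, then SZ.  A predictor value unseen at the split routes to the
child with the largest training share.  Risk is reported as
resubstitution accuracy (tree fitted on all data classifying its own
training set) alongside a stratified k-fold cross-validated
misclassification proportion (default 10 folds, seeded assignment via
scikit-learn's `StratifiedKFold`) — the interpretation taken for
"cross-validated CHAID", matching common CHAID software: the reported
tree is fitted on all data, the CV risk estimates its out-of-sample error.

*Covariable selection.*  The pipeline's default hands CHAID the
battery-significant symptoms (`selection="battery"`); `"all"` and an
explicit list are available.

## Synthetic cohort generator

The generator exists because patient-level records for such studies are
confidential; it emulates exactly the structure the published marginals
pin down, and nothing more.

- **Presence.**  With `dependence=0`, independent Bernoulli(prevalence)
  per symptom.  With loading ρ ∈ (0, 1), a one-factor Gaussian threshold
  model: patient-level latent severity z ~ N(0,1); symptom s present iff
  ρz + √(1−ρ²)εₛ > Φ⁻¹(1−pₛ).  The index is standard normal for every ρ,
  so marginal prevalences are preserved exactly while within-group
  pairwise correlations become positive (tetrachoric correlation ρ²).
  This is the simplest mechanism that keeps the published marginals while
  letting the tests exercise CHAID on correlated predictors; the source
  tables say nothing about the joint distribution.
- **Onset ages.**  For present symptoms with recorded parameters,
  N(mean, sd) truncated to [0, 17] by rejection sampling (published SDs
  put little mass outside the window, so rejection is cheap and exact).
  A recorded mean with no SD degenerates to a constant.  Onset is drawn
  independently of the latent severity factor — whether they couple in
  reality is unknowable from group-wise marginals.
- **Determinism.**  All draws come from one `numpy` generator seeded from
  the spec; the spec parameters are recorded in the cohort's metadata and
  in the pipeline manifest.  No global random state is touched.

What passing tests on these cohorts show: the analysis machinery is
correct under the stated marginal structure (calibrated type-I error,
marginal preservation, recovery of planted strong predictors).  What they
cannot show: behaviour under real-world joint dependence beyond a single
factor, documentation missingness, follow-up-duration effects, or any
systematic coding bias of retrospective chart review.

## Trajectories

Per group, symptoms whose positive count reaches
`round(threshold × group size)` (round half away from zero) qualify; at
threshold 1/3 this gives cutoffs of 41/123 and 27/82, the only rounding
convention consistent with both published cutoffs (ceiling gives 28 for
the smaller group, floor matches only by accident of divisibility).
Entries are ordered by mean recorded onset age with catalog order breaking
ties; symptoms with no recorded onset age cannot be placed on a timeline
and are omitted.  The plot encodes patient count as circle *area*
(matplotlib's scatter `s` is area in pt²).

## Numerical and edge-case conventions

- χ² on tables with a zero margin is undefined; `pearson_chi2` raises and
  directs the caller to Fisher, and `choose_test` routes such tables to
  Fisher automatically.  Inside CHAID a class-empty (pure) node never
  splits, and zero-count categories are dropped before the test.
- Exact Mann-Whitney deviations are compared with a 1e−9 absolute guard
  against floating-point rank sums; Fisher point-probability ties use
  relative tolerance 1e−7.
- CSV round-trips use pandas with `float_precision="round_trip"` so a
  written cohort reads back bit-identically (property-tested).
- Simulation-based test sizes were chosen to give stable verdicts at
  3-standard-error tolerances: 50,000 patients per group for generator
  calibration, 1,000 replicates for type-I error, 500 for the null-CHAID
  single-leaf fraction, 100 seeded cohorts for root-split recovery.
  Where many marginals are checked simultaneously, the per-comparison
  3 SE rule is applied to a small pre-committed spot set (or as an
  aggregate exceedance count) rather than demanding a simultaneous
  3-sigma event across 150+ comparisons, which a faithful generator would
  fail more often than not.

## Known limitations

- The published decision tree below its root cannot be reproduced or even
  meaningfully targeted from marginals alone: conditional splits depend on
  the joint distribution of symptoms, which was not published.  Root-split
  behaviour is the only tree-level quantity with a marginal prediction,
  and even there sampling noise at n = 205 makes the argmax over 76
  correlated-by-nothing χ² statistics unstable (the strongest predictor's
  expected χ² ≈ 31.5 vs ≈ 27.7 for the runner-up, both with sampling SD
  ≈ 10), so recovery rates well below 1 are expected under independent
  generation.
- The published "41 significantly linked variables" does not match the
  number of starred rows in the published tables; the package reports its
  own count and documents the discrepancy rather than resolving it.
- Fisher's exact test is conservative by construction; its type-I error
  sits below the nominal level on sparse tables, which is why null
  calibration is asserted on the χ² and Mann-Whitney branches.
- The CHAID variant implemented is the classical nominal one: no ordinal
  merging, exhaustive search, pruning, surrogate splits, or continuous
  predictors (the predictors here are binary flags).
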