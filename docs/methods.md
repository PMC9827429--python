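# Methods

## Model and procedure

The pipeline treats early sepsis phenotyping as unsupervised structure
discovery in an `n × p` patient-by-biomarker matrix. The analysis scale
is standardized: missing cells are imputed with the per-feature median,
then every feature is mapped to `(x − mean)/sd` with the sample sd
(`n − 1` denominator; the denominator convention is ours — either is
defensible and the difference is O(1/n)). Scaling statistics can be
computed from the table at hand or frozen from a development cohort and
re-applied to a validation cohort; both paths are supported because
published descriptions of such pipelines often pool "the entire study
population" for imputation while leaving the validation-scaling choice
unstated. The default computes parameters per table and lets callers pass
frozen parameters explicitly.

Patients are clustered by agglomerative complete linkage on Euclidean
distances. Distances are divided by `√p`, i.e. squared distance is
*averaged* over features rather than summed. This keeps merge heights on
a per-feature scale so that heights remain comparable when a feature is
ablated (the LOFO analysis re-normalizes by `√(p−1)` automatically); the
alternative `distance/p` would not preserve per-feature scale and was
rejected. Linkage is computed by `scipy.cluster.hierarchy.linkage`
(nearest-neighbor-chain), whose tie-breaking is deterministic; the test
suite proves height- and cut-equivalence against a brute-force O(n³)
agglomerator on random instances with n ≤ 12. Ties between equal-distance
merge candidates are resolved by scipy's deterministic order, which can
differ from other implementations only in the labels of exactly tied
partitions.

### Significance of clusters

The null model is "no joint structure": each biomarker column is
independently permuted across patients, preserving all marginals. Each of
`n_reps = 10` permuted tables is re-clustered; each replicate's heights
are sorted ascending and averaged rank-wise, giving a reference vector
`D_ref` with the same length (`n − 1`) as the observed sorted heights
`D₀`. Rank-wise averaging (rather than pooling) is used so that `D_ref`
is directly comparable to `D₀` rank by rank, which is also what the QQ
diagnostic plots. Replicates use independent child seeds spawned from one
master seed, so the whole construction is reproducible bit-for-bit.

At significance level α the dendrogram is cut at the `100·(1 − α)`
percentile of `D_ref`, computed by linear interpolation between closest
order statistics with inclusive endpoints (α → 0 gives `max(D_ref)`).
With only `n − 1` support points the extreme percentiles are sensitive to
the convention, so the convention is pinned here and asserted in tests.
α is always a fraction (0.004 cuts at the 99.6th percentile); percent
signs are never inferred. Clusters are the connected components after
discarding merges above the cut; labels are canonical (size-descending,
ties by smallest member index), and singleton clusters are legal outputs
reported with their sizes so callers can apply their own minimum-size
policy.

**Known limitation — anti-conservatism of the global cut.** The cut
compares the observed root height with a percentile of `D_ref` that lies
*below* the mean permuted maximum (interpolation at the 99.6th percentile
of ~150 points lands between the top two rank-averaged entries). On a
truly structureless table the observed table and its column permutations
are exchangeable, so the observed root height exceeds that threshold far
more often than α suggests: empirically, structureless Gaussian tables
(n = 150, p = 44) yield a single cluster in only ~25% of runs at
α = 0.004, with the remainder reporting two or more clusters. No
percentile convention fixes this with 10 replicates: even α → 0 caps the
single-cluster rate near P(observed max ≤ mean of 10 permuted maxima)
≈ 50–55%. The procedure is therefore best read as a *ranking* device for
merge heights (how far above expectation the top merges sit, as in the QQ
plot) rather than a calibrated family-wise test; cluster counts near the
threshold deserve skepticism, and the α ladder plus cluster sizes should
always be inspected. The acceptance suite measures this rate honestly and
documents the shortfall rather than hiding it.

Conversely, the method has real power when separation is carried *jointly*
by many features: permutation destroys cross-feature alignment, so an
observed cross-cluster merge can exceed anything reconstructible from
permuted columns. Because complete linkage's null root is a maximum
statistic, detecting K balanced phenotypes requires the closest
cross-cluster distance (factor `√(K/(K−1))` above the null's typical
height for a simplex configuration) to clear the null maximum's tail,
which shrinks like `1/√p`. Hence K = 2–3 is detectable at modest p, while
K = 5 needs several hundred jointly informative features — the recovery
tests use n = 150 with p = 40 (K = 2), 60 (K = 3) and 800 (K = 5),
choices derived from this geometry before the tests were frozen.

### LOFO robustness

Each feature is removed in turn and the *entire* pipeline (distance,
linkage, reference distribution, cut at the configured α = 0.004) is
rerun on the reduced table, reusing the same master seed so that
differences between runs reflect the removed feature and not Monte-Carlo
noise. Concordance with the primary labels is |Spearman ρ| on
canonicalized label vectors — for two-cluster partitions this equals the
phi coefficient up to sign, and the absolute value removes the arbitrary
label orientation. If either partition collapses to a single cluster the
correlation is undefined; it is reported as 0 and flagged `degenerate`.
The LOFO table correlates the primary two-cluster partition (not any
finer partition) and sorts ascending, so the most load-bearing features
come first.

### Naive Bayes transfer to validation cohorts

The classifier is Gaussian naive Bayes: priors are development-cluster
prevalences; each class/feature pair carries a sample mean and variance,
floored at `1e-9 ×` the largest per-feature variance to guard
near-constant features. The Gaussian event model is our choice (all
features are continuous). At prediction time the log-posterior sums
likelihood terms over observed features only; missing biomarkers
contribute nothing, which is the property that makes the model robust
when validation panels are incomplete — no imputation happens at predict
time, and a patient with every feature missing receives the priors plus a
warning. Posterior ties break to the higher-prior class, then the lower
label id.

"Leave-one-feature-out cross-validation" is ambiguous between refitting
without each feature (feature ablation) and patient-level CV; both are
implemented (`lofo_cv_accuracy`, `lopo_cv_accuracy`), the feature-ablated
reading is the default, and each model records which flavor produced a
reported accuracy.

### Outcomes

Adjudication is an exhaustive, mutually exclusive trichotomy evaluated in
order: early death (death ≤ 14.0 days from onset, computed from
timestamps truncated to whole days), then CCI (ICU length of stay ≥ 14
days *and* persistent organ dysfunction on day-14 SOFA components:
cardiovascular ≥ 1 or any other system ≥ 2 — assessed at day 14 only, a
single-day reading of "persistent"), else non-CCI. A long ICU stay with
missing day-14 components is an error rather than a silent non-CCI.
Free days to day 28 are `max(0, window − min(outcome_days, window))` with
`window = min(28, death day)`, in whole days.

Two-group comparisons use Fisher's exact test for categoricals (two-sided
by the point-probability rule; multi-level tables by full enumeration
when the grand total is ≤ 30, otherwise margin-conditional Monte-Carlo
with a fixed seed and an add-one estimator) and Wilcoxon rank-sum for
continuous variables by default. A config flag enables a Shapiro screen
(both groups at 0.05) that switches to Welch's t — the default is
rank-based everywhere because "as appropriate" decisions are not
verifiable post hoc. Summaries render as `n (%)` with whole-number
percent and `median (25th, 75th)`. Per-variable p-values are reported
without multiplicity correction, matching how such clinical tables are
conventionally presented.

### SOM mosaics

Each biomarker's patient profile (length n) is one training item for a
small 2-D batch SOM. The batch update (recompute best-matching units,
then replace each prototype by the Gaussian-neighborhood-weighted mean of
all items) is fully deterministic given the seed. The neighborhood radius
decays linearly from `max(rows, cols)/2` to 0.5 over 50 epochs; the
default grid is the smallest near-square grid with at least one tile per
feature. These schedule choices are ours — the original mosaic software's
settings for this application are not published. A cluster's mosaic
colors each tile by the mean standardized value over (tile features ×
cluster patients); the size-weighted average of per-cluster mosaics
equals the whole-cohort mosaic exactly, and on standardized data the
whole-cohort mosaic is ~0 everywhere. Mosaics are exported as numeric
CSV matrices plus a color-scale JSON (red > 0, green ≈ 0, blue < 0);
rendering is left to plotting front-ends.

## Synthetic cohorts: what they emulate and what they do not

The generator plants K latent phenotypes, each a diagonal Gaussian over
standardized features, with per-cell MCAR missingness and
phenotype-linked outcomes (Bernoulli 14-day mortality with uniform death
day, geometric ICU length of stay truncated at death, Bernoulli day-14
SOFA persistence feeding the CCI gates). Phenotype labels are allocated
by exact prevalence counts (largest remainder, then a seeded shuffle), so
stated prevalences hold exactly. Three RNG streams (features,
missingness, outcomes) are spawned from the master seed so that
requesting outcomes never perturbs feature values.

Deliberately *not* emulated: raw laboratory units (features are generated
on the standardized scale, since clustering operates there anyway),
feature-feature correlation within a phenotype, informative missingness,
longitudinal trajectories, and late (> 14 d) mortality. Passing tests
therefore demonstrate correctness of the machinery and its behavior under
clean mixture separation — not that real sepsis cohorts contain such
structure, and not robustness to correlated panels, where the permutation
null is known to be most fragile.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| α (primary cut) | 0.004 | fraction | the 99.6th-percentile cut used for cluster selection |
| permutation reps | 10 | count | matches the described resampling depth; more reps sharpen `D_ref` at linear cost |
| distance normalization | `√p` | — | per-feature scale, comparable across LOFO subsets |
| variance floor | 1e-9 × max var | — | guards degenerate likelihoods |
| free-days horizon | 28 | days | the standard 28-day outcome window |
| early-death / CCI LOS cutoffs | 14 / 14 | days | the adjudication gates |
| SOM | 50 epochs, radius max(r,c)/2 → 0.5 | — | small grids converge well before 50 batch epochs |
| r×c exact-test cutoff | total ≤ 30 | patients | enumeration cost grows combinatorially beyond |

## Numerical and degenerate-input choices

Percentiles: linear interpolation, inclusive endpoints. Heights are kept
at full float precision; no rounding before threshold comparisons.
Zero-variance features abort standardization by name (callers decide to
drop). All-missing features abort imputation unless frozen medians are
supplied. Single-cluster partitions in concordance are 0-by-definition
and flagged. Cluster labels are always canonicalized before comparison so
that label ids never carry meaning. Posterior vectors are normalized in
log space (max-subtraction) and sum to 1 within 1e-12.

## Problem sizes used by the test and acceptance runs

Cohorts of 60–200 patients and 8–800 features; 100-seed null calibration
at n = 150, p = 44; classifier checks at n = 157 with clusters of 18 and
139 (the development-cohort split). These sizes were chosen to make every
property measurable in seconds on one CPU while staying in the regime the
method targets (a few hundred patients, tens of biomarkers).
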