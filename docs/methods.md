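# Methods

This note documents the statistical procedures in `lfqpipe`, the defaults
and why they were chosen, the behavior of the synthetic-data generator, and
the numerical conventions that make runs reproducible.

## Input model and preprocessing

The unit of analysis is a protein-group row with one linear-scale intensity
per measurement column. Three quality flags (contaminant, reverse-database
decoy, only-identified-by-site) and the unique-peptide count drive row
filtering; all four are standard MaxQuant annotations, and the parser also
accepts the older `Contaminant` column name. Generic matrices (first column
protein IDs, remaining columns numeric) carry no flags or peptide counts, so
for them only the missingness filter applies and a notice is logged.

Defaults:

| parameter       | default | meaning |
|-----------------|---------|---------|
| `uniq_pep_min`  | 3       | keep proteins with ≥ 3 unique peptides (i.e. remove "two or fewer") |
| `max_group_na`  | 0.34    | largest tolerated missing fraction within any single group |
| `intensity_type`| LFQ     | which column family to read (`LFQ intensity `, `iBAQ `, `Intensity `) |

Zeros in the source table denote non-quantification, not zero abundance;
they become missing values *before* the log2 transform, so no −∞ can enter
the matrix. Technical replicates are averaged on the log2 scale over
observed values only (a sample is missing only when all of its replicates
are), after row filtering and before the group-missingness filter — this
ordering means a protein seen in one of three technical runs still
contributes a value. The group-missingness comparison is performed on exact
rationals (`Fraction(missing, n) > Fraction("0.34")`), so a protein missing
1 of 3 samples (1/3 ≈ 0.3333) is retained at the 0.34 default rather than
depending on float rounding at the boundary.

The design-file schema is the package's own definition (the field has no
standard): a TSV with header `sample group [tech_rep]`, one row per
intensity column. Column resolution tries the exact column name, then the
short label, then `<sample>_<tech_rep>` with and without the intensity
prefix. Duplicate (sample, tech_rep) pairs and unresolvable rows are errors;
a single-group design is accepted with a warning but refused later by the
differential test.

## MinProb imputation

Missingness in LFQ data is left-censored: the probability of a missing
value rises as abundance falls toward the detection limit. MinProb imputes
each missing cell in sample *j* with an independent draw from
N(μⱼ, σ), where μⱼ is the q-quantile of the sample's observed values and σ
is `tune_sigma` times the median over proteins of the per-protein standard
deviation of observed values (proteins with fewer than two observations are
excluded from that median). Defaults q = 0.01 and tune_sigma = 1.0 follow
the convention of the left-censored-imputation literature; they are
package choices, exposed as parameters and recorded in a sidecar JSON
(seed, q, tune_sigma, per-sample μⱼ, σ) next to every imputed matrix.

Numerical conventions: quantiles use the linear-interpolation (type-7)
definition throughout, one seeded generator serves the whole call and draws
are consumed column-major, so results are bit-reproducible for a fixed seed
and independent of any parallelism. With tune_sigma = 0 the imputation is
deterministic — every imputed cell equals its column quantile exactly —
which the test suite uses as a degenerate-spread oracle. A sample with
fewer than two observed values is an error (its quantile would be
meaningless).

## Quantile normalization

For complete data, the value at rank r of every sample is replaced by the
mean across samples of the rank-r order statistics; tied values receive the
mean of their assigned targets, so the map is well defined and within-sample
rank order is preserved. With missing values, each sample's observed values
are mapped through linear interpolation of the *mean quantile function*
(each sample's empirical quantile function evaluated on a common grid of
n_proteins points, averaged across samples) at the observed entries'
quantile positions; missing entries stay missing. This "NA dialect" keeps
every protein rather than deleting incomplete rows, at the cost of mild
interpolation error when samples have very unequal missingness. Both
impute→normalize and normalize→impute orders are supported, as is skipping
normalization entirely (appropriate when intensities are already
MaxLFQ-normalized upstream).

## Moderated two-group test

Per protein, group means give the log2 fold change β̂ = mean(group1) −
mean(group2), with group1 the first group listed in the design file (the
contrast is recorded in the output header). The pooled residual variance
s²_g has d = n_A + n_B − 2 degrees of freedom and standard-error factor
v = 1/n_A + 1/n_B. Empirical-Bayes moment matching on
e_g = log s²_g − ψ(d/2) + log(d/2) estimates the prior: with ē the mean and
V the unbiased variance of the finite e_g, V′ = V − ψ′(d/2); if V′ > 0 then
d₀ = 2·ψ′⁻¹(V′) (damped Newton iteration to |Δ| < 1e−8) and
s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)); otherwise the prior is degenerate
(d₀ = ∞, s₀² = exp(ē)). Posterior variances are the precision-weighted
blend s̃² = (d₀s₀² + d·s²)/(d₀ + d), always between s² and s₀². Proteins
with s² = 0 are excluded from the moment estimation (log 0) but still
shrunk. The moderated statistic t = β̂/√(s̃²·v) is referred to Student-t on
d + d₀ degrees of freedom, or the normal when d₀ = ∞; a zero posterior
variance yields t = ±∞ with p = 0 and a logged warning. The implementation
is checked in the test suite against Bioconductor limma's `squeezeVar` on
simulated variances (agreement to ~1e−12) — limma is used only as an
independent oracle, never as the computation path.

Multiple testing uses Benjamini–Hochberg step-up (the adjustment procedure
is a package choice; the test suite verifies it against the brute-force
definition). Significance requires |log2FC| > 1 **and** adjusted p < 0.05,
both strict inequalities; results are sorted by adjusted p, ties broken by
|log2FC| descending then protein id. Exactly two groups are supported; with
more, the caller must name a contrast pair.

## Classifier panels

Feature selection takes up to `top_n` = 20 significant proteins by smallest
adjusted p, drops zero-variance features with a warning, then greedily
eliminates correlated ones: while any pair has |Pearson r| > 0.90, the
member of the worst pair with the larger mean absolute correlation to the
remaining features is removed (ties: the later one in the ranking). On
strongly separated classes this rule can prune aggressively — features that
all track the group difference are mutually correlated — which is the
intended behavior of correlation-based panel thinning.

The stratified split assigns round-half-up(0.7·n_c) samples of each class
to training, floored so both partitions keep at least one sample per class.
Training uses stratified k-fold cross-validation (k = 10, repeated 3 times;
the same folds for every algorithm) over small fixed grids (≤ 3 values of
one tunable per algorithm, recorded in the run report); the best setting
maximizes mean resampling accuracy, ties resolving to the smallest grid
index, and the final model is refit on the whole training partition.
Accuracy and Cohen's κ are recorded per resample. k larger than the
smallest training class count is an error suggesting a smaller k.

The algorithm registry maps the field's conventional names onto native
estimators: `rf` → random forest, `svmRadial`/`svmLinear` → SVM with
RBF/linear kernel, `glm` → logistic regression, `naive_bayes` → Gaussian
naive Bayes, `knn` → k-nearest neighbours, and `xgbLinear` → gradient
boosting with linear base learners (single-thread coordinate-descent
updater for determinism) — the last is an approximation of the boosted
linear model that name usually denotes. ROC curves enumerate (FPR, TPR) at
every distinct threshold with (0,0)/(1,1) endpoints; AUC is the
Mann–Whitney pair-counting statistic (ties ½), identical to the trapezoidal
area under that curve. The default positive class is the second class in
design order. Variable-importance figures use seeded permutation importance
on the training partition — one portable definition across all model
families.

## Synthetic data generator

`simulate_lfq_experiment` emulates the data model of a MaxQuant protein
table. Per protein, a base log2 abundance ~ N(base_mean = 25, base_sd =
2.5); `n_de` randomly chosen proteins get a ±`effect_log2` shift (random
sign) in the second group. Biological replicates add N(0, sigma_within)
noise; technical replicates scatter around their biological value with
variance sigma_within²/2, so technical pairs are visibly tighter than
biological ones. Dropout is a decreasing logistic in the cell's log2
intensity, centred at the `mnar_center` = 0.1 quantile of all intensities
with slope `mnar_steepness` = 0.8 per log2 unit (≈ 10–17% missing cells at
the defaults — a realistic LFQ missingness level); dropped cells are
written as `0`, exactly as MaxQuant renders non-quantified proteins.
Decoy rows (5% contaminants, 5% reverse, 2% only-by-site) carry flags and
low unique-peptide counts purely to exercise the filters. Everything is
reproducible from a single seed, and `dropout=False` disables censoring
while leaving the latent intensities identical under the same seed.

What the generator does *not* emulate: peptide-level identification,
shared/razor peptides, retention-time effects, batch structure, or
correlated proteins (each protein is independent). Passing tests therefore
demonstrate the correctness of the algorithms under the stated stochastic
model, not performance on any particular real dataset.

## Validation design and problem sizes

The acceptance checks separate concerns deliberately:

* The **power/FDR oracle** (20 simulated experiments, 500 proteins, 50
  effects of |log2FC| = 2, σ = 0.5, 3 vs 3) runs with dropout disabled: its
  purpose is to verify the testing engine against the stated Gaussian
  conditions, where the moderated 3-vs-3 design has high power. Heavy
  left-censored dropout at n = 3 is a property of the *data*, not the test
  — floor-imputed values legitimately inflate within-group variances and
  reduce power — so censoring is exercised separately by the imputation
  contract, the MNAR property tests and the end-to-end workflow run rather
  than being folded into a power claim.
* Null calibration uses 2,000 no-effect proteins (3 vs 3); prior recovery
  uses 5,000 scaled-F variances; the imputation contract checks 10,000
  imputed values against their declared Gaussian; modeling oracles use 30
  samples per class (separable blobs and permuted labels). These sizes keep
  the whole suite and the acceptance script in the minutes range on one CPU
  while leaving the statistical assertions comfortably powered.

## Known limitations

* Two-group contrasts only; no blocking, pairing or multi-factor designs.
* The mean-quantile-function NA dialect of quantile normalization is an
  interpolation, not an exact match to complete-case normalization.
* MinProb's q and tune_sigma defaults are conventions, not estimated from
  the data; strongly non-left-censored missingness would be imputed
  incorrectly.
* `xgbLinear` is an approximation (see above), and SVM probabilities come
  from Platt scaling, which can be coarse on very small training sets.
* The 70/30 split rounding rule (round half up, one-sample floor per
  partition) is one documented convention among several reasonable ones.
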