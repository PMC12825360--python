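# Methods

## The problem

Differential-abundance (DA) methods (Milo, DA-seq, Scissor, ...) select
cells whose local neighborhoods shift in frequency between conditions. The
genes that characterize those cells are usually a mixture of signals: some
track cell state wherever it occurs, some track the phenotype in every cell
state, and some do both in a state-dependent way. iDAS separates these by
fitting, per gene, a family of nested factorial ANOVA models on pseudobulk
expression and classifying each gene by which model comparisons reject.

## Pseudobulk

Cells are grouped by (sample, cell state) — optionally also timepoint —
and each group becomes one observation: `log2(mean(x) + pseudocount)` with
the mean taken on the input value scale and pseudocount 1 by default. The
mean-then-log order avoids minus infinity on all-zero genes and keeps the
aggregate interpretable as a group-level expression level. Aggregation
trades cell-level resolution for approximate normality, which is what
licenses the Gaussian linear-model machinery downstream; count-level
pseudobulk testing (negative binomial on sums) is deliberately out of
scope. Whether the input values are raw counts or normalized expression is
a declared configuration of the run, not a hidden default: the aggregate
is the mean of whatever scale is supplied. `min_cells` (default 1) drops
under-populated groups, since tiny groups inflate pseudobulk variance.
Phenotype is a sample-level attribute; cells of one sample disagreeing on
phenotype is an error, never a vote.

## The model family

Two-way (fixed effects), for gene g with factors f1 (levels i = 1..I) and
f2 (levels j = 1..J), replicates m:

    full        y_ijm = mu + a_i + b_j + (ab)_ij + e_ijm
    additive    y_ijm = mu + a_i + b_j + e_ijm
    f1-only     y_ijm = mu + a_i + e_ijm
    f2-only     y_ijm = mu + b_j + e_ijm
    null        y_ijm = mu + e_ijm

Three-way adds factor f3 (levels k = 1..K) and a subject random intercept
u_n ~ N(0, sigma_u^2): the ten candidate models are the full model with
all two- and three-way interactions, the all-two-way model, the three
leave-one-two-way-out models, the additive model, three single-factor
models, and the intercept-plus-subject null.

Fixed-effect fits are ordinary least squares with treatment coding (the
comparisons are coding-invariant); nested models are compared with the
exact F-test on residual sums of squares. Mixed fits maximize the ML (not
REML) likelihood, because every classification test changes the
fixed-effect structure and REML likelihoods are not comparable across
fixed specs; comparisons use the chi-square likelihood-ratio test with df
equal to the difference in estimable fixed-effect parameters. The
random-intercept variance is present in both models of every comparison,
so no boundary correction applies.

### Random-intercept fitting

The ML problem is solved by profiling: with lambda = sigma_u^2/sigma_e^2
fixed, V = I + lambda ZZ' is block diagonal, the GLS coefficients and the
profiled sigma_e^2 are closed-form, and the remaining one-dimensional
likelihood in log(lambda) is maximized by bounded Brent search seeded from
a coarse grid. The boundary lambda = 0 is evaluated exactly and wins ties,
so genes with no subject-level variance — which the staged classifier
produces constantly — cannot fail to converge; there is no per-gene
exclusion path in practice. The fit agrees with `statsmodels` `MixedLM`
(ML) to ~1e-9 away from the boundary (cross-checked in the test suite) and
with the closed-form Gaussian likelihood at the boundary exactly.

## The staged classification

Two-way, five categories:

1. **No-effect test** (null vs full): genes not selected are `non-sig`.
2. **Interaction test** (additive vs full) on the significant set: selected
   genes are `F1xF2`.
3. **Main-effect tests** on the rest: f1 is tested by f2-only vs additive,
   f2 by f1-only vs additive. Genes significant in exactly one test get
   that factor's label.
4. Remaining significant genes are `F1+F2` (additive). This includes genes
   significant in both main-effect tests and genes significant in neither:
   "everything significant not yet assigned", which keeps the five
   categories an exact partition.

Three-way, ten categories, same logic: no-effect (null vs full), then
interaction (additive vs full) splits significant genes into interacting
and non-interacting. Non-interacting genes face the three single-factor
tests (single-factor model vs additive); a gene is a single-factor gene
iff its own factor's test does NOT reject while the other two DO — the
single-factor model is the one model not contradicted. Genes matching no
unique pattern go to `additive` (flagged `ambiguous-main` when more than
one single-factor model survives, since no unique factor is identified).
Interacting genes face the three-way test (all-two-way vs full): rejection
means `F1xF2xF3`; otherwise the three pairwise tests (each leave-one-out
model vs all-two-way) assign `F1xF2`/`F2xF3`/`F1xF3` when exactly one
rejects, else `two-way-combine`.

Thresholds: p-values are Benjamini-Hochberg adjusted **within each stage
across exactly the genes entering that stage** — pooling across stages
would mix null distributions. Stage 1 supports either a fixed level
(default: adjusted p <= 0.05) or a quantile rule (the top q% smallest
p-values, boundary ties broken by gene id); later stages always use a
fixed level (default 0.05, or the stage-1 level in alpha mode). Both the
level and raw-vs-adjusted switch are exposed.

Degenerate genes never break the partition: zero-variance genes carry p=1
everywhere and land in `non-sig` with a reason code; genes whose stage df
collapse (missing values, incomplete designs) are `non-sig` with an
`untestable` reason.

### Operating characteristics worth knowing

* BH adjustment is anti-conservative for *accept-the-null* decisions: in a
  stage where most genes are truly non-null, the step-up inflates the
  rejection rate of the few true-null tests. The three-way single-factor
  categories require two rejections *and one acceptance*, so their recall
  tops out around 0.85-0.95 even at effect/noise = 4. This is a property of
  the published staging, reproduced faithfully.
* Testing a *between-subject* factor by chi-square LRT with few subjects is
  anti-conservative (the effective sample size is the number of subjects).
  The default generator therefore crosses subjects with all factors; the
  nested variant (`nest_subjects_in_f2=True`, each subject carrying one
  phenotype, as in a treatment-response study) exhibits the inflation and
  is available for studying exactly that caveat.

## Post-hoc differential expression

Per-category contrasts are two-group OLS estimates with empirical-Bayes
variance moderation. Per-gene residual variances s2_g on d_g df are modeled
as scaled inverse-chi-square around a prior (d0, s0^2) estimated by method
of moments on log s2_g (matching the standard moderated-t estimator; the
test suite cross-checks against `limma::fitFDist`). The posterior variance
(d0 s0^2 + d s2)/(d0 + d) yields a t-statistic on d0 + d df — ordinary t at
d0 = 0, normal with common variance at d0 = infinity. When every s2 is
literally identical there is no sampling noise to correct and the prior is
the common value itself. With fewer than 10 usable genes no prior is
learned and the ordinary t is used.

* `cellstate_markers` — one-vs-rest per f1 level on the F1 genes, BH within
  each state; positive markers are log2FC > 0.
* `phenotype_signature` — f2 level-vs-level on the F2 genes, labeled
  up/down at raw p < 0.001 and |log2FC| > log2(1.5) (both configurable).
  Implemented for exactly two phenotype levels (the signed report).
* `interaction_markers` — top-k (default 10) one-vs-rest state markers
  within the interaction genes (ties: p, then |log2FC| descending, then
  gene id), then an f2 contrast within each state's observations; rows
  passing the thresholds are state-specific phenotype markers. States
  observed under a single phenotype are skipped with a warning.

## Spatial front end

For spatially resolved expression, each sample contributes one feature per
gene: the Pearson correlation between every cell's expression and that of
its single nearest spatial neighbor (Euclidean, ties to the smallest cell
index, directed pairs (i, nn(i)) for all i). Zero-variance genes are
undefined (`NA`), never zero. The genes-by-samples feature matrix feeds
`classify_two_way` unchanged, with a per-sample two-factor design; genes
undefined in >= 20% of samples are excluded with a logged reason, and
remaining undefined entries are dropped per gene inside the fits. Note the
sampling variance of a correlation depends on its magnitude, so the
homoskedastic ANOVA is an approximation here; with realistic panel sizes
the stage-wise BH absorbs the mild inflation (measured ~1% false
interaction calls at variance ratio 8 in the test suite), but single-digit
gene panels can produce spurious interaction calls.

## Synthetic data

The generators define the house benchmark protocol:

* **Two-way**: balanced I x J x m pseudobulk (defaults I=3, J=2, m=4).
  Per gene, the offsets named by its category are drawn N(0, effect_sd^2),
  re-centered to sum to zero within every margin (interaction tables are
  double-centered) and rescaled to the requested sd, so "effect size" is
  unambiguous and the category is identifiable from which offset sets are
  nonzero. Response = baseline + offsets + N(0, noise_sd^2). Defaults
  effect_sd=2, noise_sd=0.5 (effect/noise = 4, the strong-signal regime).
* **Three-way**: adds u_n ~ N(0, subject_sd^2), default 8 subjects crossed
  with all factors (see above), subject_sd=0.5, m=1 (replication across
  subjects).
* **Single-cell**: mean-preserving lognormal noise around planted
  (sample, state) group means, x = mean * exp(sigma Z - sigma^2/2), so
  `aggregate` converges to log2(mean + pseudocount). No library-size,
  dropout or batch structure — passing tests say the aggregation and
  classification arithmetic is right, not that the package is robust to
  scRNA-seq technical artifacts.
* **Spatial**: cells in tight pairs on a coarse jittered grid (pair
  spacing 1, grid spacing 3), pair expression bivariate normal with the
  requested correlation, so each cell's nearest neighbor is its partner
  and measured nnCorrelation converges to rho.

`recovery_metrics` scores a classification against the planted truth:
confusion matrix, per-category recall/precision, and the empirical FDR of
the significant set.

Benchmark sizes used by the acceptance script and test suite: two-way at
the headline setting (I=5, J=2, m=6, 200 genes/category); three-way at
I=3, J=2, K=2, 8 subjects, 60 genes/category — enough genes for recall
estimates with ~0.03-0.04 Monte-Carlo error while a full run stays around
a minute on one CPU; global-null calibration at 2000 genes x 20 seeds.

## Numerical choices

* Rank-deficient designs (missing factor-level combinations): least-squares
  via `lstsq`/pseudo-inverse, `n_fixed_params` = actual design rank, so df
  accounting stays exact; tests whose df difference collapses mark the gene
  untestable rather than erroring the run.
* F-test conventions: equal RSS -> p = 1; saturated full model (RSS below
  1e-12 of the reduced RSS) -> p = 0; deviances clipped at 0.
* The LRT chi-square reference is asymptotic; with few subjects its
  finite-sample behaviour is the documented caveat above.
* Quantile selection takes floor(q*m) genes; boundary ties break by gene id
  so classification tables are byte-identical across runs.

## Limitations

* At most three factors and a single random intercept; no random slopes,
  no continuous covariates, no nonparametric alternatives.
* The Gaussian pseudobulk contract: no count-model testing path.
* The spatial feature is the k=1 directed nnCorrelation; other estimators
  (mutual pairs, k-neighbor means) exist and a k-neighbor mean variant is
  exposed but not default.
* Real-data headline counts from DA-selected melanoma cells depend on the
  upstream DA tool and dataset and are not reproduced here; the benchmarks
  are synthetic by design.
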