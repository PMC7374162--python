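# Methods

`cfmethyl` implements a cell-free DNA (cfDNA) methylation screening analysis:
per-CpG bisulfite counts over a targeted region panel are reduced to a
region-level average methylation fraction (AMF) matrix, cancer-informative
regions are selected from tumor/normal tissue references, a split-ensemble
penalized logistic-regression classifier is trained and frozen on a matched
plasma training set, and the frozen model is evaluated on a held-out test set
with exact-binomial accuracy reporting. A synthetic cohort generator supplies
data with the statistical structure these stages assume, so the whole path is
testable without patient data.

## Average methylation fraction and QC (`amf`)

For region *r* in one sample, with per-CpG methylated/unmethylated counts
(N_C,i, N_T,i) over the region's covered sites,

    AMF_r = Σ_i N_C,i / Σ_i (N_C,i + N_T,i).

This is the depth-weighted mean of per-site methylation fractions; site order
is irrelevant. A region with total depth below `min_region_depth` (default 1)
is MISSING — an explicit NaN sentinel, never 0, because the classifier later
drops regions with any missing training value and silent 0-imputation would
change the model. Samples with fewer than 200,000 unique mapped molecules are
excluded together with their matched partner (to keep the case/control set
balanced); the cascade never chains past the pair, and the filter is
idempotent.

## Marker selection (`dmr`)

Per tissue type, tumor samples of that type are compared to all normal tissue
samples region by region with a two-sided t-test on non-missing AMF values.
Welch (unequal-variance) is the default: tumor AMF variance plausibly exceeds
normal, and the pooled test is retained behind `DMRConfig(test="pooled_t")`
for sensitivity analysis. p-values are Benjamini–Hochberg adjusted, by
default within each tissue type's family (the conservative literal reading of
a per-comparison correction; a `global` scope pools all families). A region
is selected when q ≤ α (default 0.05) in at least one tissue type. Regions
with an undefined statistic (under two observations in a group, or zero
variance in both groups) are flagged degenerate and never selected rather
than being assigned a degenerate p-value.

Each selected region gets one direction, hyper or hypo, from the sign of the
tumor-minus-normal mean difference in its most significant tissue type (the
aggregation across conflicting tissue types is otherwise underdetermined).
The optional concordance filter keeps regions whose tissue direction matches
the sign of (mean cancer plasma − mean healthy plasma) AMF over *training*
plasma only; passing any non-training sample is a hard error, because a
direction estimated on test samples would leak through the marker set.

## Ensemble classifier (`ensemble`)

The classifier is an average of `n_iter` (default 1000; the canned
experiments use 200) L1-penalized logistic models:

1. Regions with any MISSING value across the training samples are dropped, so
   every component models a complete matrix.
2. The training set is split 50/50 into a model-building and a
   model-validation half, `n_iter` times. Splits are stratified by class so
   both halves always contain both classes (an unstratified split can make a
   component unfittable; unstratified mode is available behind a flag).
   Half sizes differ by at most one.
3. Each building half fits one component with scikit-learn's liblinear L1
   path. The penalty strength is chosen by 5-fold stratified cross-validation
   restricted to the building half, over 10 log-spaced strengths
   λ ∈ [10⁻¹, 10⁴]; for ~100 training samples of bounded [0,1] features,
   strengths below 0.1 are effectively unpenalized, so the grid bottoms out
   there. Grid ties resolve toward the strongest penalty (the most
   parsimonious model). The grid search runs at liblinear's standard
   100-iteration budget; the kept component is then refit at the chosen
   strength and must fully converge (the iteration budget escalates ×10 once,
   then the fit errors). `intercept_scaling=100` keeps the L1 penalty
   effectively off the intercept, the usual LASSO convention.
4. Each component scores its validation half with
   P = 1 / (1 + exp(−(Σ M_i X_i + B))); a training sample's final score is
   the mean of its validation-half scores. The orientation is
   cancer-positive — P rises with the linear predictor. (An equivalent
   formulation writes the logistic of the negated predictor; the two differ
   only by a global sign flip of (M, B).)
5. The decision cutoff is the candidate threshold whose achieved training
   specificity — the fraction of healthy training scores strictly below the
   cutoff — is closest to the 95% target. Candidates are midpoints between
   adjacent distinct sorted healthy scores plus one below the minimum and
   one above the maximum, which makes the exhaustive-search oracle exact
   and the cutoff scale-free. Ties break toward higher specificity
   (screening favors not flagging healthy people when the target cannot be
   hit exactly).
6. The model — region order, all component coefficients and intercepts, the
   split plan, and the cutoff — is then frozen; its SHA-256 checksum is
   recorded. Held-out samples are scored by **all** components and the mean
   is compared to the frozen cutoff; a score exactly at the cutoff is a
   cancer call (documented boundary rule). A held-out sample missing any
   modeled region is a hard error in `apply_ensemble`; the pipeline
   pre-screens such samples out (with their matched partner, mirroring the
   molecule-count QC) and logs the exclusion, rather than imputing.

A training sample that never lands in any validation half (probability
≤ 2^−n_iter per sample) raises rather than producing a silent NaN. The
alternative `linear_discriminant` base learner runs through the identical
split/average/cutoff machinery with an LDA in place of the penalized
logistic fit.

All randomness — simulation, split plan, internal CV, label permutation —
derives from one master seed through named substreams, so every stage is
bit-reproducible and insensitive to the others' draw counts.

## Evaluation (`evaluation`)

Sensitivity = TP/(TP+FN) over truth-cancer samples; specificity = TN/(TN+FP)
over truth-healthy samples. Every cell carries an exact Clopper–Pearson 95%
interval from beta-distribution quantiles, which collapses to the closed
forms upper(0,n) = 1 − (α/2)^(1/n) and lower(n,n) = (α/2)^(1/n) at the
boundaries. Empty subgroups are reported undefined (n = 0), never as 0. ROC
curves sweep all thresholds; AUC is the probability a random cancer sample
outscores a random healthy one with ties counted ½ (trapezoidal area). The
covariate screen runs Kruskal–Wallis on final scores across the levels of
each covariate within each sample category, with pairwise Mann–Whitney
post-hoc tests (Bonferroni-corrected by default; exact enumeration for
levels of ≤ 20 samples, tie-corrected normal approximation otherwise) when
the omnibus p < 0.05. Continuous covariates are binned first — age by
decade, dates by year, molecule counts and DNA mass by quartile — to mirror
categorical reporting.

## Limit of detection (`lod`)

From a dilution series of tumor DNA spiked into pooled healthy plasma, the
first `n_baseline_training` (default 4) 0%-spike replicates in sample-sheet
order set, per region, a cutoff at mean + 3 SD of their AMF (sample SD,
n−1 denominator — the conservative small-n choice; population SD behind a
flag; the selection of training replicates is an override flag because
nothing pins which replicates should train). Every remaining sample is
summarized by the number of regions whose AMF *strictly* exceeds its
cutoff — strict, so zero-variance baselines never self-exceed. A spike
level is called separable when all its replicates exceed the maximum count
among held-out baseline replicates. Thresholds are translation-equivariant
and expected counts are non-decreasing in the spike ratio.

## Synthetic cohort generator (`simulate`)

The generator emulates a targeted panel over a screening cohort with a
two-component mixture: a plasma sample with circulating-tumor-DNA fraction
*f* has per-region methylation probability p_r = (1−f)·b_r + f·t_r, where
b_r is the healthy-plasma background and t_r the tumor profile.

Defaults (the study conditions the tests and acceptance script run at):

| parameter | default | rationale |
|---|---|---|
| regions / CpGs per region | 595 / 10–30 | panel of ~595 regions, ~12k CpGs |
| true DMRs | 40 hyper + 20 hypo | tunable separation with both directions |
| baseline AMF at hyper-DMRs | Beta(1.5, 48.5), mean 0.03 | cancer panels target loci unmethylated in healthy plasma (leukocyte background) |
| baseline at hypo-DMRs / background | mean 0.85 / Beta(2, 8) | hypo markers need methylated background; other loci moderate |
| tumor levels | 0.75 hyper, 0.05 hypo | strong but not saturating shifts |
| f, post-diagnosis | U(0.05, 0.15) | detectable ctDNA burden after diagnosis |
| f, pre-diagnosis | U(0.01, 0.05) | stochastically smaller than post, still detectable; the true pre-diagnosis distribution is unknown, so it is a parameter, not an assertion |
| depth per region | NB(mean 200, size 5) | amplicon depth is overdispersed |
| dropout | 2.5e-5 per sample-region | reproduces the observed rarity of incomplete regions in a depth-targeted assay (a handful out of ~500 regions incomplete across hundreds of samples) |
| cohort | 100 pre + 100 post + 200 matched healthy | 200 train / 200 test after pairing |
| tissue references | 160 tumor / 40 normal, purity U(0.7, 1.0) | reference-set sizes; tumor tissue is nearly pure |
| per-sample biological noise | Beta concentration 200 around region profiles | person-to-person variation dominates counting noise at depth 200 |
| spike-in depth | NB(mean 50,000, size 50) | a six-point dilution validation run is sequenced far deeper than a screening sample; at this depth a 0.1% spike shifts hyper-DMR AMF by several counting-noise SDs |

Metadata mirrors a matched retrospective design: each cancer sample has
exactly one healthy partner matched on sex, 10-year age group, collection
date (±30 days) and unique-molecule count; the 50/50 train/test split is
stratified by group and assigns partners jointly (splitting a pair would
leak the matching). Unique molecule totals are log-normal with ~0.3% of
samples under the 200,000 QC floor. Spike-in replicates share one
pooled-plasma baseline profile and one cell-line profile drawn once —
technical replicates differ only by counting noise — and the cell line also
drifts moderately from plasma at non-DMR regions (Beta concentration 30),
which is what gives the exceedance count its graded dose response at high
spike ratios.

Simulation truth (DMR flags, per-region profiles, per-sample true f) rides
on the returned objects but is written to sidecar files; the analysis
stages never read it.

What the generator does **not** emulate: read-level artifacts (bisulfite
conversion failure, alignment error, UMI collisions), batch effects and
storage-time degradation, correlated CpGs within a region beyond the shared
region probability, tissue-of-origin structure in the tumor profiles, and
covariate-linked signal (age, sex and collection date are independent of
class by construction, apart from the matching). Passing tests therefore
demonstrate that the pipeline's machinery is correct and leak-free under its
own assumptions — not that the assay achieves these accuracies on real
plasma.

## Numerical and design notes

* Coordinates are 0-based half-open (BED convention) throughout; read-to-
  region assignment is upstream of this package (inputs are per-region
  counts).
* BH adjustment is the exact step-up (monotone cumulative minimum on the
  sorted p-values), input order preserved, clipped at 1.
* Degenerate inputs error loudly and early: empty AMF matrices, single-class
  building sets, all-regions-missing matrices, empty healthy score lists,
  fewer baseline replicates than the cutoff-training count.
* Problem sizes in the canned experiments (595 regions, 400 plasma samples,
  200 ensemble components, 36 spike-in samples) are the package's default
  study conditions; they keep a full end-to-end run to a few minutes on one
  core while leaving every statistical margin wide.
* The permutation null permutes the cancer/healthy label vector globally
  (training labels for fitting and cutoff choice, test labels for scoring),
  the standard permutation-test construction: under the null the score
  carries no information about the permuted labels, so held-out AUC sits
  near 0.5. Permuting only the training labels would instead measure how
  strongly the learned direction aligns with the dominant variance axis,
  which is not a null.

## Known limitations

* The reference study's raw patient data is not publicly deposited, so its
  fitted coefficients, its particular cutoff instance, and its exact marker
  lists cannot be recomputed; the package reproduces the *procedures* and
  verifies them on synthetic truth.
* Exact-binomial interval arithmetic is reproduced against the published
  accuracy table's printed counts; one printed endpoint differs from exact
  arithmetic by one unit in the last digit (apparent double rounding in the
  source table) and is documented in the acceptance test.
* LDA components ignore the penalty grid (no regularization path); they
  exist to show the ensemble machinery is learner-agnostic.
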