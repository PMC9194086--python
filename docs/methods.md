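# Methods

## Problem setting

`leukopred` models a small-n clinical transcriptome classification
problem: predict preoperative pulmonary venous obstruction (the positive
class, `obstructive`) from peripheral-leukocyte transcript abundances in
a 48-sample cohort (26 obstructive / 22 non-obstructive). Two features
of the setting drive every design choice. First, surgical age is heavily
confounded with class (obstructive infants present at a median of about a
week of age, non-obstructive at about four months), so any per-gene test
must adjust for age. Second, with ~35 training samples and thousands of
transcripts, single-shot feature selection is unstable, so features are
chosen by frequency voting across repeated selection runs.

## Cohort splitting

The split rule is clinical, not random: obstructive patients whose
obstruction could **not** be identified by echocardiography/CTA are the
training positives (these are the cases a transcript model must serve);
imaging-identifiable obstructive patients form the validation positives.
Non-obstructive patients are sorted by surgical age descending — ties
broken by ascending sample id for determinism — and the oldest go to
training, the youngest `n_non_validation` (default 6) to validation. At
the default composition this yields 35 training and 13 validation
samples. The rule is deterministic given the metadata.

## Preprocessing

Counts are transformed with log2(x+1) (the +1 pseudocount keeps zeros
finite and makes the DEG fold-change scale coherent), then standardized
per gene to zero mean and unit standard deviation (n−1 denominator).
Standardization is fit on the training samples only and applied to
validation by default; `scale_on="all"` reproduces whole-cohort scaling
for comparison. Zero-variance genes are retained as all-zero rows with a
degeneracy flag so gene indices stay aligned across stages.

## Differential expression

Each gene is tested with an ordinary least-squares fit of

    log2(x+1) ~ intercept + group + z(log(age_days + 1))

where `group` is 1 for obstructive. The group coefficient is the
age-adjusted log2 fold change, tested two-sided with a Wald t statistic
(residual df = n − 3). This is a deliberate simplification of a
negative-binomial framework with dispersion shrinkage: on log-transformed
counts with ~24 samples per group the Gaussian approximation is adequate,
and the substitution is validated by simulation (type-I control, power,
sign recovery) rather than by reproducing any particular DEG list.
A constant age covariate is dropped with a warning (small fixtures); a
zero-residual-variance gene gets p = 1 for a zero effect and a
numerically tiny p otherwise. Age enters as continuous standardized
log-age; binning was rejected as information-destroying at n = 48.

P-values are corrected with the Holm step-down procedure, implemented
directly: in ascending order, adjusted_(i) = min(1, max_{j≤i}
(m−j+1)·p_(j)), mapped back to input order. A gene is a DEG when
|log2FC| ≥ 1 **and** Holm-adjusted p < 0.05; the effect threshold is
two-sided because both up- and down-regulation are of interest.

## Stability-voting feature selection

Each of 20 iterations runs a three-stage ranking ladder on a stratified
random half of the training samples (fraction 0.5, re-drawn per
iteration with seed `base_seed + i`; at least `cv_folds` samples per
class are always retained, and `subsample_fraction=1.0` restores
whole-training-set iterations):

1. **Elastic-net logistic ranking.** A binomial elastic net is tuned by
   stratified 7-fold CV scored by mean ROC AUC over a coarse ladder
   (mixing α ∈ {0, 0.4, 0.8} × 5 log-spaced strengths λ ∈ [10⁻³, 1]);
   CV ties prefer the larger λ, then the smaller α. The model is refit
   on the iteration's samples and genes are ranked by |coefficient|;
   zero-coefficient genes follow the non-zero ones, ordered by absolute
   point-biserial correlation with the class and then gene id, so the
   ranking is total and deterministic. The top 100 survive.
2. **CV-tuned random-forest ranking.** A random forest is tuned over
   mtry ∈ {1,2,3,4} by the same CV protocol (ties to smaller mtry),
   refit, and the survivors are re-ranked by Gini impurity decrease
   (same tie-breaks). The top 50 survive.
3. **Final forest ranking.** A second forest with the stage-2 mtry and
   fresh bootstraps ranks the survivors; the top 5 are the iteration's
   vote list.

Votes are tallied over the 20 lists; genes with **strictly more than 10**
votes are the final features. Per-iteration subsampling is what makes the
vote a stability measure: with identical samples every iteration, the
ranking noise comes only from fold assignment and forest bootstraps, and
genes that are spuriously class-correlated *in this particular sample*
are selected again and again — the vote then measures data-conditional
rather than sampling stability, and pure-noise cohorts yield non-empty
final sets. Half-subsampling (the standard stability-selection choice)
restores the intended null behaviour, which the calibration suite
verifies directly.

Numerical scales chosen for the iterated loop (the ladder runs 20 times
per selection and hundreds of times in the calibration suite): selection
forests use 100 trees for importance and 15 for CV scoring; saga CV fits
use tol 2·10⁻³ with warm starts along the λ path, with a tighter refit
(tol 10⁻⁴) for the coefficients actually used in ranking. Importance
rankings on ~30-sample slices stabilize well below these forest sizes.
The fine 14 × 21 elastic-net grid is reserved for model construction,
where it is part of the training protocol; the selection stage needs
only a good-enough hyperparameter to rank genes.

## Classifier heads

Three heads are trained on the selected (or user-supplied) features over
the standardized training slice, each tuned by stratified 7-fold CV with
mean fold AUC as the criterion and refit on the full training set:

- **Elastic-net GLM**: 14 evenly spaced mixing values α ∈ [0, 0.8] × 21
  evenly spaced strengths λ ∈ [0, 1] (the λ grid cardinality is a package
  choice; glmnet's λ is mapped to scikit-learn's C = 1/(nλ), with λ = 0
  floored at 10⁻⁸). Scores are logistic probabilities.
- **Random forest**: mtry ∈ {1,2,3,4} (capped at the feature count),
  200 trees. Scores are positive-class vote fractions.
- **Linear SVM**: 11 log-spaced costs C ∈ [10⁻⁴, 1]; log spacing is a
  package choice (even spacing would place 10 of 11 values above 0.1).
  CV uses the raw decision value (AUC only needs ranks); reported scores
  are Platt-calibrated by a one-dimensional logistic fit on the training
  decision values, a strictly monotone map, so AUC is unchanged while
  the 0.5 threshold becomes meaningful.

CV ties are broken toward stronger regularization (larger λ, then
smaller α / smaller mtry / smaller C) by enumerating candidates in
preference order and taking the first maximum.

## Evaluation

AUC is computed from the Mann–Whitney definition via average ranks
(ties count ½). The confusion matrix thresholds scores at 0.5
(score > 0.5 → positive); sensitivity and specificity are for the
obstructive class, F1 = 2TP/(2TP+FP+FN), and Cohen's κ uses marginal
chance agreement, reported as 0 with a flag when the margins are
degenerate (expected agreement 1). ROC points come from the standard
threshold sweep and are monotone from (0,0) to (1,1). Both a CV AUC
(`auc_cv`, mean fold AUC of the selected hyperparameters) and a
resubstitution AUC after refit (`auc_resub`) are reported, since either
convention may be wanted for a "training AUC".

## Group-comparison statistics

Continuous clinical variables are summarized as median (Q1, Q3) per
group and compared with the two-sided Wilcoxon–Mann–Whitney test: exact
permutation enumeration when the number of distinct group assignments is
≤ 50 000 (tie-safe and deterministic), otherwise the normal approximation
with tie and continuity correction — the standard choice at the 26/22
cohort size. Binary variables are summarized as n (%) (one decimal) and
compared with Fisher's exact test when any expected cell count is below
5 and the uncorrected Pearson χ² otherwise; the uncorrected χ² is what
reproduces the printed p = 0.02 for the patent-ductus-arteriosus table.

## Synthetic cohorts

The generator draws per-gene, per-sample counts from a negative binomial
with a shared size parameter (default 5) on a log2-mean scale; baseline
log2 means are uniform on [4, 10]. Planted markers shift the log2 mean
additively in the obstructive class only (default |log2FC| = 3, one
up-regulated lncRNA-labelled and one down-regulated mRNA-labelled gene,
mirroring the one-up-one-down marker pair the pipeline targets). Ages
are log-normal per class with medians 7.5 and 120 days (σ = 1.2 / 1.6 on
the log scale, matched to the reported quartile spreads), weights track
the class-typical medians (3.15 / 5.25 kg), and exactly
round(7/26 × n_obstructive) obstructive samples are flagged
imaging-identifiable. An optional per-sample log-normal size factor
models library-size variation but defaults to off, since no value was
reported. Identical configurations (including the seed) give
bit-identical cohorts.

What the generator does **not** emulate: gene–gene correlation,
per-gene dispersion variation, library-size normalization artifacts,
batch structure, and immune-cell-mixture composition. Passing the
calibration suite therefore demonstrates that the *procedure* behaves
correctly under its own assumptions (type-I control, null-empty
selection, planted-signal recovery), not that real cohorts of this size
will yield equally clean markers.

## Calibration suite and problem sizes

`leukopred.calibration` validates the pipeline by simulation, at sizes
chosen for desk-scale runs: DEG null calibration over 100 cohorts of
48 × 500 genes (false-call rate ≤ 1% expected); stability-selection null
over 10 cohorts (empty final set expected in ≥ 90%); planted-marker
recovery over 20 cohorts of 202 genes with |log2FC| = 3 (both markers
recovered in ≥ 90%); per-head validation AUC ≥ 0.9 over 20 seeds; and a
bit-reproducibility check that two identically seeded full runs
serialize identically. The reproduction script (`scripts/acceptance.py`)
recomputes all of these plus exhaustive-oracle checks of the Holm
correction (10⁴ random inputs of length ≤ 8 against a step-down
simulation) and of the AUC (200 random score sets against O(n²) pair
counting).

## Known limitations

- The Gaussian OLS test is not DESeq2; genes with very low counts are
  better served by a count model, and no independent filtering or
  dispersion moderation is performed.
- The vote threshold (> 10 of 20) has no finite-sample error guarantee;
  it is a protocol constant, not an inferential quantity.
- With 19 vs 16 training samples, stratified 7-fold CV produces folds of
  2–3 samples; fold AUC estimates are coarse, which is why CV ties are
  common and the deterministic tie-break matters.
- The half-subsample iterations retain only ~8 samples per class per
  iteration; markers with effects much weaker than the planted
  |log2FC| = 3 benchmark will not be recovered reliably at this n.
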