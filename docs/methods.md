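# Methods notes

This note records the modeling assumptions, numerical conventions, and
open design choices behind `mmsig`, in the order the pipeline runs.

## Signature construction

A sample counts as *mutated* in a driver gene when it carries at least one
non-synonymous variant (missense, missense_splice, stop_gain, frameshift);
synonymous calls never contribute to mutation status. Duplicate calls for
the same (sample, gene) collapse to a single mutated status. The
recurrence filter keeps drivers with ≥ 30 mutated samples — enough events
for the per-gene regressions to be stable at cohort sizes in the high
hundreds.

Per-gene effects come from ordinary least squares of expression on
mutation status, age, and gender (intercept included). The expression
matrix is assumed to be on log2 scale; median-centering and linear
regression are scale-sensitive, so this is a contract of the API, not a
convenience. Because the design matrix is identical for every gene, the
fit is one shared least-squares solve across all rows (validated against
`statsmodels.OLS` in the tests). The pseudoinverse is used so that a
rank-deficient design (e.g. a cohort of one gender) degrades gracefully
instead of erroring. Rows with zero residual variance are handled
explicitly: a constant expression row is invalid (weight 0), while a
perfect nonzero fit keeps its coefficient with the P-value floored at the
smallest positive float.

Weights are `min(−log(P), cap) / cap` on the side of the coefficient's
sign. Two conventions are fixed deliberately:

* **Logarithm base 10** (configurable). With the default cap of 10 this
  maps P = 1e−10 to the ceiling — a conventional significance scale.
* **Normalization by the cap**, not per-signature min–max. Dividing by the
  cap keeps weights comparable across signatures and makes the cap the
  unit; min–max would let a single extreme gene rescale everyone else.

No multiple-testing adjustment is applied before weighting: the weights
are effect rankings, not significance claims, and an FDR step would only
rescale the same ordering.

## BASE scoring

Relative expression is each gene's value minus its cohort median; each
sample is then sorted descending with a deterministic tie-break (gene id,
lexicographic). The foreground/background cumulative functions and the
signed maximal deviation follow the formulas in the README; on ties in
|f − b| the smallest rank wins, again for determinism.

The permutation null shuffles the assignment of weights to genes while
the expression order stays fixed. This preserves both the profile and the
weight multiset, the standard null for rank-based enrichment statistics.
Two details matter:

* **One permutation-index set serves both weight vectors** of a signature.
  This makes the final score exactly antisymmetric under swapping w_up
  and w_dn, and in cohort scoring the same set is reused for every sample
  (the multiset being permuted is identical across samples), which keeps
  2000-permutation scoring of a 500-sample cohort in about a minute.
* **Normalization divides by the mean magnitude of the null scores.** The
  literal alternative — the magnitude of the signed null mean — is near
  zero for symmetric nulls and makes the ratio explode; it remains
  available via `mode="abs_mean"` for comparison. Which of the two (or a
  same-sign mean) the original method intended is ambiguous; the mean
  magnitude is the numerically stable reading and the default.

An all-zero weight vector contributes a side score of exactly 0 (nothing
is weighted, so there is no enrichment to measure); a signature whose
weights are degenerate in other ways (foreground or background mass zero
against a particular profile) yields a flagged NaN score rather than
aborting the batch. Missing signature genes are dropped with a warning as
long as at least half the signature overlaps the matrix; the cumulative
formulas renormalize naturally.

A property worth knowing when testing: the single-spike permutation null
is symmetric about zero only to the extent that the profile's |e| mass is
balanced around its median. Median-centered cohort profiles approach this
balance; a deliberately sign-symmetric profile attains it exactly, and
that is the setting the symmetry tests use.

## Survival analysis

High-risk is score ≥ the empirical 0.8 quantile (linear-interpolation
quantile, the numpy default) — about 20% of patients, consistent with
expression-based MM risk stratification calling 10%–30% high-risk. The ≥
rule means a cohort of identical scores is all "high" (warned). Log-rank,
Kaplan-Meier, and Cox models are delegated to `lifelines`; ties use the
Efron approximation. Note that Efron's within-tie correction makes some
algebraic identities (e.g. invariance of the estimate under duplicating
every record) hold only approximately, at the 1e−3 relative level.

Model comparison uses repeated k-fold cross-validation (default 100 × 5).
Folds are drawn once per iteration and shared by all models; folds without
events are redrawn (logged). The concordance index is Harrell's, computed
on the held-out fold from the fitted partial hazard; iteration means are
compared across models with a paired two-sided Wilcoxon signed-rank test.
A tiny ridge penalty (1e−6) stabilizes fold fits near separation. The
C-index estimator variant (Harrell vs Uno) is a genuine open choice;
Harrell's is used because it is the field's default reporting convention.

## Microenvironment unmixing

The whole-bone-marrow sample is modeled as a two-component mixture,
tumor (CD138+) plus everything else, so the microenvironment profile is
the algebraic inversion `(E_WBM − E_MM·p)/(1 − p)`. The tumor fraction p
is the sum of four plasma-cell catalog proportions ("Plasma cells",
"B cells memory", "MM plasma cells", "PlasmaMemory") from any external
deconvolution tool — the deconvolution itself is out of scope and its
output is an input here. Negative unmixed values are retained: they are
estimation artifacts of the linear inversion, and clipping them would
bias the downstream correlations. Samples with p = 1 have no
microenvironment and are excluded with a warning.

Immune proportions are renormalized to sum to 1 by dividing by (1 − p);
cell types below a 1% average proportion are filtered before group
comparisons. Score–gene correlations are Spearman with average ranks and
the t-approximation for P-values; for n ≤ 12 untied samples an exact
permutation P is available, computed not by enumerating n! permutations
but from the exact null distribution of Σᵢ i·π(i) via dynamic programming
over subsets (ties fall back to the t-approximation). The retained-gene
rule is |ρ| > 0.1 and P < 0.01, split by sign.

## Selection statistics

Expected counts assume mutations land uniformly at each patient's
per-base rate over a gene's coding length: expected = L × Σᵢ rateᵢ. The
per-patient rate denominator (exome vs genome callable bases) is supplied
by the caller. Observed counts default to total variant calls rather than
distinct mutated samples, matching the arithmetic of the published worked
examples (which count calls); sample counting is a flag. The
"dN/dS"-style ratio here is a raw count ratio — no per-site normalization
and no mutation-context model — and the code and docs say so explicitly;
it is a coarse selection indicator, not an estimate of ω.

## Treatment response

Responders are CR/PR/MR; unknown codes are excluded with a warning.
Score groups use half-open intervals: low < 0.5 ≤ medium < 1 ≤ high —
the boundaries are inclusive on the upper group, consistent with grouping
by "scores exceeding the cutoff", and configurable. Fisher's exact test
is two-sided by the probability-mass rule (sum of tables no more probable
than the observed one); a zero-margin table carries no information and
returns P = 1 with a warning. The hazard-ratio sweep dichotomizes at the
(1 − f) quantile with the same ≥ rule as survival stratification, so
f = 0.2 reproduces the 0.8-quantile split exactly.

## Synthetic cohorts

The generator emulates the statistical design the pipeline assumes, with
stored ground truth for recovery tests:

* **Expression**: log2-scale, per-gene mean ~ N(8, 2), i.i.d. Gaussian
  noise (default SD 1). Driver target sets are disjoint draws from the
  non-driver genes.
* **Effects**: per-target magnitudes are gamma-distributed with shape 0.5
  around the configured mean (in noise-SD units), signed by the
  configured up/down mix. The small shape encodes the many-weak/few-
  strong target profile typical of differential expression downstream of
  a driver lesion; it also means the induced P-value spectrum spans the
  weight cap rather than saturating it.
* **Covariates**: age uniform over the configured range, gender
  Bernoulli(0.5) coded 0/1 — the simplest structure satisfying the
  regression design.
* **Survival**: exponential event times with rate
  baseline·exp(log_hr·score), where the latent risk score is the
  standardized sign-corrected mean target expression of the first driver
  (what a perfect signature would recover). Censoring times are
  independent exponentials whose rate is calibrated by root finding so
  the expected censored fraction matches the configuration; a censoring
  fraction of 1 yields a fully administratively censored cohort.
* **Response**: Bernoulli with logit = logit(base rate) + log-odds ×
  score, plus realistic response codes (CR/PR/MR vs NC/PD).
* **Paired bone marrow**: E_WBM is the exact convex combination of the
  tumor profile and a generated microenvironment profile (optional noise
  added after the identity), with tumor fractions uniform over the
  configured range and a cell-proportion matrix whose plasma catalogs sum
  to p and whose granulocyte share shrinks with the risk score.

What the generator deliberately does **not** emulate: copy-number and
cytogenetic structure, gene–gene correlation beyond the driver–target
construction, batch effects, or count-level (negative-binomial) noise.
Passing tests therefore demonstrate that the algorithms recover the
structure they assume — not that real MM cohorts satisfy those
assumptions.

## Problem sizes and determinism

The test suite and the acceptance script use cohorts of 120–500 samples
and 150–1000 genes, 2000 permutations for scoring, 100 × 5-fold
cross-validation at n = 300, and n = 1000 for Cox recovery — sizes at
which the recovery properties are comfortably identifiable while a full
run stays in the minutes range on a single core. Every stochastic step
takes an explicit seed (or `numpy.random.Generator`); a fixed
configuration reproduces byte-identical cohorts and scores.

## Known limitations

* The regression adjusts for age and gender only; real analyses may need
  race, stage, or cytogenetics as covariates.
* BASE scores are normalized per sample against their own permutation
  null; scores are comparable across samples within a cohort, but
  cross-cohort calibration (e.g. fixed response cutoffs 0.5/1) assumes
  comparable normalization.
* The unmixing model is strictly two-component and linear in expression
  space; applying it to log-scale data treats log-expression as
  approximately additive in mixing fraction, which is an approximation.
* The selection ratios have no significance test attached, by design.
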