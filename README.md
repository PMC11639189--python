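# mmsig

Mutation-conditioned gene signatures for multiple myeloma (MM): build
per-driver-gene dysregulation signatures from matched somatic-mutation and
expression cohorts, score single samples with a rank-based running-sum
statistic (BASE) against a permutation null, and run the downstream
analyses those scores feed — prognostic stratification, tumor-immune-
microenvironment (TIME) unmixing, mutation-selection statistics, and
treatment-response stratification.

The package is aimed at translational genomics analysts working with
MM-style cohorts: a gene × sample expression matrix (log2 scale), a
MAF-like mutation table (`sample_id`, `gene`, `variant_class`), and a
clinical table with survival and response outcomes. Because the real
cohorts of this design are controlled-access, a first-class synthetic
cohort generator reproduces their statistical structure with known ground
truth, so every stage is testable end to end.

## The model

**Signature construction.** For a driver gene recurrently mutated in at
least 30 samples, each gene *g*'s expression is regressed as

```
expression_g ~ mutation_status + age + gender        (OLS)
```

The mutation coefficient β_g and its two-sided P-value define two weight
vectors: for β_g > 0, `w_up[g] = min(−log10 P_g, 10) / 10` and
`w_dn[g] = 0`; for β_g < 0 the roles swap. Weights therefore live in
[0, 1] with the cap as the unit, and at most one of the pair is nonzero
per gene.

**BASE scoring.** A sample's profile is median-centered per gene across
the cohort and sorted descending, e₁ ≥ … ≥ e_n. With weights w aligned to
that order,

```
f(i) = Σ_{j≤i} |e_j w_j| / Σ_{j≤n} |e_j w_j|
b(i) = Σ_{j≤i} |e_j (1−w_j)| / Σ_{j≤n} |e_j (1−w_j)|
```

The preliminary score is f − b at the rank maximizing |f − b| (sign kept),
normalized by the mean magnitude of 2000 permutation-null scores obtained
by shuffling the weight-to-gene assignment. The signature score is the
normalized up-score minus the normalized down-score; mutated samples
over-expressing the up-weighted genes score high.

**Downstream.** High-risk = score ≥ the 0.8 empirical quantile;
Kaplan-Meier curves with log-rank tests; uni/multivariable Cox models;
repeated 5-fold cross-validated Harrell C-index comparisons (paired
Wilcoxon across iterations). TIME expression is unmixed from paired whole
bone marrow (WBM) and CD138+ tumor profiles as
`(E_WBM − E_MM·p) / (1 − p)` with p the summed plasma-catalog proportion,
then correlated (Spearman, |ρ| > 0.1 and P < 0.01) with signature scores.
Selection statistics are observed/expected mutation-count enrichment
ratios (expected = gene length × Σ per-patient per-base rates) and a raw
nonsynonymous/synonymous call ratio. Response analysis labels CR/PR/MR as
responders, fits multivariable logistic regressions, groups patients at
score cutoffs 0.5 and 1 with Fisher's exact test, and sweeps the hazard
ratio of the top-f% score group against the rest.

## Worked example

```python
import numpy as np
from mmsig import CohortConfig, DriverSpec, generate_cohort
from mmsig.signatures import mutation_status, fit_mutation_effects, build_signature
from mmsig.base import score_cohort
from mmsig.survival import stratify_top_quantile, logrank_test, cox_fit

config = CohortConfig(
    n_samples=300, n_genes=500,
    drivers=(DriverSpec("TP53", frequency=0.15, n_targets=40, effect=2.0),),
    seed=1,
)
cohort = generate_cohort(config)

mutated = mutation_status(cohort.mutations, "TP53", cohort.expression.columns)
effects = fit_mutation_effects(
    cohort.expression, mutated,
    cohort.clinical["age"].to_numpy(), cohort.clinical["gender"].to_numpy(),
)
signature = build_signature(effects, signature_gene="TP53")

scores = score_cohort(cohort.expression, signature, n_perm=2000, seed=2)
groups = stratify_top_quantile(scores["score"], q=0.8)
stat, p = logrank_test(groups, cohort.clinical["time"], cohort.clinical["event"])

data = cohort.clinical.assign(score=scores["score"])
cox = cox_fit(data, ["score", "age", "gender"])
```

Output:

```
samples scored:        300
high-risk group size:  60
log-rank chi2 = 56.27, P = 6.3e-14
per-unit-score HR = 1.24 (95% CI 1.19-1.29, P = 8.9e-25)
```

The synthetic cohort links survival to a latent risk score built from the
driver's true target genes; the fitted signature recovers that structure,
so the top-quantile score group has sharply worse survival (log-rank
P ≈ 6e-14) and the score is strongly prognostic per unit in a Cox model
adjusted for age and gender.

The same pipeline is available from the shell via the `mmsig` console
script (`mmsig synth-cohort`, `build-signature`, `score`, `stratify`,
`time-expr`, `enrich`, `response`); run `mmsig --help` for details.

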