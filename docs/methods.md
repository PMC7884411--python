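# Methods

## The enrichment statistic

The single-sample normalised enrichment score is the Mann–Whitney–Wilcoxon
gene-set test: with genes ranked ascending by expression within one sample
(midranks for ties), `T` the sum of in-set ranks, `m` in-set and `n`
out-set genes,

```
U = m·n + m(m+1)/2 − T,      NES = 1 − U/(m·n).
```

This is the standard Mann–Whitney identity; some descriptions of the
statistic print `m(m+1)` without the half, but only the halved form keeps
NES inside [0, 1] and lets a top-ranked set reach exactly 1, which the
probability interpretation (P[in-set gene outranks out-set gene, ties ½])
requires. Midranks are used for ties so the statistic is deterministic; the
test suite checks the pairwise-concordance identity to 1e-12 on random
instances with heavy ties.

Consequences exploited downstream and asserted as invariants: the NES of a
sample depends only on that sample's ranking, so it is unchanged by
positive scaling or any strictly increasing transform of the profile, and
the ratio score of a sample is bit-identical whether the sample is scored
alone or inside any matrix. Genes of a signature absent from the matrix are
dropped from `m` (logged once per set), not imputed as zeros. A profile
with all values equal has every rank tied, giving NES = 0.5 (warned).

## Survival models

Cox proportional-hazards fits use lifelines with the Efron tie
approximation (the default of the R `survival::coxph` tool family; no
Breslow option is exposed because the backend implements only Efron).
Cohort and gender are dummy-coded against the first level; stage is
harmonised (IA→I, …, IVC→IV; table in `miracle.survival.STAGE_MAP`) and
encoded ordinally 1–4. Multivariate models use complete cases of the larger
model, with dropped-row counts logged; nested models are compared by the
likelihood-ratio χ² with df = difference in coefficient count.

Cohort stratification fits a univariate Cox model of overall survival on
the continuous ICR NES per cohort: immune-enabled (IE) if HR < 1 and
p < 0.1, immune-disabled (ID) if HR > 1 and p < 0.1, else neutral. The p
threshold and the minimum-event exclusion rule (default 5 events; cohorts
below it are excluded and reported, mirroring the exclusion of very-low-
mortality tumour types from survival estimation) are parameters. Per-cohort
fits are univariate by default; covariates can be supplied but the
stratification contract does not use them.

Benjamini–Hochberg adjustment is implemented directly (vectorised step-up
with enforced monotonicity) so the operation can validate its input domain;
it is cross-checked against `statsmodels.multipletests` in the tests.

## Differential expression and derivation

Tertile groups are the first and last ⌊N/3⌋ samples after an ascending
stable sort on (NES, sample id); the middle tertile is excluded. The
per-gene test is the two-sided Wilcoxon rank-sum via scipy: exact
enumeration when the combined group size is ≤ 20 and the gene has no ties,
otherwise the normal approximation with tie and continuity correction.
Genes constant across both groups get p = 1. The fold change on
non-negative (count-derived) data is `log2((mean_high + 1)/(mean_low + 1))`
— the pseudocount of 1 is this package's convention — and the difference of
means for data already on a log scale (`log_scale=True`). The default DEG
filter is log2FC > 1, p < 0.05, FDR < 0.1 with strict inequalities
(configurable; descriptions of the filter vary between > and ≥ at the
fold-change boundary).

Significance ranks are 1-based over the full table: ascending p, ties
broken by descending |log2FC|, then lexical gene id. Rank direction
matters for the ΔR step: rank 1 = most significant, so the most
IE-specific genes have the most *negative* `ΔR_IE = R_IE − R_ID` and are
ordered first; a gene significant in both analyses has ΔR near 0 and sinks.
A gene absent from one table gets rank G+1 (one past the table), keeping ΔR
bounded. `top_k` truncates the ordered exclusive lists; the default "all"
keeps them whole, because the appropriate truncation depends on how many
exclusive genes the data yield — it is the single most consequential tuning
parameter and is exposed everywhere.

DE pools all samples of the IE (resp. ID) cohort group and takes tertiles
on the pooled NES distribution; per-cohort tertiles before pooling are
available as `per_cohort_tertiles=True` since either reading of "high vs
low within the pooled group" is defensible.

## The synthetic generator

Each sample carries latent stimulation `A` and suppression `S`. Cohort
archetypes set their scale: IE-like cohorts are stimulation-dominated
(sd_A = 1.0, sd_S = 0.3), ID-like suppression-dominated (0.3, 1.0), both
with corr(A, S) = 0.1 — a small positive correlation everywhere emulating
compensatory immune resistance. The scales, not the correlation alone,
carry the archetype: raising corr(A, S) high enough to flip the survival
sign would also leak `A` into the ID cohorts' ICR tertiles and make the
planted stimulatory genes differentially expressed in *both* analyses,
which would empty the exclusive lists — the derivation's premise is that
the two cohort groups expose different programmes, and the generator must
realise that premise to be a usable oracle.

Expression is lognormal: log2 values = per-gene baseline N(6, 2²) + shift +
N(0, 1) noise. ICR-like genes (named after the real 20-gene Th1 signature,
so the built-in `ICR` signature scores the synthetic data directly) shift
by `1.5·(A + 0.8·S)`; 50 IE-programme genes by `2.0·A`; 50 ID-programme
genes by `2.0·S`; the rest are noise. Effect sizes are in noise-SD units;
2.0 makes the tertile contrast ≈ 4 log2 units for on-programme genes while
cross-leakage (an IE gene's fold change in the ID analysis) stays ≈ 0.6 —
comfortably under the DEG threshold. The marginal family is immaterial to
the rank-based pipeline; lognormal keeps the generator simple.

Survival is exponential with hazard `8e-4 · exp(−0.8·(A − S))` per day, so
the true balance is protective, with independent uniform censoring whose
horizon is solved numerically for a 35% target censored fraction.
Clinical covariates (age, gender, stage) are drawn independently of the
hazard, making them exact null covariates for the model-comparison tests.
Mutations are Bernoulli(0.08) over a 200-gene panel; five planted drivers
subtract 1.0 from a carrier's `A`, five add it, and expression and survival
are regenerated from the shifted latents with the *same* stored noise and
uniform draws, so the dataset pair differs only through the mutations.
Responder status is Bernoulli with probability `sigmoid(1.5·(A − S))`;
non-responders are PD, responders spread over SD/PR/CR.

The reference scenario is 3 cohorts (IE, IE, ID) × 200 samples × 2000
genes, seed 42. These sizes keep the full test suite under a minute while
leaving all planted effects detectable with margin. What passing tests do
not show: robustness to batch effects, tumour purity, platform-specific
probe behaviour, non-proportional hazards, or covariate-confounded
mutations — none of which the generator emulates.

## Mutation association

The elastic net (scikit-learn, mixing `l1_ratio = 0.5` by default) predicts
log2(score) — the log makes the ratio's numerator and denominator
symmetric — from binary mutation columns. Cohort effects are unpenalised:
they are profiled out exactly by centring the response and every mutation
column within cohort (Frisch–Waugh applies because the penalty does not
involve the cohort block). Penalty strength is selected by inner
cross-validation on an automatic 30-point grid; the reported accuracy is
the mean ± SD Spearman correlation between held-out predictions and
observed scores over ten outer folds, refitting at the selected penalty per
fold. A fold whose prediction is constant (everything shrunk away, as
happens under the null) contributes correlation 0 by convention. All-zero
mutation columns are forced to coefficient 0. `alpha = 0` falls back to the
exact least-squares solution.

## Response evaluation

RECIST codes (long or short form, case-insensitive) map deterministically:
PD → non-responder, CR/PR/SD → responder. AUC is computed from midranks
(the Mann–Whitney form; ties count ½), which equals the trapezoidal area
under the ROC curve; curve points come from scikit-learn. The group test is
Welch's unequal-variance t (the two-sample comparison is between groups of
unknown, typically unequal spread).

## Numerical conventions and degenerate inputs

- Gene symbols are upper-cased on load; duplicate symbols collapse to the
  row with the highest mean (logged). Expression TSVs round-trip at full
  float64 precision (shortest-repr writing, round-trip float parsing).
- Tertile ties at group boundaries, DE rank ties and ΔR ties all break by
  sample/gene identifier, making every stage deterministic.
- Zero denominator NES yields a per-sample error record; other samples are
  unaffected. Identical IE/ID sets give score 1 wherever the ratio exists.
- All simulation and fitting randomness flows from explicit integer seeds;
  reruns are bit-identical.

## Known limitations

- Efron is the only tie-handling method for Cox fits.
- The DE stage offers no count-model (negative-binomial) or
  covariate-adjusted alternative; it is a rank test on normalised values.
- Enrichment p-values (permutation nulls) are out of scope — only the NES
  itself feeds the score.
- The published signature gene lists, external immunotherapy cohorts and
  curated mutation panels are not bundled; the package derives signatures
  from whatever cohorts it is given and accepts arbitrary GMT sets.
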