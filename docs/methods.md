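# Methods

## Scope and model

`bcellprs` implements a pathway-restricted polygenic risk score (PRS)
analysis for systemic lupus erythematosus (SLE). The score for individual
*j* over a set *S* of risk loci is the weighted allele count

    PRS_j = Σ_{i∈S} ln(OR_i) · d_ij,        d_ij ∈ [0, 2],

where `OR_i` is the published per-allele odds ratio for SLE at locus *i*
and `d_ij` the risk-allele dosage. Two locus sets ship with the package:
the 20-SNP **B cell** set and its 12-SNP **B cell activation** subset
(every activation locus is also a B cell locus). Weights are stored as
`ln(OR)` at full double precision computed from the table's OR column,
never from pre-rounded weights, so sums are bit-reproducible.

Protective coding is normalised before scoring: a variant with OR < 1 is
replaced by its flip (risk/other alleles swapped, OR ← 1/OR, risk-allele
frequency ← 1 − RAF), which makes all weights non-negative. Flipping
changes each sample's score only by the per-locus constant `2·ln(1/OR)`,
so quartile-based group assignments are invariant to the input coding —
a property the test suite checks directly.

Scores are analysed both continuously and binarised at the **fourth
quartile**: `high` means strictly above the linear-interpolation (type-7)
75th percentile of the analysis cohort; quartiles 1–3 are `low`. The
quantile estimator and the strict inequality are deliberate, documented
tie policies so that group counts are exactly testable. Whether the
quartile is computed over patients only or patients plus controls is the
caller's choice — the operation uses whatever cohort it is given.

Missing dosages are imputed as the per-locus expectation `2·RAF` and
counted per sample (`n_missing_used`), which is unbiased in expectation
and auditable. Allele labels are reconciled against the weight table
allowing strand flips for unambiguous pairs; A/T and C/G mismatches are
fatal because a silent strand error inverts the score.

## Genotype quality control

The QC chain runs in a fixed order — sample call rate, PCA outliers, IBD
relatedness, heterozygosity, X-chromosome sex check, then variant filters
— recording for every exclusion the stage and reason. Default thresholds:

| filter | default | rule |
|---|---|---|
| sample call rate | 0.95 | excluded iff strictly below |
| PCA outlier | 5 SD | any of the top 10 PCs beyond 5 SD of the cohort mean |
| relatedness | π̂ > 0.1875 | greedy removal, lower call rate dropped (tie: later id) |
| heterozygosity | 5 SD | autosomal het rate vs cohort mean |
| sex check | F | male with F < 0.8 or female with F > 0.2 on X markers |
| variant call rate | 0.98 | strictly below |
| MAF | 0.01 | minor allele frequency on non-missing calls |
| HWE | p < 1e-4 | exact conditional test, autosomes |

**Hardy–Weinberg exact test.** The exact conditional test enumerates all
heterozygote counts compatible with the observed allele totals and sums
the probabilities no larger than the observed configuration's. Weights
are built with an exact integer recurrence
(`W(h+2) = W(h)·4·n_AA·n_BB/((h+1)(h+2))`), so tie comparisons are exact
and the p-value is free of rounding artifacts; an independently coded
log-gamma oracle agrees to 1e-12 across an exhaustive grid of small
tables.

**Relatedness.** π̂ = P(IBD=2) + ½·P(IBD=1) is the method-of-moments
estimate from observed IBS counts and cohort allele frequencies. The
moment equations are solved sequentially with truncation: P(IBD=0) is
clamped to [0,1] before P(IBD=1) uses it, and P(IBD=2) is the simplex
complement. Sequential truncation matters — clipping all three
components simultaneously and renormalising lets a negative IBD-1 moment
leak probability into IBD-2, making a heavily inbred sample look related
to everyone. The finite-sample bias-correction factors some
implementations apply to the expected-IBS terms are omitted; at ≥1000
markers the residual bias is far below the 0.1875 decision threshold
(the duplicate / unrelated / full-sibling simulations in the test suite
bound it).

**Inbreeding coefficient.** F = (O_hom − E_hom)/(m − E_hom) with
E_hom summing `1 − 2p̂q̂·2n/(2n−1)` over the sample's non-missing
polymorphic markers (the 2n/(2n−1) factor unbiases the heterozygosity
estimate). On X markers F separates males (≈1) from females (≈0).

**PCA outliers.** Dosages are mean-imputed and standardised per variant;
outliers are flagged per component relative to the cohort itself. The
original analysis projected onto an external reference panel; flagging
relative to the cohort preserves the contract without requiring a
reference download.

**LD pruning** uses composite (dosage-Pearson) r², not haplotype-EM r² —
phase-free and standard for pruning. While any kept pair exceeds
r² = 0.2, the pair with the largest r² drops its lower-OR member (ties:
lower RAF, then the lexicographically later rsID), so output is
deterministic.

## Association analysis

Effects are estimated exactly as the study design prescribes: Student's
pooled-variance t-test for mean score differences; maximum-likelihood
logistic regression for binary outcomes against the high/low indicator
with **years of disease duration** as covariate in every logistic model;
Cox proportional hazards (Breslow ties, as implemented by lifelines) for
time to lupus nephritis (LN) onset, adjusted for **age at onset**. All
intervals are Wald 95% CIs — symmetric on the log scale, matching the
"OR (lo to hi)" reporting style. Complete cases only; per-row n is
reported. No multiplicity adjustment is applied (nominal p-values); the
battery records how many tests it ran.

Perfect or quasi-perfect separation (fitted |β| > 15 or non-finite
standard errors) raises a distinct error advising an exact or penalised
fit rather than silently reporting a diverged estimate. In stratified
analyses the error is confined to its stratum, which is reported as
not-estimable.

HLA stratification uses tag SNPs rs1269852 (HLA-DRB1\*03:01) and
rs3135388 (HLA-DRB1\*15:01) under dominant coding: carriers of neither
(`neg_neg`), exactly one (`single_pos`), or both (`double_pos`).
Stratified fits are run per stratum with the duration covariate (the
adjusted-everywhere convention), no pooling and no interaction term.

## Synthetic cohort generator

The study's patient-level data are not public, so the generator emulates
the statistical structure the analysis assumes, with defaults frozen in
`data/default_config.yaml`:

- **Genotypes**: 20 independent loci in Hardy–Weinberg proportions,
  dosage ~ Binomial(2, p). Patient frequencies are the packaged RAFs;
  control frequencies are back-derived from the per-allele ORs via
  `p_ctrl = RAF / (RAF + (1 − RAF)·OR)`, the unique frequency for which
  the allelic case/control odds ratio equals the published OR. Loci are
  independent (no LD) by default; correlated pairs exist only to
  exercise the pruner.
- **Cohort sizes**: 1248 female patients, 400 controls; HLA strata drawn
  at 354 : 656 : 143.
- **Outcomes**: each binary manifestation follows a logistic model on
  its designated exposure (the fourth-quartile PRS indicator, or dsDNA
  status for LN) with the published odds ratio as the true coefficient,
  plus a mild duration effect (0.02 per year, a generator-realism choice).
  The intercept is solved by bisection so the marginal prevalence hits
  the configured value (|Δ| < 1e-6) — e.g. renal disorder 29.7%, dsDNA
  62.6%. Where stratum-specific ORs are configured (dsDNA
  0.99/1.64/4.47; low complement 3.92 in `double_pos`), they override
  the cohort-wide value inside their stratum.
- **Survival**: exponential LN-onset times with proportional hazard
  `ln(2.89)` on dsDNA status and a small age effect (−0.01/year),
  censored by an independent exponential (0.04/year) around a baseline
  rate of 0.012/year — chosen to give a realistic ~30–40% event
  fraction. Duration and age at onset are log-normal anchored at medians
  18 and 35 years; the spreads are arbitrary, as only medians are
  published.
- **Case status** (for the disease-prevalence analysis) uses indicator
  mode: a common genotype pool at control frequencies, case status drawn
  from a logistic model on the high-PRS indicator with true OR 1.64,
  calibrated to the 1248:400 design margin. Quartile-level and
  per-allele effects are not mutually constrained by the published
  results, so the observed quartile ORs are modelled directly on the
  indicator rather than re-derived from per-allele effects; frequency
  mode (cases at RAFs, controls at derived frequencies) is what
  `generate_cohort` uses for genotypes.

Controls carry genotypes only; their phenotype columns are missing,
matching the blood-donor control design. Each cohort embeds a `truth`
record that round-trips the generating configuration, and generation is
bit-reproducible given the seed.

### What the generator does *not* emulate

Real LD structure, genotyping error, population stratification,
missingness patterns, correlated comorbidity between outcomes ("renal"
and "ln" are generated as independent columns even though both describe
the ACR-7 nephritis criterion, so that each configured effect is
recoverable in isolation), or the empirical patient PRS means (2.92 /
1.81), which depend on unpublished per-sample data and exceed the
Hardy–Weinberg expectation Σ2·RAF·ln(OR) ≈ 1.84 computed from the
packaged table — the generator is calibrated to frequencies and effect
sizes, not to those means. Passing tests therefore demonstrate that the
pipeline's arithmetic, filters and estimators behave correctly under the
assumed model, not that the synthetic cohorts are indistinguishable from
the real one.

## Numerical and statistical notes

- **Quartile ties**: with lattice-valued scores ties at the threshold
  are possible; `high` is strictly above the type-7 percentile. With all
  scores identical the operation refuses (`degenerate score
  distribution`); the CLI degrades to all-`low` with a warning, since
  nothing exceeds the third quartile of a constant distribution.
- **Score distribution**: the PRS is a lattice sum of 20 discrete
  dosages, mildly right-skewed (skew ≈ 0.48 at the packaged
  frequencies, driven by low-RAF/high-weight loci). It is approximately
  Gaussian in the sense that the KS distance to a fitted normal
  plateaus around 0.034 at n = 10⁵; tests assert < 0.05 rather than
  pretending continuity.
- **Small-stratum logistic bias**: at the `double_pos` stratum size
  (n = 143, ~36 exposed, expected non-event cell ≈ 4.5) the ML log-OR
  has the textbook O(1/n) upward bias: its exact sampling expectation —
  computable by enumerating the 2×2 table distribution — is ln(4.84)
  when the generating OR is 4.47. Recovery tests therefore compare the
  replicate mean against that enumerated expectation, which coincides
  with the generating log-OR to < 1% at the full-cohort sizes. The
  published stratum estimate (4.47, CI 1.21–16.47) is a single draw
  from the same estimator and carries the same tendency.
- **Replicate sizes**: recovery experiments use 200 replicate cohorts
  (500 for the n = 143 strata), sized so Monte-Carlo error on the mean
  log-effect is ≈ 1–2.5% while the whole suite stays interactive.
- **Separation handling**: replicates whose fit separates are excluded
  from recovery averages (they correspond to infinite ML estimates);
  at the configured prevalences this affects ~1–2% of n = 143 strata
  and essentially no full-size cohorts.
- **Determinism**: every stochastic routine takes a seed or Generator;
  per-replicate generators are spawned from a single SeedSequence, so
  one integer reproduces any experiment byte-for-byte.

## Known limitations

- The PCA outlier stage flags relative to the analysed cohort; with a
  majority of outliers it would mask itself (as any self-referential
  filter does).
- The IBD estimator assumes the cohort's allele frequencies estimate the
  source population's; small cohorts inflate π̂ slightly for unrelated
  pairs.
- `cox_assoc` reports Wald intervals only; likelihood-ratio intervals
  would behave better in tiny event counts but would not match the
  reporting style being reproduced.
- The weight table's `other_allele` column completes the published
  risk-allele list with reference alleles (dbSNP where known); scoring
  and simulation only require the pair to be internally consistent and
  strand-unambiguous, which holds for all 20 loci.
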