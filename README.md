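# bcellprs

Pathway-restricted polygenic risk scores (PRS) for systemic lupus
erythematosus (SLE): genotype quality control, B cell PRS construction
from a packaged 20-SNP weight table, HLA tag-SNP stratification,
quartile-based association analysis, and a calibrated synthetic cohort
generator.

## The problem

SLE risk is polygenic, and B cell dysfunction is a central disease
mechanism: autoreactive B cells drive anti-dsDNA antibody production,
immune-complex formation and lupus nephritis (LN). A *pathway-restricted*
PRS asks whether the cumulative genetic burden in B cell genes
specifically — rather than genome-wide risk — predicts a patient's
autoantibody profile and organ involvement. The score for individual *j*
is the weighted risk-allele count

    PRS_j = Σ_i ln(OR_i) · d_ij

over a curated set of SLE risk loci in B cell pathway genes, with
`OR_i` the published per-allele odds ratio and `d_ij ∈ [0, 2]` the
risk-allele dosage. Patients in the fourth score quartile ("high") are
compared with quartiles 1–3 ("low") by duration-adjusted logistic
regression, within HLA-DRB1\*03:01/\*15:01 tag-SNP strata where the HLA
background modifies the effect, and by age-adjusted Cox regression for
time to LN onset.

The package is aimed at statistical geneticists and rheumatology
researchers who want a tested, reproducible implementation of this
pipeline: the weight table of 20 B cell loci (12 of them in the B cell
activation subset) ships with the package, the engine accepts any
user-supplied weight table in the same format, and a synthetic cohort
generator — calibrated to the published allele frequencies, prevalences
and effect sizes — makes every stage testable without access to patient
data.

## Worked example

Simulate a default cohort (1248 patients, 400 controls, 20 loci), score
it, and run the association battery:

```bash
bcellprs simulate --seed 1 --out demo
bcellprs score --genotypes demo/genotypes.vcf --out demo
bcellprs associate --scores demo/scores.tsv --phenotypes demo/phenotypes.tsv --out demo
bcellprs report demo
```

`score` prints the pooled score summaries:

```
bcell: mean 1.738 (95% CI 1.705 to 1.772), SD 0.697, n=1648
bcell_activation: mean 0.956 (95% CI 0.932 to 0.979), SD 0.481, n=1648
```

— each sample's B cell PRS is the sum of `ln(OR) × dosage` over the 20
loci (a patient homozygous for every risk allele would score 11.95), and
the quartile threshold behind the `group_*` columns is taken over the
cohort passed in. `report` renders the battery as a table; a few rows
from this run:

| outcome | exposure | stratum | n | estimate (95% CI), p |
|---|---|---|---|---|
| dsdna | bcell_high | all | 1248 | 1.29 (0.98 to 1.71), p=0.0691 |
| dsdna | bcell_high | double_pos | 151 | 3.96 (1.41 to 11.11), p=0.00904 |
| renal | activation_high | all | 1248 | 1.27 (0.97 to 1.67), p=0.0854 |
| time_to_ln | dsdna | all | 1248 | 2.93 (2.34 to 3.67), p=9.15e-21 |

Each row is a duration-adjusted logistic odds ratio (or, for
`time_to_ln`, an age-adjusted Cox hazard ratio) for the outcome in
high-PRS versus low-PRS patients (or dsDNA-positive versus negative).
This cohort was generated with true stratum ORs 0.99/1.64/4.47 for dsDNA,
OR 1.32 for renal disorder and HR 2.89 for LN onset, so the fitted values
above are single-replicate draws around those targets.

The same stages run on real data: `qc` accepts a VCF or a dosage TSV
plus variant sidecar and applies the full filter chain (call rates, PCA
outliers, IBD > 0.1875, heterozygosity, sex check, MAF, exact HWE test)
before scoring.

## Library use

```python
from bcellprs import packaged_weight_table, compute_prs, classify_quartiles
from bcellprs.simulate import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig.default(), seed=1)
prof = compute_prs(cohort.genotypes, CohortConfig.default().weight_table, "bcell")
groups = classify_quartiles(prof, "bcell")
```

See `docs/methods.md` for the model, QC rules, estimators, generator
calibration and numerical conventions.

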