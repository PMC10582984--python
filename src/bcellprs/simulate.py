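"""Synthetic case-control cohort generator.

Emulates the statistical structure the PRS analysis assumes: independent
loci in Hardy-Weinberg proportions, patient risk-allele frequencies from
the packaged weight table (control frequencies back-derived from the
per-allele odds ratios), clinical outcome prevalences and high-vs-low PRS
effect sizes from the packaged default configuration, and the three
HLA-DRB1*03/15 tag-SNP strata. Outcomes are drawn from logistic models on
the fourth-quartile PRS indicator (or on dsDNA status), with the intercept
calibrated by bisection so the marginal prevalence hits its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .matrix import GenotypeMatrix
from .scoring import (
    WeightTable,
    classify_quartiles,
    compute_prs,
    orient_weights,
    packaged_weight_table,
)


@dataclass(frozen=True)
class EffectSpec:
    """One true generating effect: outcome ~ exposure, optionally within
    a single HLA stratum."""

    outcome: str
    exposure: str
    value: float
    effect_type: str = "OR"
    stratum: str = None

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError(f"{self.outcome}~{self.exposure}: effect must be > 0")


@dataclass
class CohortConfig:
    n_cases: int = 1248
    n_controls: int = 400
    weight_table: WeightTable = None
    prevalences: dict = field(default_factory=dict)
    effects: list = field(default_factory=list)
    hla_stratum_weights: dict = field(default_factory=dict)
    duration_lognormal: dict = field(default_factory=lambda: {"median": 18.0, "sigma": 0.6})
    age_at_onset_lognormal: dict = field(
        default_factory=lambda: {"median": 35.0, "sigma": 0.45, "min": 3.0, "max": 82.0}
    )
    duration_beta: float = 0.02
    age_beta: float = -0.01
    survival: dict = field(default_factory=lambda: {"baseline_rate": 0.012, "censoring_rate": 0.04})

    def __post_init__(self):
        if self.weight_table is None:
            self.weight_table = orient_weights(packaged_weight_table())
        for name, p in self.prevalences.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence of {name} outside (0, 1): {p}")
        total = sum(self.hla_stratum_weights.values()) or 1.0
        self.hla_stratum_weights = {
            k: v / total for k, v in self.hla_stratum_weights.items()
        }

    def effect(self, outcome: str, exposure: str, stratum: str = None):
        """Most specific matching effect; None if unspecified (null)."""
        match = None
        for e in self.effects:
            if e.outcome != outcome or e.exposure != exposure:
                continue
            if e.stratum == stratum:
                return e
            if e.stratum is None:
                match = e
        return match

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "prevalences": dict(self.prevalences),
            "effects": [
                {
                    "outcome": e.outcome, "exposure": e.exposure,
                    "effect_type": e.effect_type, "value": e.value,
                    **({"stratum": e.stratum} if e.stratum else {}),
                }
                for e in self.effects
            ],
            "hla_stratum_weights": dict(self.hla_stratum_weights),
            "duration_lognormal": dict(self.duration_lognormal),
            "age_at_onset_lognormal": dict(self.age_at_onset_lognormal),
            "duration_beta": self.duration_beta,
            "age_beta": self.age_beta,
            "survival": dict(self.survival),
        }

    @classmethod
    def from_dict(cls, raw: dict, weight_table: WeightTable = None) -> "CohortConfig":
        effects = [EffectSpec(**e) for e in raw.get("effects", [])]
        return cls(
            n_cases=int(raw.get("n_cases", 1248)),
            n_controls=int(raw.get("n_controls", 400)),
            weight_table=weight_table,
            prevalences=dict(raw.get("prevalences", {})),
            effects=effects,
            hla_stratum_weights=dict(raw.get("hla_stratum_weights", {})),
            duration_lognormal=dict(raw.get("duration_lognormal", {"median": 18.0, "sigma": 0.6})),
            age_at_onset_lognormal=dict(
                raw.get("age_at_onset_lognormal", {"median": 35.0, "sigma": 0.45, "min": 3.0, "max": 82.0})
            ),
            duration_beta=float(raw.get("duration_beta", 0.02)),
            age_beta=float(raw.get("age_beta", -0.01)),
            survival=dict(raw.get("survival", {"baseline_rate": 0.012, "censoring_rate": 0.04})),
        )

    @classmethod
    def from_yaml(cls, path, weight_table: WeightTable = None) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, weight_table=weight_table)

    @classmethod
    def default(cls) -> "CohortConfig":
        """The packaged study-defaults configuration."""
        ref = resources.files("bcellprs").joinpath("data/default_config.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict


def derive_control_freq(raf_case: float, or_allele: float) -> float:
    """Control-population risk-allele frequency implied by the case RAF
    and the per-allele odds ratio: odds(case) / odds(control) = OR."""
    if not (0.0 < raf_case < 1.0):
        raise ValueError("raf_case must be in (0, 1)")
    if or_allele <= 0.0:
        raise ValueError("or_allele must be > 0")
    return raf_case / (raf_case + (1.0 - raf_case) * or_allele)


def simulate_genotypes(
    freqs,
    n: int,
    rng: np.random.Generator,
    snp_ids=None,
    alleles=None,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Independent HWE genotypes: dosage ~ Binomial(2, p) per locus.

    ``alleles`` is an optional list of (allele_a, allele_b) pairs; the
    dosage counts allele_b (the risk allele when built from a weight
    table).
    """
    freqs = np.asarray(freqs, dtype=float)
    if not ((freqs > 0.0) & (freqs < 1.0)).all():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    m = freqs.size
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(m)]
    if alleles is None:
        alleles = [("A", "G")] * m
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    variants = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "allele_a": [a for a, _ in alleles],
            "allele_b": [b for _, b in alleles],
            "is_x": [False] * m,
        }
    )
    sample_ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


def genotypes_from_table(
    table: WeightTable, n: int, rng: np.random.Generator,
    control_freqs: bool = False, sample_prefix: str = "S",
) -> GenotypeMatrix:
    """HWE genotypes at the weight table's risk-allele frequencies
    (case RAFs, or the implied control frequencies)."""
    freqs = np.array(
        [
            derive_control_freq(v.raf, v.or_sle) if control_freqs else v.raf
            for v in table
        ]
    )
    return simulate_genotypes(
        freqs,
        n,
        rng,
        snp_ids=[v.snp_id for v in table],
        alleles=[(v.other_allele, v.risk_allele) for v in table],
        sample_prefix=sample_prefix,
    )


def calibrate_intercept(
    linear_predictors, target_prevalence: float, tol: float = 1e-6, max_iter: int = 200
) -> float:
    """Bisection solve of mean(expit(alpha + eta)) = target."""
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target prevalence must be in (0, 1)")
    eta = np.asarray(linear_predictors, dtype=float)
    lo, hi = -50.0, 50.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        prev = float(expit(mid + eta).mean())
        if abs(prev - target_prevalence) < tol:
            return mid
        if prev < target_prevalence:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"intercept calibration did not converge to prevalence {target_prevalence}"
    )


def _draw_hla(
    n: int, weights: dict, rng: np.random.Generator
) -> pd.DataFrame:
    """Stratum labels and consistent tag-SNP dosages."""
    names = ["neg_neg", "single_pos", "double_pos"]
    probs = np.array([weights.get(k, 0.0) for k in names])
    probs = probs / probs.sum()
    strata = rng.choice(names, size=n, p=probs)
    t03 = np.zeros(n, dtype=int)
    t15 = np.zeros(n, dtype=int)
    single = strata == "single_pos"
    which = rng.integers(0, 2, size=n).astype(bool)
    t03[single & which] = 1
    t15[single & ~which] = 1
    double = strata == "double_pos"
    t03[double] = 1
    t15[double] = 1
    return pd.DataFrame(
        {"hla_group": strata, "tag_rs1269852": t03, "tag_rs3135388": t15}
    )


def _lognormal(params: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    vals = rng.lognormal(mean=np.log(params["median"]), sigma=params["sigma"], size=n)
    if "min" in params or "max" in params:
        vals = np.clip(vals, params.get("min", 0.0), params.get("max", np.inf))
    return vals


def simulate_phenotypes(
    exposures: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw patient phenotypes given exposure indicators.

    ``exposures`` is indexed by sample_id with binary columns
    ``bcell_high`` and ``activation_high``. Binary outcomes follow
    logistic models whose exposure log-odds come from the config's effect
    spec (stratum-specific entries override cohort-wide ones; outcomes
    with no entry are null) and whose intercepts are calibrated to the
    configured marginal prevalences. Time to LN onset is exponential with
    a proportional-hazards effect of dsDNA status and independent
    exponential censoring.
    """
    n = len(exposures)
    pheno = pd.DataFrame(index=exposures.index.copy())
    pheno["is_case"] = 1
    hla = _draw_hla(n, config.hla_stratum_weights, rng)
    for col in hla.columns:
        pheno[col] = hla[col].to_numpy()
    duration = _lognormal(config.duration_lognormal, n, rng)
    age = _lognormal(config.age_at_onset_lognormal, n, rng)
    pheno["disease_duration"] = duration
    pheno["age_at_onset"] = age
    dur_c = config.duration_beta * (duration - duration.mean())

    available = {c: exposures[c].to_numpy(dtype=float) for c in exposures.columns}
    strata = pheno["hla_group"].to_numpy()

    outcome_order = list(config.prevalences)
    if "ln" not in outcome_order and "renal" in config.prevalences:
        outcome_order.append("ln")  # LN column driven by dsDNA status
    # dsDNA must be drawn before outcomes that depend on it.
    if "dsdna" in outcome_order:
        outcome_order.remove("dsdna")
        outcome_order.insert(0, "dsdna")

    for outcome in outcome_order:
        target = config.prevalences.get(
            outcome, config.prevalences.get("renal")
        )
        eta = np.zeros(n) + dur_c
        for exposure, vec in available.items():
            base = config.effect(outcome, exposure, None)
            per_stratum = {
                s: config.effect(outcome, exposure, s)
                for s in ("neg_neg", "single_pos", "double_pos")
            }
            if base is None and not any(per_stratum.values()):
                continue
            log_or = np.full(n, np.log(base.value) if base else 0.0)
            for s, spec in per_stratum.items():
                if spec is not None:
                    log_or[strata == s] = np.log(spec.value)
            eta += log_or * vec
        alpha = calibrate_intercept(eta, target)
        y = rng.random(n) < expit(alpha + eta)
        pheno[outcome] = y.astype(int)
        available[outcome] = y.astype(float)

    # Survival: exponential LN onset, dsDNA proportional hazard.
    hr_spec = config.effect("time_to_ln", "dsdna")
    log_hr = np.log(hr_spec.value) if hr_spec else 0.0
    lam = config.survival["baseline_rate"] * np.exp(
        log_hr * available.get("dsdna", np.zeros(n))
        + config.age_beta * (age - age.mean())
    )
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.exponential(1.0 / config.survival["censoring_rate"], size=n)
    pheno["time_to_ln"] = np.minimum(t_event, t_cens)
    pheno["ln_event"] = (t_event <= t_cens).astype(int)
    return pheno


def generate_cohort(config: CohortConfig = None, seed: int = 0) -> SyntheticCohort:
    """Full synthetic cohort: case/control genotypes, patient phenotypes.

    Cases carry genotypes at the table's patient risk-allele frequencies,
    controls at the implied control frequencies; phenotypes are generated
    for cases only (controls emulate blood donors without clinical data).
    """
    if config is None:
        config = CohortConfig.default()
    rng = np.random.default_rng(seed)
    table = config.weight_table
    cases = genotypes_from_table(table, config.n_cases, rng, sample_prefix="case")
    controls = genotypes_from_table(
        table, config.n_controls, rng, control_freqs=True, sample_prefix="ctrl"
    )
    dosages = np.vstack([cases.dosages, controls.dosages])
    genotypes = GenotypeMatrix(
        sample_ids=cases.sample_ids + controls.sample_ids,
        variants=cases.variants,
        dosages=dosages,
        annotated_sex={s: "female" for s in cases.sample_ids + controls.sample_ids},
    )

    case_g = genotypes.subset(sample_ids=cases.sample_ids)
    exposures = pd.DataFrame(index=pd.Index(cases.sample_ids, name="sample_id"))
    for pathway, col in (("bcell", "bcell_high"), ("bcell_activation", "activation_high")):
        prof = compute_prs(case_g, table, pathway)
        grp = classify_quartiles(prof, pathway)
        exposures[f"prs_{pathway}"] = prof["score"]
        exposures[col] = (grp["group"] == "high").astype(int)

    pheno_cases = simulate_phenotypes(exposures[["bcell_high", "activation_high"]], config, rng)
    pheno_cases = exposures.join(pheno_cases)
    pheno_controls = pd.DataFrame(
        index=pd.Index(controls.sample_ids, name="sample_id")
    )
    pheno_controls["is_case"] = 0
    phenotypes = pd.concat([pheno_cases, pheno_controls])

    truth = {"seed": seed, "config": config.to_dict()}
    return SyntheticCohort(genotypes=genotypes, phenotypes=phenotypes, truth=truth)


def simulate_case_control(
    config: CohortConfig, rng: np.random.Generator, exposure: str = "bcell_high"
) -> pd.DataFrame:
    """Indicator-mode case-control draw for the disease-prevalence analysis.

    A common pool of n_cases + n_controls genomes is drawn at the control
    allele frequencies; case status then follows a logistic model on the
    fourth-quartile PRS indicator with the configured true odds ratio,
    calibrated so the expected case fraction matches the design.
    """
    n = config.n_cases + config.n_controls
    table = config.weight_table
    g = genotypes_from_table(table, n, rng, control_freqs=True)
    pathway = "bcell" if exposure == "bcell_high" else "bcell_activation"
    prof = compute_prs(g, table, pathway)
    grp = classify_quartiles(prof, pathway)
    high = (grp["group"] == "high").astype(float).to_numpy()
    spec = config.effect("sle", exposure)
    log_or = np.log(spec.value) if spec else 0.0
    eta = log_or * high
    alpha = calibrate_intercept(eta, config.n_cases / n)
    case = (rng.random(n) < expit(alpha + eta)).astype(int)
    return pd.DataFrame(
        {"case": case, exposure: high.astype(int), "score": prof["score"].to_numpy()},
        index=prof.index,
    )
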