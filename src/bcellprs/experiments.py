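"""Parameter-recovery experiments on synthetic cohorts.

Each function generates replicate cohorts with a single known true effect
(taken from the packaged default configuration unless overridden),
re-estimates it with the association module, and returns the recovered
log-effects. Exponentiating their mean gives the geometric-mean recovered
OR / HR, the quantity used to validate the analysis chain against its
generating truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .association import SeparationError, cox_assoc, logistic_assoc
from .scoring import classify_quartiles, compute_prs
from .simulate import CohortConfig, calibrate_intercept, genotypes_from_table, simulate_case_control

PATHWAY_FOR_EXPOSURE = {"bcell_high": "bcell", "activation_high": "bcell_activation"}


def _child_rngs(seed: int, n: int):
    """Independent per-replicate generators derived from one base seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def recover_sle_or(
    config: CohortConfig, n_reps: int = 200, seed: int = 1, exposure: str = "bcell_high"
) -> np.ndarray:
    """Case-control replicates: case status ~ high-PRS indicator.

    Each replicate draws a pool of n_cases + n_controls genomes at the
    control frequencies, binarises the pathway PRS at its fourth quartile,
    assigns case status from the configured true OR, and refits the
    crude logistic association (the disease model has no duration).
    """
    lors = []
    for rng in _child_rngs(seed, n_reps):
        df = simulate_case_control(config, rng, exposure=exposure)
        res = logistic_assoc(df["case"], df[exposure])
        lors.append(np.log(res.estimate))
    return np.asarray(lors)


def _patient_exposure(config, n, rng, exposure):
    """High-PRS indicator (or dsDNA status) for one simulated patient set."""
    if exposure == "dsdna":
        prev = config.prevalences["dsdna"]
        return (rng.random(n) < prev).astype(float)
    pathway = PATHWAY_FOR_EXPOSURE[exposure]
    g = genotypes_from_table(config.weight_table, n, rng)
    prof = compute_prs(g, config.weight_table, pathway)
    grp = classify_quartiles(prof, pathway)
    return (grp["group"] == "high").to_numpy().astype(float)


def recover_outcome_or(
    config: CohortConfig,
    outcome: str,
    exposure: str,
    n_reps: int = 200,
    seed: int = 1,
    stratum: str = None,
    n: int = None,
) -> np.ndarray:
    """Patient-cohort replicates: one binary outcome ~ one exposure.

    The outcome is drawn from a logistic model with the configured true
    log-odds on the exposure plus the duration nuisance effect, intercept
    calibrated to the outcome's marginal prevalence; the fit adjusts for
    duration, mirroring the analysis battery. Stratum-specific effects use
    the configured stratum size by default. Replicates where the fit is
    not estimable (separation at small n) are skipped; the returned array
    holds the estimable log-ORs.
    """
    spec = config.effect(outcome, exposure, stratum)
    if spec is None:
        raise KeyError(f"no configured effect for {outcome} ~ {exposure} [{stratum}]")
    if n is None:
        if stratum is None:
            n = config.n_cases
        else:
            n = int(round(config.hla_stratum_weights[stratum] * config.n_cases))
    prev = config.prevalences.get(outcome, config.prevalences.get("renal"))
    true_lor = np.log(spec.value)
    lors = []
    for rng in _child_rngs(seed, n_reps):
        x = _patient_exposure(config, n, rng, exposure)
        duration = rng.lognormal(
            np.log(config.duration_lognormal["median"]),
            config.duration_lognormal["sigma"],
            n,
        )
        eta = true_lor * x + config.duration_beta * (duration - duration.mean())
        alpha = calibrate_intercept(eta, prev)
        y = (rng.random(n) < expit(alpha + eta)).astype(int)
        try:
            res = logistic_assoc(y, x, duration)
        except (ValueError, SeparationError):
            continue
        lors.append(np.log(res.estimate))
    return np.asarray(lors)


def recover_ln_hr(
    config: CohortConfig, n_reps: int = 200, seed: int = 1, n: int = None
) -> np.ndarray:
    """Survival replicates: time to LN onset ~ dsDNA status.

    Exponential onset times with the configured true log-hazard on dsDNA
    and the age-at-onset nuisance effect, independent exponential
    censoring; the Cox fit adjusts for age at onset.
    """
    spec = config.effect("time_to_ln", "dsdna")
    true_lhr = np.log(spec.value)
    if n is None:
        n = config.n_cases
    prev = config.prevalences["dsdna"]
    lhrs = []
    for rng in _child_rngs(seed, n_reps):
        dsdna = (rng.random(n) < prev).astype(float)
        age = rng.lognormal(
            np.log(config.age_at_onset_lognormal["median"]),
            config.age_at_onset_lognormal["sigma"],
            n,
        )
        lam = config.survival["baseline_rate"] * np.exp(
            true_lhr * dsdna + config.age_beta * (age - age.mean())
        )
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.exponential(1.0 / config.survival["censoring_rate"], n)
        t = np.minimum(t_event, t_cens)
        e = (t_event <= t_cens).astype(int)
        res = cox_assoc(t, e, dsdna, age)
        lhrs.append(np.log(res.estimate))
    return np.asarray(lhrs)


def renal_prevalence(config: CohortConfig, n: int = 100_000, seed: int = 42) -> float:
    """Marginal renal-disorder prevalence in one large simulated patient
    cohort (calibration check of the generator)."""
    from .simulate import simulate_phenotypes

    rng = np.random.default_rng(seed)
    g = genotypes_from_table(config.weight_table, n, rng)
    exposures = pd.DataFrame(index=pd.Index(g.sample_ids, name="sample_id"))
    for pathway, col in (("bcell", "bcell_high"), ("bcell_activation", "activation_high")):
        prof = compute_prs(g, config.weight_table, pathway)
        grp = classify_quartiles(prof, pathway)
        exposures[col] = (grp["group"] == "high").astype(int)
    pheno = simulate_phenotypes(exposures, config, rng)
    return float(pheno["renal"].mean())


def geometric_mean_effect(log_effects: np.ndarray) -> float:
    return float(np.exp(np.mean(log_effects)))
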