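"""Case-control and within-patient association analyses.

Reproduces the analysis battery of the B cell PRS study design: Student's
t-tests on mean scores, duration-adjusted logistic regression of clinical
manifestations on the high/low PRS indicator (overall and within HLA
tag-SNP strata), and age-adjusted Cox regression of time to lupus
nephritis onset. Effects are reported as OR or HR with Wald 95% CIs,
complete cases only, no multiplicity adjustment (the number of tests run
is recorded instead).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

logger = logging.getLogger(__name__)

HLA_GROUPS = ("neg_neg", "single_pos", "double_pos")


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation in a logistic fit.

    The maximum-likelihood estimate diverges; consider an exact or
    penalised (Firth) fit instead of trusting Wald output.
    """


@dataclass
class AssociationResult:
    effect_type: str  # "OR", "HR" or "mean_diff"
    estimate: float
    ci95: tuple
    p: float
    n: int
    covariates: list = field(default_factory=list)

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.estimate <= hi):
            raise ValueError("estimate outside its confidence interval")


def hla_group_assign(pheno: pd.DataFrame) -> pd.Series:
    """Assign HLA-DRB1*03:01/*15:01 carrier strata from tag-SNP dosages.

    Dominant coding on tag SNPs rs1269852 (DRB1*03:01) and rs3135388
    (DRB1*15:01): carrying neither tag allele -> ``neg_neg``, exactly one
    -> ``single_pos``, both -> ``double_pos``. Samples missing either tag
    dosage are left unassigned (NaN) and logged.
    """
    t03 = pheno["tag_rs1269852"]
    t15 = pheno["tag_rs3135388"]
    pos03 = t03 >= 1
    pos15 = t15 >= 1
    group = pd.Series(
        np.select(
            [pos03 & pos15, ~pos03 & ~pos15],
            ["double_pos", "neg_neg"],
            default="single_pos",
        ),
        index=pheno.index,
        name="hla_group",
    )
    missing = t03.isna() | t15.isna()
    if missing.any():
        logger.info("%d samples lack tag-SNP dosages; unassigned", int(missing.sum()))
        group[missing] = np.nan
    return group


def compare_means_ttest(scores_a, scores_b) -> AssociationResult:
    """Two-sample pooled-variance Student's t-test on mean scores."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = float(a.mean() - b.mean())
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    se = math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    if se == 0.0:
        # zero pooled variance: equal-mean convention
        p = 1.0 if diff == 0.0 else 0.0
        return AssociationResult("mean_diff", diff, (diff, diff), max(p, np.finfo(float).tiny), a.size + b.size)
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(0.975, df) * se)
    return AssociationResult(
        "mean_diff", diff, (diff - half, diff + half), p, int(a.size + b.size)
    )


def _fit_logit(y: np.ndarray, X: np.ndarray):
    import warnings

    try:
        model = sm.Logit(y, X)
        with warnings.catch_warnings():
            # divergence is detected below from the fitted parameters;
            # statsmodels' convergence chatter adds nothing
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and kin
        raise SeparationError(
            f"logistic fit failed ({exc}); data may be perfectly separated - "
            "consider an exact or penalised (Firth) fit"
        ) from exc
    if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 15.0:
        raise SeparationError(
            "diverging logistic estimate (|beta| > 15 or infinite SE); "
            "perfect separation suspected - consider an exact or penalised fit"
        )
    return res


def logistic_assoc(
    outcome, exposure, covariate=None, covariate_name: str = "disease_duration"
) -> AssociationResult:
    """Logistic regression of a binary outcome on a binary exposure.

    Complete cases only. The exposure effect is reported as an odds ratio
    with Wald 95% CI; an optional continuous covariate (disease duration
    in the standard battery) is adjusted for but not reported.
    """
    y = pd.Series(np.asarray(outcome, dtype=float))
    x = pd.Series(np.asarray(exposure, dtype=float))
    cols = {"y": y, "x": x}
    covars = []
    if covariate is not None:
        cols["cov"] = pd.Series(np.asarray(covariate, dtype=float))
        covars = [covariate_name]
    df = pd.DataFrame(cols).dropna()
    if df["y"].nunique() < 2:
        raise ValueError("outcome has a single class among complete cases")
    if df["x"].nunique() < 2:
        raise ValueError("exposure has a single level among complete cases")
    X = sm.add_constant(df.drop(columns="y").to_numpy())
    res = _fit_logit(df["y"].to_numpy(), X)
    beta = res.params[1]
    se = res.bse[1]
    z = stats.norm.ppf(0.975)
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
    return AssociationResult(
        "OR",
        float(np.exp(beta)),
        (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        max(p, np.finfo(float).tiny),
        int(len(df)),
        covariates=covars,
    )


def stratified_assoc(
    outcome, exposure, covariate, strata: pd.Series
) -> pd.DataFrame:
    """One logistic association per stratum; no pooling, no interaction.

    Strata whose data cannot support the fit (single outcome class,
    separation, ...) are reported as not estimable rather than aborting
    the others. Returns one row per stratum.
    """
    y = pd.Series(np.asarray(outcome, dtype=float))
    x = pd.Series(np.asarray(exposure, dtype=float))
    cov = pd.Series(np.asarray(covariate, dtype=float)) if covariate is not None else None
    s = pd.Series(strata).reset_index(drop=True)
    rows = []
    for name in sorted(s.dropna().unique()):
        mask = (s == name).to_numpy()
        try:
            res = logistic_assoc(
                y[mask], x[mask], cov[mask] if cov is not None else None
            )
            rows.append(
                {
                    "stratum": name,
                    "estimable": True,
                    "n": res.n,
                    "estimate": res.estimate,
                    "ci_lo": res.ci95[0],
                    "ci_hi": res.ci95[1],
                    "p": res.p,
                    "note": "",
                }
            )
        except (ValueError, SeparationError) as exc:
            rows.append(
                {
                    "stratum": name,
                    "estimable": False,
                    "n": int(mask.sum()),
                    "estimate": np.nan,
                    "ci_lo": np.nan,
                    "ci_hi": np.nan,
                    "p": np.nan,
                    "note": str(exc),
                }
            )
    return pd.DataFrame(rows)


def cox_assoc(
    time, event, exposure, covariate=None, covariate_name: str = "age_at_onset"
) -> AssociationResult:
    """Cox proportional-hazards fit (Breslow ties) for a binary exposure.

    Reports the exposure hazard ratio with Wald 95% CI, optionally
    adjusted for a continuous covariate (age at onset in the standard
    battery).
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=float),
            "x": np.asarray(exposure, dtype=float),
        }
    )
    covars = []
    if covariate is not None:
        df["cov"] = np.asarray(covariate, dtype=float)
        covars = [covariate_name]
    df = df.dropna()
    events_by_group = df.groupby("x")["event"].sum()
    if len(events_by_group) < 2 or (events_by_group < 1).any():
        raise ValueError("need at least one event in each exposure group")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise ValueError(
            f"Cox fit failed ({exc}); the partial likelihood may be "
            "monotone (non-overlapping risk sets)"
        ) from exc
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = stats.norm.ppf(0.975)
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
    return AssociationResult(
        "HR",
        math.exp(beta),
        (math.exp(beta - z * se), math.exp(beta + z * se)),
        max(p, np.finfo(float).tiny),
        int(len(df)),
        covariates=covars,
    )


# ---------------------------------------------------------------------------
# Analysis battery

#: Table-style battery: every manifestation against the high B cell PRS
#: indicator, duration-adjusted.
DEFAULT_BATTERY = (
    [
        {"outcome": o, "exposure": "bcell_high", "model": "logistic"}
        for o in (
            "malar_rash", "discoid_rash", "photosensitivity", "oral_ulcer",
            "arthritis", "serositis", "renal", "neurological",
            "haematological", "immunological", "ana", "dsdna", "sm",
            "low_complement",
        )
    ]
    + [
        {"outcome": o, "exposure": "bcell_high", "model": "logistic",
         "stratify": "hla_group"}
        for o in ("immunological", "dsdna", "low_complement")
    ]
    + [
        {"outcome": "renal", "exposure": "activation_high", "model": "logistic"},
        {"outcome": "ln", "exposure": "dsdna", "model": "logistic"},
        {"outcome": "time_to_ln", "exposure": "dsdna", "model": "cox"},
    ]
)


def run_analysis_battery(
    pheno: pd.DataFrame, exposures: pd.DataFrame, battery=None
) -> pd.DataFrame:
    """Run a configured set of associations and return a tidy results table.

    ``pheno`` holds outcome columns, ``disease_duration``, ``age_at_onset``
    and (for Cox rows) ``time_to_ln`` / ``ln_event``; ``exposures`` holds
    the binary exposure indicators (``bcell_high``, ``activation_high``)
    aligned on the same index. ``battery`` rows are dicts with keys
    ``outcome``, ``exposure``, ``model`` ("logistic" or "cox") and an
    optional ``stratify`` column name.
    """
    if battery is None:
        battery = DEFAULT_BATTERY
    data = pheno.join(exposures, how="inner", rsuffix="_exp")
    if "hla_group" not in data.columns and {
        "tag_rs1269852", "tag_rs3135388"
    } <= set(data.columns):
        data["hla_group"] = hla_group_assign(data)
    rows = []
    for spec in battery:
        outcome = spec["outcome"]
        exposure = spec["exposure"]
        model = spec.get("model", "logistic")
        stratify = spec.get("stratify")
        if exposure not in data.columns:
            raise KeyError(f"unknown exposure column {exposure!r}")
        if model == "cox":
            if outcome != "time_to_ln":
                raise KeyError(f"unknown survival outcome {outcome!r}")
            try:
                res = cox_assoc(
                    data["time_to_ln"], data["ln_event"], data[exposure],
                    data.get("age_at_onset"),
                )
                rows.append(_row(outcome, exposure, "all", res))
            except ValueError as exc:
                rows.append(_na_row(outcome, exposure, "all", len(data), exc))
            continue
        if outcome not in data.columns:
            raise KeyError(f"unknown outcome column {outcome!r}")
        duration = data.get("disease_duration")
        if stratify:
            strat = stratified_assoc(
                data[outcome].reset_index(drop=True),
                data[exposure].reset_index(drop=True),
                duration.reset_index(drop=True) if duration is not None else None,
                data[stratify].reset_index(drop=True),
            )
            for r in strat.itertuples():
                if r.estimable:
                    rows.append(
                        {
                            "outcome": outcome, "exposure": exposure,
                            "stratum": r.stratum, "model": "logistic",
                            "n": r.n, "effect_type": "OR",
                            "estimate": r.estimate, "ci_lo": r.ci_lo,
                            "ci_hi": r.ci_hi, "p": r.p, "estimable": True,
                            "note": "",
                        }
                    )
                else:
                    rows.append(
                        {
                            "outcome": outcome, "exposure": exposure,
                            "stratum": r.stratum, "model": "logistic",
                            "n": r.n, "effect_type": "OR",
                            "estimate": np.nan, "ci_lo": np.nan,
                            "ci_hi": np.nan, "p": np.nan,
                            "estimable": False, "note": r.note,
                        }
                    )
        else:
            try:
                res = logistic_assoc(data[outcome], data[exposure], duration)
                rows.append(_row(outcome, exposure, "all", res))
            except (ValueError, SeparationError) as exc:
                rows.append(_na_row(outcome, exposure, "all", len(data), exc))
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(out)
    logger.info("analysis battery: %d tests run, no multiplicity adjustment", len(out))
    return out


def _row(outcome, exposure, stratum, res: AssociationResult) -> dict:
    return {
        "outcome": outcome, "exposure": exposure, "stratum": stratum,
        "model": "cox" if res.effect_type == "HR" else "logistic",
        "n": res.n, "effect_type": res.effect_type, "estimate": res.estimate,
        "ci_lo": res.ci95[0], "ci_hi": res.ci95[1], "p": res.p,
        "estimable": True, "note": "",
    }


def _na_row(outcome, exposure, stratum, n, exc) -> dict:
    return {
        "outcome": outcome, "exposure": exposure, "stratum": stratum,
        "model": "logistic", "n": n, "effect_type": "OR",
        "estimate": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
        "estimable": False, "note": str(exc),
    }


def format_result(res_row) -> str:
    """Render one battery row in 'estimate (lo to hi), p' style."""
    if not res_row["estimable"]:
        return "not estimable"
    return (
        f"{res_row['estimate']:.2f} ({res_row['ci_lo']:.2f} to "
        f"{res_row['ci_hi']:.2f}), p={res_row['p']:.3g}"
    )
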