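"""Sample- and variant-level genotype quality control.

The QC chain runs in a fixed order: sample call rate, PCA outlier removal,
IBD relatedness pruning, heterozygosity outliers, X-chromosome sex check,
then variant-level filters (call rate, MAF, Hardy-Weinberg exact test).
Each stage operates on the samples surviving the previous ones, and every
exclusion records the stage and reason.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

# Study-default thresholds.
SAMPLE_CALL_RATE_MIN = 0.95
VARIANT_CALL_RATE_MIN = 0.98
MAF_MIN = 0.01
HWE_P_MIN = 1e-4
IBD_MAX = 0.1875
HET_SD_MAX = 5.0
PCA_SD_MAX = 5.0
SEX_F_MALE_MIN = 0.8
SEX_F_FEMALE_MAX = 0.2
LD_R2_MAX = 0.2


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity as the minor-allele total) whose
    conditional probability does not exceed the observed one. Probabilities
    are evaluated in exact integer arithmetic, so ties are resolved
    exactly; the returned p-value lies in (0, 1].
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0  # monomorphic: single attainable configuration

    # Unnormalised conditional weight of het count h:
    #   W(h) = 2^h * n! / (n_aa! h! n_bb!)  with the same allele totals,
    # built by the exact integer recurrence
    #   W(h+2) = W(h) * 4 * aa(h) * bb(h) / ((h+1)(h+2)).
    h0 = rare % 2
    aa0 = (n_a - h0) // 2
    bb0 = (n_b - h0) // 2
    w = (
        2**h0
        * math.factorial(n)
        // (math.factorial(aa0) * math.factorial(h0) * math.factorial(bb0))
    )
    weights = {h0: w}
    aa, bb = aa0, bb0
    for h in range(h0, rare - 1, 2):
        w = w * 4 * aa * bb // ((h + 1) * (h + 2))
        aa -= 1
        bb -= 1
        weights[h + 2] = w
    total = sum(weights.values())
    w_obs = weights[n_ab]
    p_num = sum(v for v in weights.values() if v <= w_obs)
    return p_num / total


# ---------------------------------------------------------------------------
# Sample-level filters


def _call_rates(g: GenotypeMatrix) -> np.ndarray:
    return 1.0 - np.isnan(g.dosages).mean(axis=1)


def sample_call_rate_filter(
    g: GenotypeMatrix, threshold: float = SAMPLE_CALL_RATE_MIN
) -> pd.DataFrame:
    """Flag samples whose genotype call rate falls strictly below threshold."""
    if g.n_variants < 1:
        raise ValueError("genotype matrix has no variants")
    cr = _call_rates(g)
    excluded = cr < threshold
    return pd.DataFrame(
        {
            "call_rate": cr,
            "excluded": excluded,
            "reasons": [["low_call_rate"] if e else [] for e in excluded],
        },
        index=pd.Index(g.sample_ids, name="sample_id"),
    )


def heterozygosity_rates(g: GenotypeMatrix) -> pd.Series:
    """Fraction of heterozygous calls among non-missing autosomal genotypes."""
    auto = ~g.variants["is_x"].to_numpy(dtype=bool)
    d = g.dosages[:, auto]
    nonmiss = ~np.isnan(d)
    n_calls = nonmiss.sum(axis=1)
    n_het = np.nansum(d == 1.0, axis=1)
    with np.errstate(invalid="ignore"):
        rates = np.where(n_calls > 0, n_het / np.maximum(n_calls, 1), np.nan)
    return pd.Series(rates, index=pd.Index(g.sample_ids, name="sample_id"))


def heterozygosity_filter(
    g: GenotypeMatrix, sd_threshold: float = HET_SD_MAX
) -> pd.DataFrame:
    """Flag samples whose autosomal heterozygosity is > ``sd_threshold``
    standard deviations from the cohort mean."""
    if g.n_samples < 3:
        raise ValueError("need at least 3 samples for heterozygosity QC")
    rates = heterozygosity_rates(g)
    mean = rates.mean()
    sd = rates.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        excluded = np.zeros(len(rates), dtype=bool)
    else:
        excluded = (np.abs(rates - mean) > sd_threshold * sd).to_numpy()
    return pd.DataFrame(
        {
            "het_rate": rates,
            "excluded": excluded,
            "reasons": [["het_outlier"] if e else [] for e in excluded],
        },
        index=rates.index,
    )


def inbreeding_f(
    g: GenotypeMatrix, sample_id: str, x_only: bool = False
) -> float:
    """Method-of-moments inbreeding coefficient for one sample.

    F = (O_hom - E_hom) / (m - E_hom) where E_hom sums, over the sample's
    non-missing polymorphic markers, 1 - 2*p*q * 2n/(2n-1) with p the
    cohort allele frequency and n the cohort genotype count at the marker
    (the 2n/(2n-1) factor unbiases the heterozygosity estimate). On the X
    chromosome F separates males (~1) from females (~0).
    """
    mask = g.variants["is_x"].to_numpy(dtype=bool)
    cols = np.where(mask if x_only else ~mask)[0]
    if cols.size == 0:
        raise ValueError("no markers in requested subset")
    d = g.dosages[:, cols]
    row = d[g.sample_ids.index(sample_id)]
    n_geno = (~np.isnan(d)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_geno)
    usable = (
        ~np.isnan(row)
        & (n_geno > 1)
        & (p > 0.0)
        & (p < 1.0)
    )
    if not usable.any():
        raise ValueError(f"{sample_id}: no polymorphic markers with data")
    pu, nu, ru = p[usable], n_geno[usable], row[usable]
    e_hom = np.sum(1.0 - 2.0 * pu * (1.0 - pu) * (2.0 * nu) / (2.0 * nu - 1.0))
    o_hom = float(np.sum((ru == 0.0) | (ru == 2.0)))
    m = float(ru.size)
    denom = m - e_hom
    if denom == 0:
        raise ValueError(f"{sample_id}: degenerate expected homozygosity")
    return float((o_hom - e_hom) / denom)


def sex_check_filter(
    f_values: pd.Series, annotated_sex: dict
) -> pd.DataFrame:
    """Compare X-chromosome inbreeding F with annotated sex.

    A sample annotated male with F < 0.8, or annotated female with
    F > 0.2, is flagged sex-discordant. Unknown sex is never flagged.
    """
    rows = []
    for sid, f in f_values.items():
        sex = annotated_sex.get(sid, "unknown")
        discordant = (sex == "male" and f < SEX_F_MALE_MIN) or (
            sex == "female" and f > SEX_F_FEMALE_MAX
        )
        if sex == "unknown":
            logger.info("%s: unknown annotated sex, sex check skipped", sid)
        rows.append(
            {
                "sample_id": sid,
                "F": f,
                "annotated_sex": sex,
                "excluded": discordant,
                "reasons": ["sex_discordant"] if discordant else [],
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Relatedness (IBD)


@dataclass
class RelatednessEstimate:
    sample_pair: tuple
    pi_hat: float
    ibs_counts: tuple
    ibd_probs: tuple


def ibd_estimate(
    g: GenotypeMatrix, pair: tuple, min_overlap: int = 50
) -> RelatednessEstimate:
    """PLINK-style method-of-moments IBD estimate for one sample pair.

    Uses autosomal markers where both samples are called. Observed IBS
    counts are combined with the cohort allele frequencies to solve for
    P(IBD=0/1/2) moment by moment; component probabilities are truncated
    to [0, 1] and renormalised. pi_hat = P(IBD=2) + P(IBD=1)/2.
    """
    auto = ~g.variants["is_x"].to_numpy(dtype=bool)
    d = g.dosages[:, auto]
    i1 = g.sample_ids.index(pair[0])
    i2 = g.sample_ids.index(pair[1])
    d1, d2 = d[i1], d[i2]
    both = ~np.isnan(d1) & ~np.isnan(d2)
    if both.sum() < min_overlap:
        raise ValueError(
            f"insufficient markers: {int(both.sum())} overlapping calls "
            f"(< {min_overlap}) for pair {pair}"
        )
    n_geno = (~np.isnan(d)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_geno)
    poly = both & (p > 0.0) & (p < 1.0)
    d1, d2, p = d1[poly], d2[poly], p[poly]
    q = 1.0 - p

    ibs = 2.0 - np.abs(d1 - d2)
    # Heterozygote pairs are IBS2 regardless of phase under dosage coding.
    n0 = int((ibs == 0).sum())
    n1 = int((ibs == 1).sum())
    n2 = int((ibs == 2).sum())
    n = float(len(p))

    # Expected IBS class probabilities under each IBD state.
    e0_ibd0 = float(np.sum(2.0 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4.0 * p**3 * q + 4.0 * p * q**3))
    e2_ibd0 = n - e0_ibd0 - e1_ibd0
    e1_ibd1 = float(np.sum(2.0 * p**2 * q + 2.0 * p * q**2))
    e2_ibd1 = n - e1_ibd1

    # Sequential moment solve with truncation: each component is bounded
    # to [0, 1] before the next uses it, and P(IBD=2) is the complement.
    p0 = min(max(n0 / e0_ibd0 if e0_ibd0 > 0 else 0.0, 0.0), 1.0)
    p1 = (n1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p1 = min(max(p1, 0.0), 1.0 - p0)
    p2 = 1.0 - p0 - p1
    probs = np.array([p0, p1, p2])
    pi_hat = float(probs[2] + 0.5 * probs[1])
    return RelatednessEstimate(
        sample_pair=tuple(pair),
        pi_hat=pi_hat,
        ibs_counts=(n0, n1, n2),
        ibd_probs=tuple(float(x) for x in probs),
    )


def ibd_all_pairs(g: GenotypeMatrix, min_overlap: int = 50) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(g.sample_ids, 2):
        est = ibd_estimate(g, (a, b), min_overlap=min_overlap)
        rows.append(
            {
                "sample_1": a,
                "sample_2": b,
                "pi_hat": est.pi_hat,
                "ibs0": est.ibs_counts[0],
                "ibs1": est.ibs_counts[1],
                "ibs2": est.ibs_counts[2],
            }
        )
    return pd.DataFrame(rows, columns=["sample_1", "sample_2", "pi_hat", "ibs0", "ibs1", "ibs2"])


def relatedness_filter(
    estimates, call_rates: pd.Series, threshold: float = IBD_MAX
) -> set:
    """Greedy removal of related samples (pi_hat > threshold).

    Pairs are processed in descending pi_hat order; for each pair with
    both members still present, the member with the lower call rate is
    removed (ties: the later sample_id). Returns the removed sample set.
    """
    if isinstance(estimates, pd.DataFrame):
        pairs = [
            ((r.sample_1, r.sample_2), r.pi_hat) for r in estimates.itertuples()
        ]
    else:
        pairs = [(e.sample_pair, e.pi_hat) for e in estimates]
    pairs = [p for p in pairs if p[1] > threshold]
    pairs.sort(key=lambda x: (-x[1], x[0]))
    removed = set()
    for (a, b), _ in pairs:
        if a in removed or b in removed:
            continue
        cr_a = call_rates.get(a, 1.0)
        cr_b = call_rates.get(b, 1.0)
        if cr_a < cr_b:
            removed.add(a)
        elif cr_b < cr_a:
            removed.add(b)
        else:
            removed.add(max(a, b))
    return removed


# ---------------------------------------------------------------------------
# PCA outliers


def pca_outlier_filter(
    g: GenotypeMatrix,
    n_components: int = 10,
    sd_threshold: float = PCA_SD_MAX,
) -> pd.DataFrame:
    """Flag samples > ``sd_threshold`` SD from the mean on any top PC.

    Dosages are mean-imputed and standardised per variant before the
    decomposition. Outlier flagging is relative to the cohort itself.
    """
    if g.n_samples < n_components + 1:
        raise ValueError("need more samples than components")
    auto = ~g.variants["is_x"].to_numpy(dtype=bool)
    d = g.dosages[:, auto].copy()
    col_mean = np.nanmean(d, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(d))
    d[nan_rows, nan_cols] = col_mean[nan_cols]
    d -= col_mean
    sd = d.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("constant genotype matrix: PCA undefined")
    d = d[:, keep] / sd[keep]
    k = min(n_components, min(d.shape) - 1)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    mu = pcs.mean(axis=0)
    sigma = pcs.std(axis=0, ddof=1)
    sigma[sigma == 0] = np.inf
    z = np.abs(pcs - mu) / sigma
    with np.errstate(invalid="ignore"):
        outlier = (z > sd_threshold).any(axis=1)
    out = pd.DataFrame(
        pcs, index=pd.Index(g.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    out["excluded"] = outlier
    out["reasons"] = [["pca_outlier"] if e else [] for e in outlier]
    return out


# ---------------------------------------------------------------------------
# Variant-level filters


def variant_filters(
    g: GenotypeMatrix,
    call_thr: float = VARIANT_CALL_RATE_MIN,
    maf_thr: float = MAF_MIN,
    hwe_thr: float = HWE_P_MIN,
) -> pd.DataFrame:
    """Per-variant call-rate, MAF and HWE filters (strict thresholds)."""
    if g.n_samples < 1:
        raise ValueError("genotype matrix has no samples")
    rows = []
    is_x = g.variants["is_x"].to_numpy(dtype=bool)
    for j, snp_id in enumerate(g.variants["snp_id"]):
        d = g.dosages[:, j]
        called = d[~np.isnan(d)]
        call_rate = called.size / g.n_samples
        reasons = []
        if call_rate < call_thr:
            reasons.append("low_call_rate")
        maf = np.nan
        hwe_p = np.nan
        if called.size > 0:
            freq_b = called.sum() / (2.0 * called.size)
            maf = min(freq_b, 1.0 - freq_b)
            if maf < maf_thr:
                reasons.append("low_maf")
            if not is_x[j]:
                n_bb = int((called == 2).sum())
                n_ab = int((called == 1).sum())
                n_aa = int((called == 0).sum())
                hwe_p = hwe_exact_test(n_aa, n_ab, n_bb)
                if hwe_p < hwe_thr:
                    reasons.append("hwe_fail")
        rows.append(
            {
                "snp_id": snp_id,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "excluded": bool(reasons),
                "reasons": reasons,
            }
        )
    return pd.DataFrame(rows).set_index("snp_id")


# ---------------------------------------------------------------------------
# LD pruning


@dataclass
class LDPruneResult:
    kept: list
    removed: list  # (snp_id, partner_snp_id, r2)


def _pairwise_r2(g: GenotypeMatrix, snp_ids: list) -> pd.DataFrame:
    cols = {s: g.dosage_vector(s) for s in snp_ids}
    k = len(snp_ids)
    r2 = pd.DataFrame(np.zeros((k, k)), index=snp_ids, columns=snp_ids)
    for a, b in itertools.combinations(snp_ids, 2):
        da, db = cols[a], cols[b]
        both = ~np.isnan(da) & ~np.isnan(db)
        x, y = da[both], db[both]
        if x.size < 2 or x.std() == 0 or y.std() == 0:
            logger.warning("r2(%s, %s): zero-variance dosage, defined as 0", a, b)
            val = 0.0
        else:
            val = float(np.corrcoef(x, y)[0, 1] ** 2)
        r2.loc[a, b] = r2.loc[b, a] = val
    return r2


def ld_prune(
    g: GenotypeMatrix, table, r2_threshold: float = LD_R2_MAX
) -> LDPruneResult:
    """Greedy LD pruning keeping the highest-OR SNP per correlated pair.

    While any kept pair has squared dosage correlation above the
    threshold, the pair with the largest r-squared is resolved by dropping
    the member with the lower OR (ties: lower RAF, then the
    lexicographically later snp_id).
    """
    snp_ids = [v.snp_id for v in table]
    missing = [s for s in snp_ids if s not in set(g.variants["snp_id"])]
    if missing:
        raise KeyError(f"table SNPs absent from genotypes: {missing}")
    r2 = _pairwise_r2(g, snp_ids)
    info = {v.snp_id: v for v in table}
    kept = list(snp_ids)
    removed = []
    while True:
        best = None
        for a, b in itertools.combinations(kept, 2):
            val = r2.loc[a, b]
            if val > r2_threshold and (best is None or val > best[2]):
                best = (a, b, val)
        if best is None:
            break
        a, b, val = best
        # Drop the weaker member: lower OR, then lower RAF, then later id.
        va, vb = info[a], info[b]
        if va.or_sle != vb.or_sle:
            drop = a if va.or_sle < vb.or_sle else b
        elif va.raf != vb.raf:
            drop = a if va.raf < vb.raf else b
        else:
            drop = max(a, b)
        partner = b if drop == a else a
        kept.remove(drop)
        removed.append((drop, partner, float(val)))
    return LDPruneResult(kept=kept, removed=removed)


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class QCResult:
    samples: pd.DataFrame
    variants: pd.DataFrame
    pairs: pd.DataFrame
    filtered: GenotypeMatrix
    stages: dict = field(default_factory=dict)


def run_qc(
    g: GenotypeMatrix,
    sample_call_thr: float = SAMPLE_CALL_RATE_MIN,
    variant_call_thr: float = VARIANT_CALL_RATE_MIN,
    maf_thr: float = MAF_MIN,
    hwe_thr: float = HWE_P_MIN,
    ibd_thr: float = IBD_MAX,
    het_sd: float = HET_SD_MAX,
    pca_sd: float = PCA_SD_MAX,
    n_components: int = 10,
    run_pca: bool = True,
    run_ibd: bool = True,
    ibd_min_overlap: int = 50,
) -> QCResult:
    """Run the full QC chain in the standard order and return reports plus
    the filtered matrix.

    Order: sample call rate -> PCA outliers -> IBD relatedness ->
    heterozygosity -> sex check -> variant filters.
    """
    sample_report = sample_call_rate_filter(g, sample_call_thr)
    sample_report["stage"] = np.where(sample_report["excluded"], "call_rate", "")
    surviving = [s for s in g.sample_ids if not sample_report.loc[s, "excluded"]]
    stages = {"input": g.n_samples, "call_rate": len(surviving)}

    def mark(ids, reason, stage):
        for sid in ids:
            sample_report.at[sid, "excluded"] = True
            sample_report.at[sid, "reasons"] = list(
                sample_report.at[sid, "reasons"]
            ) + [reason]
            if not sample_report.at[sid, "stage"]:
                sample_report.at[sid, "stage"] = stage

    current = g.subset(sample_ids=surviving)

    if run_pca and current.n_samples > n_components:
        pca = pca_outlier_filter(current, n_components=n_components, sd_threshold=pca_sd)
        out = list(pca.index[pca["excluded"]])
        mark(out, "pca_outlier", "pca")
        surviving = [s for s in surviving if s not in set(out)]
        current = g.subset(sample_ids=surviving)
    stages["pca"] = len(surviving)

    pairs = pd.DataFrame(columns=["sample_1", "sample_2", "pi_hat", "ibs0", "ibs1", "ibs2"])
    if run_ibd and current.n_samples >= 2:
        pairs = ibd_all_pairs(current, min_overlap=ibd_min_overlap)
        cr = sample_report.loc[surviving, "call_rate"]
        related = relatedness_filter(pairs, cr, ibd_thr)
        mark(sorted(related), "related", "ibd")
        surviving = [s for s in surviving if s not in related]
        current = g.subset(sample_ids=surviving)
    stages["ibd"] = len(surviving)

    if current.n_samples >= 3:
        het = heterozygosity_filter(current, het_sd)
        sample_report.loc[het.index, "het_rate"] = het["het_rate"]
        out = list(het.index[het["excluded"]])
        mark(out, "het_outlier", "heterozygosity")
        surviving = [s for s in surviving if s not in set(out)]
        current = g.subset(sample_ids=surviving)
    stages["heterozygosity"] = len(surviving)

    if g.variants["is_x"].any() and g.annotated_sex:
        f_vals = pd.Series(
            {sid: inbreeding_f(current, sid, x_only=True) for sid in surviving}
        )
        sex = sex_check_filter(f_vals, g.annotated_sex)
        sample_report.loc[sex.index, "F_x"] = sex["F"]
        out = list(sex.index[sex["excluded"]])
        mark(out, "sex_discordant", "sex_check")
        surviving = [s for s in surviving if s not in set(out)]
        current = g.subset(sample_ids=surviving)
    stages["sex_check"] = len(surviving)

    variant_report = variant_filters(current, variant_call_thr, maf_thr, hwe_thr)
    kept_snps = list(variant_report.index[~variant_report["excluded"]])
    filtered = current.subset(snp_ids=kept_snps)
    stages["variants_kept"] = len(kept_snps)

    return QCResult(
        samples=sample_report,
        variants=variant_report,
        pairs=pairs,
        filtered=filtered,
        stages=stages,
    )
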