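"""PRS weight tables and per-sample score computation.

A polygenic risk score here is the weighted allele count

    PRS_j = sum_i  w_i * d_ij,     w_i = ln(OR_i),  d_ij in [0, 2]

over the variants of a pathway (the full B cell set or its B cell
activation subset), with protective alleles re-oriented so every weight is
non-negative. High/low grouping binarises the score at the 75th percentile
(fourth quartile = "high").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

PATHWAY_FLAGS = {
    "bcell": "in_bcell_prs",
    "bcell_activation": "in_bcell_activation_prs",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class WeightTableError(ValueError):
    """Raised for malformed or inconsistent weight tables."""


class AlleleMismatchError(ValueError):
    """Raised when a variant's alleles cannot be reconciled with the table."""


@dataclass(frozen=True)
class RiskVariant:
    """One PRS locus: risk allele, published odds ratio, pathway flags."""

    snp_id: str
    risk_allele: str
    other_allele: str
    raf: float
    or_sle: float
    gene: str
    in_bcell_prs: bool
    in_bcell_activation_prs: bool
    source: str = ""

    @property
    def weight(self) -> float:
        """ln(OR), computed at full double precision."""
        return math.log(self.or_sle)

    def flipped(self) -> "RiskVariant":
        """Swap risk/other allele, invert the OR, complement the RAF."""
        return replace(
            self,
            risk_allele=self.other_allele,
            other_allele=self.risk_allele,
            or_sle=1.0 / self.or_sle,
            raf=1.0 - self.raf,
        )


class WeightTable:
    """Ordered collection of :class:`RiskVariant` with pathway lookups."""

    def __init__(self, variants: Iterable[RiskVariant]):
        self.variants = list(variants)
        seen = set()
        for v in self.variants:
            if v.snp_id in seen:
                raise WeightTableError(f"duplicate snp_id: {v.snp_id}")
            seen.add(v.snp_id)
            if not (0.0 < v.raf < 1.0):
                raise WeightTableError(
                    f"{v.snp_id}: raf {v.raf} outside (0, 1)"
                )
            if v.or_sle <= 0.0:
                raise WeightTableError(f"{v.snp_id}: or_sle {v.or_sle} <= 0")
            if v.in_bcell_activation_prs and not v.in_bcell_prs:
                raise WeightTableError(
                    f"{v.snp_id}: activation flag set without B cell flag"
                )
        if not self.variants:
            raise WeightTableError("empty weight table")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def pathway_names(self):
        return set(PATHWAY_FLAGS)

    def pathway_variants(self, pathway: str) -> list:
        flag = PATHWAY_FLAGS.get(pathway)
        if flag is None:
            raise KeyError(f"unknown pathway {pathway!r}; choose from {sorted(PATHWAY_FLAGS)}")
        return [v for v in self.variants if getattr(v, flag)]

    def get(self, snp_id: str) -> RiskVariant:
        for v in self.variants:
            if v.snp_id == snp_id:
                return v
        raise KeyError(snp_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": v.snp_id,
                "risk_allele": v.risk_allele,
                "other_allele": v.other_allele,
                "raf": v.raf,
                "or_sle": v.or_sle,
                "weight": v.weight,
                "gene": v.gene,
                "in_bcell_prs": int(v.in_bcell_prs),
                "in_bcell_activation_prs": int(v.in_bcell_activation_prs),
                "source": v.source,
            }
            for v in self.variants
        ]
        return pd.DataFrame(rows)


REQUIRED_COLUMNS = [
    "snp_id",
    "risk_allele",
    "other_allele",
    "raf",
    "or_sle",
    "gene",
    "in_bcell_prs",
    "in_bcell_activation_prs",
    "source",
]


def load_weight_table(path) -> WeightTable:
    """Load and validate a TSV weight table.

    Expected columns: ``snp_id, risk_allele, other_allele, raf, or_sle,
    gene, in_bcell_prs, in_bcell_activation_prs, source``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise WeightTableError(f"weight table missing columns: {missing}")
    if df.empty:
        raise WeightTableError("empty weight table")
    variants = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            raf = float(row["raf"])
            or_sle = float(row["or_sle"])
        except ValueError as exc:
            raise WeightTableError(f"row {rownum}: non-numeric raf/or_sle") from exc
        if not (0.0 < raf < 1.0):
            raise WeightTableError(f"row {rownum} ({row['snp_id']}): raf {raf} outside (0, 1)")
        if or_sle <= 0.0:
            raise WeightTableError(f"row {rownum} ({row['snp_id']}): or_sle {or_sle} <= 0")
        variants.append(
            RiskVariant(
                snp_id=str(row["snp_id"]),
                risk_allele=str(row["risk_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                raf=raf,
                or_sle=or_sle,
                gene=str(row["gene"]),
                in_bcell_prs=bool(int(row["in_bcell_prs"])),
                in_bcell_activation_prs=bool(int(row["in_bcell_activation_prs"])),
                source=str(row["source"]),
            )
        )
    return WeightTable(variants)


def packaged_weight_table() -> WeightTable:
    """The 20-SNP B cell weight table shipped with the package."""
    ref = resources.files("bcellprs").joinpath("data/table2_weights.tsv")
    with resources.as_file(ref) as path:
        return load_weight_table(path)


def orient_weights(table: WeightTable) -> WeightTable:
    """Flip protective-coded variants so every OR is >= 1.

    A variant with OR < 1 is replaced by its complement-coded form (risk
    and other alleles swapped, OR inverted, RAF complemented), so risk
    directionality is consistently positive. OR exactly 1 contributes zero
    weight and is left in place with a logged note.
    """
    oriented = []
    for v in table:
        if v.or_sle < 1.0:
            oriented.append(v.flipped())
        else:
            if v.or_sle == 1.0:
                logger.info("%s: OR exactly 1, zero-weight variant", v.snp_id)
            oriented.append(v)
    return WeightTable(oriented)


def _is_ambiguous_pair(a: str, b: str) -> bool:
    return {a, b} in ({"A", "T"}, {"C", "G"})


def _resolve_orientation(variant: RiskVariant, allele_a: str, allele_b: str):
    """Return +1 if dosage (counting allele_b) counts the risk allele,
    -1 if it counts the other allele; handles strand flips for
    non-ambiguous pairs."""
    risk, other = variant.risk_allele, variant.other_allele
    if {allele_a, allele_b} == {risk, other}:
        return 1 if allele_b == risk else -1
    comp_risk = _COMPLEMENT.get(risk)
    comp_other = _COMPLEMENT.get(other)
    if comp_risk and {allele_a, allele_b} == {comp_risk, comp_other}:
        if _is_ambiguous_pair(risk, other):
            raise AlleleMismatchError(
                f"{variant.snp_id}: ambiguous strand (A/T or C/G) with "
                f"discordant allele labels {allele_a}/{allele_b} vs "
                f"{risk}/{other}"
            )
        logger.warning(
            "%s: strand flip applied (%s/%s vs table %s/%s)",
            variant.snp_id, allele_a, allele_b, risk, other,
        )
        return 1 if allele_b == comp_risk else -1
    raise AlleleMismatchError(
        f"{variant.snp_id}: alleles {allele_a}/{allele_b} irreconcilable "
        f"with table {risk}/{other}"
    )


def compute_prs(
    genotypes: GenotypeMatrix, table: WeightTable, pathway: str = "bcell"
) -> pd.DataFrame:
    """Per-sample pathway PRS.

    Missing dosages are imputed with the per-locus expectation ``2 * raf``
    and counted in ``n_missing_used``. Returns a DataFrame indexed by
    sample_id with columns ``score`` and ``n_missing_used``.
    """
    variants = table.pathway_variants(pathway)
    present = set(genotypes.variants["snp_id"])
    absent = [v.snp_id for v in variants if v.snp_id not in present]
    if absent:
        raise KeyError(f"pathway variants absent from genotypes: {absent}")

    n = genotypes.n_samples
    score = np.zeros(n)
    n_missing = np.zeros(n, dtype=int)
    for v in variants:
        col = genotypes.variant_index(v.snp_id)
        rec = genotypes.variants.iloc[col]
        sign = _resolve_orientation(v, str(rec["allele_a"]), str(rec["allele_b"]))
        d = genotypes.dosages[:, col]
        risk_dosage = d if sign == 1 else 2.0 - d
        miss = np.isnan(risk_dosage)
        risk_dosage = np.where(miss, 2.0 * v.raf, risk_dosage)
        score += v.weight * risk_dosage
        n_missing += miss.astype(int)
    return pd.DataFrame(
        {"score": score, "n_missing_used": n_missing},
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
    )


def classify_quartiles(scores, pathway: str = "bcell") -> pd.DataFrame:
    """High/low grouping at the 75th percentile.

    ``high`` means score strictly above the linear-interpolation (type-7)
    75th percentile; quartiles 1-3 are ``low``. Accepts a score Series /
    array or the DataFrame produced by :func:`compute_prs`.
    """
    if isinstance(scores, pd.DataFrame):
        s = scores["score"]
    elif isinstance(scores, pd.Series):
        s = scores.astype(float)
    else:
        s = pd.Series(np.asarray(scores, dtype=float))
    if len(s) < 4:
        raise ValueError("need at least 4 profiles to form quartiles")
    vals = s.to_numpy(dtype=float)
    if np.allclose(vals, vals[0]):
        raise ValueError("degenerate score distribution: all scores identical")
    q3 = float(np.percentile(vals, 75))
    out = pd.DataFrame(
        {
            "pathway_name": pathway,
            "group": np.where(vals > q3, "high", "low"),
            "q3_threshold": q3,
        },
        index=s.index,
    )
    out.index.name = "sample_id"
    return out


def summarize_scores(scores) -> dict:
    """Mean, 95% t-interval of the mean, SD and n of a score collection."""
    if isinstance(scores, pd.DataFrame):
        scores = scores["score"]
    vals = np.asarray(scores, dtype=float)
    n = vals.size
    if n < 2:
        raise ValueError("need at least 2 scores to summarize")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return {
        "mean": mean,
        "ci95": (mean - half, mean + half),
        "sd": sd,
        "n": int(n),
    }
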