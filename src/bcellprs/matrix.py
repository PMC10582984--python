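"""Genotype dosage matrix container.

Dosages count copies of ``allele_b`` (0/1/2), stored as floats with NaN
marking missing calls. Variant metadata travels in a pandas DataFrame so
QC and scoring can subset samples and variants without copying genotypes
more than once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b", "is_x"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with allele labels.

    Parameters
    ----------
    sample_ids : list of str
        Row labels, one per sample.
    variants : pandas.DataFrame
        One row per variant with columns ``snp_id, chrom, pos, allele_a,
        allele_b, is_x`` (positions 1-based, as in VCF).
    dosages : ndarray of float
        ``n_samples x n_variants``; each entry in {0, 1, 2, NaN}, counting
        copies of ``allele_b``.
    annotated_sex : dict, optional
        sample_id -> {"male", "female", "unknown"}.
    """

    sample_ids: list
    variants: pd.DataFrame
    dosages: np.ndarray
    annotated_sex: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        n_s, n_v = self.dosages.shape
        if n_s != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n_s} dosage rows"
            )
        if n_v != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variant records but {n_v} dosage columns"
            )
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns: {missing_cols}")
        ids = self.variants["snp_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate snp_ids: {dups}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, snp_id: str) -> int:
        idx = self.variants.index[self.variants["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(snp_id)
        return int(idx[0])

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        """Dosage column (copies of allele_b) for one variant."""
        return self.dosages[:, self.variant_index(snp_id)]

    def subset(self, sample_ids=None, snp_ids=None) -> "GenotypeMatrix":
        """Restrict to the given samples and/or variants (order preserved)."""
        row_idx = np.arange(self.n_samples)
        samples = self.sample_ids
        if sample_ids is not None:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            row_idx = np.array([pos[s] for s in sample_ids], dtype=int)
            samples = list(sample_ids)
        col_idx = np.arange(self.n_variants)
        variants = self.variants
        if snp_ids is not None:
            pos = {s: i for i, s in enumerate(self.variants["snp_id"])}
            col_idx = np.array([pos[s] for s in snp_ids], dtype=int)
            variants = self.variants.iloc[col_idx]
        return GenotypeMatrix(
            sample_ids=samples,
            variants=variants.reset_index(drop=True),
            dosages=self.dosages[np.ix_(row_idx, col_idx)],
            annotated_sex={s: self.annotated_sex.get(s, "unknown") for s in samples}
            if self.annotated_sex
            else {},
        )

    def to_dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.sample_ids, columns=list(self.variants["snp_id"])
        )
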