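"""Reading and writing genotype, phenotype and report files.

Genotypes come in as VCF (biallelic SNVs, dosage from GT) or as a TSV
dosage matrix with a sidecar variant table; both land in a
:class:`~bcellprs.matrix.GenotypeMatrix`. All outputs are plain text (TSV,
VCF, JSON) so runs diff cleanly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

_X_NAMES = {"X", "chrX", "23"}


def read_vcf(path, annotated_sex: dict = None) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a dosage matrix.

    Dosage counts ALT-allele copies; half-missing genotypes are treated
    as missing. Multi-allelic records raise.
    """
    from cyvcf2 import VCF  # deferred: htslib import is slow

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    rows = []
    for lineno, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: record {var.ID or var.POS} is not biallelic"
            )
        records.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "allele_a": var.REF,
                "allele_b": var.ALT[0],
                "is_x": var.CHROM in _X_NAMES,
            }
        )
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
    if not records:
        raise ValueError(f"{path}: no variant records")
    variants = pd.DataFrame(records)
    dosages = np.column_stack(rows)
    return GenotypeMatrix(
        sample_ids=samples,
        variants=variants,
        dosages=dosages,
        annotated_sex=annotated_sex or {},
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as an uncompressed VCF (GT only)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bcellprs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, rec in g.variants.iterrows():
            calls = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosages[:, j]
            ]
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{rec['snp_id']}\t"
                f"{rec['allele_a']}\t{rec['allele_b']}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_dosage_tsv(matrix_path, variants_path, annotated_sex: dict = None) -> GenotypeMatrix:
    """Read a TSV dosage matrix (first column sample_id, rsID header)
    plus a sidecar variant table (snp_id, chrom, pos, allele_a, allele_b,
    is_x)."""
    dm = pd.read_csv(matrix_path, sep="\t", index_col=0)
    variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    required = ["snp_id", "chrom", "pos", "allele_a", "allele_b", "is_x"]
    missing = [c for c in required if c not in variants.columns]
    if missing:
        raise ValueError(f"{variants_path}: missing columns {missing}")
    order = list(variants["snp_id"])
    absent = [s for s in order if s not in dm.columns]
    if absent:
        raise ValueError(f"{matrix_path}: dosage columns missing for {absent}")
    variants["is_x"] = variants["is_x"].astype(bool)
    return GenotypeMatrix(
        sample_ids=list(dm.index.astype(str)),
        variants=variants,
        dosages=dm[order].to_numpy(dtype=float),
        annotated_sex=annotated_sex or {},
    )


def write_dosage_tsv(g: GenotypeMatrix, matrix_path, variants_path) -> None:
    g.to_dosage_frame().to_csv(matrix_path, sep="\t", index_label="sample_id")
    g.variants.to_csv(variants_path, sep="\t", index=False)


def read_genotypes(path, variants_path=None, annotated_sex: dict = None) -> GenotypeMatrix:
    """Dispatch on extension: .vcf -> VCF reader, otherwise dosage TSV."""
    p = Path(path)
    if p.suffix.lower() == ".vcf":
        return read_vcf(p, annotated_sex=annotated_sex)
    if variants_path is None:
        raise ValueError("TSV dosage input requires a sidecar variant table")
    return read_dosage_tsv(p, variants_path, annotated_sex=annotated_sex)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
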