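"""Readers and writers for the on-disk interchange formats.

Dosages travel either as VCF 4.2 with a ``DS`` FORMAT field (one record per
SNP, GT omitted; ALT is the risk/counted allele) or as a plain TSV with rows
= individuals and columns = SNPs. Phenotypes are TSV with the header
``id status age sex pc1 pc2``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CohortTable, DosageMatrix
from .snp_panel import Panel

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
]


def write_dosage_tsv(dosages: DosageMatrix, path) -> None:
    df = pd.DataFrame(dosages.dosages, columns=list(dosages.snp_ids))
    df.insert(0, "id", dosages.individual_ids)
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path, cohort: str = "") -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"dosage TSV {path} lacks an 'id' column")
    ids = df.pop("id").to_numpy(dtype=object)
    return DosageMatrix(ids, np.array(df.columns, dtype=object), df.to_numpy(dtype=float), cohort=cohort)


def write_vcf(dosages: DosageMatrix, panel: Panel, path) -> None:
    """VCF 4.2 with one DS-only record per panel SNP; ALT is the risk allele."""
    chroms = dict.fromkeys(s.chrom for s in panel.snps)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected risk-allele dosage">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        samples = "\t".join(str(i) for i in dosages.individual_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for s in panel.snps:
            col = dosages.snp_column(s.rsid)
            ds = "\t".join(f"{v:.4g}" for v in col)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.rsid}\t{s.other_allele}\t{s.risk_allele}\t.\t.\t.\tDS\t{ds}\n")


def read_vcf(path, cohort: str = "") -> DosageMatrix:
    """Read a DS-dosage VCF into a matrix counting the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    rsids, cols = [], []
    for v in vcf:
        ds = v.format("DS")
        if ds is None:
            raise ValueError(f"{path}: record {v.ID} has no DS field")
        rsids.append(v.ID)
        cols.append(np.asarray(ds, dtype=float).reshape(-1))
    vcf.close()
    return DosageMatrix(ids, np.array(rsids, dtype=object), np.column_stack(cols), cohort=cohort)


def write_phenotypes(table: CohortTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_phenotypes(path, name: str = "") -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sex": str})
    return CohortTable.from_frame(df, name=name)
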