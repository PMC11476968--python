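"""Readers and writers for the tab-separated interchange formats.

Matrices travel as TSV with the row identifier in the first column; SNP and
CpG positions as BED-like tables with columns ``id``, ``chrom``, ``pos``
(1-based).  Genotype dosages may alternatively come from a VCF, using the
alternative-allele count of each genotype call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    """TSV matrix with the first column as index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_positions(path) -> pd.DataFrame:
    """Position table with columns id, chrom, pos (header required)."""
    tab = pd.read_csv(path, sep="\t")
    missing = {"id", "chrom", "pos"} - set(tab.columns)
    if missing:
        raise ValueError(f"position table lacks columns {sorted(missing)}")
    return tab


def read_vcf_dosages(path, exclude_multiallelic: bool = True) -> pd.DataFrame:
    """SNP x sample dosage matrix from a VCF (alt-allele counts, NaN for missing).

    Multi-allelic records and non-autosomal chromosomes X/Y are skipped by
    default, mirroring the scan's exclusions.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows = [], []
    for variant in vcf:
        if exclude_multiallelic and len(variant.ALT) != 1:
            continue
        chrom = variant.CHROM.removeprefix("chr")
        if chrom in ("X", "Y"):
            continue
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types.astype(float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        ids.append(name)
        rows.append(dosage)
    return pd.DataFrame(rows, index=ids, columns=samples)
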