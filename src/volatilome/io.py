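"""Readers and writers for the pipeline's plain-text formats.

Matrices and tidy tables travel as TSV (volatile names can contain commas);
genotypes as minimal VCF with a GT FORMAT field; dendrograms as Newick.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("volatilome")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_replicates",
    "write_replicates",
    "read_genotypes",
    "write_genotypes",
    "read_pairs",
    "write_pairs",
]

_NA_VALUES = ["", "NA"]


def _check_rectangular(path: Path) -> None:
    with open(path) as fh:
        header_fields = None
        for lineno, line in enumerate(fh, start=1):
            n_fields = line.rstrip("\n").count("\t") + 1
            if header_fields is None:
                header_fields = n_fields
            elif n_fields != header_fields:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({n_fields} fields, expected {header_fields})"
                )


def read_matrix(path) -> pd.DataFrame:
    """Samples x volatiles TSV: header of volatile ids, first column sample
    ids; empty cells or "NA" are missing. Errors name ragged lines and
    reject duplicate sample ids."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    df.index.name = "sample"
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_matrix`; missing cells written empty."""
    out = matrix.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep="")


def read_replicates(path) -> pd.DataFrame:
    """Tidy technical-replicate table (sample, volatile, run, area,
    area_istd, mass_istd, mass_powder)."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    required = {"sample", "volatile", "run", "area", "area_istd", "mass_istd", "mass_powder"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("area", "area_istd", "mass_istd", "mass_powder"):
        df[col] = df[col].astype(float)
    df["run"] = df["run"].astype(int)
    return df


def write_replicates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")


def write_genotypes(dosages: pd.DataFrame, path) -> None:
    """Write a samples x SNPs dosage frame as a minimal VCF (FORMAT=GT).

    Dosage 0 -> 0/0, 1 -> 0/1, 2 -> 1/1, NaN -> ./. ; SNPs are laid out on a
    single synthetic contig at consecutive positions.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    samples = list(dosages.index)
    n_snps = dosages.shape[1]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID=chr1,length={10 * (n_snps + 1)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        arr = dosages.to_numpy(dtype=float)
        for j, snp in enumerate(dosages.columns):
            calls = [
                gt_map.get(float(g), "./.") if not np.isnan(g) else "./."
                for g in arr[:, j]
            ]
            fh.write(
                f"chr1\t{10 * (j + 1)}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_genotypes(path) -> pd.DataFrame:
    """Read biallelic GT calls from a VCF into a samples x SNPs dosage frame.

    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> NaN; phased separators are
    equivalent. Multi-allelic records are skipped with a warning; a record
    without a GT FORMAT field is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if variant.FORMAT is None or "GT" not in variant.FORMAT:
            raise ValueError(f"{path}: record {variant.ID or variant.POS} lacks a GT field")
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping non-biallelic record %s (%d ALT alleles)",
                variant.ID or f"{variant.CHROM}:{variant.POS}",
                len(variant.ALT),
            )
            continue
        # with gts012: 0/1/2 = dosage of ALT, 3 = missing
        gt = variant.gt_types.astype(float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    return pd.DataFrame(np.array(rows).T, index=samples, columns=snp_ids)


def read_pairs(path) -> list[tuple[str, str]]:
    """Clone-pair list: TSV with columns sample_a, sample_b."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_a", "sample_b"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_a, sample_b")
    return list(zip(df["sample_a"].astype(str), df["sample_b"].astype(str)))


def write_pairs(pairs: list[tuple[str, str]], path) -> None:
    pd.DataFrame(pairs, columns=["sample_a", "sample_b"]).to_csv(path, sep="\t", index=False)
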