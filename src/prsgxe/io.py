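"""Readers and writers for the package's plain-text formats.

Genotypes: a subjects x variants TSV of effect-allele dosages in [0, 2],
or a VCF whose per-sample ``DS`` format field carries the ALT-allele
dosage (hard genotype calls are the fallback).  Weight tables and
phenotype tables are TSV; rate tables are CSV with columns
``age_start, age_end, rate_per_100k`` (registry-export-like).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .prs import WEIGHT_COLUMNS, validate_weight_table

PHENOTYPE_COLUMNS = ["case_status", "age", "bmi", "study", "pc1", "pc2", "pc3",
                     "mht_any", "mht_eonly", "mht_ep"]


class InputError(ValueError):
    """A file failed to parse or violated a table invariant."""


def read_weight_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    try:
        return validate_weight_table(df)
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_weight_table(weights: pd.DataFrame, path: str | Path) -> None:
    weights[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a dosage matrix TSV (first column ``subject_id``).

    Returns ``(genotypes, None)`` — a plain matrix carries no allele
    metadata, so the weight table's encoding is trusted as-is.
    """
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    arr = df.to_numpy(dtype=float)
    if arr.size == 0:
        raise InputError(f"{path}: empty genotype matrix")
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 2)
    if np.nansum(bad):
        raise InputError(f"{path}: dosages outside [0, 2]")
    return df, None


def write_genotype_tsv(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="subject_id", float_format="%.6g")


def read_genotype_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ALT-allele dosages from a VCF.

    Dosage comes from the ``DS`` format field when present, else from hard
    genotype calls.  Returns ``(genotypes, variant_meta)`` where the
    metadata frame records the counted (ALT) and other (REF) allele per
    variant for weight alignment.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise InputError(f"{path}: variant {var.ID or var.POS} is not biallelic")
        ds = var.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gts = np.asarray(var.genotypes, dtype=object)
            alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
            alleles[alleles < 0] = np.nan
            dose = alleles.sum(axis=1)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dose)
    vcf.close()
    if not rows:
        raise InputError(f"{path}: no variants")
    genotypes = pd.DataFrame(np.asarray(rows).T,
                             index=pd.Index(samples, name="subject_id"), columns=ids)
    meta = pd.DataFrame({"variant_id": ids, "chrom": chroms, "pos": poss,
                         "counted_allele": alts, "other_allele": refs})
    return genotypes, meta


def write_genotype_vcf(genotypes: pd.DataFrame, weights: pd.DataFrame, path: str | Path) -> None:
    """Write dosages as a minimal VCF 4.2 with a per-sample ``DS`` field.

    The weight table supplies coordinates and alleles; the effect allele is
    written as ALT so the DS dosage counts it directly.
    """
    w = weights.set_index("variant_id")
    samples = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n')
        for chrom in dict.fromkeys(w["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for vid in genotypes.columns:
            rec = w.loc[vid]
            doses = "\t".join(f"{d:.6g}" for d in genotypes[vid].to_numpy(dtype=float))
            fh.write(f"{rec['chrom']}\t{int(rec['pos'])}\t{vid}\t{rec['other_allele']}\t"
                     f"{rec['effect_allele']}\t.\tPASS\t.\tDS\t{doses}\n")


def validate_phenotypes(df: pd.DataFrame, path: str = "<memory>") -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: phenotype table missing columns {missing}")
    if df.empty:
        raise InputError(f"{path}: empty phenotype table")
    if not df["case_status"].isin([0, 1]).all():
        raise InputError(f"{path}: case_status must be 0/1")
    both = (df["mht_eonly"] == 1) & (df["mht_ep"] == 1)
    if both.any():
        rows = list(df.index[both])[:5]
        raise InputError(
            f"{path}: mht_eonly and mht_ep both 1 (mutually exclusive) at rows {rows}"
        )
    typed = (df["mht_eonly"] == 1) | (df["mht_ep"] == 1)
    bad = typed & (df["mht_any"] != 1)
    if bad.any():
        rows = list(df.index[bad])[:5]
        raise InputError(f"{path}: MHT-type user without mht_any=1 at rows {rows}")
    return df


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col="subject_id")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty phenotype file") from exc
    return validate_phenotypes(df, str(path))


def write_phenotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="subject_id", float_format="%.6g")


def read_rate_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty rate table") from exc
    need = {"age_start", "age_end", "rate_per_100k"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: rate table needs columns {sorted(need)}")
    if (df["rate_per_100k"] < 0).any():
        raise InputError(f"{path}: negative rates")
    return df


def write_rate_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def check_subject_overlap(genotypes: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.Index:
    """Subjects present in both tables; error with examples if disjoint."""
    common = genotypes.index.intersection(phenotypes.index)
    if len(common) == 0:
        raise InputError(
            "no overlapping subject ids between genotypes and phenotypes "
            f"(genotype examples: {list(genotypes.index[:3])}, "
            f"phenotype examples: {list(phenotypes.index[:3])})"
        )
    return common
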