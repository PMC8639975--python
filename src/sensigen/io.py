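"""Readers and writers for the plain-text formats the pipeline exchanges.

Genotypes travel as VCF v4.2 (GT-only) or as an additive-dosage TSV with a
separate SNP metadata table; phenotypes, expression, eQTL pairs and reports
are TSV; gene coordinates are 6-column BED (0-based half-open); gene sets
are GMT. All writers are deterministic: same in-memory objects, same bytes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel

PHENO_COLUMNS = [
    "subject_id", "family_id", "role", "sex", "age", "bmi",
    "vo2max_per_kg", "si_baseline", "si_delta",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and offending line."""


@dataclass
class GenotypeMatrix:
    """Additive genotype dosages (subjects x SNPs, values 0/1/2, -1 missing)."""

    dosage: np.ndarray
    snp_meta: pd.DataFrame  # columns: snp_id, chrom, pos (1-based), ref, alt
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (subjects x SNPs)")
        if self.dosage.shape[1] != len(self.snp_meta):
            raise ValueError(
                f"dosage has {self.dosage.shape[1]} SNPs but snp_meta has "
                f"{len(self.snp_meta)} rows"
            )
        if self.subjects and len(self.subjects) != self.dosage.shape[0]:
            raise ValueError("subjects length does not match dosage rows")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_snps(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
            subjects=list(self.subjects),
        )

    def __eq__(self, other) -> bool:  # round-trip identity checks
        return (
            isinstance(other, GenotypeMatrix)
            and np.array_equal(self.dosage, other.dosage)
            and self.snp_meta.equals(other.snp_meta)
            and self.subjects == other.subjects
        )


# ---------------------------------------------------------------------------
# VCF

_GT_FROM_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path: str | os.PathLike) -> None:
    meta = geno.snp_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sensigen\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in meta["chrom"].drop_duplicates():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.subjects)
            + "\n"
        )
        for j in range(geno.n_snps):
            row = meta.iloc[j]
            gts = "\t".join(_GT_FROM_DOSAGE[int(d)] for d in geno.dosage[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows, meta = [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        rows.append(code[var.gt_types])
        meta.append((var.ID, var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    snp_meta = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosage = (
        np.vstack(rows).T.astype(np.int8)
        if rows
        else np.zeros((len(subjects), 0), np.int8)
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=snp_meta, subjects=subjects)


# ---------------------------------------------------------------------------
# Dosage TSV (alternative genotype carrier) + SNP metadata TSV

def write_genotypes_tsv(geno: GenotypeMatrix, path, meta_path) -> None:
    df = pd.DataFrame(
        geno.dosage.astype(object), index=geno.subjects, columns=geno.snp_meta["snp_id"]
    )
    df = df.mask(df == MISSING)  # NaN -> written as NA
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA")
    geno.snp_meta.to_csv(meta_path, sep="\t", index=False)


def read_genotypes_tsv(path, meta_path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    meta = pd.read_csv(meta_path, sep="\t")
    dosage = df.to_numpy(dtype=float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    return GenotypeMatrix(dosage=dosage, snp_meta=meta, subjects=list(df.index))


# ---------------------------------------------------------------------------
# Phenotypes

def write_phenotypes(cohort: pd.DataFrame, path) -> None:
    # %.17g preserves float64 exactly across a write/read cycle
    cohort[PHENO_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing phenotype columns {missing}")
    return df


# ---------------------------------------------------------------------------
# BED (6-column, 0-based half-open)

def write_bed(genes: pd.DataFrame, path) -> None:
    out = genes[["chrom", "start", "end", "gene_id", "strand"]].copy()
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            records.append((name, chrom, start, end, strand))
    return pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# GMT gene sets

def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# Expression matrix (genes x subjects) and eQTL table

def write_expression(expr: pd.DataFrame, path) -> None:
    expr.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.17g")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index.name = None
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate gene ids")
    if df.isna().any().any():
        raise ParseError(f"{path}: expression matrix contains missing values")
    return df


def write_eqtl(eqtl: pd.DataFrame, path) -> None:
    eqtl[["snp_id", "gene_id", "effect"]].to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_eqtl(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = {"snp_id", "gene_id", "effect"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: eQTL table must have columns {sorted(need)}")
    return df
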