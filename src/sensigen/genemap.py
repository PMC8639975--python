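"""Linkage-disequilibrium utilities and SNP-to-gene assignment.

LD is the squared Pearson correlation of additive dosages over
pairwise-complete subjects. Pruning keeps, of any pair closer than
``window`` SNPs with r^2 above the threshold, the SNP with the smaller
association p-value. Positional mapping assigns a SNP to every gene whose
body, extended by a +/- 20 kb window, contains the SNP; eQTL mapping is a
lookup join. Gene coordinates are BED-native (0-based half-open)
internally; SNP positions are 1-based.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = ["ld_r2", "prune_by_ld", "map_positional", "map_eqtl"]


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation between two SNPs' dosage vectors."""
    a = np.asarray(dosages_a, float)
    b = np.asarray(dosages_b, float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete genotypes")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance SNP in LD computation; r2 undefined")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prune_by_ld(
    assoc_table: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_max: float = 0.8,
    window: int = 50,
) -> list[str]:
    """Greedy LD pruning preferring smaller association p-values.

    Candidates are visited in order of increasing p (ties: genomic
    position); a SNP is kept unless an already-kept SNP on the same
    chromosome within ``window`` positions in the sorted SNP order has
    r^2 > ``r2_max`` with it. Returns kept SNP ids in positional order.
    """
    meta = assoc_table.reset_index(drop=True)
    order_idx = {s: i for i, s in enumerate(geno.snp_meta["snp_id"])}
    pvals = meta["p"].to_numpy(float)
    pvals = np.where(np.isfinite(pvals), pvals, np.inf)
    visit = sorted(
        range(len(meta)),
        key=lambda i: (pvals[i], meta["chrom"].iloc[i], meta["pos"].iloc[i]),
    )
    kept: list[int] = []
    D = geno.dosage
    for i in visit:
        gi = order_idx[meta["snp_id"].iloc[i]]
        conflict = False
        for j in kept:
            gj = order_idx[meta["snp_id"].iloc[j]]
            if meta["chrom"].iloc[i] != meta["chrom"].iloc[j]:
                continue
            if abs(gi - gj) > window:
                continue
            try:
                r2 = ld_r2(D[:, gi], D[:, gj])
            except ValueError:
                continue
            if np.isfinite(r2) and r2 > r2_max:
                conflict = True
                break
        if not conflict:
            kept.append(i)
    kept_rows = meta.iloc[sorted(kept, key=lambda i: (meta["chrom"].iloc[i], meta["pos"].iloc[i]))]
    return list(kept_rows["snp_id"])


def _norm_chrom(values) -> np.ndarray:
    out = np.array([str(v) for v in values], dtype=object)
    stripped = np.array([v[3:] if v.lower().startswith("chr") else v for v in out], dtype=object)
    if not np.array_equal(out, stripped):
        warnings.warn("normalized 'chr' prefixes in chromosome names")
    return stripped


def map_positional(
    snp_meta: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 20_000,
) -> pd.DataFrame:
    """Map each SNP to genes within a +/- ``window_bp`` window of the body.

    A SNP at 1-based position p maps to a gene with BED coordinates
    [start, end) iff  start + 1 - window_bp <= p <= end + window_bp.
    Returns a tidy frame (snp_id, gene_id, source='positional').
    """
    snp_chrom = _norm_chrom(snp_meta["chrom"])
    gene_chrom = _norm_chrom(genes["chrom"])
    records = []
    for chrom in np.unique(snp_chrom):
        s_mask = snp_chrom == chrom
        g_mask = gene_chrom == chrom
        if not g_mask.any():
            continue
        pos = snp_meta.loc[s_mask, "pos"].to_numpy(int)
        sids = snp_meta.loc[s_mask, "snp_id"].to_numpy()
        lo = genes.loc[g_mask, "start"].to_numpy(int) + 1 - window_bp
        hi = genes.loc[g_mask, "end"].to_numpy(int) + window_bp
        gids = genes.loc[g_mask, "gene_id"].to_numpy()
        hit = (pos[:, None] >= lo[None, :]) & (pos[:, None] <= hi[None, :])
        si, gi = np.nonzero(hit)
        records += [(sids[i], gids[j], "positional") for i, j in zip(si, gi)]
    return (
        pd.DataFrame(records, columns=["snp_id", "gene_id", "source"])
        .drop_duplicates()
        .reset_index(drop=True)
    )


def map_eqtl(snp_ids, eqtl_table: pd.DataFrame) -> pd.DataFrame:
    """eQTL lookup join; source tagged 'eqtl'."""
    snp_ids = set(snp_ids)
    sub = eqtl_table[eqtl_table["snp_id"].isin(snp_ids)]
    out = sub[["snp_id", "gene_id"]].copy()
    out["source"] = "eqtl"
    return out.drop_duplicates().reset_index(drop=True)


def combine_maps(*maps: pd.DataFrame) -> pd.DataFrame:
    """Union of mapping channels; (snp, gene, source) triples kept distinct."""
    if not maps:
        return pd.DataFrame(columns=["snp_id", "gene_id", "source"])
    return pd.concat(maps, ignore_index=True).drop_duplicates().reset_index(drop=True)
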