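"""Gene-set enrichment of GWAS p-values by Fisher combination (GLOSSI).

For a gene set, the p-values of the (LD-pruned, hence approximately
independent) SNPs mapping to its member genes are combined as

    X = -2 * sum(ln p_i)  ~  chi-square with 2k degrees of freedom

under the null of uniform p-values. Set-level p-values are Bonferroni
corrected across the tested sets. For each set the member genes carrying a
SNP with nominal p < 0.05 are reported alongside.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["glossi_set_p", "run_setstat"]

log = logging.getLogger(__name__)

_MIN_P = np.finfo(float).tiny  # smallest positive normal double


def glossi_set_p(snp_pvalues) -> tuple[float, float]:
    """Fisher-combine SNP p-values; returns (statistic, combined p)."""
    p = np.asarray(list(snp_pvalues), float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any(p > 1.0) or np.any(p < 0.0) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0.0):
        warnings.warn("p-value of 0 clamped to the smallest positive normal")
        p = np.clip(p, _MIN_P, 1.0)
    statistic = float(-2.0 * np.sum(np.log(p)))
    return statistic, float(stats.chi2.sf(statistic, 2 * p.size))


def run_setstat(
    assoc_table: pd.DataFrame,
    pruned_snps,
    snp_gene_map: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    nominal_alpha: float = 0.05,
) -> pd.DataFrame:
    """GLOSSI over gene sets; Bonferroni across tested sets.

    Within a set each pruned SNP contributes once, even when it maps to
    several member genes. Sets with no mapped pruned SNP are reported
    untested (statistic and p-values NaN).
    """
    pruned = [s for s in pruned_snps if s in set(assoc_table["snp_id"])]
    ptab = assoc_table.set_index("snp_id")["p"]
    usable = [s for s in pruned if np.isfinite(ptab.get(s, np.nan))]
    gmap = snp_gene_map[snp_gene_map["snp_id"].isin(usable)]
    gene_to_snps: dict[str, set] = {}
    for snp, gene in zip(gmap["snp_id"], gmap["gene_id"]):
        gene_to_snps.setdefault(gene, set()).add(snp)

    rows = []
    for name, members in gene_sets.items():
        snps = sorted(set().union(*(gene_to_snps.get(g, set()) for g in members)) if members else set())
        if not snps:
            log.info("gene set %s has no mapped pruned SNPs; untested", name)
            rows.append((name, 0, np.nan, np.nan, np.nan, ""))
            continue
        pvals = ptab.loc[snps].to_numpy(float)
        statistic, p = glossi_set_p(pvals)
        contributing = sorted(
            {g for g in members
             if any(ptab[s] < nominal_alpha for s in gene_to_snps.get(g, ()))}
        )
        rows.append((name, len(snps), statistic, p, np.nan, ",".join(contributing)))
    table = pd.DataFrame(
        rows, columns=["set", "k", "statistic", "p", "p_adjusted", "contributing_genes"]
    )
    tested = table["p"].notna()
    n_tested = int(tested.sum())
    if n_tested:
        table.loc[tested, "p_adjusted"] = np.minimum(1.0, table.loc[tested, "p"] * n_tested)
    return table
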