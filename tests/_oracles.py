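"""Independent reference implementations used to cross-check the package.

Each oracle deliberately uses a different algorithmic route than the
library code: dense covariance inversion instead of per-family sums,
exact-fraction enumeration instead of log-gamma arithmetic, explicit
O(N) running sums instead of the closed-form hit/miss bookkeeping, and
exhaustive pair scans instead of greedy windows.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def gls_fit(y, g, fam_codes, lam):
    """Dense GLS for y = b0 + b1*g + u_family + e at a fixed variance ratio."""
    y = np.asarray(y, float)
    n = len(y)
    Z = np.zeros((n, int(np.max(fam_codes)) + 1))
    Z[np.arange(n), fam_codes] = 1.0
    W = np.eye(n) + lam * Z @ Z.T
    Wi = np.linalg.inv(W)
    X = np.column_stack([np.ones(n), np.asarray(g, float)])
    XtWiX = X.T @ Wi @ X
    beta = np.linalg.solve(XtWiX, X.T @ Wi @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ Wi @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 * np.linalg.inv(XtWiX)[1, 1]))
    return float(beta[1]), se


def hwe_enumeration(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact-fraction enumeration of the conditional heterozygote
    distribution given the allele counts."""
    n = hom_ref + het + hom_alt
    n_minor = min(2 * hom_ref + het, 2 * hom_alt + het)
    if n_minor == 0:
        return 1.0
    weights = {}
    for x in range(n_minor % 2, n_minor + 1, 2):
        hmin = (n_minor - x) // 2
        hmaj = n - x - hmin
        weights[x] = comb(n, hmin) * comb(n - hmin, x) * (2**x)
    total = sum(weights.values())
    w_obs = weights[het]
    p = Fraction(sum(w for w in weights.values() if w <= w_obs), total)
    return float(p)


def es_running_sum(tvals, hit_mask, weight=1.0) -> float:
    """Brute-force GSEA enrichment score by an explicit running sum."""
    tvals = np.asarray(tvals, float)
    hit_mask = np.asarray(hit_mask, bool)
    N = len(tvals)
    k = int(hit_mask.sum())
    w = np.abs(tvals) ** weight
    nr = w[hit_mask].sum()
    running = 0.0
    best = 0.0
    for i in range(N):
        if hit_mask[i]:
            running += w[i] / nr if nr > 0 else 0.0
        else:
            running -= 1.0 / (N - k)
        if abs(running) > abs(best):
            best = running
    return best


def prune_bruteforce(snp_ids, pvals, chroms, order_index, r2, r2_max, window):
    """Iteratively drop the worse (larger p) SNP of any conflicting pair."""
    alive = list(range(len(snp_ids)))
    pvals = np.where(np.isfinite(pvals), pvals, np.inf)
    while True:
        conflict = None
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                i, j = alive[ai], alive[bi]
                if chroms[i] != chroms[j]:
                    continue
                if abs(order_index[i] - order_index[j]) > window:
                    continue
                if np.isfinite(r2[i, j]) and r2[i, j] > r2_max:
                    conflict = (i, j)
                    break
            if conflict:
                break
        if conflict is None:
            break
        i, j = conflict
        drop = j if (pvals[i], order_index[i]) <= (pvals[j], order_index[j]) else i
        alive.remove(drop)
    return [snp_ids[i] for i in alive]


def map_positional_bruteforce(snp_meta, genes, window_bp=20_000):
    """O(n*m) interval check, 1-based SNP vs BED half-open gene."""
    pairs = set()
    for _, s in snp_meta.iterrows():
        for _, g in genes.iterrows():
            if str(s.chrom).removeprefix("chr") != str(g.chrom).removeprefix("chr"):
                continue
            if g.start + 1 - window_bp <= s.pos <= g.end + window_bp:
                pairs.add((s.snp_id, g.gene_id))
    return pairs
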