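"""Per-predictor association under a family random-intercept mixed model,
and SimpleM effective-test multiple-testing correction.

Model, per predictor g (SNP dosage or a gene's expression):

    y = mu + beta * g + u_family + e,   u ~ N(0, s2_f),  e ~ N(0, s2_e)

fitted by REML with a 1-D profile over the variance ratio
``lambda = s2_f / s2_e`` (coarse log-spaced grid, then golden-section
refinement). Because the random effect is a family intercept, every GLS
quantity reduces to per-family sums, so the profile is evaluated for all
predictors simultaneously in O(n_families x n_predictors) per grid point.

SimpleM estimates the effective number of independent tests as the number
of leading eigenvalues of the SNP-SNP correlation matrix needed to reach a
fixed fraction (default C = 0.995) of its trace, summed over contiguous
SNP blocks; the genome-wide significance threshold is alpha / m_eff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix

__all__ = ["lmm_scan", "mixed_scan", "simplem_meff", "thresholds",
           "MultipleTestingResult", "ScanResult"]

_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-3.0, 2.0, 31)])
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class ScanResult:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lam: np.ndarray       # fitted s2_family / s2_residual per predictor
    n_used: np.ndarray
    flag: list[str]


class _FamilyProfile:
    """REML profile machinery for one trait vector and many predictors."""

    def __init__(self, y: np.ndarray, P: np.ndarray, fam_codes: np.ndarray):
        self.n, self.m = P.shape
        self.y = y
        self.k = int(fam_codes.max()) + 1
        self.n_i = np.bincount(fam_codes, minlength=self.k).astype(float)
        F = np.zeros((self.k, self.n))
        F[fam_codes, np.arange(self.n)] = 1.0
        self.Sy = F @ y                     # (k,)
        self.SP = F @ P                     # (k, m)
        self.sy = float(y.sum())
        self.yy = float(y @ y)
        self.sg = P.sum(axis=0)             # (m,)
        self.g2 = np.einsum("ij,ij->j", P, P)
        self.gty = P.T @ y

    def _quads(self, lam):
        """GLS cross-products for lambda scalar or per-predictor vector."""
        n_i, Sy, SP = self.n_i, self.Sy, self.SP
        if np.ndim(lam) == 0:
            c = lam / (1.0 + n_i * lam)          # (k,)
            q11 = self.n - c @ (n_i**2)
            q1y = self.sy - c @ (n_i * Sy)
            qyy = self.yy - c @ (Sy**2)
            q1g = self.sg - (c * n_i) @ SP
            qgg = self.g2 - c @ (SP**2)
            qgy = self.gty - (c * Sy) @ SP
            logdetW = float(np.sum(np.log1p(n_i * lam)))
        else:
            lam = np.asarray(lam)
            c = lam[None, :] / (1.0 + n_i[:, None] * lam[None, :])   # (k, m)
            q11 = self.n - (n_i**2) @ c
            q1y = self.sy - (n_i * Sy) @ c
            qyy = self.yy - (Sy**2) @ c
            q1g = self.sg - np.einsum("ij,ij->j", c * n_i[:, None], SP)
            qgg = self.g2 - np.einsum("ij,ij->j", c, SP**2)
            qgy = self.gty - np.einsum("ij,ij->j", c * Sy[:, None], SP)
            logdetW = np.sum(np.log1p(n_i[:, None] * lam[None, :]), axis=0)
        return q11, q1g, qgg, q1y, qgy, qyy, logdetW

    def criterion(self, lam):
        """Negative restricted log-likelihood (up to a constant), per predictor."""
        q11, q1g, qgg, q1y, qgy, qyy, logdetW = self._quads(lam)
        det = q11 * qgg - q1g**2
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_g = (q11 * qgy - q1g * q1y) / det
            beta_0 = (qgg * q1y - q1g * qgy) / det
            rss = qyy - beta_0 * q1y - beta_g * qgy
            crit = (self.n - 2) * np.log(rss) + logdetW + np.log(det)
        return np.where(det > 0, crit, np.inf)

    def estimates(self, lam):
        q11, q1g, qgg, q1y, qgy, qyy, _ = self._quads(lam)
        det = q11 * qgg - q1g**2
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_g = (q11 * qgy - q1g * q1y) / det
            beta_0 = (qgg * q1y - q1g * qgy) / det
            rss = qyy - beta_0 * q1y - beta_g * qgy
            sigma2 = rss / (self.n - 2)
            se = np.sqrt(sigma2 * q11 / det)
        return beta_g, se


def _reml_scan_dense(y, P, fam_codes, grid=_LAMBDA_GRID, refine_iters=40) -> tuple:
    """Fit the family mixed model for every column of P; returns estimates."""
    prof = _FamilyProfile(y, P, fam_codes)
    crits = np.vstack([prof.criterion(l) for l in grid])     # (G, m)
    best = np.argmin(crits, axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, len(grid) - 1)]
    for _ in range(refine_iters):
        span = hi - lo
        x1 = hi - _GOLDEN * span
        x2 = lo + _GOLDEN * span
        f1 = prof.criterion(x1)
        f2 = prof.criterion(x2)
        take_left = f1 < f2
        lo = np.where(take_left, lo, x1)
        hi = np.where(take_left, x2, hi)
    lam = 0.5 * (lo + hi)
    # snap to the exact OLS boundary when it is at least as good
    at_zero = prof.criterion(0.0)
    at_lam = prof.criterion(lam)
    lam = np.where(at_zero <= at_lam, 0.0, lam)
    beta, se = prof.estimates(lam)
    return beta, se, lam


def mixed_scan(y: np.ndarray, P: np.ndarray, fam_codes: np.ndarray) -> ScanResult:
    """Family random-intercept scan of trait ``y`` over predictor columns ``P``.

    ``P`` must be complete (no missing values); callers handle per-column
    missingness by subsetting. Constant columns are flagged and skipped.
    """
    y = np.asarray(y, float)
    P = np.asarray(P, float)
    fam_codes = np.asarray(fam_codes)
    n, m = P.shape
    variable = P.std(axis=0) > 0
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    lam = np.full(m, np.nan)
    flag = ["monomorphic"] * m
    if variable.any():
        b, s, l = _reml_scan_dense(y, P[:, variable], fam_codes)
        beta[variable], se[variable], lam[variable] = b, s, l
        for j in np.flatnonzero(variable):
            flag[j] = ""
    bad = variable & ~(np.isfinite(beta) & np.isfinite(se) & (se > 0))
    if bad.any():
        # fall back to plain OLS for numerically degenerate fits
        for j in np.flatnonzero(bad):
            x = np.column_stack([np.ones(n), P[:, j]])
            coef, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
            if rank < 2:
                flag[j] = "monomorphic"
                continue
            rss = float(res[0]) if len(res) else float(np.sum((y - x @ coef) ** 2))
            sigma2 = rss / (n - 2)
            xtx_inv = np.linalg.inv(x.T @ x)
            beta[j], se[j], lam[j] = coef[1], np.sqrt(sigma2 * xtx_inv[1, 1]), 0.0
            flag[j] = "ols_fallback"
    with np.errstate(invalid="ignore"):
        t = beta / se
    df = n - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return ScanResult(beta=beta, se=se, t=t, p=p, lam=lam,
                      n_used=np.full(m, n), flag=flag)


def lmm_scan(adjusted, geno: GenotypeMatrix, families) -> pd.DataFrame:
    """Per-SNP mixed-model association table for an adjusted trait.

    ``adjusted`` is an :class:`~sensigen.cohortqc.AdjustedTrait` or a plain
    numeric vector aligned with the genotype rows. Missing genotypes are
    dropped per SNP (complete-case).
    """
    y = np.asarray(getattr(adjusted, "values", adjusted), float)
    fams = pd.Categorical(np.asarray(families)).codes.astype(int)
    if len(np.unique(fams)) < 3:
        raise ValueError("mixed-model scan requires >= 3 families")
    if len(y) != geno.n_subjects:
        raise ValueError("trait and genotype matrix are not aligned")

    D = geno.dosage
    has_missing = (D == MISSING).any(axis=0)
    complete = ~has_missing
    m = geno.n_snps
    out = ScanResult(
        beta=np.full(m, np.nan), se=np.full(m, np.nan), t=np.full(m, np.nan),
        p=np.full(m, np.nan), lam=np.full(m, np.nan),
        n_used=np.zeros(m, int), flag=[""] * m,
    )
    if complete.any():
        res = mixed_scan(y, D[:, complete].astype(float), fams)
        idx = np.flatnonzero(complete)
        for name in ("beta", "se", "t", "p", "lam", "n_used"):
            getattr(out, name)[idx] = getattr(res, name)
        for i, j in enumerate(idx):
            out.flag[j] = res.flag[i]
    for j in np.flatnonzero(has_missing):
        ok = D[:, j] != MISSING
        sub_f = pd.Categorical(fams[ok]).codes.astype(int)
        out.n_used[j] = int(ok.sum())
        if ok.sum() < 4 or len(np.unique(sub_f)) < 3 or D[ok, j].std() == 0:
            out.flag[j] = "monomorphic" if D[ok, j].std() == 0 else "too_few_families"
            continue
        res = mixed_scan(y[ok], D[ok, j].astype(float)[:, None], sub_f)
        out.beta[j], out.se[j], out.t[j] = res.beta[0], res.se[0], res.t[0]
        out.p[j], out.lam[j], out.flag[j] = res.p[0], res.lam[0], res.flag[0]
    meta = geno.snp_meta
    return pd.DataFrame(
        {
            "snp_id": meta["snp_id"], "chrom": meta["chrom"], "pos": meta["pos"],
            "beta": out.beta, "se": out.se, "t": out.t, "p": out.p,
            "lambda": out.lam, "n_used": out.n_used, "flag": out.flag,
        }
    )


# ---------------------------------------------------------------------------
# SimpleM

def simplem_meff(
    geno: GenotypeMatrix | np.ndarray,
    variance_explained_C: float = 0.995,
    block_size: int = 1000,
) -> int:
    """Effective number of independent tests (SimpleM).

    Contiguous blocks of at most ``block_size`` SNPs; per block, the number
    of leading eigenvalues of the genotype correlation matrix whose sum
    reaches ``C`` of the trace. Zero-variance SNPs are excluded from the
    eigen-decomposition and each counted as one extra test.
    """
    D = geno.dosage if isinstance(geno, GenotypeMatrix) else np.asarray(geno)
    n, m = D.shape
    if m < 2:
        raise ValueError("SimpleM needs >= 2 SNPs")
    X = D.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])

    m_eff = 0
    for lo in range(0, m, block_size):
        block = X[:, lo: lo + block_size]
        sd = block.std(axis=0)
        degenerate = sd == 0
        m_eff += int(degenerate.sum())
        block = block[:, ~degenerate]
        if block.shape[1] == 0:
            continue
        if block.shape[1] == 1:
            m_eff += 1
            continue
        corr = np.corrcoef(block, rowvar=False)
        eig = np.linalg.eigvalsh(corr)[::-1]
        eig = np.clip(eig, 0.0, None)
        cum = np.cumsum(eig)
        target = variance_explained_C * cum[-1]
        m_eff += int(np.searchsorted(cum, target * (1 - 1e-12)) + 1)
    return m_eff


@dataclass
class MultipleTestingResult:
    m_total: int
    m_eff: int
    threshold_genomewide: float
    threshold_suggestive: float


def thresholds(
    m_eff: int, alpha: float = 0.05, suggestive: float = 1e-5,
    m_total: int | None = None,
) -> MultipleTestingResult:
    """Bonferroni threshold on the effective test count (alpha / m_eff)."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    if m_total is not None and m_eff > m_total:
        warnings.warn("m_eff exceeds m_total; check inputs")
    return MultipleTestingResult(
        m_total=m_total if m_total is not None else m_eff,
        m_eff=m_eff,
        threshold_genomewide=alpha / m_eff,
        threshold_suggestive=suggestive,
    )
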