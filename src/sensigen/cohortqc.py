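"""Genotype quality control, trait adjustment and family variance partition.

QC mirrors standard GWAS practice: SNPs are dropped when the minor allele
frequency is below 5%, the Hardy-Weinberg exact test rejects at p < 1e-6,
or more than 10% of genotypes are missing. Traits are adjusted by ordinary
least squares on the design the downstream association stages assume
(baseline Si on sex, age, log BMI and weight-adjusted VO2max; the training
response additionally on log baseline Si), and the residuals standardized.
The family variance partition is a one-way random-effects ANOVA with
method-of-moments variance components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix

__all__ = [
    "compute_maf", "hwe_exact_p", "qc_filter", "adjust_trait", "family_variance",
    "QcReport", "AdjustedTrait", "FamilyVariance",
]


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from additive dosages; NaN if all missing."""
    d = np.asarray(dosages)
    ok = d != MISSING
    if not ok.any():
        return float("nan")
    p = d[ok].sum() / (2.0 * ok.sum())
    return float(min(p, 1.0 - p))


def hwe_exact_p(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity as the minor allele count) that are
    no more probable than the observed one.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_ref + het + hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = min(2 * hom_ref + het, 2 * hom_alt + het)
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    # log P(het = x | n, n_minor) up to a common constant
    logp = hets * math.log(2.0) - (
        gammaln(hom_minor + 1) + gammaln(hets + 1) + gammaln(hom_major + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == het][0]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


@dataclass
class QcReport:
    table: pd.DataFrame  # snp_id, maf, hwe_p, missing_rate, pass, reasons

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_min: float = 1e-6,
    miss_max: float = 0.10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs failing MAF / HWE / missingness criteria; report every call."""
    if geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    d = geno.dosage
    n = geno.n_subjects
    rows = []
    for j in range(geno.n_snps):
        col = d[:, j]
        ok = col != MISSING
        missing_rate = 1.0 - ok.sum() / n
        reasons = []
        if not ok.any():
            maf = float("nan")
            hwe = float("nan")
            reasons.append("all_missing")
        else:
            maf = compute_maf(col)
            counts = np.bincount(col[ok], minlength=3)
            hwe = hwe_exact_p(int(counts[0]), int(counts[1]), int(counts[2]))
            if maf < maf_min:
                reasons.append("maf")
            if hwe < hwe_min:
                reasons.append("hwe")
        if missing_rate > miss_max:
            reasons.append("missingness")
        rows.append((geno.snp_meta["snp_id"].iloc[j], maf, hwe, missing_rate,
                     not reasons, ",".join(reasons)))
    table = pd.DataFrame(
        rows, columns=["snp_id", "maf", "hwe_p", "missing_rate", "pass", "reasons"]
    )
    keep = table["pass"].to_numpy()
    return geno.subset_snps(keep), QcReport(table)


# ---------------------------------------------------------------------------
# trait adjustment

_BASE_COVARIATES = ("sex", "age", "log_bmi", "vo2max_per_kg")


@dataclass
class AdjustedTrait:
    values: pd.Series           # residuals, standardized; index = subject_id
    recipe: dict = field(default_factory=dict)


def _design_from_cohort(cohort: pd.DataFrame, names: list[str]) -> np.ndarray:
    cols = []
    for name in names:
        if name == "sex":
            cols.append((cohort["sex"].to_numpy() == "F").astype(float))
        elif name == "log_bmi":
            cols.append(np.log(cohort["bmi"].to_numpy(float)))
        elif name == "log_si_baseline":
            base = cohort["si_baseline"].to_numpy(float)
            if np.any(base <= 0):
                raise ValueError("si_baseline must be positive to log-transform")
            cols.append(np.log(base))
        else:
            cols.append(cohort[name].to_numpy(float))
    return np.column_stack(cols)


def adjust_trait(
    cohort: pd.DataFrame,
    trait: str,
    extra_covariates: list[str] | tuple[str, ...] = (),
    method: str = "zscore",
) -> AdjustedTrait:
    """OLS-residualize a trait on its covariate recipe and normalize.

    ``method='zscore'`` standardizes the residuals to unit variance;
    ``method='inverse_normal'`` applies a rank-based inverse-normal
    (Blom) transform instead.
    """
    if trait not in ("si_baseline", "si_delta"):
        raise ValueError(f"unknown trait {trait!r}")
    names = list(_BASE_COVARIATES)
    if trait == "si_delta":
        names.append("log_si_baseline")
    names += list(extra_covariates)

    y = cohort[trait].to_numpy(float)
    if trait == "si_baseline":
        if np.any(y <= 0):
            raise ValueError("si_baseline must be positive")
        y = np.log(y)
    X = np.column_stack([np.ones(len(y)), _design_from_cohort(cohort, names)])
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in trait or covariates")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on correlations
        r = np.linalg.qr(X, mode="r")
        bad = [names[i - 1] for i in range(1, X.shape[1])
               if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta

    if method == "zscore":
        sd = resid.std(ddof=1)
        # an (almost) perfect fit leaves numerical dust; don't rescale it up
        degenerate = sd <= 1e-10 * max(1.0, float(np.abs(y).max()))
        values = resid if degenerate else resid / sd
    elif method == "inverse_normal":
        ranks = stats.rankdata(resid)
        values = stats.norm.ppf((ranks - 0.375) / (len(resid) + 0.25))
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    recipe = {
        "trait": trait,
        "log_transform_trait": trait == "si_baseline",
        "covariates": names,
        "method": method,
        "coefficients": {n: float(b) for n, b in zip(["intercept"] + names, beta)},
    }
    return AdjustedTrait(
        values=pd.Series(values, index=cohort["subject_id"].to_numpy(), name=trait),
        recipe=recipe,
    )


# ---------------------------------------------------------------------------
# family variance partition

@dataclass
class FamilyVariance:
    icc: float
    var_between: float
    var_within: float
    f_statistic: float
    p_value: float
    ms_between: float
    ms_within: float


def family_variance(cohort: pd.DataFrame, trait: str) -> FamilyVariance:
    """One-way random-effects ANOVA by family membership.

    Method-of-moments components (negative between-family estimates
    truncated at zero); F = MS_between / MS_within on (k-1, N-k) df.
    """
    y = cohort[trait].to_numpy(float)
    fam = cohort["family_id"].to_numpy()
    codes, counts = np.unique(fam, return_counts=True)
    k, N = len(codes), len(y)
    if k < 2:
        raise ValueError("family variance partition needs >= 2 families")
    idx = {c: i for i, c in enumerate(codes)}
    code = np.array([idx[f] for f in fam])
    sums = np.bincount(code, weights=y)
    means = sums / counts
    grand = y.mean()
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((y - means[code]) ** 2))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - np.sum(counts**2) / N) / (k - 1)
    var_within = ms_within
    var_between = max(0.0, (ms_between - ms_within) / n0)
    icc = var_between / (var_between + var_within) if var_between + var_within > 0 else 0.0
    f_stat = ms_between / ms_within if ms_within > 0 else float("inf")
    p = float(stats.f.sf(f_stat, k - 1, N - k))
    return FamilyVariance(
        icc=float(icc), var_between=var_between, var_within=var_within,
        f_statistic=float(f_stat), p_value=p,
        ms_between=ms_between, ms_within=ms_within,
    )
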