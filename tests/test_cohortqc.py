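"""QC filters, Hardy-Weinberg exact test, trait adjustment and the family
variance partition."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import _oracles
from conftest import null_config
from sensigen import cohortqc, io, synthio


def _geno(dosage_cols, ids=None):
    dosage = np.array(dosage_cols, dtype=np.int8).T
    m = dosage.shape[1]
    ids = ids or [f"s{j}" for j in range(m)]
    meta = pd.DataFrame({"snp_id": ids, "chrom": "1",
                         "pos": np.arange(1, m + 1) * 100, "ref": "A", "alt": "G"})
    return io.GenotypeMatrix(dosage=dosage, snp_meta=meta,
                             subjects=[f"i{i}" for i in range(dosage.shape[0])])


@pytest.mark.parametrize(
    "dosages,expected",
    [
        ([0] * 10, 0.0),
        ([0] * 25 + [1] * 50 + [2] * 25, 0.5),
        ([0] * 90 + [1] * 10, 0.05),
        ([io.MISSING, 1, 1], 0.5),
    ],
)
def test_minor_allele_frequency(dosages, expected):
    assert cohortqc.compute_maf(np.array(dosages)) == pytest.approx(expected)


def test_all_missing_snp_flagged_nan():
    assert np.isnan(cohortqc.compute_maf(np.array([io.MISSING] * 5)))


@pytest.mark.parametrize(
    "counts,expected",
    [
        ((50, 0, 0), 1.0),           # monomorphic
        ((1, 2, 1), 1.0),            # every outcome no more probable
        ((5, 0, 5), _oracles.hwe_enumeration(5, 0, 5)),
    ],
)
def test_hwe_exact_examples(counts, expected):
    assert cohortqc.hwe_exact_p(*counts) == pytest.approx(expected, abs=1e-12)


@given(
    st.integers(min_value=0, max_value=12),
    st.integers(min_value=0, max_value=12),
    st.integers(min_value=0, max_value=12),
)
def test_hwe_matches_exact_fraction_enumeration(a, b, c):
    if a + b + c == 0:
        return
    assert cohortqc.hwe_exact_p(a, b, c) == pytest.approx(
        _oracles.hwe_enumeration(a, b, c), abs=1e-12
    )


def test_qc_filter_planted_failures():
    """10 SNPs, three violating exactly one rule each -> 7 survivors."""
    n = 100
    rng = np.random.default_rng(1)
    good = [rng.binomial(2, 0.3, n) for _ in range(7)]
    low_maf = np.zeros(n, int); low_maf[:8] = 1                      # maf 0.04
    hwe_bad = np.array([0] * 50 + [2] * 50)                          # no hets
    missing = rng.binomial(2, 0.3, n); missing[:11] = io.MISSING     # 11% missing
    geno = _geno(good + [low_maf, hwe_bad, missing])
    filtered, report = cohortqc.qc_filter(geno)
    assert filtered.n_snps == 7
    reasons = dict(zip(report.table["snp_id"], report.table["reasons"]))
    assert reasons["s7"] == "maf"
    assert reasons["s8"] == "hwe"
    assert reasons["s9"] == "missingness"
    # pass flag consistent with thresholds
    t = report.table
    expected = (t.maf >= 0.05) & (t.hwe_p >= 1e-6) & (t.missing_rate <= 0.10)
    assert (t["pass"] == expected.fillna(False)).all()


def test_qc_filter_idempotent(small_bundle):
    once, _ = cohortqc.qc_filter(small_bundle.genotypes)
    twice, rep2 = cohortqc.qc_filter(once)
    assert twice == once
    assert rep2.table["pass"].all()


def test_adjust_trait_residuals_orthogonal_to_covariates(small_bundle):
    adj = cohortqc.adjust_trait(small_bundle.cohort, "si_delta")
    X = np.column_stack([
        (small_bundle.cohort["sex"] == "F").astype(float),
        small_bundle.cohort["age"],
        np.log(small_bundle.cohort["bmi"]),
        small_bundle.cohort["vo2max_per_kg"],
        np.log(small_bundle.cohort["si_baseline"]),
    ])
    r = adj.values.to_numpy()
    assert abs(r.mean()) < 1e-10 * r.std()
    for j in range(X.shape[1]):
        c = X[:, j] - X[:, j].mean()
        assert abs(c @ r) < 1e-8 * np.linalg.norm(c) * np.linalg.norm(r)
    assert np.std(r, ddof=1) == pytest.approx(1.0)


def test_adjust_trait_perfect_fit_gives_zero_residuals(small_bundle):
    cohort = small_bundle.cohort.copy()
    cohort["si_delta"] = 2.0 * cohort["age"]
    adj = cohortqc.adjust_trait(cohort, "si_delta")
    assert np.allclose(adj.values.to_numpy(), 0.0, atol=1e-8)


def test_adjust_trait_recovers_baseline_coupling_slope():
    """The generator couples dSi to log baseline Si with slope -0.5; the
    adjustment recipe must recover it within 2 SE (oracle: statsmodels)."""
    cfg = synthio.SimulationConfig(seed=42, n_snps=10, n_ld_blocks=2, n_genes=45,
                                   signature_genes=("G0001", "G0002", "G0003"),
                                   signature_coefficients=(0.0,) * 6,
                                   trait_latent_sd=0.0, family_icc_delta=0.1)
    b = synthio.simulate_cohort(cfg)
    adj = cohortqc.adjust_trait(b.cohort, "si_delta")
    X = sm.add_constant(np.column_stack([
        (b.cohort["sex"] == "F").astype(float), b.cohort["age"],
        np.log(b.cohort["bmi"]), b.cohort["vo2max_per_kg"],
        np.log(b.cohort["si_baseline"]),
    ]))
    fit = sm.OLS(b.cohort["si_delta"].to_numpy(), X).fit()
    mine = adj.recipe["coefficients"]["log_si_baseline"]
    assert mine == pytest.approx(fit.params[5], abs=1e-8)
    assert abs(mine - cfg.baseline_to_delta_slope) < 2 * fit.bse[5]


def test_adjust_trait_inverse_normal_is_gaussian_and_monotone(small_bundle):
    z = cohortqc.adjust_trait(small_bundle.cohort, "si_delta", method="zscore")
    q = cohortqc.adjust_trait(small_bundle.cohort, "si_delta", method="inverse_normal")
    assert stats.kstest(q.values.to_numpy(), "norm").pvalue > 0.05
    assert (np.argsort(z.values.to_numpy()) == np.argsort(q.values.to_numpy())).all()


def test_adjust_trait_rank_deficient_design_names_columns(small_bundle):
    cohort = small_bundle.cohort.copy()
    cohort["dup_age"] = cohort["age"]
    with pytest.raises(ValueError, match="collinear"):
        cohortqc.adjust_trait(cohort, "si_delta", extra_covariates=["dup_age"])


def test_family_variance_definition_and_errors(small_bundle):
    fv = cohortqc.family_variance(small_bundle.cohort, "si_delta")
    assert fv.icc == pytest.approx(fv.var_between / (fv.var_between + fv.var_within))
    assert 0.0 <= fv.icc <= 1.0
    single = small_bundle.cohort[small_bundle.cohort.family_id == "F001"]
    with pytest.raises(ValueError, match="2 families"):
        cohortqc.family_variance(single, "si_delta")


def test_family_variance_null_icc_near_zero():
    iccs = []
    for s in range(40):
        b = synthio.simulate_cohort(null_config(seed=500 + s, n_snps=4, n_ld_blocks=2))
        iccs.append(cohortqc.family_variance(b.cohort, "si_delta").icc)
    assert np.mean(iccs) < 0.05
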