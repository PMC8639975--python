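"""Three-gene interaction model: fitting, exhaustive search, diagnostics,
and transfer to a replication cohort."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sensigen import sigsearch, synthio


def _cohort_from(expression, genes, coefs, sex, vo2, noise, rng,
                 sex_beta=-0.5, vo2_beta=0.03):
    a, b, c, d, e, f = coefs
    t1, t2, t3 = (expression.loc[g].to_numpy() for g in genes)
    y = (a * t1 + b * t2 + c * t3 + d * t1 * t2 + e * t1 * t3 + f * t2 * t3
         + sex_beta * sex + vo2_beta * vo2 + noise)
    n = len(y)
    return pd.DataFrame({
        "subject_id": list(expression.columns), "family_id": "F001",
        "role": "offspring", "sex": np.where(sex > 0, "F", "M"),
        "age": 30.0, "bmi": 25.0, "vo2max_per_kg": vo2,
        "si_baseline": 3.5, "si_delta": y,
    })


def _random_expression(rng, n_genes=12, n=40):
    return pd.DataFrame(rng.normal(size=(n_genes, n)),
                        index=[f"G{i:02d}" for i in range(n_genes)],
                        columns=[f"s{i}" for i in range(n)])


def test_noiseless_equation_identifies_coefficients_exactly(rng):
    expr = _random_expression(rng)
    sex = rng.integers(0, 2, 40).astype(float)
    vo2 = rng.normal(33, 8, 40)
    coefs = (1.2, -0.7, 0.4, 0.9, -1.1, 0.3)
    cohort = _cohort_from(expr, ("G01", "G03", "G07"), coefs, sex, vo2,
                          noise=np.zeros(40), rng=rng)
    model = sigsearch.fit_triad(expr, cohort, ("G01", "G03", "G07"))
    for name, truth in zip("abcdef", coefs):
        assert model.coefficients[name] == pytest.approx(truth, abs=1e-8)
    assert model.coefficients["sex"] == pytest.approx(-0.5, abs=1e-8)
    assert model.coefficients["vo2max_per_kg"] == pytest.approx(0.03, abs=1e-8)
    assert model.r2 == pytest.approx(1.0, abs=1e-10)


def test_fit_matches_normal_equations_closed_form(rng):
    expr = _random_expression(rng)
    sex = rng.integers(0, 2, 40).astype(float)
    vo2 = rng.normal(33, 8, 40)
    cohort = _cohort_from(expr, ("G00", "G01", "G02"), (0.5,) * 6, sex, vo2,
                          noise=rng.normal(0, 1, 40), rng=rng)
    model = sigsearch.fit_triad(expr, cohort, ("G00", "G01", "G02"))
    t1, t2, t3 = (expr.loc[g].to_numpy() for g in ("G00", "G01", "G02"))
    X = np.column_stack([np.ones(40), t1, t2, t3, t1 * t2, t1 * t3, t2 * t3, sex, vo2])
    beta = np.linalg.solve(X.T @ X, X.T @ cohort.si_delta.to_numpy())
    got = [model.coefficients[k] for k in
           ("intercept", "a", "b", "c", "d", "e", "f", "sex", "vo2max_per_kg")]
    assert np.allclose(got, beta, atol=1e-10)


def test_coefficient_confidence_interval_coverage(rng):
    """95% Wald intervals cover the generating coefficients ~95% of the
    time at n = 47 (pooled over the six gene-term coefficients)."""
    coefs = (0.15, 0.15, 0.15, 0.75, 0.75, 0.75)
    covered = total = 0
    tcrit = stats.t.ppf(0.975, 47 - 9)
    for s in range(250):
        r = np.random.default_rng(10_000 + s)
        expr = _random_expression(r, n_genes=5, n=47)
        sex = r.integers(0, 2, 47).astype(float)
        vo2 = r.normal(33, 8, 47)
        cohort = _cohort_from(expr, ("G00", "G01", "G02"), coefs, sex, vo2,
                              noise=r.normal(0, 1.6, 47), rng=r)
        m = sigsearch.fit_triad(expr, cohort, ("G00", "G01", "G02"))
        for name, truth in zip("abcdef", coefs):
            covered += abs(m.coefficients[name] - truth) <= tcrit * m.se[name]
            total += 1
    assert 0.92 <= covered / total <= 0.975


def test_model_f_p_uniform_when_genes_uninformative():
    pvals = []
    for s in range(200):
        r = np.random.default_rng(20_000 + s)
        expr = _random_expression(r, n_genes=4, n=40)
        cohort = _cohort_from(expr, ("G00", "G01", "G02"), (0.0,) * 6,
                              r.integers(0, 2, 40).astype(float),
                              r.normal(33, 8, 40), noise=r.normal(0, 1, 40),
                              rng=r, sex_beta=0.0, vo2_beta=0.0)
        pvals.append(sigsearch.fit_triad(expr, cohort, ("G00", "G01", "G02")).model_p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_duplicated_gene_rejected(rng):
    expr = _random_expression(rng)
    cohort = _cohort_from(expr, ("G00", "G01", "G02"), (0.5,) * 6,
                          rng.integers(0, 2, 40).astype(float),
                          rng.normal(33, 8, 40), noise=rng.normal(0, 1, 40), rng=rng)
    with pytest.raises(ValueError, match="distinct"):
        sigsearch.fit_triad(expr, cohort, ("G00", "G00", "G01"))
    expr.loc["G01"] = expr.loc["G00"]
    with pytest.raises(ValueError, match="collinear"):
        sigsearch.fit_triad(expr, cohort, ("G00", "G01", "G02"))


@pytest.mark.parametrize("n_candidates,expected", [(3, 1), (10, 120)])
def test_search_fits_all_combinations(n_candidates, expected, triad_bundle):
    b = triad_bundle
    sub = b.cohort.iloc[:47].reset_index(drop=True)
    cands = list(b.expression.index)[:n_candidates]
    res = sigsearch.search_all_triads(b.expression[sub.subject_id], sub, cands)
    assert res.n_models_fitted == expected == comb(n_candidates, 3)
    assert len(res.table) == expected


def test_combination_counts_match_binomial():
    assert all(comb(n, 3) == n * (n - 1) * (n - 2) // 6 for n in range(3, 61))


def test_search_ranking_consistent_with_single_fits(triad_bundle):
    """Batched search scores agree with individually refitted models."""
    b = triad_bundle
    sub = b.cohort.iloc[:47].reset_index(drop=True)
    expr = b.expression[sub.subject_id]
    res = sigsearch.search_all_triads(expr, sub, list(expr.index)[:8])
    assert res.table.adjusted_r2.is_monotonic_decreasing
    for _, row in res.table.head(5).iterrows():
        m = sigsearch.fit_triad(expr, sub, (row.gene1, row.gene2, row.gene3))
        assert row.r2 == pytest.approx(m.r2, abs=1e-9)
        assert row.adjusted_r2 == pytest.approx(m.adjusted_r2, abs=1e-9)


def test_covariate_only_baseline(rng):
    expr = _random_expression(rng, n=60)
    vo2 = rng.normal(33, 8, 60)
    cohort = _cohort_from(expr, ("G00", "G01", "G02"), (0.0,) * 6,
                          rng.integers(0, 2, 60).astype(float), vo2,
                          noise=rng.normal(0, 1, 60), rng=rng,
                          sex_beta=0.0, vo2_beta=0.0)
    null = sigsearch.covariate_only_baseline(cohort)
    assert null["adjusted_r2"] < 0.1  # may be negative under the null
    cohort2 = cohort.copy()
    cohort2["si_delta"] = 2.0 * vo2 + rng.normal(0, 1, 60)
    strong = sigsearch.covariate_only_baseline(cohort2)
    expected = np.var(2.0 * vo2) / np.var(cohort2.si_delta.to_numpy())
    assert strong["adjusted_r2"] == pytest.approx(expected, abs=0.05)
    assert strong["model_p"] < 1e-10
    cohort3 = cohort.copy()
    cohort3["si_delta"] = 1.0
    assert sigsearch.covariate_only_baseline(cohort3)["r2"] == 0.0


class TestDiagnostics:
    def _model(self, rng, noise):
        expr = _random_expression(rng, n_genes=4, n=47)
        sex = rng.integers(0, 2, 47).astype(float)
        vo2 = rng.normal(33, 8, 47)
        cohort = _cohort_from(expr, ("G00", "G01", "G02"), (0.4,) * 6, sex, vo2,
                              noise=noise, rng=rng)
        return sigsearch.fit_triad(expr, cohort, ("G00", "G01", "G02"))

    def test_null_calibration(self):
        keys = ("normality_p", "heteroscedasticity_p", "linearity_p")
        collected = {k: [] for k in keys}
        for s in range(120):
            rng = np.random.default_rng(30_000 + s)
            d = sigsearch.diagnose(self._model(rng, rng.normal(0, 1.2, 47)))
            for k in keys:
                collected[k].append(d[k])
        for k in keys:
            assert stats.kstest(collected[k], "uniform").pvalue > 0.01, k

    def test_heteroscedasticity_detected(self):
        flagged = 0
        nsim = 20
        for s in range(nsim):
            rng = np.random.default_rng(40_000 + s)
            expr = _random_expression(rng, n_genes=4, n=80)
            sex = rng.integers(0, 2, 80).astype(float)
            vo2 = rng.normal(33, 8, 80)
            base = _cohort_from(expr, ("G00", "G01", "G02"), (0.6,) * 6, sex, vo2,
                                noise=np.zeros(80), rng=rng)
            signal = base.si_delta.to_numpy()
            base["si_delta"] = signal + rng.normal(size=80) * 0.6 * np.abs(signal)
            m = sigsearch.fit_triad(expr, base, ("G00", "G01", "G02"))
            flagged += sigsearch.diagnose(m)["heteroscedasticity_p"] < 0.05
        assert flagged >= 0.8 * nsim

    def test_too_few_residuals_rejected(self, rng):
        m = self._model(rng, rng.normal(0, 1, 47))
        with pytest.raises(ValueError, match=">= 10"):
            sigsearch.diagnose(m, residuals=np.arange(5.0))


class TestTransfer:
    def test_refit_on_training_cohort_is_idempotent(self, triad_bundle):
        b = triad_bundle
        sub = b.cohort.iloc[:47].reset_index(drop=True)
        expr = b.expression[sub.subject_id]
        genes = ("G0010", "G0025", "G0040")
        m = sigsearch.fit_triad(expr, sub, genes)
        rep = sigsearch.transfer_evaluate(genes, expr, sub)
        assert rep["r2"] == pytest.approx(m.r2, abs=1e-10)
        assert rep["adjusted_r2"] == pytest.approx(m.adjusted_r2, abs=1e-10)

    def test_transfer_tracks_training_fit_and_null_transfer_is_flat(self):
        genes = ("G0010", "G0025", "G0040")
        gaps, nulls = [], []
        for s in range(30):
            tb = synthio.simulate_cohort(synthio.triad_study_config(seed=6000 + s))
            train = tb.cohort.iloc[:47].reset_index(drop=True)
            m = sigsearch.fit_triad(tb.expression[train.subject_id], train, genes)
            rb = synthio.simulate_cohort(synthio.triad_study_config(
                seed=60_000 + s, n_families=10, offspring_per_family=(1, 1)))
            repl = rb.cohort.iloc[:20].reset_index(drop=True)
            rep = sigsearch.transfer_evaluate(genes, rb.expression[repl.subject_id], repl)
            gaps.append(rep["adjusted_r2"] - m.adjusted_r2)
            nb = synthio.simulate_cohort(synthio.triad_study_config(
                seed=90_000 + s, n_families=10, offspring_per_family=(1, 1),
                signature_coefficients=(0.0,) * 6))
            nullc = nb.cohort.iloc[:20].reset_index(drop=True)
            nulls.append(sigsearch.transfer_evaluate(
                genes, nb.expression[nullc.subject_id], nullc)["adjusted_r2"])
        assert abs(np.mean(gaps)) < 0.10
        assert abs(np.mean(nulls)) < 0.10

    def test_missing_gene_listed(self, triad_bundle):
        b = triad_bundle
        sub = b.cohort.iloc[:47].reset_index(drop=True)
        with pytest.raises(ValueError, match="MISSING_GENE"):
            sigsearch.transfer_evaluate(("G0010", "G0025", "MISSING_GENE"),
                                        b.expression[sub.subject_id], sub)
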