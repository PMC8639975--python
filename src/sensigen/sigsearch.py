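"""Exhaustive three-gene pairwise-interaction regression search.

For every unordered triple (t1, t2, t3) from a candidate gene list, fits

    dSi = a*t1 + b*t2 + c*t3 + d*t1*t2 + e*t1*t3 + f*t2*t3
          + sex + VO2max/kg + intercept + error

by ordinary least squares on baseline expression, ranks the C(n, 3)
models by (adjusted) R^2, and reports the top model with residual
diagnostics (normality, homoscedasticity, linearity). A fitted model's
FORM can be transferred to a replication cohort by refitting the same
genes and interactions there. Family structure is deliberately not
modelled in this stage; a note is logged when family ids are present.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "fit_triad", "search_all_triads", "covariate_only_baseline",
    "diagnose", "transfer_evaluate", "TriadModel", "SearchResult",
]

log = logging.getLogger(__name__)

_COEF_NAMES = ["intercept", "a", "b", "c", "d", "e", "f", "sex", "vo2max_per_kg"]


@dataclass
class TriadModel:
    genes: tuple[str, str, str]
    coefficients: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    r2: float
    adjusted_r2: float
    f_statistic: float
    model_p: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)
    design: np.ndarray = field(repr=False, default=None)


@dataclass
class SearchResult:
    table: pd.DataFrame
    n_models_fitted: int
    criterion: str
    top_model: TriadModel
    diagnostics: dict


def _covariates(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sex = (cohort["sex"].to_numpy() == "F").astype(float)
    vo2 = cohort["vo2max_per_kg"].to_numpy(float)
    return sex, vo2


def _triad_design(expression, cohort, genes) -> tuple[np.ndarray, np.ndarray]:
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    subjects = cohort["subject_id"].to_numpy()
    t1, t2, t3 = (expression.loc[g, subjects].to_numpy(float) for g in genes)
    sex, vo2 = _covariates(cohort)
    X = np.column_stack(
        [np.ones(len(subjects)), t1, t2, t3, t1 * t2, t1 * t3, t2 * t3, sex, vo2]
    )
    y = cohort["si_delta"].to_numpy(float)
    return X, y


def _ols_summary(X: np.ndarray, y: np.ndarray, names: list[str]) -> dict:
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        r = np.linalg.qr(X, mode="r")
        scale = max(abs(r[0, 0]), 1.0)
        bad = [names[i] for i in range(p) if abs(r[i, i]) < 1e-8 * scale]
        raise ValueError(f"collinear design columns: {bad or names}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - p
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    df_model = p - 1
    if tss > rss and df_model > 0:
        f = ((tss - rss) / df_model) / sigma2
        model_p = float(stats.f.sf(f, df_model, df_resid))
    else:
        f, model_p = 0.0, 1.0
    return {
        "coef": dict(zip(names, coef)), "se": dict(zip(names, se)),
        "t": dict(zip(names, tvals)), "p": dict(zip(names, pvals)),
        "r2": float(r2), "adjusted_r2": float(adj), "f": float(f),
        "model_p": model_p, "resid": resid, "fitted": fitted, "n": n,
    }


def fit_triad(expression: pd.DataFrame, cohort: pd.DataFrame, genes) -> TriadModel:
    """OLS fit of the three-gene pairwise-interaction model."""
    genes = tuple(genes)
    if len(set(genes)) != 3:
        raise ValueError("need 3 distinct gene ids")
    if len(cohort) <= 10:
        raise ValueError("need more than 10 subjects")
    X, y = _triad_design(expression, cohort, genes)
    s = _ols_summary(X, y, _COEF_NAMES)
    return TriadModel(
        genes=genes, coefficients=s["coef"], se=s["se"], t=s["t"], p=s["p"],
        r2=s["r2"], adjusted_r2=s["adjusted_r2"], f_statistic=s["f"],
        model_p=s["model_p"], n=s["n"], residuals=s["resid"], fitted=s["fitted"],
        design=X,
    )


def search_all_triads(
    expression: pd.DataFrame,
    cohort: pd.DataFrame,
    candidates: list[str],
    criterion: str = "adjusted_r2",
) -> SearchResult:
    """Fit every unordered gene triple from the candidate list.

    All C(n, 3) models are fitted by batched normal equations; models are
    ranked by the chosen criterion (descending, ties broken by the
    lexicographic gene triple) and the winner is refitted for full
    per-coefficient statistics and residual diagnostics.
    """
    if criterion not in ("r2", "adjusted_r2"):
        raise ValueError("criterion must be 'r2' or 'adjusted_r2'")
    candidates = list(candidates)
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate gene ids in candidate list")
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate genes")
    missing = [g for g in candidates if g not in expression.index]
    if missing:
        raise ValueError(f"candidate genes absent from expression matrix: {missing}")
    if cohort["family_id"].nunique() > 1:
        log.info("family ids present but not modelled in the triad search "
                 "(fixed-effects-only model form)")

    subjects = cohort["subject_id"].to_numpy()
    E = expression.loc[candidates, subjects].to_numpy(float)   # (c, n)
    sex, vo2 = _covariates(cohort)
    y = cohort["si_delta"].to_numpy(float)
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    triples = np.array(list(combinations(range(len(candidates)), 3)))
    n_models = comb(len(candidates), 3)

    p = 9
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("more parameters than subjects")
    base = np.column_stack([np.ones(n), sex, vo2])
    r2 = np.empty(len(triples))
    chunk = 4000
    for lo in range(0, len(triples), chunk):
        tr = triples[lo: lo + chunk]
        t1, t2, t3 = E[tr[:, 0]], E[tr[:, 1]], E[tr[:, 2]]     # (T, n)
        X = np.stack(
            [np.broadcast_to(base[:, 0], t1.shape), t1, t2, t3,
             t1 * t2, t1 * t3, t2 * t3,
             np.broadcast_to(base[:, 1], t1.shape),
             np.broadcast_to(base[:, 2], t1.shape)],
            axis=2,
        )                                                       # (T, n, 9)
        G = np.einsum("tni,tnj->tij", X, X)
        b = np.einsum("tni,n->ti", X, y)
        try:
            coef = np.linalg.solve(G, b[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            coef = np.full((len(tr), p), np.nan)
            for i in range(len(tr)):
                try:
                    coef[i] = np.linalg.solve(G[i], b[i])
                except np.linalg.LinAlgError:
                    log.warning("singular triad %s excluded", tr[i])
        rss = float(y @ y) - np.einsum("ti,ti->t", coef, b)
        r2[lo: lo + len(tr)] = 1.0 - rss / tss

    adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    score = r2 if criterion == "r2" else adj
    gene_arr = np.array(candidates)
    table = pd.DataFrame(
        {
            "gene1": gene_arr[triples[:, 0]],
            "gene2": gene_arr[triples[:, 1]],
            "gene3": gene_arr[triples[:, 2]],
            "r2": r2,
            "adjusted_r2": adj,
        }
    )
    table["_ok"] = np.isfinite(score)
    table = table.sort_values(
        [criterion, "gene1", "gene2", "gene3"],
        ascending=[False, True, True, True], kind="mergesort",
    )
    table = table[table["_ok"]].drop(columns="_ok").reset_index(drop=True)

    top_genes = tuple(table.iloc[0][["gene1", "gene2", "gene3"]])
    top_model = fit_triad(expression, cohort, top_genes)
    diagnostics = diagnose(top_model)
    return SearchResult(
        table=table, n_models_fitted=n_models, criterion=criterion,
        top_model=top_model, diagnostics=diagnostics,
    )


def covariate_only_baseline(cohort: pd.DataFrame) -> dict:
    """OLS of dSi on sex and VO2max/kg only, for contrast with the triads."""
    sex, vo2 = _covariates(cohort)
    y = cohort["si_delta"].to_numpy(float)
    X = np.column_stack([np.ones(len(y)), sex, vo2])
    s = _ols_summary(X, y, ["intercept", "sex", "vo2max_per_kg"])
    return {
        "r2": s["r2"], "adjusted_r2": s["adjusted_r2"],
        "f_statistic": s["f"], "model_p": s["model_p"],
        "coefficients": s["coef"], "n": s["n"],
    }


def diagnose(model: TriadModel, residuals: np.ndarray | None = None) -> dict:
    """Residual diagnostics: normality, homoscedasticity, linearity.

    Shapiro-Wilk on the residuals; Breusch-Pagan of squared residuals on
    the fitted values; linearity as a RESET-style test (squared fitted
    values added to the design, Wald t on the added term). Reported only,
    never gating.
    """
    resid = np.asarray(residuals if residuals is not None else model.residuals, float)
    if resid is None or len(resid) < 10:
        raise ValueError("need >= 10 residuals for diagnostics")
    fitted = np.asarray(model.fitted, float)
    _, normality_p = stats.shapiro(resid)
    exog = np.column_stack([np.ones(len(fitted)), fitted])
    _, bp_p, _, _ = het_breuschpagan(resid, exog)
    f2 = fitted**2
    if model.design is not None and np.std(f2) > 0:
        names = [f"x{i}" for i in range(model.design.shape[1])] + ["fitted_sq"]
        aug = _ols_summary(np.column_stack([model.design, f2]), fitted + resid, names)
        lin_p = aug["p"]["fitted_sq"]
    elif np.std(f2) > 0:
        _, lin_p = stats.pearsonr(resid, f2)
    else:
        lin_p = 1.0
    return {
        "normality_p": float(normality_p),
        "heteroscedasticity_p": float(bp_p),
        "linearity_p": float(lin_p),
    }


def transfer_evaluate(
    genes,
    expression: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "vo2max_per_kg"),
) -> dict:
    """Refit the same model form (genes + pairwise interactions) on a
    replication cohort; transfer is by FORM, not frozen coefficients.

    ``covariates`` restricts the covariate columns to those available in
    the replication cohort (any subset of sex / vo2max_per_kg).
    """
    genes = tuple(genes)
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise ValueError(f"genes absent from replication expression matrix: {missing}")
    subjects = cohort["subject_id"].to_numpy()
    t1, t2, t3 = (expression.loc[g, subjects].to_numpy(float) for g in genes)
    cols = [np.ones(len(subjects)), t1, t2, t3, t1 * t2, t1 * t3, t2 * t3]
    names = ["intercept", "a", "b", "c", "d", "e", "f"]
    if "sex" in covariates and "sex" in cohort.columns:
        cols.append((cohort["sex"].to_numpy() == "F").astype(float))
        names.append("sex")
    if "vo2max_per_kg" in covariates and "vo2max_per_kg" in cohort.columns:
        cols.append(cohort["vo2max_per_kg"].to_numpy(float))
        names.append("vo2max_per_kg")
    X = np.column_stack(cols)
    y = cohort["si_delta"].to_numpy(float)
    if len(y) <= X.shape[1]:
        warnings.warn("replication cohort barely identifies the model form")
    s = _ols_summary(X, y, names)
    return {
        "genes": genes, "r2": s["r2"], "adjusted_r2": s["adjusted_r2"],
        "f_statistic": s["f"], "model_p": s["model_p"],
        "coefficients": s["coef"], "n": s["n"],
    }
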