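"""Cohort statistics: contingency-table tests and logistic-regression odds
ratios for regional copy-number covariates.

The group-comparison test for clinicopathological characteristics is the
Pearson chi-square without continuity correction, computed after dropping
all-zero rows/columns ('unknown' categories are excluded by the caller). A
warning is emitted when any expected cell count falls below 5 — the usual
small-sample caveat — but no exact-test fallback is applied by default.

The 20q analysis regresses a binary outcome (e.g. liver metastasis) on the
per-sample mean log2 of a genomic region, optionally with covariates such as
nodal status. Effect sizes are reported as odds ratios per amplification
unit (default 0.1 log2), with Wald confidence intervals at a configurable
level (default 90%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool


def chi_square_independence(table) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    Accepts a DataFrame or array. All-zero rows/columns are dropped before
    testing; degrees of freedom are (r-1)(c-1) on the reduced table.
    """
    obs = pd.DataFrame(table).astype(float)
    obs = obs.loc[obs.sum(axis=1) > 0, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("degenerate table: fewer than 2 non-zero rows or columns")
    stat, p, df, expected = sps.chi2_contingency(obs.to_numpy(), correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn("expected cell count below 5; chi-square approximation is rough")
    return ContingencyResult(obs, float(stat), int(df), float(p), expected, low)


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    ci_level: float
    n_obs: int
    converged: bool
    llf: float


def _check_separation(y: np.ndarray, X: pd.DataFrame) -> None:
    for col in X.columns:
        if col == "const":
            continue
        v = X[col].to_numpy(dtype=float)
        if len(np.unique(v)) < 2:
            continue
        if v[y == 1].min() > v[y == 0].max() or v[y == 1].max() < v[y == 0].min():
            raise ValueError(f"perfect separation on covariate {col!r}")


def logistic_fit(outcome, covariates, ci_level: float = 0.90) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``outcome`` is binary (0/1 or bool) per sample; ``covariates`` a
    DataFrame (or dict of vectors) of numeric covariates. An intercept is
    always included. Fitting is IRLS with a relative log-likelihood
    convergence tolerance of 1e-8 (at most 100 iterations); perfect
    separation raises an error naming the covariate.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    X = pd.DataFrame(covariates).astype(float)
    _check_separation(y, X)
    X = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = model.fit(maxiter=100, tol=1e-8, scale=1.0)
        except sm.tools.sm_exceptions.PerfectSeparationWarning as exc:  # pragma: no cover
            raise ValueError(f"perfect separation detected during fit: {exc}") from exc
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge in 100 iterations "
                           f"(final deviance {res.deviance:.6g})")
    ci = res.conf_int(alpha=1.0 - ci_level)
    ci.columns = ["lower", "upper"]
    return LogisticFit(res.params, res.bse, res.pvalues, ci, ci_level,
                       int(res.nobs), bool(res.converged), float(res.llf))


def odds_ratio_per_unit(fit: LogisticFit, covariate: str, unit: float = 0.1,
                        ci_level: float | None = None) -> tuple[float, tuple[float, float]]:
    """Odds ratio per ``unit`` change of a covariate with its Wald CI:
    OR = exp(unit * beta), CI = exp(unit * (beta +/- z * SE))."""
    if covariate not in fit.params.index:
        raise KeyError(f"covariate {covariate!r} not in fit")
    level = ci_level if ci_level is not None else fit.ci_level
    beta = fit.params[covariate]
    se = fit.bse[covariate]
    z = sps.norm.ppf(0.5 + level / 2.0)
    lo, hi = np.exp(unit * (beta - z * se)), np.exp(unit * (beta + z * se))
    return float(np.exp(unit * beta)), (float(lo), float(hi))


def cohort_characteristic_tests(tables: dict[str, pd.DataFrame],
                                exclude_categories: tuple[str, ...] = ("unknown",)) -> pd.DataFrame:
    """Run the chi-square comparison for every characteristic table,
    excluding the listed categories (explicit unknowns) and dropping
    categories absent in all groups. Returns one row per characteristic."""
    rows = []
    for name, tab in tables.items():
        tab = tab.loc[[c for c in tab.index if str(c).lower() not in exclude_categories]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = chi_square_independence(tab)
        rows.append({"characteristic": name, "chi_square": res.statistic,
                     "df": res.df, "p_value": res.p_value,
                     "low_expected": res.low_expected_warning})
    return pd.DataFrame(rows)
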