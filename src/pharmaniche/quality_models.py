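"""Statistics linking functional-factor chemistry to the environment.

Covers the four analyses used to relate quality indicators to habitat:
Mann–Whitney U comparison of factor concentrations between suitability
classes, SPSS-style stepwise multiple linear regression of each factor on
the main ecological covariates, exact evaluation of fitted (or published)
linear models, and Spearman correlation with hierarchical clustering of the
ecological factors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionModel",
    "mann_whitney_u",
    "stepwise_ols",
    "evaluate_regression",
    "spearman_matrix",
    "cluster_factors",
    "load_table4_models",
]


@dataclass
class RegressionModel:
    """A named linear model: intercept + ordered covariate coefficients."""

    response: str
    intercept: float
    coefficients: dict[str, float]
    r_squared: float | None = None
    f_pvalue: float | None = None
    coef_pvalues: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"response": self.response, "intercept": self.intercept,
                "coefficients": dict(self.coefficients)}


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    The statistic reported is ``min(U, n₁n₂ − U)`` with U counting
    (a > b) pairs plus half the ties.  The p-value is exact (full null
    enumeration) when n₁·n₂ ≤ 400 and the data are untied, otherwise the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2)
    n1n2 = a.size * b.size
    u = min(u_a, n1n2 - u_a)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (n1n2 <= 400 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return u, float(min(res.pvalue, 1.0))


def group_comparisons(table: pd.DataFrame, factor_cols: list[str],
                      class_col: str = "class", high: str = "high",
                      moderate: str = "moderate") -> pd.DataFrame:
    """Mann–Whitney comparison of every factor between two suitability classes."""
    rows = []
    ha = table[table[class_col] == high]
    mo = table[table[class_col] == moderate]
    for col in factor_cols:
        u, p = mann_whitney_u(ha[col], mo[col])
        direction = "higher" if ha[col].mean() > mo[col].mean() else "lower"
        rows.append({"factor": col, "n_high": len(ha), "n_moderate": len(mo),
                     "U": u, "p": p, "high_vs_moderate": direction})
    return pd.DataFrame(rows).set_index("factor")


def _partial_f_pvalue(y, X_in: np.ndarray, x_new: np.ndarray) -> float | None:
    """p-value of the t (equivalently partial F) test for adding one column."""
    X = np.column_stack([X_in, x_new])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None  # perfectly collinear with what is already in
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[-1])


def stepwise_ols(y, X: pd.DataFrame, p_enter: float = 0.05,
                 p_remove: float = 0.10) -> RegressionModel:
    """SPSS-style stepwise regression.

    Forward step: enter the candidate with the smallest partial-F p-value if
    it is below ``p_enter``; backward step after every entry: remove any
    included covariate whose p-value exceeds ``p_remove``; iterate to a fixed
    point and refit the final model by OLS.
    """
    y = np.asarray(y, dtype=float)
    response = getattr(y, "name", "y")
    candidates = list(X.columns)
    if len(y) < 3:
        raise ValueError("too few observations")
    included: list[str] = []
    while True:
        changed = False
        # forward
        X_in = np.column_stack([np.ones(len(y))] +
                               [X[c].to_numpy() for c in included])
        best_p, best_c = None, None
        for c in candidates:
            if c in included:
                continue
            p = _partial_f_pvalue(y, X_in, X[c].to_numpy())
            if p is None:
                continue
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_p is not None and best_p < p_enter:
            included.append(best_c)
            changed = True
        # backward
        while len(included) > 0:
            Xm = sm.add_constant(X[included].to_numpy())
            fit = sm.OLS(y, Xm).fit()
            pv = fit.pvalues[1:]
            worst = int(np.argmax(pv))
            if pv[worst] > p_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not included:
        return RegressionModel(str(response), float(np.mean(y)), {})
    Xm = sm.add_constant(X[included].to_numpy())
    fit = sm.OLS(y, Xm).fit()
    return RegressionModel(
        response=str(response),
        intercept=float(fit.params[0]),
        coefficients={c: float(v) for c, v in zip(included, fit.params[1:])},
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        coef_pvalues={c: float(p) for c, p in zip(included, fit.pvalues[1:])},
    )


def fit_full_ols(y, X: pd.DataFrame, response: str = "y") -> RegressionModel:
    """Ordinary least squares on all candidates (the non-stepwise mode)."""
    Xm = sm.add_constant(X.to_numpy())
    fit = sm.OLS(np.asarray(y, dtype=float), Xm).fit()
    return RegressionModel(
        response=response, intercept=float(fit.params[0]),
        coefficients={c: float(v) for c, v in zip(X.columns, fit.params[1:])},
        r_squared=float(fit.rsquared), f_pvalue=float(fit.f_pvalue),
        coef_pvalues={c: float(p) for c, p in zip(X.columns, fit.pvalues[1:])},
    )


def evaluate_regression(model: RegressionModel, x: dict[str, float]) -> float:
    """intercept + Σ coefficient·value; raises if a covariate is missing."""
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in x:
            raise KeyError(f"covariate {name!r} missing from input")
        total += coef * x[name]
    return float(total)


@dataclass
class CorrelationClusterReport:
    rho: pd.DataFrame            # eco factors × functional factors
    pvalues: pd.DataFrame
    significant_05: pd.DataFrame
    significant_01: pd.DataFrame
    eco_rho: pd.DataFrame        # eco × eco, for clustering
    clusters: dict[str, int] = field(default_factory=dict)


def spearman_matrix(eco: pd.DataFrame, func: pd.DataFrame,
                    k_clusters: int = 3) -> CorrelationClusterReport:
    """Spearman ρ of every ecological factor against every functional factor,
    with significance flags and an eco-factor clustering at k clusters."""
    if len(eco) < 5 or len(eco) != len(func):
        raise ValueError("need ≥ 5 paired samples")
    rho = pd.DataFrame(index=eco.columns, columns=func.columns, dtype=float)
    pv = rho.copy()
    for e in eco.columns:
        for f in func.columns:
            r, p = stats.spearmanr(eco[e], func[f])
            rho.loc[e, f] = r
            pv.loc[e, f] = p
    if eco.shape[1] == 1:
        eco_rho = pd.DataFrame([[1.0]], index=eco.columns, columns=eco.columns)
    else:
        eco_rho = pd.DataFrame(
            stats.spearmanr(eco.to_numpy()).statistic if eco.shape[1] > 2
            else np.corrcoef(stats.rankdata(eco.to_numpy(), axis=0), rowvar=False),
            index=eco.columns, columns=eco.columns)
    clusters = (cluster_factors(eco_rho, k=k_clusters)
                if 1 < k_clusters <= eco.shape[1] else {})
    return CorrelationClusterReport(
        rho=rho, pvalues=pv,
        significant_05=pv < 0.05, significant_01=pv < 0.01,
        eco_rho=eco_rho, clusters=clusters)


def cluster_factors(corr: pd.DataFrame, k: int = 3) -> dict[str, int]:
    """Average-linkage hierarchical clustering on distance 1 − |ρ|, cut at k."""
    if not np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    d = 1.0 - np.abs(corr.to_numpy())
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return {name: int(lab) for name, lab in zip(corr.index, labels)}


def load_table4_models() -> tuple[list[RegressionModel], list[str]]:
    """The 22 published regression models shipped with the package, plus the
    covariate order (the 10 main ecological factors)."""
    with resources.files("pharmaniche.data").joinpath(
            "table4_models.json").open() as fh:
        raw = json.load(fh)
    models = [RegressionModel(m["response"], m["intercept"],
                              dict(m["coefficients"]))
              for m in raw["models"]]
    return models, list(raw["covariate_order"])
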