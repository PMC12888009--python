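"""Correlation and regression layer: Pearson r, OLS with adjusted R², mean±SD."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["pearson", "ols_adj_r2", "mean_sd", "OLSResult"]


def pearson(x, y) -> dict[str, float]:
    """Product-moment correlation with R² and two-sided p-value.

    p comes from t = r·sqrt((n-2)/(1-r²)) against Student t with n-2
    degrees of freedom, the standard test for zero correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return {"r": r, "r_squared": r * r, "p_two_sided": float(res.pvalue)}


@dataclass
class OLSResult:
    coefficients: dict[str, float]
    r_squared: float
    adjusted_r_squared: float
    model_p: float


def ols_adj_r2(
    y,
    predictors: pd.DataFrame | np.ndarray,
    factor: list[str] | pd.Series | None = None,
    interaction: bool = False,
) -> OLSResult:
    """OLS fit with adjusted R² and overall-F p-value.

    ``factor`` adds a categorical term (e.g. species) as reference-level
    dummies, reference = alphabetically first level; ``interaction=True``
    additionally crosses the dummies with every numeric predictor.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(predictors, np.ndarray):
        predictors = pd.DataFrame(
            predictors.reshape(len(y), -1),
            columns=[f"x{i}" for i in range(predictors.reshape(len(y), -1).shape[1])],
        )
    X = predictors.reset_index(drop=True).astype(float)
    if factor is not None:
        levels = pd.Categorical(list(factor), ordered=False)
        dummies = pd.get_dummies(
            pd.Series(levels, name="species"), prefix="species", dtype=float
        )
        dummies = dummies[sorted(dummies.columns)].iloc[:, 1:]  # drop reference
        if interaction:
            for col in list(X.columns):
                for dcol in dummies.columns:
                    X[f"{col}:{dcol}"] = X[col] * dummies[dcol]
        X = pd.concat([X, dummies.reset_index(drop=True)], axis=1)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        cols: list[str] = []
        base = np.ones((n, 1))
        for c in Xc.columns[1:]:
            cand = np.column_stack([base, Xc[c].to_numpy()])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                collinear.append(str(c))
            else:
                base = cand
                cols.append(str(c))
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(y, Xc).fit()
    return OLSResult(
        coefficients={str(k): float(v) for k, v in res.params.items()},
        r_squared=float(res.rsquared),
        adjusted_r_squared=float(res.rsquared_adj),
        model_p=float(res.f_pvalue),
    )


def mean_sd(values) -> dict[str, float]:
    """Arithmetic mean and sample SD (n-1 denominator).

    The sample SD is undefined for a single observation, so n = 1 raises.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if v.size == 1:
        raise ValueError("sample SD undefined for n = 1")
    return {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
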