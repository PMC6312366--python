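"""Regression and correlation analysis of simulation experiments.

Network metrics are regressed one at a time on each landscape metric
with single-predictor generalized linear models: identity-link Gaussian
for the continuous responses (connectance, nestedness, H2', asymmetry)
and log-link Poisson for the count response (network size).  Pairwise
Spearman rank correlations describe the collinearity of the landscape
metrics themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GlmResult",
    "LANDSCAPE_METRICS",
    "NETWORK_RESPONSES",
    "fit_single_glm",
    "spearman",
    "spearman_matrix",
    "run_study_analysis",
]

#: landscape metric columns, in table order
LANDSCAPE_METRICS = ("pland", "area_mn", "area_am", "shape_mn", "shape_am", "connect")

#: network response -> GLM family
NETWORK_RESPONSES = {
    "connectance": "gaussian_identity",
    "nestedness": "gaussian_identity",
    "h2": "gaussian_identity",
    "size": "poisson_log",
    "asymmetry": "gaussian_identity",
}


@dataclass(frozen=True)
class GlmResult:
    response: str
    predictor: str
    family: str
    estimate: float
    std_error: float
    test_statistic: float
    p_value: float
    n: int


def fit_single_glm(
    table: pd.DataFrame, response: str, predictor: str, family: str = "gaussian_identity"
) -> GlmResult:
    """Fit ``response ~ 1 + predictor`` and return the slope row.

    Rows with a missing response or predictor are dropped listwise.
    The Poisson family requires a non-negative integer response.
    """
    data = table[[response, predictor]].dropna()
    if len(data) < 3:
        raise ValueError(
            f"need at least 3 complete rows for {response} ~ {predictor}, "
            f"got {len(data)}"
        )
    yv = data[response].to_numpy(dtype=float)
    xv = data[predictor].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    if family == "gaussian_identity":
        fam = sm.families.Gaussian()
    elif family == "poisson_log":
        if (yv < 0).any() or not np.allclose(yv, np.round(yv)):
            raise ValueError("Poisson family requires non-negative integer response")
        fam = sm.families.Poisson()
    else:
        raise ValueError(f"unknown family {family!r}")
    exog = sm.add_constant(xv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits trip dof warnings
        fit = sm.GLM(yv, exog, family=fam).fit()
    return GlmResult(
        response=response,
        predictor=predictor,
        family=family,
        estimate=float(fit.params[1]),
        std_error=float(fit.bse[1]),
        test_statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        n=len(data),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties; t-approx p).

    Returns (nan, nan) with a warning when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; Spearman correlation undefined")
        return float("nan"), float("nan")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def spearman_matrix(table: pd.DataFrame, columns=LANDSCAPE_METRICS):
    """Pairwise Spearman r and p matrices over the given columns."""
    cols = list(columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rij, pij = spearman(table[cols[i]], table[cols[j]])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def run_study_analysis(
    table: pd.DataFrame,
    responses: dict[str, str] | None = None,
    predictors=LANDSCAPE_METRICS,
) -> dict:
    """The full analysis layer: 30 single-predictor GLMs + Spearman matrix.

    ``table`` is the tidy experiment results table (one row per run).
    Returns a dict with a long-format ``glm`` DataFrame (one row per
    response x predictor pair) and ``spearman_r`` / ``spearman_p``
    matrices over the landscape metrics (n = number of runs).
    """
    responses = dict(NETWORK_RESPONSES) if responses is None else responses
    rows = []
    for response, family in responses.items():
        for predictor in predictors:
            try:
                res = fit_single_glm(table, response, predictor, family)
            except ValueError as exc:
                raise ValueError(
                    f"GLM failed for ({response}, {predictor}): {exc}"
                ) from exc
            rows.append(res.__dict__)
    glm = pd.DataFrame(rows)
    r, p = spearman_matrix(table, predictors)
    return {"glm": glm, "spearman_r": r, "spearman_p": p, "n": len(table)}
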