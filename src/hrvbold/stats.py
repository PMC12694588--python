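"""Between-subject regressions of HRV on age, with FDR correction.

Each log HRV measure is regressed on age in a separate OLS model with
sex and race as binary covariates (separate models avoid collinearity
among the HRV measures).  Benjamini-Hochberg step-up false discovery
rate correction is applied across the four HRV outcomes within a
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = ["RegressionResult", "ols_covariates", "bh_fdr", "hrv_age_regressions"]

HRV_MEASURES = ("log_sdnn", "log_rmssd", "log_lf", "log_hf")


@dataclass
class RegressionResult:
    """One OLS fit: the focal predictor's slope and inference."""

    outcome: str
    predictor: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)
    p_fdr: float = np.nan


def ols_covariates(
    y: np.ndarray,
    x: np.ndarray,
    covariates: pd.DataFrame | None = None,
    outcome: str = "y",
    predictor: str = "x",
) -> RegressionResult:
    """OLS of ``y`` on ``x`` plus covariate columns, with intercept."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cols = {"x": x}
    cov_names: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            cols[c] = covariates[c].to_numpy(float)
            cov_names.append(c)
    X = pd.DataFrame(cols)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} predictors plus intercept")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("collinear design matrix")
    res = sm.OLS(y, design).fit()
    return RegressionResult(
        outcome=outcome,
        predictor=predictor,
        beta=float(res.params["x"]),
        se=float(res.bse["x"]),
        t=float(res.tvalues["x"]),
        p=float(res.pvalues["x"]),
        n=n,
        covariates=cov_names,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone, capped at 1, input order preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def hrv_age_regressions(
    subjects: pd.DataFrame,
    measures: tuple[str, ...] = HRV_MEASURES,
    covariate_cols: tuple[str, ...] = ("sex", "race"),
    sample: str = "synthetic",
) -> pd.DataFrame:
    """Age -> log HRV regressions with BH-FDR across the measures.

    One OLS model per HRV measure (age as focal predictor, sex and race
    as covariates); returns one row per measure with beta, se, t, p and
    p_fdr.
    """
    results = []
    cov = subjects[list(covariate_cols)]
    for m in measures:
        r = ols_covariates(
            subjects[m].to_numpy(float),
            subjects["age"].to_numpy(float),
            covariates=cov,
            outcome=m,
            predictor="age",
        )
        results.append(r)
    adj = bh_fdr([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_fdr = float(a)
    return pd.DataFrame(
        {
            "sample": sample,
            "outcome": [r.outcome for r in results],
            "predictor": "age",
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "n": [r.n for r in results],
        }
    )
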