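"""Hierarchical multiple regression on standardized variables, the
two-predictor standardized-regression algebra, and effect sizes.

The prediction of post-traumatic stress symptoms proceeds in ordered blocks
(state-anger first, the high-anger EFP window mean second); each step reports
standardized betas, coefficient p-values, R-squared, the R-squared increment
with its F-test, and per-predictor tolerance (1 minus the R-squared of the
predictor regressed on its co-predictors).

For two standardized predictors the normal equations are closed-form:

    beta1 = (r1y - r12*r2y)/(1 - r12^2),   beta2 = (r2y - r12*r1y)/(1 - r12^2)
    R^2   = beta1*r1y + beta2*r2y,          tolerance = 1 - r12^2

:func:`reconstruct_two_predictor` inverts them: given the step-1 beta (which
equals the first predictor's validity r1y) and the two step-2 betas, it
recovers the predictor intercorrelation, the second validity, R-squared and
tolerance — the algebra that makes a printed hierarchical-regression table
internally reconstructable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-8


@dataclass
class RegressionStep:
    """One block of a hierarchical regression on z-scored variables."""

    step: int
    predictors: list
    betas: dict
    p_values: dict
    r_squared: float
    delta_r_squared: float
    delta_f: float
    delta_f_p: float
    tolerance: dict
    n: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant variable cannot be standardized")
    return (x - x.mean()) / sd


def hierarchical_regression(
    data: pd.DataFrame, y: str, blocks: list[list[str]]
) -> list[RegressionStep]:
    """Hierarchical OLS with standardized coefficients.

    ``blocks`` is an ordered list of predictor groups; step ``s`` regresses
    the z-scored outcome on the z-scored union of blocks 1..s.  Rows with any
    missing value among the outcome and all block predictors are dropped
    listwise (the count is logged).  A predictor whose tolerance within its
    step falls below 1e-8 raises an error naming it.
    """
    all_predictors = [p for b in blocks for p in b]
    cols = [y] + all_predictors
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    frame = data[cols].dropna()
    n_dropped = len(data) - len(frame)
    if n_dropped:
        logger.info("hierarchical_regression: %d case(s) dropped listwise", n_dropped)
    n = len(frame)
    if n <= len(all_predictors) + 1:
        raise ValueError(
            f"need n > p + 1 cases; have n={n} for p={len(all_predictors)} predictors"
        )
    z = {c: _zscore(frame[c].to_numpy(dtype=float)) for c in cols}
    steps: list[RegressionStep] = []
    prev_r2 = 0.0
    prev_p = 0
    for s_idx, _ in enumerate(blocks, start=1):
        preds = [p for b in blocks[:s_idx] for p in b]
        X = np.column_stack([z[p] for p in preds])
        tol = {}
        for j, pred in enumerate(preds):
            if len(preds) == 1:
                tol[pred] = 1.0
                continue
            others = np.column_stack([X[:, k] for k in range(len(preds)) if k != j])
            fit_j = sm.OLS(X[:, j], sm.add_constant(others)).fit()
            tol[pred] = float(1.0 - fit_j.rsquared)
            if tol[pred] < _COLLINEAR_TOL:
                raise ValueError(f"predictor {pred!r} is collinear with its co-predictors")
        fit = sm.OLS(z[y], sm.add_constant(X)).fit()
        r2 = float(fit.rsquared)
        q = len(preds) - prev_p
        df_resid = n - len(preds) - 1
        if q > 0 and r2 < 1.0:
            delta_f = ((r2 - prev_r2) / q) / ((1.0 - r2) / df_resid)
            delta_f_p = float(scipy.stats.f.sf(delta_f, q, df_resid))
        else:
            delta_f, delta_f_p = np.inf, 0.0
        steps.append(
            RegressionStep(
                step=s_idx,
                predictors=list(preds),
                betas={p: float(fit.params[j + 1]) for j, p in enumerate(preds)},
                p_values={p: float(fit.pvalues[j + 1]) for j, p in enumerate(preds)},
                r_squared=r2,
                delta_r_squared=r2 - prev_r2,
                delta_f=float(delta_f),
                delta_f_p=delta_f_p,
                tolerance=tol,
                n=n,
            )
        )
        prev_r2, prev_p = r2, len(preds)
    return steps


def steps_table(steps: list[RegressionStep]) -> pd.DataFrame:
    """Regression steps as a printed-table-shaped DataFrame
    (Step, Factor, Beta, p, R2, dR2, Tolerance)."""
    rows = []
    for st in steps:
        for j, p in enumerate(st.predictors):
            rows.append(
                {
                    "step": st.step,
                    "factor": p,
                    "beta": st.betas[p],
                    "p": st.p_values[p],
                    "r_squared": st.r_squared if j == 0 else np.nan,
                    "delta_r_squared": st.delta_r_squared if j == 0 else np.nan,
                    "tolerance": st.tolerance[p],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ReconstructionResult:
    """Quantities implied by a printed two-predictor standardized regression."""

    r12: float
    r1y: float
    r2y: float
    r_squared: float
    tolerance: float


def reconstruct_two_predictor(
    beta_step1: float, beta1: float, beta2: float
) -> ReconstructionResult:
    """Invert the two-predictor standardized normal equations.

    Parameters
    ----------
    beta_step1 : the step-1 standardized beta, which for a single predictor
        equals its validity r1y.
    beta1, beta2 : the step-2 standardized betas of the first and second
        predictor.
    """
    if beta2 == 0:
        raise ValueError("beta2 must be nonzero")
    r1y = float(beta_step1)
    r12 = (r1y - beta1) / beta2
    if abs(r12) > 1:
        raise ValueError(
            f"inconsistent inputs: implied predictor intercorrelation {r12:.3f} "
            "falls outside [-1, 1]"
        )
    r2y = beta2 + beta1 * r12
    r_squared = beta1 * r1y + beta2 * r2y
    return ReconstructionResult(
        r12=float(r12),
        r1y=r1y,
        r2y=float(r2y),
        r_squared=float(r_squared),
        tolerance=float(1.0 - r12**2),
    )


def cohens_d(
    values: np.ndarray, other: np.ndarray | None = None, mode: str = "one-sample"
) -> float:
    """Cohen's d.

    one-sample: mean/SD (equivalently t/sqrt(n)).  pooled: the two-group
    standardized mean difference with the pooled SD.
    """
    x = np.asarray(values, dtype=float)
    if mode == "one-sample":
        if x.size < 2:
            raise ValueError("need n >= 2")
        sd = x.std(ddof=1)
        return float(x.mean() / sd) if sd > 0 else np.nan
    if mode == "pooled":
        if other is None:
            raise ValueError("pooled mode needs two groups")
        y = np.asarray(other, dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError("need n >= 2 per group")
        sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
            x.size + y.size - 2
        )
        return float((x.mean() - y.mean()) / np.sqrt(sp2)) if sp2 > 0 else np.nan
    raise ValueError(f"unknown mode {mode!r}")
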