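"""Weighted binary logistic regression and average marginal effects.

Each utilization outcome y is modelled on the log-odds scale,

    ln(p / (1 - p)) = alpha + sum_j beta_j x_j,

fitted by iteratively reweighted least squares maximizing the
weight-multiplied Bernoulli log-likelihood (statsmodels GLM backend).
Marginal effects are AVERAGE marginal effects (dy/dx): for an indicator
regressor the weighted mean of the discrete probability change
p(x=1) - p(x=0) holding the other columns at their observed values; for
a continuous regressor the weighted mean of p(1-p) times the
coefficient.  Standard errors come from the delta method and 95%
intervals use the normal quantile 1.959964.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LogitFit",
    "MarginalEffects",
    "SeparationError",
    "fit_logit",
    "drop_zero_event_categories",
    "average_marginal_effects",
]

Z95 = 1.959964  # normal quantile for 95% intervals
SEPARATION_BOUND = 15.0  # |coefficient| beyond this flags complete separation
MAX_ITER = 100


class SeparationError(RuntimeError):
    pass


@dataclass
class LogitFit:
    """Fitted logit: coefficients, covariance and convergence state."""

    params: pd.Series  # includes "const"
    cov: pd.DataFrame
    llf: float
    converged: bool
    n_iter: int
    n_obs: int
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def design_columns(self) -> list[str]:
        return [c for c in self.params.index if c != "const"]

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.params["const"])
        for c in self.design_columns:
            eta = eta + self.params[c] * X[c].to_numpy(float)
        return eta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return _sigmoid(self.linear_predictor(X))


@dataclass
class MarginalEffects:
    """Average marginal effects on the probability scale with 95% CIs."""

    table: pd.DataFrame  # index: design column; columns: ame, se, ci_low, ci_high

    @property
    def ame(self) -> pd.Series:
        return self.table["ame"]


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logit(
    outcome: np.ndarray,
    X: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> LogitFit:
    """Fit the weighted logit by IRLS.

    Parameters
    ----------
    outcome : binary array with both classes present.
    X : design matrix WITHOUT a constant column (one is added).
    weights : positive sampling weights; the likelihood contribution of
        row i is multiplied by w_i, so rescaling all weights leaves the
        coefficients unchanged.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max() and len(X.columns) > 0:
        raise ValueError("outcome has a single class; logit is undefined")
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    Xc = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.GLM(y, Xc, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings handled below
        res = model.fit(maxiter=MAX_ITER, tol=1e-10)

    params = pd.Series(res.params, index=Xc.columns)
    big = params[params.abs() > SEPARATION_BOUND]
    if len(big):
        raise SeparationError(
            "complete separation suspected: coefficient(s) diverging for "
            + ", ".join(big.index)
        )
    if not res.converged:
        raise RuntimeError(
            f"IRLS failed to converge after {MAX_ITER} iterations "
            f"(deviance {res.deviance:.6g})"
        )
    return LogitFit(
        params=params,
        cov=pd.DataFrame(res.cov_params(), index=Xc.columns, columns=Xc.columns),
        llf=float(res.llf),
        converged=bool(res.converged),
        n_iter=int(res.fit_history["iteration"]),
        n_obs=int(y.size),
    )


def drop_zero_event_categories(
    outcome: np.ndarray,
    design,
) -> tuple[np.ndarray, "object", dict[str, int]]:
    """Remove categorical levels in which no respondent has the event.

    A level dummy whose member rows contain zero events would drive its
    coefficient to -inf (quasi-complete separation); the study convention
    is to drop those respondents and the dummy column entirely, shrinking
    the regression sample.  Returns (row mask kept, reduced design,
    log of {column: rows dropped}); a no-op when nothing is degenerate.
    """
    y = np.asarray(outcome, dtype=float)
    log: dict[str, int] = {}
    keep = np.ones(y.size, dtype=bool)
    drop_cols: list[str] = []
    for col in design.columns:
        x = design.data[col].to_numpy(float)
        members = x == 1.0
        if members.any() and y[members].sum() == 0.0:
            log[col] = int(members.sum())
            keep &= ~members
            drop_cols.append(col)
    if not drop_cols:
        return keep, design, log
    reduced = design.drop_columns(drop_cols).select_rows(keep)
    return keep, reduced, log


def average_marginal_effects(
    fit: LogitFit,
    X: pd.DataFrame,
    weights: np.ndarray | None = None,
    continuous: set[str] | None = None,
) -> MarginalEffects:
    """Average marginal effects with delta-method standard errors.

    Columns in ``continuous`` use the derivative form mean_w[p(1-p)] * b;
    all others are treated as indicators and use the discrete change
    mean_w[p(x=1) - p(x=0)].
    """
    continuous = continuous or set()
    cols = fit.design_columns
    missing = [c for c in X.columns if c not in cols]
    if missing:
        raise ValueError(f"column(s) absent from fit: {missing}")
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    wn = w / w.sum()

    Xc = X.astype(float).copy()
    Xc.insert(0, "const", 1.0)
    Xm = Xc[fit.params.index]  # align order with params/cov
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    A = Xm.to_numpy(float)

    eta = A @ beta
    p = _sigmoid(eta)
    dp = p * (1.0 - p)

    rows = []
    for col in X.columns:
        j = list(fit.params.index).index(col)
        if col in continuous:
            ame = float(np.sum(wn * dp) * beta[j])
            # grad_k = b_j * sum w p(1-p)(1-2p) x_k  (+ sum w p(1-p) at k=j)
            g = beta[j] * (A * (wn * dp * (1.0 - 2.0 * p))[:, None]).sum(axis=0)
            g[j] += float(np.sum(wn * dp))
        else:
            x_j = A[:, j]
            eta1 = eta + (1.0 - x_j) * beta[j]
            eta0 = eta - x_j * beta[j]
            p1, p0 = _sigmoid(eta1), _sigmoid(eta0)
            ame = float(np.sum(wn * (p1 - p0)))
            A1 = A.copy(); A1[:, j] = 1.0
            A0 = A.copy(); A0[:, j] = 0.0
            g = (
                (A1 * (wn * p1 * (1.0 - p1))[:, None]).sum(axis=0)
                - (A0 * (wn * p0 * (1.0 - p0))[:, None]).sum(axis=0)
            )
        se = float(np.sqrt(g @ V @ g))
        rows.append({"column": col, "ame": ame, "se": se,
                     "ci_low": ame - Z95 * se, "ci_high": ame + Z95 * se})
    return MarginalEffects(table=pd.DataFrame(rows).set_index("column"))
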