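"""Concentration index, concentration curve, Wagstaff-type decomposition
and the horizontal inequity (HI) index.

The concentration index of an outcome y against the fractional income
rank r is

    C = (2 / mu) * cov_w(y, r),

where mu is the (weighted) mean of y and cov_w the weighted *population*
covariance (divide by total weight).  Equivalently C is twice the area
between the concentration curve — cumulative outcome share against
cumulative population share, poorest first — and the 45-degree line of
equality; a curve above the diagonal (C < 0) means the outcome is
concentrated among the poor ("pro-poor"), below the diagonal (C > 0)
among the rich ("pro-rich").

For a binary outcome modelled by logit regression, C decomposes over the
regressors through the average-marginal-effect linear approximation:

    C = sum_j (AME_j * xbar_j / ybar) * C_j  +  GC_u / ybar,

where C_j is the concentration index of regressor j computed against the
same rank vector and the residual term GC_u / ybar is defined as the
remainder, so the identity holds exactly.  Summing the terms of the
need variables (gender, age, self-assessed health, chronic) gives the
need contribution; the horizontal inequity index is

    HI = C - (need contribution),

positive HI meaning pro-rich inequity in utilization at equal need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DesignMatrix, RankVector

__all__ = [
    "ConcentrationResult",
    "DecompositionResult",
    "concentration_index",
    "ci_from_curve",
    "decompose",
    "horizontal_inequity",
]


def _weights(w, n: int) -> np.ndarray:
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must match outcome length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return w


@dataclass
class ConcentrationResult:
    """Concentration index with its curve.

    ``curve`` is an (m+1, 2) array of (cumulative population share,
    cumulative outcome share) points from (0, 0) to (1, 1), ranked
    poorest-first.
    """

    index: float
    mean: float
    curve: np.ndarray

    @property
    def direction(self) -> str:
        return "pro-rich" if self.index > 0 else ("pro-poor" if self.index < 0 else "neutral")


def concentration_index(
    outcome: np.ndarray,
    ranks: RankVector | np.ndarray,
    weights: np.ndarray | None = None,
) -> ConcentrationResult:
    """Concentration index C = (2/mu) cov_w(y, r) plus the curve.

    The covariance is the weighted population covariance; the curve is
    obtained by sorting on rank and accumulating weight shares and
    weighted outcome shares.
    """
    y = np.asarray(outcome, dtype=float)
    r = ranks.rank if isinstance(ranks, RankVector) else np.asarray(ranks, dtype=float)
    if y.shape != r.shape:
        raise ValueError("outcome and ranks must have the same length")
    w = _weights(weights, y.size)

    total = w.sum()
    mu = float(np.sum(w * y) / total)
    if mu == 0.0:
        raise ValueError("index undefined for all-zero outcome")
    rbar = float(np.sum(w * r) / total)
    cov = float(np.sum(w * (y - mu) * (r - rbar)) / total)
    c = 2.0 * cov / mu

    order = np.argsort(r, kind="mergesort")
    pop = np.concatenate([[0.0], np.cumsum(w[order]) / total])
    out = np.concatenate([[0.0], np.cumsum(w[order] * y[order]) / np.sum(w * y)])
    curve = np.column_stack([pop, out])
    return ConcentrationResult(index=c, mean=mu, curve=curve)


def ci_from_curve(curve: np.ndarray) -> float:
    """Concentration index as twice the area between curve and diagonal.

    Uses trapezoid quadrature; serves as an independent cross-check of
    the covariance formula (they agree up to O(1/n) discretization).
    """
    pts = np.asarray(curve, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    if (np.diff(x) < 0).any() or (np.diff(y) < -1e-12).any():
        raise ValueError("curve points must be sorted and non-decreasing")
    area = float(np.trapezoid(y, x))
    return 1.0 - 2.0 * area


@dataclass
class DecompositionResult:
    """Per-regressor decomposition of the concentration index.

    ``table`` has one row per design column with the regressor's weighted
    mean, its concentration index, elasticity (AME * mean_x / mean_y),
    contribution (elasticity * C_x) and signed percent of total C.
    ``group_contributions`` sums contributions per conceptual variable
    (e.g. the four income-quintile dummies).  ``residual`` is the
    generalized-concentration remainder GC_u / ybar, defined so that
    need_total + socioeconomic_total + residual == total_index exactly.
    """

    table: pd.DataFrame
    group_contributions: pd.Series
    group_percents: pd.Series
    need_total: float
    socioeconomic_total: float
    residual: float
    total_index: float
    outcome_mean: float
    hi: float = field(init=False)

    def __post_init__(self) -> None:
        self.hi = horizontal_inequity(self.total_index, self.need_total)

    @property
    def hi_direction(self) -> str:
        return "pro-rich" if self.hi > 0 else ("pro-poor" if self.hi < 0 else "neutral")


def decompose(
    ames: pd.Series,
    design: DesignMatrix,
    outcome: np.ndarray,
    ranks: RankVector | np.ndarray,
    weights: np.ndarray | None = None,
) -> DecompositionResult:
    """Decompose the outcome's concentration index over the regressors.

    ``ames`` maps every design column to its average marginal effect on
    the probability scale (the elasticity numerator for the logit model's
    linear approximation).
    """
    y = np.asarray(outcome, dtype=float)
    w = _weights(weights, y.size)
    missing = [c for c in design.columns if c not in ames.index]
    if missing:
        raise ValueError(f"AME missing for design column(s): {missing}")

    total_res = concentration_index(y, ranks, w)
    ybar = total_res.mean
    r = ranks.rank if isinstance(ranks, RankVector) else np.asarray(ranks, dtype=float)
    rbar = float(np.sum(w * r) / w.sum())

    rows = []
    for col in design.columns:
        x = design.data[col].to_numpy(float)
        xbar = float(np.sum(w * x) / w.sum())
        if xbar > 0:
            cov_x = float(np.sum(w * (x - xbar) * (r - rbar)) / w.sum())
            c_x = 2.0 * cov_x / xbar
        else:  # degenerate all-zero regressor contributes nothing
            c_x = 0.0
        elasticity = float(ames[col]) * xbar / ybar
        contribution = elasticity * c_x
        rows.append({
            "column": col,
            "group": design.groups[col],
            "role": design.roles[col],
            "ame": float(ames[col]),
            "mean_x": xbar,
            "ci_x": c_x,
            "elasticity": elasticity,
            "contribution": contribution,
        })
    table = pd.DataFrame(rows).set_index("column")
    total_c = total_res.index
    table["percent"] = np.where(
        total_c != 0.0, 100.0 * table["contribution"] / total_c, np.nan
    )

    group_contrib = table.groupby("group", sort=False)["contribution"].sum()
    group_pct = (
        100.0 * group_contrib / total_c if total_c != 0.0
        else pd.Series(np.nan, index=group_contrib.index)
    )
    need_total = float(table.loc[table["role"] == "need", "contribution"].sum())
    socio_total = float(table.loc[table["role"] == "socioeconomic", "contribution"].sum())
    residual = total_c - need_total - socio_total

    return DecompositionResult(
        table=table,
        group_contributions=group_contrib,
        group_percents=group_pct,
        need_total=need_total,
        socioeconomic_total=socio_total,
        residual=residual,
        total_index=total_c,
        outcome_mean=ybar,
    )


def horizontal_inequity(total_c: float, need_total: float) -> float:
    """HI = total concentration index minus the need contribution.

    Positive HI: utilization concentrated among the rich at equal need
    (pro-rich inequity); negative: pro-poor.
    """
    if not (np.isfinite(total_c) and np.isfinite(need_total)):
        raise ValueError("total_c and need_total must be finite")
    return float(total_c - need_total)
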