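"""Group comparison descriptives: level-by-scheme contingency tables with
column percentages and Pearson chi-square tests.

Counts are unweighted raw counts — the study's printed group-comparison
statistics reproduce exactly from raw counts without continuity
correction, so that is the convention here (later stages weight).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DEFAULT_CUTPOINTS, assign_quintiles

__all__ = [
    "ContingencyTable",
    "crosstab",
    "pearson_chi_square",
    "format_percent",
    "DESCRIPTIVE_VARIABLES",
]

#: Variables summarized in the scheme-comparison table, with display levels.
DESCRIPTIVE_VARIABLES: dict[str, dict] = {
    "outpatient": {1: "yes", 0: "no"},
    "inpatient": {1: "yes", 0: "no"},
    "gender": {1: "male", 0: "female"},
    "age_band": {0: "45-59", 1: "60+"},
    "self_health": {1: "excellent", 2: "very_good", 3: "good", 4: "fair", 5: "poor"},
    "chronic": {1: "sick", 0: "not_sick"},
    "married": {1: "married", 0: "single"},
    "education": {0: "illiterate", 1: "primary", 2: "junior_senior", 3: "college"},
    "income_quintile": {1: "q1", 2: "q2", 3: "q3", 4: "q4", 5: "q5"},
    "region": {"east": "east", "central": "central", "west": "west"},
    "community": {1: "town_center", 0: "rural"},
}


@dataclass
class ContingencyTable:
    """Level x scheme counts with rendered column percentages."""

    counts: pd.DataFrame      # rows: levels, cols: schemes, int counts
    percents: pd.DataFrame    # same shape, strings rendered to 2 decimals
    variable: str

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def format_percent(numerator: int, denominator: int) -> str:
    """Column percentage rendered to 2 decimals with half-up rounding
    (e.g. 734/3593 -> '20.43')."""
    if denominator == 0:
        return "nan"
    pct = Decimal(int(numerator)) * 100 / Decimal(int(denominator))
    return str(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _derived_series(records: pd.DataFrame, variable: str) -> pd.Series:
    if variable == "age_band":
        return (records["age"].astype(float) >= 60).astype(int)
    if variable == "income_quintile":
        return pd.Series(
            assign_quintiles(records["income"].to_numpy(float), cutpoints=DEFAULT_CUTPOINTS),
            index=records.index,
        )
    if variable not in records.columns:
        raise KeyError(f"variable {variable!r} not in records")
    return records[variable]


def crosstab(records: pd.DataFrame, variable: str) -> ContingencyTable:
    """Unweighted level-by-scheme contingency table.

    Levels listed in the variable's schema but absent from the data are
    retained as zero rows.
    """
    series = _derived_series(records, variable)
    schemes = ["URRBMI", "NCMS"]
    level_map = DESCRIPTIVE_VARIABLES.get(variable)
    if level_map is None:
        levels = sorted(series.unique())
        level_map = {lv: str(lv) for lv in levels}

    counts = pd.DataFrame(0, index=list(level_map.values()), columns=schemes, dtype=int)
    for raw_level, label in level_map.items():
        for scheme in schemes:
            counts.loc[label, scheme] = int(
                ((series == raw_level) & (records["scheme"] == scheme)).sum()
            )
    col_totals = counts.sum(axis=0)
    percents = counts.copy().astype(object)
    for label in counts.index:
        for scheme in schemes:
            percents.loc[label, scheme] = format_percent(
                counts.loc[label, scheme], col_totals[scheme]
            )
    return ContingencyTable(counts=counts, percents=percents, variable=variable)


def pearson_chi_square(table: ContingencyTable | pd.DataFrame | np.ndarray):
    """Pearson chi-square test of independence (no continuity correction).

    Returns (statistic, df, p_value).  Expected counts come from the
    product of marginals; a zero row or column marginal is degenerate.
    """
    obs = table.counts if isinstance(table, ContingencyTable) else table
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
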