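"""Respondent data model: inclusion filtering, dummy encoding, income
quintiles, and the weighted fractional rank.

The analysis operates on a flat respondent table (one row per survey
respondent) with two binary utilization outcomes, health-need covariates
(gender, age band, self-assessed health, chronic morbidity), socioeconomic
covariates (marital status, education, per-capita household income, region,
community type), the insurance scheme, and a sampling weight.

Column schema of the input CSV (UTF-8, missing = empty cell):

======== =======================================================
column    meaning
======== =======================================================
outpatient  visited a doctor in the last month (1/0)
inpatient   received inpatient care in the last year (1/0)
gender      male = 1, female = 0
age         age in completed years (45+); the model uses the 60+ band
self_health self-assessed health, 1 (excellent) .. 5 (poor)
chronic     at least one chronic disease (1/0)
married     married/cohabiting = 1, single/divorced/widowed = 0
education   0 illiterate, 1 primary, 2 junior/senior high, 3 college+
income      per-capita household income, yuan/year (>= 0)
region      east | central | west
community   town-center / urban-fringe address = 1, rural = 0
scheme      URRBMI | NCMS
weight      positive sampling weight
======== =======================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ANALYSIS_COLUMNS",
    "NEED_VARIABLES",
    "SOCIOECONOMIC_VARIABLES",
    "DEFAULT_CUTPOINTS",
    "DesignMatrix",
    "RankVector",
    "apply_inclusion_criteria",
    "encode_design",
    "assign_quintiles",
    "weighted_fractional_rank",
]

#: Columns every analysis row must carry (complete-case analysis).
ANALYSIS_COLUMNS = [
    "outpatient", "inpatient", "gender", "age", "self_health", "chronic",
    "married", "education", "income", "region", "community", "scheme",
    "weight",
]

#: Conceptual variables whose utilization differences are considered
#: equitable (health need) vs. inequitable (socioeconomic).
NEED_VARIABLES = ["gender", "age", "self_health", "chronic"]
SOCIOECONOMIC_VARIABLES = ["married", "education", "income", "region", "community"]

#: Printed per-capita income quintile upper bounds (yuan): the lowest
#: quintile is [0, 17], then (17, 495], (495, 2587], (2587, 9992], > 9992.
DEFAULT_CUTPOINTS = (17.0, 495.0, 2587.0, 9992.0)

VALID_SCHEMES = ("URRBMI", "NCMS")
VALID_REGIONS = ("east", "central", "west")

SELF_HEALTH_LEVELS = {1: "excellent", 2: "very_good", 3: "good", 4: "fair"}
EDUCATION_LEVELS = {1: "primary", 2: "junior_senior", 3: "college"}


@dataclass
class DesignMatrix:
    """Dummy-encoded regressor matrix with role and group annotations.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per retained respondent, one column per indicator regressor.
    roles : dict
        Column -> ``"need"`` or ``"socioeconomic"``.
    groups : dict
        Column -> conceptual variable name (all four income-quintile
        dummies share group ``"income"``, etc.).
    reference_categories : dict
        Conceptual variable -> omitted level.
    """

    data: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    reference_categories: dict[str, str] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def need_columns(self) -> list[str]:
        return [c for c in self.columns if self.roles[c] == "need"]

    def socioeconomic_columns(self) -> list[str]:
        return [c for c in self.columns if self.roles[c] == "socioeconomic"]

    def drop_columns(self, cols: list[str]) -> "DesignMatrix":
        keep = [c for c in self.columns if c not in cols]
        return DesignMatrix(
            data=self.data[keep],
            roles={c: self.roles[c] for c in keep},
            groups={c: self.groups[c] for c in keep},
            reference_categories=dict(self.reference_categories),
        )

    def select_rows(self, mask: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            data=self.data.loc[mask],
            roles=dict(self.roles),
            groups=dict(self.groups),
            reference_categories=dict(self.reference_categories),
        )

    def decode(self, variable: str) -> pd.Series:
        """Recover the categorical level from the variable's dummy columns."""
        cols = [c for c in self.columns if self.groups[c] == variable]
        if not cols:
            raise KeyError(f"no columns for variable {variable!r}")
        ref = self.reference_categories.get(variable)
        sub = self.data[cols]
        level = pd.Series(ref, index=sub.index, dtype=object)
        for c in cols:
            level[sub[c] == 1] = c.removeprefix(f"{variable}_") or c
        return level


@dataclass
class RankVector:
    """Weighted fractional income ranks r_i in (0, 1).

    Ranks are midpoint cumulative weighted population shares: each
    respondent's rank is the weight share of everyone strictly poorer plus
    half the share of their own tie group; the weighted mean rank is 0.5.
    """

    rank: np.ndarray
    ordering_variable: str = "income"
    weights_used: bool = True

    def __post_init__(self) -> None:
        r = np.asarray(self.rank, dtype=float)
        if r.size and (r.min() <= 0.0 or r.max() >= 1.0):
            raise ValueError("fractional ranks must lie strictly in (0, 1)")
        self.rank = r


def apply_inclusion_criteria(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study inclusion rules and log every exclusion.

    Drops rows with any missing analysis variable, negative per-capita
    income, or an insurance scheme outside {URRBMI, NCMS}.  Returns the
    retained rows and a log counting exclusions by reason
    (``missing``, ``negative_income``, ``non_target_scheme``).
    Rows failing several rules are counted once, by the first rule above.
    """
    missing_cols = [c for c in ANALYSIS_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"input lacks required columns: {missing_cols}")

    df = raw.copy()
    log: dict[str, int] = {}

    miss = df[ANALYSIS_COLUMNS].isna().any(axis=1)
    if miss.any():
        log["missing"] = int(miss.sum())
    df = df.loc[~miss]

    neg = df["income"].astype(float) < 0
    if neg.any():
        log["negative_income"] = int(neg.sum())
    df = df.loc[~neg]

    bad_scheme = ~df["scheme"].isin(VALID_SCHEMES)
    if bad_scheme.any():
        log["non_target_scheme"] = int(bad_scheme.sum())
    df = df.loc[~bad_scheme]

    if len(df) == 0:
        raise ValueError("no analyzable records")
    return df.reset_index(drop=True), log


def _check_levels(values: pd.Series, allowed, variable: str) -> None:
    bad = set(values.unique()) - set(allowed)
    if bad:
        raise ValueError(f"unknown level(s) {sorted(map(str, bad))!r} for variable {variable!r}")


def encode_design(
    records: pd.DataFrame,
    cutpoints: tuple[float, float, float, float] = DEFAULT_CUTPOINTS,
    quintile_mode: str = "fixed_cutpoints",
) -> DesignMatrix:
    """Dummy-encode the respondents into the regression design.

    Reference categories follow the study convention: female, age 45-59,
    self-assessed health "poor", no chronic disease, single/divorced/widowed,
    illiterate, lowest income quintile, east region, rural community.
    Income enters as four quintile dummies (see :func:`assign_quintiles`).
    """
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    groups: dict[str, str] = {}

    def add(name: str, values, role: str, group: str) -> None:
        cols[name] = np.asarray(values, dtype=float)
        roles[name] = role
        groups[name] = group

    gender = records["gender"].astype(float)
    _check_levels(gender, {0.0, 1.0}, "gender")
    add("gender", gender, "need", "gender")

    age = records["age"].astype(float)
    add("age", (age >= 60).astype(float), "need", "age")

    sh = records["self_health"].astype(int)
    _check_levels(sh, {1, 2, 3, 4, 5}, "self_health")
    for lev, name in SELF_HEALTH_LEVELS.items():
        add(f"self_health_{name}", (sh == lev).astype(float), "need", "self_health")

    chronic = records["chronic"].astype(float)
    _check_levels(chronic, {0.0, 1.0}, "chronic")
    add("chronic", chronic, "need", "chronic")

    married = records["married"].astype(float)
    _check_levels(married, {0.0, 1.0}, "married")
    add("married", married, "socioeconomic", "married")

    edu = records["education"].astype(int)
    _check_levels(edu, {0, 1, 2, 3}, "education")
    for lev, name in EDUCATION_LEVELS.items():
        add(f"education_{name}", (edu == lev).astype(float), "socioeconomic", "education")

    if quintile_mode == "fixed_cutpoints":
        q = assign_quintiles(records["income"].to_numpy(float), cutpoints=cutpoints)
    elif quintile_mode == "weighted_quantiles":
        q = assign_quintiles(
            records["income"].to_numpy(float),
            weights=records["weight"].to_numpy(float),
            mode="weighted_quantiles",
        )
    else:
        raise ValueError(f"unknown quintile mode {quintile_mode!r}")
    for lev, name in enumerate(["q2", "q3", "q4", "q5"], start=2):
        add(f"income_{name}", (q == lev).astype(float), "socioeconomic", "income")

    region = records["region"].astype(str)
    _check_levels(region, VALID_REGIONS, "region")
    add("region_central", (region == "central").astype(float), "socioeconomic", "region")
    add("region_west", (region == "west").astype(float), "socioeconomic", "region")

    community = records["community"].astype(float)
    _check_levels(community, {0.0, 1.0}, "community")
    add("community", community, "socioeconomic", "community")

    data = pd.DataFrame(cols, index=records.index)
    refs = {
        "gender": "female", "age": "45-59", "self_health": "poor",
        "chronic": "not_sick", "married": "single", "education": "illiterate",
        "income": "q1", "region": "east", "community": "rural",
    }
    return DesignMatrix(data=data, roles=roles, groups=groups, reference_categories=refs)


def assign_quintiles(
    income: np.ndarray,
    weights: np.ndarray | None = None,
    cutpoints: tuple[float, float, float, float] = DEFAULT_CUTPOINTS,
    mode: str = "fixed_cutpoints",
) -> np.ndarray:
    """Label incomes 1..5 by quintile.

    ``fixed_cutpoints`` uses the supplied upper bounds (c1..c4): quintile 1
    is the closed interval [0, c1]; quintiles 2-4 are the half-open
    intervals (c_{k-1}, c_k]; quintile 5 is (c4, inf).
    ``weighted_quantiles`` first computes the weighted 20/40/60/80th
    percentiles of ``income`` and then applies the same interval logic.
    """
    x = np.asarray(income, dtype=float)
    if (x < 0).any():
        raise ValueError("income must be non-negative")
    if mode == "weighted_quantiles":
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
        cutpoints = tuple(weighted_quantile(x, w, [0.2, 0.4, 0.6, 0.8]))
    c1, c2, c3, c4 = cutpoints
    if not (c1 <= c2 <= c3 <= c4):
        raise ValueError(f"cutpoints must be non-decreasing, got {cutpoints}")
    q = np.full(x.shape, 5, dtype=int)
    q[x <= c4] = 4
    q[x <= c3] = 3
    q[x <= c2] = 2
    q[x <= c1] = 1
    return q


def weighted_quantile(values: np.ndarray, weights: np.ndarray, probs) -> np.ndarray:
    """Weighted quantiles by inverse of the right-continuous weighted CDF."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / w.sum()
    return np.array([v[np.searchsorted(cum, p, side="left")] for p in np.atleast_1d(probs)])


def weighted_fractional_rank(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    ordering_variable: str = "income",
) -> RankVector:
    """Midpoint weighted fractional ranks in (0, 1).

    Sorting by value ascending, rank_i = (cumulative weight of strictly
    lower values + half the combined weight of i's tie group) / total
    weight.  Tied values share one rank.  With equal weights and distinct
    values this reduces to (2i - 1) / (2n).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot rank an empty vector")
    weights_used = weights is not None
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    order = np.argsort(v, kind="mergesort")
    v_sorted, w_sorted = v[order], w[order]
    total = w_sorted.sum()
    below = np.concatenate([[0.0], np.cumsum(w_sorted)[:-1]])

    # collapse tie groups: every member gets (below_first + half group weight)
    rank_sorted = np.empty_like(v_sorted)
    i = 0
    n = v_sorted.size
    while i < n:
        j = i
        while j + 1 < n and v_sorted[j + 1] == v_sorted[i]:
            j += 1
        group_w = w_sorted[i : j + 1].sum()
        rank_sorted[i : j + 1] = (below[i] + group_w / 2.0) / total
        i = j + 1

    rank = np.empty_like(rank_sorted)
    rank[order] = rank_sorted
    return RankVector(rank=rank, ordering_variable=ordering_variable, weights_used=weights_used)
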