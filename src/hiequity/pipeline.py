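"""Full study pipeline: include -> describe -> fit -> AME -> CI ->
decompose -> HI, per insurance scheme group and outcome, with rendered
report tables.

Stage-specific weighting defaults follow the study's mixed conventions:
descriptive contingency tables use raw unweighted counts, while the
regression, the concentration index and the decomposition use the
sampling weights; each can be switched independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .data_model import (
    DEFAULT_CUTPOINTS,
    RankVector,
    apply_inclusion_criteria,
    encode_design,
    weighted_fractional_rank,
)
from .descriptives import DESCRIPTIVE_VARIABLES, crosstab, pearson_chi_square
from .inequity import DecompositionResult, concentration_index, decompose
from .outcome_model import average_marginal_effects, drop_zero_event_categories, fit_logit

__all__ = [
    "RunConfig", "StudyReport", "run_full_analysis", "render_tables",
    "load_config", "estimate_hi",
]

OUTCOMES = ("outpatient", "inpatient")
SCHEMES = ("URRBMI", "NCMS")


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str | None = None
    outcomes: tuple[str, ...] = OUTCOMES
    schemes: tuple[str, ...] = SCHEMES
    ranking_variable: str = "income"
    weights_column: str = "weight"
    quintile_mode: str = "fixed_cutpoints"
    cutpoints: tuple[float, float, float, float] = DEFAULT_CUTPOINTS
    weighted_ranks: bool = True
    weighted_fit: bool = True
    weighted_ci: bool = True
    output_dir: str | None = None
    seed: int | None = None


@dataclass
class GroupOutcomeResult:
    scheme: str
    outcome: str
    n_group: int
    n_regression: int
    dropped_rows: dict[str, int]
    fit_params: pd.Series
    ame_table: pd.DataFrame
    ci_full_sample: float
    decomposition: DecompositionResult


@dataclass
class StudyReport:
    config: RunConfig
    exclusion_log: dict[str, int]
    group_sizes: dict[str, int]
    descriptives: dict[str, dict]
    results: list[GroupOutcomeResult] = field(default_factory=list)
    version: str = __version__

    def result(self, scheme: str, outcome: str) -> GroupOutcomeResult:
        for r in self.results:
            if r.scheme == scheme and r.outcome == outcome:
                return r
        raise KeyError((scheme, outcome))

    def hi_table(self) -> pd.DataFrame:
        """Analogue of the CI / need-contribution / HI summary table."""
        cols = {}
        for r in self.results:
            d = r.decomposition
            cols[f"{r.outcome}_{r.scheme}"] = {
                "CI": d.total_index,
                "need_contribution": d.need_total,
                "HI": d.hi,
            }
        return pd.DataFrame(cols)


def estimate_hi(
    records: pd.DataFrame,
    outcome: str,
    weighted: bool = True,
) -> DecompositionResult:
    """One-shot decomposition of a respondent table (no scheme split).

    Convenience wrapper chaining encode -> rank -> zero-event drop ->
    logit fit -> AMEs -> decomposition; returns the full
    :class:`~hiequity.inequity.DecompositionResult` (its ``hi`` attribute
    is the horizontal inequity index).
    """
    records = records.reset_index(drop=True)
    w = records["weight"].to_numpy(float) if weighted else None
    design = encode_design(records)
    ranks = weighted_fractional_rank(records["income"].to_numpy(float), w)
    y = records[outcome].to_numpy(float)
    keep, design_r, _ = drop_zero_event_categories(y, design)
    y_r = y[keep]
    ranks_r = RankVector(ranks.rank[keep], ranks.ordering_variable, ranks.weights_used)
    w_r = None if w is None else w[keep]
    fit = fit_logit(y_r, design_r.data, w_r)
    ame = average_marginal_effects(fit, design_r.data, w_r)
    return decompose(ame.ame, design_r, y_r, ranks_r, w_r)


def load_config(path: str | Path) -> RunConfig:
    """Read a plain ``key: value`` (YAML-compatible) config file."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "cutpoints" in raw:
        raw["cutpoints"] = tuple(float(c) for c in raw["cutpoints"])
    for key in ("outcomes", "schemes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def run_full_analysis(records: pd.DataFrame, config: RunConfig | None = None) -> StudyReport:
    """Execute every stage on ``records`` and assemble the report.

    Deterministic given (records, config).  The concentration index of
    each outcome is computed on the full retained group sample; the
    decomposition runs on the regression sample (after any zero-event
    level drop), and both are reported.
    """
    config = config or RunConfig()
    try:
        retained, excl_log = apply_inclusion_criteria(records)
    except ValueError as e:
        raise RuntimeError(f"stage inclusion: {e}") from e

    group_sizes = {s: int((retained["scheme"] == s).sum()) for s in config.schemes}
    descr: dict[str, dict] = {}
    for var in DESCRIPTIVE_VARIABLES:
        try:
            tab = crosstab(retained, var)
        except KeyError as e:
            raise RuntimeError(f"stage describe ({var}): {e}") from e
        try:
            stat, df, p = pearson_chi_square(tab)
        except ValueError:
            # a level empty in both schemes makes the test degenerate;
            # keep the counts, mark the test as unavailable
            stat, df, p = float("nan"), 0, float("nan")
        descr[var] = {"counts": tab.counts, "percents": tab.percents,
                      "chi2": stat, "df": df, "p": p}

    report = StudyReport(
        config=config, exclusion_log=excl_log, group_sizes=group_sizes,
        descriptives=descr,
    )

    for scheme in config.schemes:
        sub = retained[retained["scheme"] == scheme].reset_index(drop=True)
        if len(sub) == 0:
            raise RuntimeError(f"stage split: no records for scheme {scheme!r}")
        w = sub[config.weights_column].to_numpy(float)
        rank_w = w if config.weighted_ranks else None
        ranks = weighted_fractional_rank(
            sub[config.ranking_variable].to_numpy(float), rank_w,
            ordering_variable=config.ranking_variable,
        )
        design = encode_design(sub, cutpoints=config.cutpoints,
                               quintile_mode=config.quintile_mode)
        ci_w = w if config.weighted_ci else None
        fit_w = w if config.weighted_fit else None

        for outcome in config.outcomes:
            y = sub[outcome].to_numpy(float)
            try:
                full_ci = concentration_index(y, ranks, ci_w)
                keep, design_r, drop_log = drop_zero_event_categories(y, design)
                y_r = y[keep]
                ranks_r = RankVector(ranks.rank[keep], ranks.ordering_variable,
                                     ranks.weights_used)
                w_fit = None if fit_w is None else fit_w[keep]
                w_ci = None if ci_w is None else ci_w[keep]
                fit = fit_logit(y_r, design_r.data, w_fit)
                ame = average_marginal_effects(fit, design_r.data, w_fit)
                dec = decompose(ame.ame, design_r, y_r, ranks_r, w_ci)
            except (ValueError, RuntimeError) as e:
                raise RuntimeError(f"stage fit/decompose ({scheme}, {outcome}): {e}") from e
            report.results.append(GroupOutcomeResult(
                scheme=scheme, outcome=outcome, n_group=len(sub),
                n_regression=int(keep.sum()), dropped_rows=drop_log,
                fit_params=fit.params, ame_table=ame.table,
                ci_full_sample=full_ci.index, decomposition=dec,
            ))
    return report


def render_tables(report: StudyReport, out_dir: str | Path, fmt: str = "csv") -> list[Path]:
    """Write the report's table files (descriptives, AMEs, CI,
    contributions, HI) plus a JSON run log; deterministic re-render.

    Contributions and indices are rounded to 3 decimals for display,
    percentages of counts to 2; full precision lives in the report
    object.  ``fmt`` must be ``csv`` (machine-readable tables; the run
    log is always JSON).
    """
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = []
    for var, d in report.descriptives.items():
        for level in d["counts"].index:
            row = {"variable": var, "level": level}
            for scheme in d["counts"].columns:
                row[f"n_{scheme}"] = d["counts"].loc[level, scheme]
                row[f"pct_{scheme}"] = d["percents"].loc[level, scheme]
            row["chi2"] = round(d["chi2"], 3)
            row["p"] = round(d["p"], 3)
            rows.append(row)
    p = out / "table_descriptives.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    ame_rows = []
    for r in report.results:
        t = r.ame_table.round(3)
        for col in t.index:
            ame_rows.append({"outcome": r.outcome, "scheme": r.scheme, "variable": col,
                             **t.loc[col].to_dict()})
    p = out / "table_marginal_effects.csv"
    pd.DataFrame(ame_rows).to_csv(p, index=False)
    written.append(p)

    ci_rows = [{"outcome": r.outcome, "scheme": r.scheme,
                "ci_full_sample": round(r.ci_full_sample, 3),
                "ci_regression_sample": round(r.decomposition.total_index, 3)}
               for r in report.results]
    p = out / "table_concentration_index.csv"
    pd.DataFrame(ci_rows).to_csv(p, index=False)
    written.append(p)

    contrib_rows = []
    for r in report.results:
        t = r.decomposition.table
        for col in t.index:
            contrib_rows.append({
                "outcome": r.outcome, "scheme": r.scheme, "variable": col,
                "group": t.loc[col, "group"], "role": t.loc[col, "role"],
                "contribution": round(t.loc[col, "contribution"], 3),
                "percent": round(t.loc[col, "percent"], 3),
            })
    p = out / "table_contributions.csv"
    pd.DataFrame(contrib_rows).to_csv(p, index=False)
    written.append(p)

    p = out / "table_horizontal_inequity.csv"
    report.hi_table().round(3).to_csv(p)
    written.append(p)

    log = {
        "version": report.version,
        "exclusions": report.exclusion_log,
        "group_sizes": report.group_sizes,
        "regression_samples": {
            f"{r.outcome}_{r.scheme}": {"n": r.n_regression, "dropped": r.dropped_rows}
            for r in report.results
        },
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(report.config).items()},
    }
    p = out / "run_log.json"
    p.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(p)
    return written
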