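#!/usr/bin/env python
"""Weighted logit fits and average marginal effects per scheme and outcome.

Reads results/data/synthetic_survey.csv, fits the utilization logit for
each scheme x outcome cell (dropping zero-event levels as needed), and
writes results/tables/table_marginal_effects.csv with dy/dx and 95% CIs.
"""

from pathlib import Path

import pandas as pd

from hiequity import apply_inclusion_criteria, encode_design
from hiequity.outcome_model import (
    average_marginal_effects,
    drop_zero_event_categories,
    fit_logit,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    records = pd.read_csv(ROOT / "results" / "data" / "synthetic_survey.csv")
    retained, _ = apply_inclusion_criteria(records)

    rows = []
    for scheme in ("URRBMI", "NCMS"):
        sub = retained[retained.scheme == scheme].reset_index(drop=True)
        design = encode_design(sub)
        w = sub.weight.to_numpy(float)
        for outcome in ("outpatient", "inpatient"):
            y = sub[outcome].to_numpy(float)
            keep, d, drop_log = drop_zero_event_categories(y, design)
            fit = fit_logit(y[keep], d.data, w[keep])
            ame = average_marginal_effects(fit, d.data, w[keep])
            dropped = f" (dropped {drop_log})" if drop_log else ""
            print(f"{scheme} {outcome}: n={fit.n_obs}{dropped}")
            sig = ame.table[ame.table.ci_low * ame.table.ci_high > 0]
            for col, r in sig.iterrows():
                print(f"    {col:<26} dy/dx={r.ame:+.3f} [{r.ci_low:+.3f}, {r.ci_high:+.3f}]")
            for col, r in ame.table.iterrows():
                rows.append({"scheme": scheme, "outcome": outcome, "variable": col,
                             "n": fit.n_obs, **r.round(4).to_dict()})
    out = ROOT / "results" / "tables"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "table_marginal_effects.csv", index=False)
    print(f"\nwrote {out / 'table_marginal_effects.csv'} "
          "(significant effects at the 5% level printed above)")


if __name__ == "__main__":
    main()
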