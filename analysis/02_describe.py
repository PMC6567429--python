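#!/usr/bin/env python
"""Scheme-comparison descriptives on the simulated survey.

Reads results/data/synthetic_survey.csv, applies the inclusion rules,
tabulates every analysis variable by insurance scheme with column
percentages and Pearson chi-square tests, and writes
results/tables/table_descriptives.csv.
"""

from pathlib import Path

import pandas as pd

from hiequity import apply_inclusion_criteria
from hiequity.descriptives import DESCRIPTIVE_VARIABLES, crosstab, pearson_chi_square

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    records = pd.read_csv(ROOT / "results" / "data" / "synthetic_survey.csv")
    retained, log = apply_inclusion_criteria(records)
    print(f"retained {len(retained)} respondents; exclusions: {log or 'none'}")

    rows = []
    for var in DESCRIPTIVE_VARIABLES:
        tab = crosstab(retained, var)
        stat, df, p = pearson_chi_square(tab)
        flag = " *" if p < 0.05 else ""
        print(f"{var:<16} chi2={stat:8.3f}  p={p:.3f}{flag}")
        for level in tab.counts.index:
            rows.append({
                "variable": var, "level": level,
                "n_URRBMI": tab.counts.loc[level, "URRBMI"],
                "pct_URRBMI": tab.percents.loc[level, "URRBMI"],
                "n_NCMS": tab.counts.loc[level, "NCMS"],
                "pct_NCMS": tab.percents.loc[level, "NCMS"],
                "chi2": round(stat, 3), "p": round(p, 3),
            })
    out = ROOT / "results" / "tables"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "table_descriptives.csv", index=False)
    print(f"\nwrote {out / 'table_descriptives.csv'}")


if __name__ == "__main__":
    main()
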