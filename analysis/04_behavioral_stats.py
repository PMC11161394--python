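#!/usr/bin/env python
"""Behavioral statistics on load scores and neuropsychological measures.

Mann-Whitney group comparisons of the zero-inflated load distributions, the
four planned diagnosis-by-outlier-status t-test contrasts per measure (both
HR and LR arms) with FDR adjustment, load-behavior Spearman correlations in
the outlier-positive subgroups, and Table-1-style group matching.  Writes
TSVs to results/stats/.  Run 01 and 02 first.
"""

import warnings
from pathlib import Path

import pandas as pd

from surfload.behavioral import (
    battery_wide_table,
    comparisons_frame,
    group_matching,
    mann_whitney_u,
    subgroup_battery,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    subjects = pd.read_csv(ROOT / "cohort" / "subjects.tsv", sep="\t")
    loads = pd.read_csv(ROOT / "outliers" / "loads.tsv", sep="\t")
    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)

    for col, label in (("hr_load", "HR"), ("lr_load", "LR")):
        u, p = mann_whitney_u(loads.loc[loads["group"] == "ASD", col],
                              loads.loc[loads["group"] == "TC", col])
        print(f"{label}-load ASD vs TC (Mann-Whitney): U={u:.0f}, p={p:.3f}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for arm in ("HR", "LR"):
            rows = subgroup_battery(loads, subjects, arm=arm)
            comparisons_frame(rows).to_csv(out / f"battery_{arm}.tsv", sep="\t",
                                           index=False, float_format="%.10g")
            battery_wide_table(rows).to_csv(out / f"battery_{arm}_wide.tsv",
                                            sep="\t", float_format="%.10g")
            sig = [r for r in rows if r.p_fdr is not None and r.p_fdr < 0.05]
            print(f"{arm} arm: {len(rows)} tests, "
                  f"{len(sig)} FDR-significant at q<0.05")
            for r in sig[:10]:
                print(f"  {r.measure:>9} | {r.comparison}: "
                      f"stat={r.statistic:+.2f}, p={r.p:.2g}, q={r.p_fdr:.2g}")

    matching = group_matching(subjects)
    comparisons_frame(matching).to_csv(out / "group_matching.tsv", sep="\t",
                                       index=False, float_format="%.10g")
    unmatched = [r for r in matching if r.p < 0.05]
    print(f"group matching: {len(matching)} variables tested, "
          f"{len(unmatched)} differ at p<0.05")


if __name__ == "__main__":
    main()
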