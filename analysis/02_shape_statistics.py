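#!/usr/bin/env python
"""Validate shape distributions and group the study by peak pressure.

Checks that the simulated initial areas/perimeters are normal
(Shapiro-Wilk) and the inclination angles uniform (Kolmogorov-Smirnov),
clusters records into pressure levels with the 5%-variation rule, and
fits the per-group zeta ~ A_initial lines.  Run 01_simulate_study.py
first.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from cellshock import inference

STUDY = Path("results/study")


def main() -> None:
    records = pd.read_csv(STUDY / "records.csv")

    reports = inference.test_distributions(records)
    (STUDY / "distributions.json").write_text(
        json.dumps([dataclasses.asdict(r) for r in reports], indent=2))
    for r in reports:
        verdict = "ok" if r.passed else "REJECTED"
        print(f"{r.feature:10s} {r.test:11s} p={r.p_value:.3f}  {verdict}")

    adhered = records[~records["detached"]].reset_index(drop=True)
    groups, ungrouped = inference.group_by_pressure(adhered)
    gdf = pd.DataFrame([{"label": g.label, "mean_pmax_kPa": g.mean_pmax,
                         "sd_pmax_kPa": g.sd_pmax, "n": g.n} for g in groups])
    gdf.to_csv(STUDY / "groups.csv", index=False)
    print(f"\n{len(groups)} pressure groups recovered "
          f"({len(ungrouped)} records ungrouped, "
          f"{len(records) - len(adhered)} detached excluded)")

    lines = inference.fit_group_lines(adhered, groups)
    lines.to_csv(STUDY / "group_lines.csv", index=False)
    neg = (lines["slope"] < 0).sum()
    print(f"zeta ~ A_initial slopes: {neg}/{len(lines)} negative "
          "(larger cells deform relatively less)")

    n_shrink, frac = inference.count_shrinking(records)
    print(f"shrinking records (zeta < 1): {n_shrink} ({100 * frac:.1f}%)")


if __name__ == "__main__":
    main()
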