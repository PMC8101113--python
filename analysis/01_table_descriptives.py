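#!/usr/bin/env python
"""Descriptive look at the Georgia county table.

Loads the bundled 159-county transcription (2012-2016, male population and
mean annual prostate-cancer cases plus eight socio-economic covariates),
recomputes crude rates and the descriptive "all counties" row, forms 5-year
period totals and internally standardized expected counts, and writes the
per-county standardized morbidity ratios.  The SMR is the raw, unsmoothed
relative risk the spatial model later stabilises.
"""

import json
from pathlib import Path

import numpy as np

from bymmap import (
    compute_expected_counts,
    load_county_table,
    smr,
    summarize_table,
    with_period_totals,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = load_county_table("georgia_2012_2016")
    summary = summarize_table(table)
    with open(OUT / "table_descriptives.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"{table.n} counties; period = {table.period_years} years")
    print(
        "mean %65+ = {:.2f}; mean county median income = ${:,.0f}; "
        "mean crude rate = {:.2f}/100k".format(
            summary["pct_65plus"]["mean"],
            summary["median_family_income"]["mean"],
            summary["crude_rate"]["mean"],
        )
    )

    period = compute_expected_counts(with_period_totals(table))
    ratios = smr(period)
    frame = period.to_frame()
    frame["smr"] = ratios
    frame.to_csv(OUT / "georgia_smr.csv", index=False)
    order = np.argsort(-ratios)
    print("\nunsmoothed SMR extremes (Y_i / E_i over 2012-2016 totals):")
    for i in order[:6]:
        print(f"  high  {period.area_ids[i]:15s} {ratios[i]:.2f}")
    for i in order[-3:][::-1]:
        print(f"  low   {period.area_ids[i]:15s} {ratios[i]:.2f}")
    print(f"\nmean SMR = {ratios.mean():.2f} (population-weighted mean is 1 "
          "by construction of the internally standardized expected counts)")
    print(f"wrote {OUT / 'table_descriptives.json'} and {OUT / 'georgia_smr.csv'}")


if __name__ == "__main__":
    main()
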