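#!/usr/bin/env python
"""Linear trends in diversity against calendar year and against ASMR.

Reads the tables written by 03_lifetables_diversity.py and reports the OLS
slopes: under the diversification scenario the effective number of causes
rises with year and falls with the mortality rate in every subpopulation.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"

trends = pd.read_csv(ROOT / "run" / "trends.csv")
q1 = trends[trends["subcommunity"].str.endswith("q=1")]

print("diversity trend fits (q = 1):")
for _, row in q1.iterrows():
    unit = "per year" if row.predictor == "year" else "per 100k-rate unit"
    print(f"  {row.subcommunity:40s} vs {row.predictor:4s}: "
          f"slope {row.slope:+.4f} {unit}  (R^2 = {row.r_squared:.2f})")

year_up = (q1[q1["predictor"] == "year"]["slope"] > 0).all()
asmr_down = (q1[q1["predictor"] == "asmr"]["slope"] < 0).all()
print(f"diversity rises with year in all subpopulations: {year_up}")
print(f"diversity falls with ASMR in all subpopulations: {asmr_down}")
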