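"""Retention-ratio statistics on simulated paired samples.

Computes per-taxon retention ratios (granular relative abundance divided by
effluent relative abundance at the same day), tests the steady-state ratios
against 1 with the one-sample Wilcoxon signed-rank test, and correlates
ratios with time (Pearson).  Compare the calls with the simulator's surface
affinities: taxa the model placed at the granule surface should be flagged
below 1.
"""

import pandas as pd

from washout import (
    build_paired_index,
    pearson_trend,
    retention_series,
    scenario_paper_like,
    simulate,
    to_relative,
    wilcoxon_vs_one,
)
from washout.retention import STEADY, phase_test_table, trend_table
from washout.tables_io import CountTable

config = scenario_paper_like(seed=1)[1]
out = simulate(config)

counts = CountTable(pd.concat([out.granular.data, out.effluent.data], axis=1))
ra = to_relative(counts)
pairs = build_paired_index(out.metadata)
series = retention_series(ra, pairs, counts.taxa)

tests = phase_test_table([wilcoxon_vs_one(s, STEADY) for s in series])
trends = trend_table([pearson_trend(s) for s in series])
affinity = pd.Series({t.label: t.surface_affinity for t in config.taxa}, name="affinity")

report = (
    tests.set_index("taxon")[["n", "median_ratio", "p", "direction"]]
    .join(affinity)
    .sort_values("median_ratio")
)
print("steady-state Wilcoxon-vs-1 (7 paired days), sorted by median ratio:")
print(report.round(4).to_string())
print(
    "\ndirection below_1 = preferentially washed out (high surface affinity), "
    "above_1 = preferentially retained (core taxa)."
)
n_sig = (trends["stars"].isin(["*", "**", "***"])).sum()
print(f"\n{n_sig}/{len(trends)} taxa show a significant (p < 0.05) temporal "
      "trend of the retention ratio over the 84-day run.")
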