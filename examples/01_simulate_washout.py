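"""Simulate a granulating reactor and inspect the wash-out ground truth.

Builds the bundled three-reactor scenario (30 genera, 13 paired sampling
days, sequencing depth 20,000), runs the wash-out model, and prints the true
retention ratios of the most surface-bound and most core-bound taxa.  Before
granulation every ratio is 1 (proportional wash-out); once granules develop,
surface taxa wash out preferentially (ratio < 1) and core taxa are retained
(ratio > 1).
"""

import pandas as pd

from washout import scenario_paper_like, simulate

config = scenario_paper_like(seed=1)[1]  # the middle reactor, beta = 1.5
out = simulate(config)

truth = out.truth.table
affinity = {t.label: t.surface_affinity for t in config.taxa}
surface = max(affinity, key=affinity.get)
core = min(affinity, key=affinity.get)

print(f"reactor {config.reactor}: beta = {config.enrichment_strength}, "
      f"granulation days {config.granulation_start_day}-{config.granulation_end_day}")
view = (
    truth[truth["taxon"].isin([surface, core])]
    .pivot(index="day", columns="taxon", values="rho")
    .round(3)
)
print(view.to_string())
print(
    f"\n{surface} (surface affinity {affinity[surface]:.2f}) is increasingly "
    f"washed out as granulation proceeds; {core} (affinity {affinity[core]:.2f}) "
    "is increasingly retained. Ratios are exactly 1 before granulation starts."
)
print(f"\nobserved counts: {out.granular.shape[0]} taxa x "
      f"{out.granular.shape[1]} granular + {out.effluent.shape[1]} effluent samples")
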