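"""Community-level comparison of granular and effluent samples.

Builds the full three-reactor study, computes the Bray-Curtis dissimilarity
matrix on relative abundances, summarizes the similarity of contemporaneous
granular/effluent pairs per reactor, contrasts it with the cross-reactor
similarity at the end of the run, and ordinates all 78 samples by NMDS.
"""

from washout import (
    build_paired_index,
    between_group_similarity,
    dissimilarity_matrix,
    diversity_table,
    nmds,
    paired_similarity_summary,
    scenario_paper_like,
    simulate_scenario,
)

study = simulate_scenario(scenario_paper_like(seed=1))
dm = dissimilarity_matrix(study.counts)
pairs = build_paired_index(study.metadata)

paired = paired_similarity_summary(dm, pairs)
print("paired granular-vs-effluent Bray-Curtis similarity (mean ± sd %):")
for _, row in paired.iterrows():
    print(f"  {row['reactor']}: {row['mean']:.0f} ± {row['sd']:.0f}%  (n = {row['n']})")

last = int(study.metadata["day"].max())
between = between_group_similarity(dm, study.metadata, window=(last - 14, last))
lo, hi = between["mean_similarity"].min(), between["mean_similarity"].max()
print(f"\ncross-reactor similarity over the final two weeks: {lo:.0f}-{hi:.0f}%")
print("each reactor's effluent mirrors its own granules far more closely than "
      "any other reactor's community.")

res = nmds(dm, k=2, n_restarts=10, seed=1)
print(f"\nNMDS: stress = {res.stress:.3f} after {len(res.stress_trace)} "
      f"iterations (best of {res.n_restarts} starts, converged = {res.converged})")

div = diversity_table(study.counts).describe().loc[["mean", "std"], ["margalef", "shannon", "pielou"]]
print("\nper-sample diversity indices over all 78 samples:")
print(div.round(3).to_string())
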