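"""Build the prevalence fold-change heatmap from unified trait scores.

For each trait and sex, the cohort median pools all three groups; a
group's prevalence is the share of its animals scoring strictly above
that median, and each cell of the heatmap is the relative change of
that prevalence versus the wildtype baseline (0 = matches WT).
"""

from phenoscore import (
    CohortConfig,
    build_heatmap,
    compute_prevalence,
    generate_cohort,
    plant_deficit,
    score_cohort,
)

config = plant_deficit(CohortConfig(n_per_cell=20, seed=2), "anxiety", 1.5)
config = plant_deficit(config, "sociability", 1.0, sexes=["M"])
cohort = generate_cohort(config)
unified = score_cohort(cohort.records, cohort.trait_map).unified_scores

prevalence = compute_prevalence(unified, reference_group="WT")
heatmap = build_heatmap(prevalence)
print("prevalence change vs WT (rows: traits; columns: group_sex):")
print(heatmap.round(2))

# Positive cells mean more animals of that group exceed the cohort
# median deficit than in WT: the planted anxiety effect should light up
# both Tg columns, the male-only sociability effect the Tg_M/NTg_M cells.
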