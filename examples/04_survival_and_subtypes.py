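"""Group-stratified scoring: survival quartiles and discordant genes.

Generates a cohort whose samples fall into short- and long-survival
groups, with planted genes that behave oncogenically in short survivors
and suppressor-like in long survivors. Scoring the two survival
quartiles separately exposes those flips: genes with a strong positive
score in one quartile and a non-trivial negative score in the other are
classified sign_opposite (opposite classes beyond |s| > 2.5 on both
sides would be threshold_dual).
"""

import sscore as ss

flip = tuple(
    ss.PlantedGene(
        gene=f"FLIP{i}", role="dual",
        group_freqs={"short": {"freq_amp": 0.5, "freq_over": 0.5},
                     "long": {"freq_amp": 0.2, "freq_over": 0.2,
                              "freq_del": 0.6, "freq_under": 0.6}})
    for i in range(3))
config = ss.GeneratorConfig(
    cohort_id="OVDEMO", n_samples=400, n_genes=60,
    planted=flip + (ss.oncogene("STEADY", 0.5, 0.5),),
    background={"amp": 0, "del": 0, "over": 0, "under": 0, "ns": 0,
                "met": 0, "missense": 0},
    group=ss.GroupSpec(covariate="os_group", values=("short", "long"),
                       survival_by_value={"short": (30, 300),
                                          "long": (1200, 3000)}),
    seed=5)
cohort, _ = ss.generate_cohort(config)

q1, q4 = ss.quartile_stratify(cohort.clinical)
print(f"shortest-survival quartile: {len(q1)} samples; "
      f"longest: {len(q4)} samples")
res = ss.compare_groups(cohort, (q1, q4),
                        group_labels=("shortest", "longest"))
interesting = res.data[res.data["classification"] != "concordant"]
print(interesting.round(2))
print("\nSTEADY (oncogenic in both quartiles):")
print(res.data.loc[["STEADY"]].round(2))

# s_1 / s_2 are the scores computed from the shortest- and longest-
# survival quartile samples alone; a sign_opposite gene is a candidate
# context-dependent oncogene/suppressor and prognosis marker.
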