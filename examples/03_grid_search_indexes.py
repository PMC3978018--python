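"""Select index weights by benchmark enrichment across cohorts.

In this world the benchmark genes differ from background only in their
nonsense-mutation load, so an index profile that up-weights nonsense
mutations (i_ns=5) should produce a far stronger enrichment than the
uniform profile (all indexes 0.5) — mirroring how the default profile
was chosen. Scenarios are ranked by the total number of simulated sets
matching or beating the real benchmark count across all cohorts
(smaller = more consistently enriched).
"""

import sscore as ss

bench = [f"NSB{i}" for i in range(8)]
clean = {"amp": 0, "del": 0, "over": 0, "under": 0, "ns": 0, "met": 0,
         "missense": 0}
cohorts = []
for j in range(3):
    planted = tuple(ss.PlantedGene(gene=g, role="suppressor", freq_ns=0.03)
                    for g in bench)
    cfg = ss.GeneratorConfig(cohort_id=f"T{j}", n_samples=200, n_genes=80,
                             planted=planted, background=dict(clean),
                             seed=100 + j)
    cohorts.append(ss.generate_cohort(cfg)[0])

scenarios = [
    ("uniform 0.5", ss.IndexWeights(i_ns=0.5)),
    ("i_ns = 2", ss.IndexWeights(i_ns=2.0)),
    ("i_ns = 5", ss.IndexWeights(i_ns=5.0)),
]
ranked = ss.grid_search_indexes(cohorts, bench, scenarios,
                                threshold_rule="fixed", n_sim=2000, seed=3)
for rank, scen in enumerate(ranked, 1):
    detail = ", ".join(f"{cid}: {e.real_count} extreme (p {e.p_label})"
                       for cid, e in scen.enrichment_by_cohort.items())
    print(f"#{rank} {scen.label:12s} total exceedance "
          f"{scen.aggregate_exceedance:5d} | {detail}")

# The winning scenario is the one whose real benchmark counts are hardest
# to match by random gene sets in every cohort simultaneously.
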