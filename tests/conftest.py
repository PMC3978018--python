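import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import sscore as ss

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cohort(cnv: dict, expr: dict, samples: list[str],
                methylation: dict | None = None,
                mutations: list[tuple] = (),
                clinical: pd.DataFrame | None = None,
                cohort_id: str = "TOY") -> ss.CohortDataset:
    """Build a small in-memory cohort from {gene: [values]} dicts;
    mutation tuples are (gene, sample, variant_class[, source])."""

    def mat(d: dict) -> pd.DataFrame:
        return pd.DataFrame(
            {s: [d[g][i] for g in d] for i, s in enumerate(samples)},
            index=pd.Index(list(d), name="gene"), dtype=float)

    muts = [ss.MutationRecord(*t) for t in mutations]
    clin = ss.ClinicalTable(clinical) if clinical is not None else None
    return ss.CohortDataset(
        cohort_id=cohort_id, cnv=mat(cnv), expression_z=mat(expr),
        methylation_call=mat(methylation) if methylation else None,
        mutations=muts, clinical=clin)


@pytest.fixture
def toy_cohort() -> ss.CohortDataset:
    """3 genes x 4 samples with one clear oncogene-like and one clear
    suppressor-like pattern plus a neutral gene."""
    samples = ["s1", "s2", "s3", "s4"]
    nan = float("nan")
    return make_cohort(
        cnv={"ONC": [2.1, 2.5, 0.0, 3.0], "SUP": [-2.3, -1.5, 0.0, nan],
             "NEU": [0.0, 0.2, -0.3, 0.1]},
        expr={"ONC": [2.5, 3.0, 0.0, 2.2], "SUP": [-2.5, -3.0, nan, -2.2],
              "NEU": [0.1, -0.2, 0.0, 0.3]},
        samples=samples,
        methylation={"ONC": [0, 0, 0, 0], "SUP": [1, 1, 0, nan],
                     "NEU": [0, 0, 0, 0]},
        mutations=[("SUP", "s1", "Nonsense_Mutation"),
                   ("SUP", "s2", "Nonsense_Mutation"),
                   ("SUP", "s2", "Nonsense_Mutation"),
                   ("ONC", "s1", "Missense_Mutation")],
        clinical=pd.DataFrame(
            {"os_time": [100.0, 400.0, 900.0, 1500.0],
             "ER": ["+", "+", "-", "-"]},
            index=pd.Index(samples, name="sample")),
    )


def brute_force_tally(cohort: ss.CohortDataset, gene: str,
                      z_thr: float = 2.0) -> dict:
    """Independent cell-by-cell recount using raw comparisons only
    (no calls to sscore.calls)."""
    import math

    out = dict(A=0, D=0, T_cnv=0, O=0, U=0, T_exp=0, M=0, T_met=0, ns=0,
               N_cohort=len(cohort.samples))
    if gene in cohort.cnv.index:
        for v in cohort.cnv.loc[gene]:
            v = float(v)
            if math.isnan(v):
                continue
            out["T_cnv"] += 1
            if v >= 2:
                out["A"] += 1
            elif v <= -1:
                out["D"] += 1
    if gene in cohort.expression_z.index:
        for v in cohort.expression_z.loc[gene]:
            v = float(v)
            if math.isnan(v):
                continue
            out["T_exp"] += 1
            if v >= z_thr:
                out["O"] += 1
            elif v <= -z_thr:
                out["U"] += 1
    if cohort.methylation_call is not None and gene in cohort.methylation_call.index:
        for v in cohort.methylation_call.loc[gene]:
            v = float(v)
            if math.isnan(v):
                continue
            out["T_met"] += 1
            if v == 1.0:
                out["M"] += 1
    cohort_samples = set(cohort.samples)
    hit = set()
    for r in cohort.mutations:
        if (r.gene == gene and r.variant_class == "Nonsense_Mutation"
                and r.source == "cohort" and r.sample in cohort_samples):
            hit.add(r.sample)
    out["ns"] = len(hit)
    return out
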