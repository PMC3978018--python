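"""Group-stratified scoring, discordance classes, cross-tumor screen,
top-k scatter pairing and per-gene diagnostics."""

import numpy as np
import pandas as pd
import pytest

import sscore as ss
from sscore.score import WEIGHT_PROFILES

from conftest import make_cohort
from test_benchmark import table_from_scores

W = WEIGHT_PROFILES["paper2014"]


def clinical_with_times(times: list[float]) -> ss.ClinicalTable:
    idx = pd.Index([f"s{i}" for i in range(len(times))], name="sample")
    return ss.ClinicalTable(pd.DataFrame({"os_time": times}, index=idx))


def test_quartile_stratify_basic():
    q1, q4 = ss.quartile_stratify(clinical_with_times(
        [1, 2, 3, 4, 5, 6, 7, 8]))
    assert q1 == ["s0", "s1"]   # times 1, 2
    assert q4 == ["s6", "s7"]   # times 7, 8


def test_quartile_stratify_guards():
    with pytest.raises(ss.DegenerateInputError):   # below minimum n
        ss.quartile_stratify(clinical_with_times([1, 2, 3, 4, 5, 6, 7]))
    with pytest.raises(ss.DegenerateInputError):   # all identical
        ss.quartile_stratify(clinical_with_times([5.0] * 10))
    # missing times are excluded before the minimum-n check
    times = [1, 2, 3, 4, 5, 6, 7, 8, np.nan, np.nan]
    q1, q4 = ss.quartile_stratify(clinical_with_times(times))
    assert set(q1) | set(q4) <= {f"s{i}" for i in range(8)}


def test_quartile_ties_fall_inward():
    """Samples tied on a shared quartile boundary are excluded from both
    groups, which stay disjoint."""
    q1, q4 = ss.quartile_stratify(clinical_with_times(
        [1.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0, 9.0]))
    assert q1 == ["s0"] and q4 == ["s7"]  # the 4.0 block falls inward
    # fully degenerate ties collapse a group -> explicit error
    with pytest.raises(ss.DegenerateInputError):
        ss.quartile_stratify(clinical_with_times([1.0] * 7 + [9.0]))


def test_quartile_groups_large_enough_without_ties():
    times = list(np.linspace(10, 500, 21))
    q1, q4 = ss.quartile_stratify(clinical_with_times(times))
    assert len(q1) >= 21 // 4 and len(q4) >= 21 // 4
    assert not set(q1) & set(q4)


@pytest.mark.parametrize("s1,s2,expected", [
    (3.04, -1.40, "sign_opposite"),     # the survival-screen exemplar
    (-1.40, 3.04, "sign_opposite"),
    (3.0, -3.0, "threshold_dual"),
    (2.6, -2.55, "threshold_dual"),
    (2.5, -2.6, "sign_opposite"),       # 2.5 is not strictly above 2.5
    (0.5, -0.4, "concordant"),          # opposite but trivial magnitudes
    (3.0, -0.5, "concordant"),          # one side too weak
    (1.5, -1.5, "concordant"),          # neither side strong
    (3.0, 3.0, "concordant"),
    (0.0, -3.0, "concordant"),
])
def test_classify_discordance(s1, s2, expected):
    assert ss.classify_discordance(s1, s2) == expected


def _group_structured_cohort():
    """120 samples in two survival groups; DSC is oncogenic in the
    short-survival group and moderately suppressive in the long one."""
    planted = (
        ss.PlantedGene(
            gene="DSC", role="dual",
            group_freqs={"short": {"freq_amp": 0.5, "freq_over": 0.5},
                         "long": {"freq_del": 0.2, "freq_ns": 0.0}}),
        ss.oncogene("ONC", 0.5, 0.5),
    )
    cfg = ss.GeneratorConfig(
        cohort_id="OVX", n_samples=120, n_genes=30, planted=planted,
        background={"amp": 0, "del": 0, "over": 0, "under": 0, "ns": 0,
                    "met": 0, "missense": 0},
        group=ss.GroupSpec(covariate="os_group", values=("short", "long"),
                           survival_by_value={"short": (30, 300),
                                              "long": (1200, 3000)}),
        seed=21)
    return ss.generate_cohort(cfg)[0]


def test_compare_groups_flags_planted_discordance():
    cohort = _group_structured_cohort()
    q1, q4 = ss.quartile_stratify(cohort.clinical)
    # disjoint survival ranges: quartiles land inside their groups
    groups = cohort.clinical.data.loc[q1, "os_group"]
    assert (groups == "short").all()
    res = ss.compare_groups(cohort, (q1, q4), W,
                            group_labels=("short", "long"))
    assert res.data.loc["DSC", "s_1"] > 2
    assert res.data.loc["DSC", "s_2"] < 0
    assert res.data.loc["DSC", "classification"] == "sign_opposite"
    # ONC is oncogenic in both groups; everything else is null
    assert res.discordant() == ["DSC"]


def test_compare_groups_restriction_oracle():
    """Group scoring must equal cohort scoring on a from-scratch cohort
    built from only those samples."""
    cohort = _group_structured_cohort()
    g1 = cohort.samples[:40]
    g2 = cohort.samples[40:80]
    res = ss.compare_groups(cohort, (g1, g2), W)
    rebuilt = ss.CohortDataset(
        cohort_id="rebuilt", cnv=cohort.cnv[g1].copy(),
        expression_z=cohort.expression_z[g1].copy(),
        methylation_call=cohort.methylation_call[g1].copy(),
        mutations=[r for r in cohort.mutations if r.sample in set(g1)])
    expected = ss.score_cohort(rebuilt, W)
    pd.testing.assert_series_equal(res.table1.data["s"],
                                   expected.data["s"], check_names=False)


def test_compare_groups_identical_groups_symmetry(toy_cohort):
    # identical sample *composition* is forbidden (disjointness), so use
    # two single-sample groups with identical data instead
    with pytest.raises(ss.ValidationError):
        ss.compare_groups(toy_cohort, (["s1"], ["s1"]), W)
    res = ss.compare_groups(toy_cohort, (["s1", "s2"], ["s3", "s4"]), W)
    assert set(res.data["classification"]) <= set(
        ("sign_opposite", "threshold_dual", "concordant"))


def test_compare_groups_forces_cohort_mutation_mode(caplog):
    cohort = _group_structured_cohort()
    cfg = ss.ScoreConfig(mutation_mode="external_catalog")
    import logging
    with caplog.at_level(logging.WARNING, logger="sscore.compare"):
        ss.compare_groups(cohort, (cohort.samples[:30], cohort.samples[30:60]),
                          W, cfg)
    assert any("forces mutation_mode=cohort" in m for m in caplog.messages)


def test_cross_tumor_dual_rules():
    ta = table_from_scores({"G1": 3.0, "G2": 3.0, "G3": 2.5, "G4": 0.0}, "A")
    tb = table_from_scores({"G1": -3.0, "G2": 3.0, "G3": -2.6, "G4": -3.0}, "B")
    out = ss.cross_tumor_dual([ta, tb], threshold=2.5)
    assert bool(out.loc["G1", "dual"])        # +3 / -3
    assert not out.loc["G2", "dual"]          # same direction
    assert not out.loc["G3", "dual"]          # +2.5 not strictly above
    assert not out.loc["G4", "dual"]          # no positive extreme
    assert out.loc["G1", "max_cohort"] == "A"
    assert out.loc["G1", "min_cohort"] == "B"


def test_cross_tumor_dual_symmetry_and_guards():
    ta = table_from_scores({"G1": 3.0, "G2": 1.0}, "A")
    tb = table_from_scores({"G1": -3.0, "G2": 1.0}, "B")
    fwd = ss.cross_tumor_dual([ta, tb])
    rev = ss.cross_tumor_dual([tb, ta])
    pd.testing.assert_series_equal(fwd["dual"], rev["dual"])
    with pytest.raises(ValueError):
        ss.cross_tumor_dual([ta])
    disjoint = table_from_scores({"H1": 1.0}, "C")
    with pytest.raises(ss.DegenerateInputError):
        ss.cross_tumor_dual([ta, disjoint])


def test_top_k_scatter():
    t1 = table_from_scores({"A": 2.0, "B": 0.0, "C": -2.0}, "x")
    t2 = table_from_scores({"A": 1.0, "B": 0.5, "C": 1.5}, "y")
    out = ss.top_k_scatter(t1, t2, k=1)
    assert set(out.index) == {"A", "C"}
    assert out.loc["A", "side"] == "oncogene"
    assert out.loc["C", "side"] == "suppressor"
    assert out.loc["C", "s_2"] == 1.5

    # identity: table2 = table1 puts every point on the diagonal
    diag = ss.top_k_scatter(t1, t1, k=1)
    assert (diag["s_1"] == diag["s_2"]).all()

    # shrink with warning when fewer than k genes exist on a side
    with pytest.warns(UserWarning, match="available"):
        out = ss.top_k_scatter(t1, t2, k=5)
    assert len(out) == 2


@pytest.mark.filterwarnings("ignore:only 1 suppressor")
def test_top_k_scatter_tie_break_lexicographic():
    t1 = table_from_scores({"B": 2.0, "A": 2.0, "C": 2.0, "Z": -1.0}, "x")
    out = ss.top_k_scatter(t1, t1, k=2)
    onc = out[out["side"] == "oncogene"]
    assert list(onc.index) == ["A", "B"]


def test_gene_diagnostic(toy_cohort):
    d = ss.gene_diagnostic(toy_cohort, "SUP", axis="cnv")
    # s4 is NA on cnv -> only jointly informative samples remain; s3 is
    # NA on expression
    assert set(d.index) == {"s1", "s2"}
    assert d.loc["s1", "category"] == "homozygous_deletion"
    assert d.loc["s2", "category"] == "deletion"
    m = ss.gene_diagnostic(toy_cohort, "SUP", axis="methylation")
    assert m.loc["s1", "category"] == "methylated"

    neu = ss.gene_diagnostic(toy_cohort, "NEU", axis="cnv")
    assert set(neu["category"]) == {"neutral"}  # single category column

    with pytest.raises(KeyError):
        ss.gene_diagnostic(toy_cohort, "ABSENT")


def test_gene_diagnostic_silenced_suppressor_clusters():
    cfg = ss.GeneratorConfig(
        cohort_id="S", n_samples=80, n_genes=10,
        planted=(ss.silenced_suppressor("SIL", freq_met=0.4),),
        background={"amp": 0, "del": 0, "over": 0, "under": 0, "ns": 0,
                    "met": 0, "missense": 0},
        missingness={"cnv": 0, "expression": 0, "methylation": 0},
        seed=4)
    cohort, truth = ss.generate_cohort(cfg)
    d = ss.gene_diagnostic(cohort, "SIL", axis="methylation")
    met = d[d["category"] == "methylated"]
    unmet = d[d["category"] == "unmethylated"]
    assert len(met) == truth.loc["SIL", "M"] > 0
    assert (met["expression_z"] <= -2).all()       # silenced cluster
    assert (unmet["expression_z"] > -2).all()
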