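"""Monte Carlo enrichment, index grid search and PPV/NPV resampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import sscore as ss
from sscore.score import WEIGHT_PROFILES

from conftest import make_cohort

W = WEIGHT_PROFILES["paper2014"]


def table_from_scores(scores: dict[str, float],
                      cohort_id: str = "T") -> ss.SScoreTable:
    df = pd.DataFrame({"So": 0.0, "Ss": 0.0, "s": pd.Series(scores),
                       "guard_case": "ratio"})
    df.index.name = "gene"
    return ss.SScoreTable(cohort_id, df, W, "raw_counts")


def hypergeom_world(n_universe=100, n_extreme=10):
    scores = {f"g{i:03d}": (3.0 if i < n_extreme else 0.0)
              for i in range(n_universe)}
    return table_from_scores(scores)


def test_enrichment_matches_hypergeometric_tail():
    """Uniform draws without replacement make the extreme count
    hypergeometric; the empirical p must sit within 3 SE of the
    closed-form tail."""
    table = hypergeom_world()
    bench = ["g000", "g001", "g002", "g050", "g051"]  # 3 extreme of 5
    p_true = float(hypergeom.sf(2, 100, 10, 5))  # P[X >= 3]
    n_sim = 20_000
    se = np.sqrt(p_true * (1 - p_true) / n_sim)
    r = ss.monte_carlo_enrichment(table, bench, (-2, 2), n_sim=n_sim, seed=7)
    assert r.real_count == 3
    assert abs(r.p_hat - p_true) <= 3 * se
    # simulated mean matches the hypergeometric mean too
    assert r.sim_mean == pytest.approx(5 * 10 / 100, abs=4 * 0.05)


def test_enrichment_trivial_cases():
    table = hypergeom_world()
    # benchmark = whole universe: every draw ties the real count
    r = ss.monte_carlo_enrichment(table, list(table.genes), (-2, 2),
                                  n_sim=200, seed=1)
    assert r.real_count == 10
    assert r.p_hat == 1.0
    # no extreme genes at all
    flat = table_from_scores({f"g{i}": 0.0 for i in range(20)})
    r = ss.monte_carlo_enrichment(flat, ["g1", "g2"], (-2, 2),
                                  n_sim=200, seed=1)
    assert r.real_count == 0 and r.p_hat == 1.0


def test_enrichment_determinism_and_floor():
    table = hypergeom_world()
    bench = [f"g{i:03d}" for i in range(10)]  # all extremes
    a = ss.monte_carlo_enrichment(table, bench, (-2, 2), n_sim=3000, seed=42)
    b = ss.monte_carlo_enrichment(table, bench, (-2, 2), n_sim=3000, seed=42)
    assert np.array_equal(a.sim_counts, b.sim_counts)
    assert a.p_hat == b.p_hat
    # real count 10 of 10 is unreachable by chance here -> floored label
    assert a.exceed == 0
    assert a.p_label == "<0.000333333"
    plus = ss.monte_carlo_enrichment(table, bench, (-2, 2), n_sim=3000,
                                     seed=42, plus_one=True)
    assert plus.p_hat == pytest.approx(1 / 3001)


def test_enrichment_drops_unknown_benchmark_genes():
    table = hypergeom_world(20, 5)
    with pytest.warns(UserWarning, match="absent"):
        r = ss.monte_carlo_enrichment(table, ["g000", "NOPE"], (-2, 2),
                                      n_sim=50, seed=0)
    assert r.real_count == 1
    with pytest.raises(ss.DegenerateInputError):
        ss.monte_carlo_enrichment(table, ["NOPE"], (-2, 2), n_sim=50, seed=0)


def test_null_benchmark_p_is_superuniform():
    """Random benchmarks exchangeable with the universe give
    P(p_hat <= a) <= a + 1/n_sim."""
    table = hypergeom_world(60, 8)
    rng = np.random.default_rng(11)
    n_sim, alpha = 250, 0.1
    hits = 0
    reps = 120
    for _ in range(reps):
        bench = list(rng.choice(table.genes, size=10, replace=False))
        r = ss.monte_carlo_enrichment(table, bench, (-2, 2), n_sim=n_sim,
                                      seed=int(rng.integers(2**31)))
        hits += r.p_hat <= alpha
    rate = hits / reps
    # allow 3 SE of binomial noise on top of the superuniform bound
    bound = alpha + 1 / n_sim
    assert rate <= bound + 3 * np.sqrt(bound * (1 - bound) / reps)


def _ns_only_cohorts():
    """Two small cohorts where benchmark genes differ from nulls only in
    nonsense-mutation load."""
    cohorts = []
    for cid, seed in (("A", 5), ("B", 6)):
        planted = tuple(
            ss.PlantedGene(gene=f"BM{i}", role="suppressor", freq_ns=0.04)
            for i in range(5))
        cfg = ss.GeneratorConfig(
            cohort_id=cid, n_samples=150, n_genes=40, planted=planted,
            background={"amp": 0, "del": 0, "over": 0, "under": 0,
                        "ns": 0, "met": 0, "missense": 0},
            seed=seed)
        cohorts.append(ss.generate_cohort(cfg)[0])
    return cohorts, [f"BM{i}" for i in range(5)]


def test_grid_search_prefers_heavier_nonsense_weight():
    cohorts, bench = _ns_only_cohorts()
    scenarios = [("i_ns=0.5", WEIGHT_PROFILES["uniform"]),
                 ("i_ns=5", WEIGHT_PROFILES["paper2014"])]
    ranked = ss.grid_search_indexes(cohorts, bench, scenarios,
                                    threshold_rule="fixed", n_sim=300, seed=3)
    assert ranked[0].label == "i_ns=5"
    assert (ranked[0].aggregate_exceedance
            < ranked[1].aggregate_exceedance)


def test_grid_search_single_scenario_and_ties():
    cohorts, bench = _ns_only_cohorts()
    only = ss.grid_search_indexes(cohorts, bench,
                                  [("solo", WEIGHT_PROFILES["paper2014"])],
                                  n_sim=100, seed=3)
    assert len(only) == 1 and only[0].label == "solo"
    twin = ss.grid_search_indexes(
        cohorts, bench,
        [("first", WEIGHT_PROFILES["uniform"]),
         ("second", WEIGHT_PROFILES["uniform"])],
        n_sim=100, seed=3)
    assert [t.label for t in twin] == ["first", "second"]  # tie keeps order


def test_predictive_values_forced_outcomes():
    # every positive extreme, no negative extreme
    scores = {f"p{i}": 3.0 for i in range(10)}
    scores.update({f"n{i}": 0.0 for i in range(30)})
    t = table_from_scores(scores)
    pos = [f"p{i}" for i in range(10)]
    pv = ss.predictive_values(t, pos, threshold_pair=(-2, 2), n_sets=50,
                              set_size=5, seed=1)
    assert pv.ppv == 1.0 and pv.npv == 1.0
    assert pv.tp == 5.0 and pv.fp == 0.0

    # nothing extreme: tp = fp = 0, ppv undefined; every drawn negative
    # is a TN and every drawn positive an FN, so npv = tn/(tn+fn) = 0.5
    flat = table_from_scores({g: 0.0 for g in scores})
    pv = ss.predictive_values(flat, pos, threshold_pair=(-2, 2), n_sets=50,
                              set_size=5, seed=1)
    assert pv.ppv is None and pv.npv == 0.5
    assert pv.tp == 0.0 and pv.fp == 0.0


def test_predictive_values_match_full_confusion_matrix():
    """Resampled means converge to the full-population confusion matrix
    (each draw is an unbiased sample of its pool)."""
    rng = np.random.default_rng(2)
    scores = {}
    pos = [f"p{i}" for i in range(40)]
    neg = [f"n{i}" for i in range(160)]
    for g in pos:
        scores[g] = 3.0 if rng.random() < 0.7 else 0.0
    for g in neg:
        scores[g] = 3.0 if rng.random() < 0.05 else 0.0
    t = table_from_scores(scores)
    extreme = {g for g, v in scores.items() if v > 2}
    frac_pos = len(extreme & set(pos)) / len(pos)
    frac_neg = len(extreme & set(neg)) / len(neg)
    pv = ss.predictive_values(t, pos, threshold_pair=(-2, 2), n_sets=4000,
                              set_size=20, seed=9)
    se_tp = 20 * np.sqrt(frac_pos * (1 - frac_pos) / 4000)
    se_fp = 20 * np.sqrt(frac_neg * (1 - frac_neg) / 4000)
    assert pv.tp == pytest.approx(20 * frac_pos, abs=4 * se_tp + 1e-9)
    assert pv.fp == pytest.approx(20 * frac_neg, abs=4 * se_fp + 1e-9)


def test_predictive_values_set_size_guard():
    t = table_from_scores({f"g{i}": 0.0 for i in range(10)})
    with pytest.raises(ValueError):
        ss.predictive_values(t, [f"g{i}" for i in range(3)], set_size=5,
                             n_sets=10, seed=0)
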