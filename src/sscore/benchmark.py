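"""Benchmarking machinery: Monte Carlo enrichment of a benchmark gene
list among extreme scores, index grid search, and PPV/NPV resampling.

The enrichment test asks whether a curated cancer-gene list (e.g. the
138-gene Vogelstein compilation) contains more extreme-scoring genes
than same-size sets drawn uniformly without replacement from the scored
universe. Because the number of extreme genes in such a draw is exactly
hypergeometric, the closed-form tail serves as an independent oracle for
the Monte Carlo estimate in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .config import ScoreConfig
from .errors import DegenerateInputError, ValidationError
from .score import (IndexWeights, SScoreTable, extreme_genes, score_from_tallies,
                    zscore_thresholds)
from .calls import tally_cohort

DEFAULT_SEED = 20140407

_CHUNK = 20_000  # simulated sets scored per vectorized block


@dataclass
class EnrichmentResult:
    """Monte Carlo enrichment of a benchmark list among extreme scores.

    p_hat is the plain exceedance fraction #(sim >= real) / n_sim; when
    no simulated set reaches the real count it is 0.0 and ``p_label``
    renders the conventional "< 1/n_sim" floor. ``plus_one`` selects the
    (count+1)/(n_sim+1) estimator instead.
    """

    real_count: int
    sim_counts: np.ndarray
    n_sim: int
    seed: int
    plus_one: bool = False

    @property
    def exceed(self) -> int:
        return int((self.sim_counts >= self.real_count).sum())

    @property
    def p_hat(self) -> float:
        if self.plus_one:
            return (self.exceed + 1) / (self.n_sim + 1)
        return self.exceed / self.n_sim

    @property
    def p_label(self) -> str:
        if not self.plus_one and self.exceed == 0:
            return f"<{1 / self.n_sim:g}"
        return f"{self.p_hat:g}"

    @property
    def sim_mean(self) -> float:
        return float(np.mean(self.sim_counts))

    @property
    def sim_sd(self) -> float:
        return float(np.std(self.sim_counts, ddof=1)) if self.n_sim > 1 else 0.0

    def summary(self) -> dict:
        return {
            "real_count": self.real_count,
            "sim_mean": self.sim_mean,
            "sim_sd": self.sim_sd,
            "p_hat": self.p_hat,
            "p_label": self.p_label,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def resolve_thresholds(table: SScoreTable, rule: str = "fixed",
                       value: float = 2.0) -> tuple[float, float]:
    """Threshold pair for extreme calls: ``fixed`` gives (-value, +value);
    ``zscore`` gives mean_s -/+ value * sd_s for this cohort."""
    if rule == "fixed":
        return -value, value
    if rule == "zscore":
        return zscore_thresholds(table, value)
    raise ValueError(f"unknown threshold rule {rule!r}")


def _random_subset_counts(flag: np.ndarray, k: int, n_sim: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Extreme-gene counts in ``n_sim`` uniform draws of ``k`` genes
    without replacement from a universe described by the boolean ``flag``
    vector. Each draw is the k smallest of N iid uniform keys, which is a
    uniform k-subset."""
    n = flag.size
    out = np.empty(n_sim, dtype=np.int64)
    done = 0
    flag_f = flag.astype(np.float64)
    while done < n_sim:
        m = min(_CHUNK, n_sim - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[done:done + m] = flag_f[idx].sum(axis=1).astype(np.int64)
        done += m
    return out


def monte_carlo_enrichment(table: SScoreTable, benchmark: set[str] | list[str],
                           threshold_pair: tuple[float, float] = (-2.0, 2.0),
                           n_sim: int = 10_000, seed: int = DEFAULT_SEED,
                           plus_one: bool = False) -> EnrichmentResult:
    """Empirical enrichment p-value of a benchmark gene list.

    The real count is the number of benchmark genes with extreme scores;
    each simulated set draws |benchmark ∩ universe| genes uniformly
    without replacement from the scored universe and counts extremes.
    Benchmark genes absent from the universe are dropped with a warning.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    universe = list(table.genes)
    uset = set(universe)
    bench = [g for g in dict.fromkeys(benchmark) if g in uset]
    dropped = len(set(benchmark)) - len(bench)
    if not bench:
        raise DegenerateInputError(
            "benchmark has no overlap with the scored gene universe"
        )
    if dropped:
        warnings.warn(
            f"{dropped} benchmark gene(s) absent from the scored universe "
            "were dropped from the enrichment test",
            stacklevel=2,
        )
    lower, upper = threshold_pair
    extreme = extreme_genes(table, lower, upper)
    real_count = len(extreme & set(bench))
    flag = np.fromiter((g in extreme for g in universe), dtype=bool,
                       count=len(universe))
    rng = np.random.default_rng(seed)
    sim = _random_subset_counts(flag, len(bench), n_sim, rng)
    return EnrichmentResult(real_count=real_count, sim_counts=sim,
                            n_sim=n_sim, seed=seed, plus_one=plus_one)


@dataclass
class IndexScenario:
    """One weight combination evaluated across cohorts."""

    weights: IndexWeights
    label: str
    enrichment_by_cohort: dict[str, EnrichmentResult] = field(default_factory=dict)

    @property
    def aggregate_exceedance(self) -> int:
        """Sum over cohorts of the number of simulated sets at or above
        the real count; smaller means more consistently enriched."""
        return sum(e.exceed for e in self.enrichment_by_cohort.values())


def grid_search_indexes(cohorts: list[CohortDataset],
                        benchmark: set[str] | list[str],
                        scenarios: list[tuple[str, IndexWeights]],
                        threshold_rule: str = "fixed",
                        threshold_value: float = 2.0,
                        n_sim: int = 10_000, seed: int = DEFAULT_SEED,
                        config: ScoreConfig | None = None,
                        ) -> list[IndexScenario]:
    """Evaluate index-weight scenarios and rank them by how strongly the
    benchmark list is enriched across every cohort.

    Each scenario is scored on every cohort (alteration tallies are
    computed once per cohort and reused), the Monte Carlo enrichment is
    run under the chosen threshold rule, and scenarios are ranked by the
    total exceedance count ascending. Ties keep input order.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    cfg = config or ScoreConfig()
    tallies = {c.cohort_id: tally_cohort(c, cfg) for c in cohorts}
    # one independent child seed per (scenario, cohort), order-stable
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(scenarios) * len(cohorts)))
    results: list[IndexScenario] = []
    for label, w in scenarios:
        scen = IndexScenario(weights=w, label=label)
        for c in cohorts:
            table = score_from_tallies(tallies[c.cohort_id], w,
                                       cfg.normalization_mode,
                                       cohort_id=c.cohort_id,
                                       config_digest=cfg.digest())
            pair = resolve_thresholds(table, threshold_rule, threshold_value)
            child = next(children)
            scen.enrichment_by_cohort[c.cohort_id] = monte_carlo_enrichment(
                table, benchmark, pair, n_sim=n_sim,
                seed=int(child.generate_state(1)[0] % (2 ** 31)))
        results.append(scen)
    return sorted(results, key=lambda s: s.aggregate_exceedance)


@dataclass
class PredictiveValues:
    """Resampled positive/negative predictive values.

    tp/fp/tn/fn are mean counts over the resampled sets; ppv and npv are
    the ratios of those means per the standard definitions and are None
    when a denominator is zero (never silently 0).
    """

    tp: float
    fn: float
    tn: float
    fp: float
    n_sets: int
    set_size: int
    seed: int

    @property
    def ppv(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom > 0 else None

    @property
    def npv(self) -> float | None:
        denom = self.tn + self.fn
        return self.tn / denom if denom > 0 else None

    def summary(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "ppv": self.ppv, "npv": self.npv,
                "n_sets": self.n_sets, "set_size": self.set_size,
                "seed": self.seed}


def predictive_values(table: SScoreTable, positives: set[str] | list[str],
                      universe: set[str] | list[str] | None = None,
                      threshold_pair: tuple[float, float] = (-2.0, 2.0),
                      n_sets: int = 1000, set_size: int = 50,
                      seed: int = DEFAULT_SEED) -> PredictiveValues:
    """PPV/NPV of the extreme-score classifier by set resampling.

    ``n_sets`` random sets of ``set_size`` genes are drawn from the
    positive list (drawn positives beyond threshold are TP, else FN) and
    another ``n_sets`` from the universe minus the positives (beyond
    threshold are FP, else TN); predictive values are formed from the
    mean counts.
    """
    uni = list(universe) if universe is not None else list(table.genes)
    uset = set(uni)
    pos = [g for g in dict.fromkeys(positives) if g in uset]
    neg = [g for g in uni if g not in set(pos)]
    if set_size > len(pos) or set_size > len(neg):
        raise ValueError(
            f"set_size={set_size} exceeds available positives ({len(pos)}) "
            f"or negatives ({len(neg)})"
        )
    extreme = extreme_genes(table, *threshold_pair)
    rng = np.random.default_rng(seed)
    pos_flag = np.fromiter((g in extreme for g in pos), dtype=bool, count=len(pos))
    neg_flag = np.fromiter((g in extreme for g in neg), dtype=bool, count=len(neg))
    tp_counts = _random_subset_counts(pos_flag, set_size, n_sets, rng)
    fp_counts = _random_subset_counts(neg_flag, set_size, n_sets, rng)
    tp = float(np.mean(tp_counts))
    fn = set_size - tp
    fp = float(np.mean(fp_counts))
    tn = set_size - fp
    return PredictiveValues(tp=tp, fn=fn, tn=tn, fp=fp, n_sets=n_sets,
                            set_size=set_size, seed=seed)
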