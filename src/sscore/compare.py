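"""Group-stratified scoring and discordance detection.

Three workflows: survival-quartile comparison (score the shortest- and
longest-surviving quartiles separately and look for genes whose score
flips sign), categorical-subtype comparison (e.g. ER+PR+ vs ER-PR-
breast tumors), and a cross-tumor screen for genes behaving as oncogene
in one tumor type and suppressor in another. A per-gene diagnostic
table (expression vs copy-number category or methylation status) backs
the scatter-plot style inspection of individual candidates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .calls import classify_cnv
from .cohort import ClinicalTable, CohortDataset
from .config import ScoreConfig
from .errors import DegenerateInputError, ValidationError
from .score import IndexWeights, SScoreTable, score_cohort

log = logging.getLogger(__name__)

DISCORDANCE_CLASSES = ("sign_opposite", "threshold_dual", "concordant")


def quartile_stratify(clinical: ClinicalTable,
                      time_column: str = "os_time",
                      min_samples: int = 8) -> tuple[list[str], list[str]]:
    """Shortest- and longest-survival quartile sample groups.

    Q1 holds samples with time <= the 25th empirical percentile, Q4 those
    with time >= the 75th percentile (linear-interpolation quantiles).
    Samples with missing time are excluded. If heavy ties make the two
    boundaries coincide, samples sitting on the shared boundary fall
    inward (are excluded from both groups) to keep the groups disjoint.
    """
    t = pd.to_numeric(clinical.data[time_column], errors="coerce").dropna()
    if len(t) < min_samples:
        raise DegenerateInputError(
            f"need >= {min_samples} samples with survival time, have {len(t)}"
        )
    if t.nunique() == 1:
        raise DegenerateInputError("all survival times identical")
    q1b = float(t.quantile(0.25, interpolation="linear"))
    q3b = float(t.quantile(0.75, interpolation="linear"))
    q1 = t.index[t <= q1b]
    q4 = t.index[t >= q3b]
    overlap = set(q1) & set(q4)
    if overlap:
        q1 = [s for s in q1 if s not in overlap]
        q4 = [s for s in q4 if s not in overlap]
    q1, q4 = list(q1), list(q4)
    if not q1 or not q4:
        raise DegenerateInputError(
            "survival ties collapse a quartile group to zero samples"
        )
    return q1, q4


def classify_discordance(s1: float, s2: float, *, sign_min: float = 1.0,
                         strong_min: float = 2.0,
                         dual_threshold: float = 2.5) -> str:
    """Classify a gene's score pair across two groups.

    threshold_dual: opposite signs with both |s| strictly above
    ``dual_threshold`` — the stringent dual-behavior call. sign_opposite:
    opposite signs with both |s| >= ``sign_min`` and at least one side
    >= ``strong_min`` — a sign flip with non-trivial evidence on both
    sides (the survival-screen call; e.g. (+3.04, -1.40) qualifies).
    Everything else is concordant.
    """
    lo, hi = sorted((abs(s1), abs(s2)))
    if s1 * s2 < 0:
        if lo > dual_threshold:
            return "threshold_dual"
        if lo >= sign_min and hi >= strong_min:
            return "sign_opposite"
    return "concordant"


@dataclass
class GroupComparisonResult:
    """Scores and discordance classification for two sample groups."""

    group_labels: tuple[str, str]
    table1: SScoreTable
    table2: SScoreTable
    data: pd.DataFrame  # gene-indexed: s_1, s_2, classification

    def discordant(self, kinds: tuple[str, ...] = ("sign_opposite",
                                                   "threshold_dual")) -> list[str]:
        mask = self.data["classification"].isin(kinds)
        return list(self.data.index[mask])


def compare_groups(cohort: CohortDataset, groups: tuple[list[str], list[str]],
                   w: IndexWeights | None = None,
                   config: ScoreConfig | None = None,
                   group_labels: tuple[str, str] = ("group1", "group2"),
                   sign_min: float = 1.0, strong_min: float = 2.0,
                   dual_threshold: float = 2.5) -> GroupComparisonResult:
    """Score two disjoint sample groups independently and classify
    per-gene discordance.

    Counts and informative totals are recomputed on each group's sample
    subset, so group scoring is exactly cohort scoring on the restricted
    cohort. External-catalog mutation counting cannot be restricted to a
    subgroup, so it is forced to cohort mode here (logged).
    """
    g1, g2 = groups
    if not g1 or not g2:
        raise ValidationError("both groups must be nonempty")
    if set(g1) & set(g2):
        raise ValidationError("groups must be disjoint")
    cfg = config or ScoreConfig()
    if cfg.mutation_mode == "external_catalog":
        log.warning(
            "group comparison forces mutation_mode=cohort: external-catalog "
            "nonsense totals cannot be restricted to a sample subgroup"
        )
        cfg = replace(cfg, mutation_mode="cohort")
    tables = []
    for label, members in zip(group_labels, (g1, g2)):
        sub = cohort.subset_samples(members,
                                    cohort_id=f"{cohort.cohort_id}:{label}")
        if all(sub.informative_counts(p).sum() == 0
               for p, _ in sub._matrices()):
            raise DegenerateInputError(
                f"group {label!r} has zero informative samples on every platform"
            )
        tables.append(score_cohort(sub, w, cfg))
    t1, t2 = tables
    common = t1.data.index.intersection(t2.data.index)
    s1 = t1.data.loc[common, "s"]
    s2 = t2.data.loc[common, "s"]
    cls = [classify_discordance(a, b, sign_min=sign_min, strong_min=strong_min,
                                dual_threshold=dual_threshold)
           for a, b in zip(s1, s2)]
    data = pd.DataFrame({"s_1": s1, "s_2": s2, "classification": cls},
                        index=common)
    return GroupComparisonResult(group_labels=group_labels, table1=t1,
                                 table2=t2, data=data)


def subtype_groups(clinical: ClinicalTable, covariates: dict[str, str],
                   other: dict[str, str]) -> tuple[list[str], list[str]]:
    """Sample groups defined by exact covariate-value matches, e.g.
    ({'ER': '+', 'PR': '+'}, {'ER': '-', 'PR': '-'})."""

    def match(spec: dict[str, str]) -> list[str]:
        mask = pd.Series(True, index=clinical.data.index)
        for k, v in spec.items():
            if k not in clinical.data.columns:
                raise ValidationError(f"unknown clinical covariate {k!r}")
            mask &= clinical.data[k].astype(str) == v
        return list(clinical.data.index[mask])

    return match(covariates), match(other)


def cross_tumor_dual(tables: list[SScoreTable],
                     threshold: float = 2.5) -> pd.DataFrame:
    """Genes behaving as oncogene in one tumor type and suppressor in
    another: s > +threshold in at least one cohort and s < -threshold in
    a different cohort (strict inequalities).

    Returns a gene-indexed frame with one score column per cohort plus
    max/min cohorts and a ``dual`` flag, restricted to genes scored in
    at least two cohorts. Symmetric in cohort order.
    """
    if len(tables) < 2:
        raise ValueError("need at least two cohorts")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ids = [t.cohort_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"cohort_ids must be unique, got {ids}")
    scores = pd.DataFrame({t.cohort_id: t.data["s"] for t in tables})
    shared = scores.dropna(thresh=2)
    if shared.empty:
        raise DegenerateInputError("cohort gene universes are disjoint")
    smax = shared.max(axis=1)
    smin = shared.min(axis=1)
    out = shared.copy()
    out["max_cohort"] = shared.idxmax(axis=1)
    out["min_cohort"] = shared.idxmin(axis=1)
    out["dual"] = (smax > threshold) & (smin < -threshold)
    # a single cohort cannot supply both extremes
    out.loc[out["max_cohort"] == out["min_cohort"], "dual"] = False
    return out


def top_k_scatter(table1: SScoreTable, table2: SScoreTable,
                  k: int = 50) -> pd.DataFrame:
    """Paired scores for the k top-positive and k top-negative genes of
    ``table1`` (classification by table1), restricted to genes scored in
    both tables. Ranks sort by score then gene symbol, so ties at rank k
    resolve lexicographically and deterministically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    common = table1.data.index.intersection(table2.data.index)
    s1 = table1.data.loc[common, "s"]
    s2 = table2.data.loc[common, "s"]

    def pick(side: str) -> pd.Index:
        if side == "oncogene":
            cand = s1[s1 > 0].sort_values(ascending=False)
        else:
            cand = s1[s1 < 0].sort_values(ascending=True)
        cand = cand.groupby(level=0).first()  # defensive; index already unique
        ordered = sorted(cand.index, key=lambda g: (cand[g] if side == "suppressor"
                                                    else -cand[g], g))
        if len(ordered) < k:
            warnings.warn(
                f"only {len(ordered)} {side} gene(s) available; requested {k}",
                stacklevel=3,
            )
        return pd.Index(ordered[:k])

    rows = []
    for side in ("oncogene", "suppressor"):
        for g in pick(side):
            rows.append((g, float(s1[g]), float(s2[g]), side))
    return pd.DataFrame(rows, columns=["gene", "s_1", "s_2", "side"]
                        ).set_index("gene")


def gene_diagnostic(cohort: CohortDataset, gene: str,
                    axis: str = "cnv") -> pd.DataFrame:
    """Per-sample diagnostic table for one gene: expression z against the
    requested categorical axis (copy-number category or methylation
    status), restricted to samples informative on both axes."""
    if axis not in ("cnv", "methylation"):
        raise ValueError(f"axis must be 'cnv' or 'methylation', got {axis!r}")
    if gene not in set(cohort.genes):
        raise KeyError(f"gene {gene!r} not in cohort {cohort.cohort_id!r}")
    if gene not in cohort.expression_z.index:
        raise DegenerateInputError(f"gene {gene!r} has no expression data")
    expr = cohort.expression_z.loc[gene]
    if axis == "cnv":
        if gene not in cohort.cnv.index:
            raise DegenerateInputError(f"gene {gene!r} has no CNV data")
        other = cohort.cnv.loc[gene]
        labeler = classify_cnv
    else:
        if cohort.methylation_call is None or gene not in cohort.methylation_call.index:
            raise DegenerateInputError(f"gene {gene!r} has no methylation data")
        other = cohort.methylation_call.loc[gene]
        labeler = lambda v: "methylated" if float(v) == 1.0 else "unmethylated"
    joint = pd.concat([expr.rename("expression_z"), other.rename("_x")],
                      axis=1, join="inner").dropna()
    if joint.empty:
        raise DegenerateInputError(
            f"gene {gene!r} has no samples informative on both expression "
            f"and {axis}"
        )
    joint["category"] = [labeler(float(v)) for v in joint["_x"]]
    out = joint.drop(columns="_x")
    out.index.name = "sample"
    return out
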