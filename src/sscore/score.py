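"""The S-score: a signed per-gene log2 contrast between oncogenic and
suppressive alteration evidence.

For each gene an oncogenic component So (amplification and
over-expression) and a suppressive component Ss (nonsense mutations,
methylation, deletion, under-expression) are formed as weighted sums of
alteration counts, each data type entering independently with its own
numerical index:

    So = i_A * A + i_O * O
    Ss = i_ns * ns + i_met * M + i_D * D + i_U * U

and the score is the log2 ratio s = log2(So / Ss), guarded where either
component drops below 1:

    So >= 1 and Ss >= 1 : s = log2(So / Ss)        (ratio)
    So <  1 and Ss >= 1 : s = -log2(Ss)            (so_clamped)
    Ss <  1 and So >= 1 : s = +log2(So)            (ss_clamped)
    both < 1            : s = 0                    (both_subunit_zero)

The clamp-to-1 guards are the unique choice that keeps s continuous at
the regime boundaries and consistent with "both below 1 maps to 0".
Negative scores indicate suppressor-like behavior, positive scores
oncogene-like behavior, and the ratio form rewards genes whose evidence
is exclusively on one side.

The default index profile, ``paper2014``, puts weight 5 on nonsense
mutations (an alteration that almost always abolishes protein function),
0.5 on amplification, over-expression, deletion and under-expression,
and 0 on methylation (excluded from the selected profile on quality
grounds, re-enabled by a single config change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field, replace

import numpy as np
import pandas as pd

from .calls import GeneAlterationCounts, tally_cohort
from .cohort import CohortDataset
from .config import ScoreConfig
from .errors import DegenerateInputError, ValidationError

GUARD_CASES = ("ratio", "so_clamped", "ss_clamped", "both_subunit_zero")


@dataclass(frozen=True)
class IndexWeights:
    """The six per-data-type indexes (all nonnegative)."""

    i_A: float = 0.5
    i_O: float = 0.5
    i_ns: float = 5.0
    i_met: float = 0.0
    i_D: float = 0.5
    i_U: float = 0.5

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValidationError(f"index {name} must be nonnegative, got {v}")

    def to_dict(self) -> dict:
        return asdict(self)


#: Named index profiles; ``paper2014`` is the selected default.
WEIGHT_PROFILES: dict[str, IndexWeights] = {
    "paper2014": IndexWeights(i_ns=5.0, i_A=0.5, i_O=0.5, i_D=0.5, i_U=0.5,
                              i_met=0.0),
    "uniform": IndexWeights(i_ns=0.5, i_A=0.5, i_O=0.5, i_D=0.5, i_U=0.5,
                            i_met=0.0),
}


@dataclass(frozen=True)
class SScoreResult:
    gene: str
    So: float
    Ss: float
    s: float
    guard_case: str


@dataclass
class SScoreTable:
    """Genome-wide scores for one cohort.

    ``data`` is indexed by gene with columns So, Ss, s, guard_case.
    mean_s / sd_s summarize the score distribution (sample SD, ddof=1)
    and back the Z-score-normalized extreme thresholds.
    """

    cohort_id: str
    data: pd.DataFrame
    weights: IndexWeights
    normalization_mode: str
    config_digest: str = ""

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def scores(self) -> pd.Series:
        return self.data["s"]

    @property
    def mean_s(self) -> float:
        return float(self.data["s"].mean())

    @property
    def sd_s(self) -> float:
        return float(self.data["s"].std(ddof=1))

    def row(self, gene: str) -> SScoreResult:
        r = self.data.loc[gene]
        return SScoreResult(gene=gene, So=float(r["So"]), Ss=float(r["Ss"]),
                            s=float(r["s"]), guard_case=str(r["guard_case"]))


def _component_terms(counts: GeneAlterationCounts, w: IndexWeights,
                     mode: str) -> tuple[float, float]:
    c = counts
    if mode == "raw_counts":
        so = w.i_A * c.A + w.i_O * c.O
        ss = w.i_ns * c.ns + w.i_met * c.M + w.i_D * c.D + w.i_U * c.U
    elif mode == "coverage_adjusted":
        # Rescale each platform's count to the full cohort; platforms with
        # zero informative samples contribute 0. Mutations have no
        # informative total, so the ns term stays unscaled.
        f_cnv = c.N_cohort / c.T_cnv if c.T_cnv else 0.0
        f_exp = c.N_cohort / c.T_exp if c.T_exp else 0.0
        f_met = c.N_cohort / c.T_met if c.T_met else 0.0
        so = w.i_A * c.A * f_cnv + w.i_O * c.O * f_exp
        ss = (w.i_ns * c.ns + w.i_met * c.M * f_met + w.i_D * c.D * f_cnv
              + w.i_U * c.U * f_exp)
    elif mode == "frequency":
        a = c.A / c.T_cnv if c.T_cnv else 0.0
        d = c.D / c.T_cnv if c.T_cnv else 0.0
        o = c.O / c.T_exp if c.T_exp else 0.0
        u = c.U / c.T_exp if c.T_exp else 0.0
        m = c.M / c.T_met if c.T_met else 0.0
        ns = c.ns / c.N_cohort if c.N_cohort else 0.0
        so = w.i_A * a + w.i_O * o
        ss = w.i_ns * ns + w.i_met * m + w.i_D * d + w.i_U * u
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return so, ss


def compute_components(counts: GeneAlterationCounts, w: IndexWeights,
                       normalization_mode: str = "raw_counts",
                       ) -> tuple[float, float]:
    """Oncogenic and suppressive components (So, Ss) for one gene."""
    return _component_terms(counts, w, normalization_mode)


def s_score(So: float, Ss: float) -> tuple[float, str]:
    """The signed score and which guard regime produced it."""
    if So < 0 or Ss < 0:
        raise ValidationError(f"components must be nonnegative, got ({So}, {Ss})")
    if So >= 1 and Ss >= 1:
        return math.log2(So / Ss), "ratio"
    if So < 1 and Ss >= 1:
        return -math.log2(Ss), "so_clamped"
    if Ss < 1 and So >= 1:
        return math.log2(So), "ss_clamped"
    return 0.0, "both_subunit_zero"


def _score_vector(so: np.ndarray, ss: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized guard logic, exactly mirroring :func:`s_score`."""
    so = np.asarray(so, dtype=float)
    ss = np.asarray(ss, dtype=float)
    if (so < 0).any() or (ss < 0).any():
        raise ValidationError("components must be nonnegative")
    s = np.zeros_like(so)
    case = np.full(so.shape, "both_subunit_zero", dtype=object)
    both = (so >= 1) & (ss >= 1)
    so_cl = (so < 1) & (ss >= 1)
    ss_cl = (ss < 1) & (so >= 1)
    s[both] = np.log2(so[both] / ss[both])
    s[so_cl] = -np.log2(ss[so_cl])
    s[ss_cl] = np.log2(so[ss_cl])
    case[both] = "ratio"
    case[so_cl] = "so_clamped"
    case[ss_cl] = "ss_clamped"
    return s, case


def score_from_tallies(tallies: pd.DataFrame, w: IndexWeights,
                       normalization_mode: str = "raw_counts",
                       cohort_id: str = "", config_digest: str = "",
                       ) -> SScoreTable:
    """Score a precomputed per-gene tally table (columns as produced by
    :func:`sscore.calls.tally_cohort`). Separating this step from the
    counting lets an index grid search reuse one tally per cohort."""
    t = tallies
    if (t[["ns", "M", "D", "A", "O", "U"]] < 0).any().any():
        raise ValidationError("negative alteration counts")
    mode = normalization_mode
    if mode == "raw_counts":
        so = w.i_A * t["A"] + w.i_O * t["O"]
        ss = (w.i_ns * t["ns"] + w.i_met * t["M"] + w.i_D * t["D"]
              + w.i_U * t["U"])
    elif mode == "coverage_adjusted":
        f_cnv = (t["N_cohort"] / t["T_cnv"]).where(t["T_cnv"] > 0, 0.0)
        f_exp = (t["N_cohort"] / t["T_exp"]).where(t["T_exp"] > 0, 0.0)
        f_met = (t["N_cohort"] / t["T_met"]).where(t["T_met"] > 0, 0.0)
        so = w.i_A * t["A"] * f_cnv + w.i_O * t["O"] * f_exp
        ss = (w.i_ns * t["ns"] + w.i_met * t["M"] * f_met
              + w.i_D * t["D"] * f_cnv + w.i_U * t["U"] * f_exp)
    elif mode == "frequency":
        a = (t["A"] / t["T_cnv"]).where(t["T_cnv"] > 0, 0.0)
        d = (t["D"] / t["T_cnv"]).where(t["T_cnv"] > 0, 0.0)
        o = (t["O"] / t["T_exp"]).where(t["T_exp"] > 0, 0.0)
        u = (t["U"] / t["T_exp"]).where(t["T_exp"] > 0, 0.0)
        m = (t["M"] / t["T_met"]).where(t["T_met"] > 0, 0.0)
        ns = (t["ns"] / t["N_cohort"]).where(t["N_cohort"] > 0, 0.0)
        so = w.i_A * a + w.i_O * o
        ss = w.i_ns * ns + w.i_met * m + w.i_D * d + w.i_U * u
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    s, case = _score_vector(so.to_numpy(), ss.to_numpy())
    data = pd.DataFrame(
        {"So": so.to_numpy(dtype=float), "Ss": ss.to_numpy(dtype=float),
         "s": s, "guard_case": case},
        index=t.index.copy(),
    )
    return SScoreTable(cohort_id=cohort_id, data=data, weights=w,
                       normalization_mode=mode, config_digest=config_digest)


def score_cohort(cohort: CohortDataset, w: IndexWeights | None = None,
                 config: ScoreConfig | None = None) -> SScoreTable:
    """Genome-wide S-scores for one cohort: tally every gene, form the
    components under the configured normalization mode, apply the guarded
    log2 ratio. Deterministic given inputs and config; invariant to
    sample order."""
    cfg = config or ScoreConfig()
    weights = w or WEIGHT_PROFILES["paper2014"]
    if not cohort.genes:
        raise DegenerateInputError(f"cohort {cohort.cohort_id!r} is empty")
    tallies = tally_cohort(cohort, cfg)
    return score_from_tallies(tallies, weights, cfg.normalization_mode,
                              cohort_id=cohort.cohort_id,
                              config_digest=cfg.digest())


def zscore_thresholds(table: SScoreTable, z: float = 2.0) -> tuple[float, float]:
    """Distribution-normalized extreme thresholds: mean_s -/+ z * sd_s."""
    if z <= 0:
        raise ValueError(f"z must be positive, got {z}")
    sd = table.sd_s
    if not sd > 0:
        raise DegenerateInputError(
            f"score distribution for {table.cohort_id!r} is degenerate (sd=0)"
        )
    m = table.mean_s
    return m - z * sd, m + z * sd


def extreme_genes(table: SScoreTable, lower: float, upper: float) -> set[str]:
    """Genes with s strictly below ``lower`` or strictly above ``upper``."""
    if not lower < upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")
    s = table.data["s"]
    return set(s.index[(s < lower) | (s > upper)])
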