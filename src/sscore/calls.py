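"""Alteration calling: per-sample calls from GISTIC values, expression
z-scores and methylation, aggregated into per-gene count vectors.

The copy-number categories follow the published gene-level GISTIC
thresholds: homozygous deletion <= -2, deletion (-2, -1], neutral
(-1, +1), gain [+1, 2), amplification >= 2. The five intervals partition
the real line, so every non-missing value receives exactly one category;
missing cells receive no call and do not count toward the informative
total T_cnv.

Expression calls are symmetric and boundary-inclusive: over-expressed
when z >= z_thr, under-expressed when z <= -z_thr.

Nonsense mutations are counted per gene in one of two modes mirroring
the TCGA-vs-COSMIC stratification: ``cohort`` counts at most one event
per (gene, sample) among cohort samples, while ``external_catalog``
counts every nonsense record for the gene, because catalog totals are
record-based and cannot be deduplicated against cohort membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset, MutationRecord
from .config import ScoreConfig
from .errors import ValidationError

CNV_CATEGORIES = ("homozygous_deletion", "deletion", "neutral", "gain", "amplification")


def classify_cnv(value: float) -> str:
    """Map one gene-level GISTIC value to its copy-number category.

    Raises ValueError for non-finite input; missing cells must be
    filtered out before calling (they carry no category).
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError("missing CNV value has no category; filter NaN first")
    if not math.isfinite(value):
        raise ValueError(f"CNV value must be finite, got {value}")
    if value <= -2:
        return "homozygous_deletion"
    if value <= -1:
        return "deletion"
    if value < 1:
        return "neutral"
    if value < 2:
        return "gain"
    return "amplification"


def classify_expression(z: float, z_thr: float = 2.0) -> str:
    """Call one expression z-score as over / under / neutral."""
    if z_thr <= 0:
        raise ValueError(f"z_thr must be positive, got {z_thr}")
    if z is None or (isinstance(z, float) and math.isnan(z)):
        raise ValueError("missing z-score has no call; filter NaN first")
    if not math.isfinite(z):
        raise ValueError(f"z-score must be finite, got {z}")
    if z >= z_thr:
        return "over"
    if z <= -z_thr:
        return "under"
    return "neutral"


def beta_to_binary(beta: pd.DataFrame, beta_thr: float = 0.7) -> pd.DataFrame:
    """Optional helper: threshold methylation beta values into binary
    calls (1 = methylated when beta >= beta_thr). The scoring path never
    applies this by default; it consumes precomputed binary matrices."""
    out = (beta >= beta_thr).astype(float)
    return out.where(beta.notna())


@dataclass(frozen=True)
class GeneAlterationCounts:
    """Per-gene alteration tallies feeding the score components.

    ns: nonsense mutations; M / T_met: methylated and informative sample
    counts; D / T_cnv: deleted and informative; A: amplified; O / T_exp /
    U: over-expressed, informative, under-expressed. N_cohort is the
    cohort sample count, used only by the frequency normalization mode.
    """

    gene: str
    ns: int = 0
    M: int = 0
    T_met: int = 0
    D: int = 0
    T_cnv: int = 0
    A: int = 0
    O: int = 0
    T_exp: int = 0
    U: int = 0
    N_cohort: int = 0

    def __post_init__(self) -> None:
        for name in ("ns", "M", "T_met", "D", "T_cnv", "A", "O", "T_exp", "U",
                     "N_cohort"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{name} must be a nonnegative integer, got {v}")
        if self.M > self.T_met:
            raise ValidationError(f"M={self.M} exceeds T_met={self.T_met}")
        if self.D + self.A > self.T_cnv:
            raise ValidationError(
                f"D+A={self.D + self.A} exceeds T_cnv={self.T_cnv}"
            )
        if self.O + self.U > self.T_exp:
            raise ValidationError(
                f"O+U={self.O + self.U} exceeds T_exp={self.T_exp}"
            )


def count_nonsense(mutations: list[MutationRecord], gene: str, mode: str = "cohort",
                   cohort_samples: set[str] | None = None,
                   nonsense_classes: tuple[str, ...] = ScoreConfig.nonsense_classes,
                   ) -> int:
    """Nonsense-mutation count for one gene under the declared mode.

    cohort mode requires ``cohort_samples`` and deduplicates per sample;
    external_catalog mode counts records. An absent gene yields 0.
    """
    ns_classes = set(nonsense_classes)
    recs = [r for r in mutations if r.gene == gene and r.variant_class in ns_classes]
    if mode == "external_catalog":
        return len(recs)
    if mode == "cohort":
        if cohort_samples is None:
            raise ValueError("cohort mode needs the cohort sample set")
        return len({r.sample for r in recs
                    if r.source == "cohort" and r.sample in cohort_samples})
    raise ValueError(f"unknown mutation mode {mode!r}")


def tally_gene(cohort: CohortDataset, gene: str,
               config: ScoreConfig | None = None) -> GeneAlterationCounts:
    """Per-gene alteration tallies via explicit cell-by-cell calls.

    This is the readable scalar reference path; :func:`tally_cohort`
    computes the same numbers vectorized for genome-wide runs, and the
    two are held equal by the pipeline-composition property.
    """
    cfg = config or ScoreConfig()
    if gene not in set(cohort.genes):
        raise KeyError(f"gene {gene!r} not in cohort {cohort.cohort_id!r}")

    A = D = T_cnv = 0
    if gene in cohort.cnv.index:
        for v in cohort.cnv.loc[gene]:
            if pd.isna(v):
                continue
            T_cnv += 1
            cat = classify_cnv(float(v))
            if cat == "amplification" or (cfg.include_gain_in_A and cat == "gain"):
                A += 1
            elif cat == "homozygous_deletion" or (
                    cfg.include_hetloss_in_D and cat == "deletion"):
                D += 1

    O = U = T_exp = 0
    if gene in cohort.expression_z.index:
        for v in cohort.expression_z.loc[gene]:
            if pd.isna(v):
                continue
            T_exp += 1
            call = classify_expression(float(v), cfg.z_thr)
            if call == "over":
                O += 1
            elif call == "under":
                U += 1

    M = T_met = 0
    if cohort.methylation_call is not None and gene in cohort.methylation_call.index:
        for v in cohort.methylation_call.loc[gene]:
            if pd.isna(v):
                continue
            T_met += 1
            if float(v) == 1.0:
                M += 1

    ns = count_nonsense(cohort.mutations, gene, mode=cfg.mutation_mode,
                        cohort_samples=set(cohort.samples),
                        nonsense_classes=cfg.nonsense_classes)
    return GeneAlterationCounts(gene=gene, ns=ns, M=M, T_met=T_met, D=D,
                                T_cnv=T_cnv, A=A, O=O, T_exp=T_exp, U=U,
                                N_cohort=cohort.n_samples)


def tally_cohort(cohort: CohortDataset,
                 config: ScoreConfig | None = None) -> pd.DataFrame:
    """Genome-wide alteration tallies, one row per gene.

    Columns: ns, M, T_met, D, T_cnv, A, O, T_exp, U, N_cohort — exact
    integers recomputable from the raw matrices.
    """
    cfg = config or ScoreConfig()
    genes = cohort.genes
    if not genes:
        raise ValidationError(f"cohort {cohort.cohort_id!r} has no genes")
    idx = pd.Index(genes, name="gene")
    out = pd.DataFrame(0, index=idx,
                       columns=["ns", "M", "T_met", "D", "T_cnv", "A", "O",
                                "T_exp", "U", "N_cohort"], dtype=np.int64)
    out["N_cohort"] = cohort.n_samples

    cnv = cohort.cnv
    amp = (cnv >= 2) | ((cnv >= 1) & (cnv < 2)) if cfg.include_gain_in_A else (cnv >= 2)
    dele = (cnv <= -1) if cfg.include_hetloss_in_D else (cnv <= -2)
    out.loc[cnv.index, "A"] = amp.sum(axis=1).astype(np.int64)
    out.loc[cnv.index, "D"] = dele.sum(axis=1).astype(np.int64)
    out.loc[cnv.index, "T_cnv"] = cnv.notna().sum(axis=1).astype(np.int64)

    expr = cohort.expression_z
    out.loc[expr.index, "O"] = (expr >= cfg.z_thr).sum(axis=1).astype(np.int64)
    out.loc[expr.index, "U"] = (expr <= -cfg.z_thr).sum(axis=1).astype(np.int64)
    out.loc[expr.index, "T_exp"] = expr.notna().sum(axis=1).astype(np.int64)

    met = cohort.methylation_call
    if met is not None:
        out.loc[met.index, "M"] = (met == 1).sum(axis=1).astype(np.int64)
        out.loc[met.index, "T_met"] = met.notna().sum(axis=1).astype(np.int64)

    if cohort.mutations:
        ns_classes = set(cfg.nonsense_classes)
        if cfg.mutation_mode == "cohort":
            keep = set(cohort.samples)
            pairs = {(r.gene, r.sample) for r in cohort.mutations
                     if r.variant_class in ns_classes and r.source == "cohort"
                     and r.sample in keep}
            ns = pd.Series([g for g, _ in pairs]).value_counts()
        else:
            ns = pd.Series([r.gene for r in cohort.mutations
                            if r.variant_class in ns_classes]).value_counts()
        common = ns.index.intersection(idx)
        out.loc[common, "ns"] = ns.loc[common].astype(np.int64)
    return out
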