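"""Run-time configuration for alteration calling and scoring.

The alteration-calling thresholds live here rather than being hard-coded
inside the counting routines so that every output table can record exactly
which calling convention produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

#: Variant-classification labels treated as nonsense (premature stop) calls.
#: Covers the MAF convention, a plain-word dialect, and Sequence Ontology.
DEFAULT_NONSENSE_CLASSES = ("Nonsense_Mutation", "nonsense", "stop_gained")

#: Recognised normalization modes for the score components.
NORMALIZATION_MODES = ("raw_counts", "coverage_adjusted", "frequency")

#: Mutation counting modes: restrict to cohort samples, or count every
#: catalog record for the gene (the COSMIC-style tally).
MUTATION_MODES = ("cohort", "external_catalog")


@dataclass(frozen=True)
class ScoreConfig:
    """Calling and scoring conventions.

    Parameters
    ----------
    z_thr:
        Expression z-score cutoff; a sample is over-expressed when
        z >= z_thr and under-expressed when z <= -z_thr (boundary
        inclusive). Default 2.0, the cBio-portal-era convention.
    include_hetloss_in_D:
        Count single-copy (heterozygous) losses in the per-gene deletion
        tally D alongside homozygous deletions. Default True.
    include_gain_in_A:
        Count low-level gains in the amplification tally A alongside
        high-level amplifications. Default False: only GISTIC >= +2 calls.
    mutation_mode:
        "cohort" counts nonsense mutations in cohort samples, one per
        (gene, sample) pair; "external_catalog" counts every nonsense
        record for the gene regardless of sample membership.
    beta_thr:
        Methylation beta cutoff used only by the optional beta-to-binary
        helper; the scoring path consumes precomputed binary calls.
    normalization_mode:
        How alteration counts enter the score components; see
        :func:`sscore.score.compute_components`.
    nonsense_classes:
        Variant-class labels counted as nonsense mutations.
    """

    z_thr: float = 2.0
    include_hetloss_in_D: bool = True
    include_gain_in_A: bool = False
    mutation_mode: str = "cohort"
    beta_thr: float = 0.7
    normalization_mode: str = "raw_counts"
    nonsense_classes: tuple[str, ...] = DEFAULT_NONSENSE_CLASSES

    def __post_init__(self) -> None:
        if self.z_thr <= 0:
            raise ValueError(f"z_thr must be positive, got {self.z_thr}")
        if self.mutation_mode not in MUTATION_MODES:
            raise ValueError(
                f"mutation_mode must be one of {MUTATION_MODES}, "
                f"got {self.mutation_mode!r}"
            )
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ValueError(
                f"normalization_mode must be one of {NORMALIZATION_MODES}, "
                f"got {self.normalization_mode!r}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nonsense_classes"] = list(self.nonsense_classes)
        return d

    def digest(self) -> str:
        """Stable short hash of the configuration, recorded in output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
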