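"""Seeded synthetic cohort generator with exact ground truth.

The generator emulates the statistical shape of TCGA-style gene x sample
matrices: per-gene alteration frequencies, per-platform missing-cell
masks, nonsense-mutation tables and a clinical table, with planted
extreme genes (oncogene, suppressor, silenced suppressor, dual) whose
alteration frequencies are elevated. Emitted objects and files are
exactly the formats :mod:`sscore.cohort` reads, so every pipeline stage
is testable without any download.

Determinism: one RNG stream per platform per cohort, all derived from
the master seed, so adding or removing a platform never perturbs another
platform's draws, and identical configs give byte-identical files. The
single exception is the silenced-suppressor overlay: its co-occurring
(methylated AND under-expressed) cells are drawn on the methylation
stream and stamped onto the expression matrix, because co-occurrence
cannot live in one platform alone.

Effect encoding places values comfortably past the calling thresholds
(amplified cells uniform on [2, 4], deleted on [-4, -2], outlier |z|
uniform on [z_thr + 0.5, z_thr + 3]) so planted calls are unambiguous.
Neutral z-scores are standard normal truncated just inside the calling
threshold, which keeps the realized over/under calls identical to the
configured Bernoulli draws and hence the recorded truth exact;
background over/under-expression is injected explicitly through the
background rates rather than through the tail of the neutral draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import ClinicalTable, CohortDataset, MutationRecord
from .errors import ValidationError

ROLES = ("oncogene", "suppressor", "silenced_suppressor", "dual", "custom")

_FREQ_FIELDS = ("freq_amp", "freq_over", "freq_del", "freq_ns", "freq_met",
                "freq_under")

#: integer stream tags per platform; the master seed is paired with these
_STREAMS = {"cnv": 1, "expression": 2, "methylation": 3, "mutation": 4,
            "clinical": 5}

DEFAULT_BACKGROUND = {
    "amp": 0.01, "del": 0.01, "over": 0.02, "under": 0.02,
    "ns": 0.002, "met": 0.01, "missense": 0.005,
}

DEFAULT_MISSINGNESS = {"cnv": 0.02, "expression": 0.02, "methylation": 0.05}

DEFAULT_SURVIVAL = {"dist": "lognormal", "mean_log": 6.5, "sigma_log": 0.8}


@dataclass(frozen=True)
class PlantedGene:
    """A gene with elevated per-sample alteration frequencies.

    ``group_freqs`` optionally overrides frequencies for samples whose
    group covariate takes a given value (subtype / survival scenarios):
    a map {covariate value: {freq field: probability}}.
    """

    gene: str
    role: str = "custom"
    freq_amp: float = 0.0
    freq_over: float = 0.0
    freq_del: float = 0.0
    freq_ns: float = 0.0
    freq_met: float = 0.0
    freq_under: float = 0.0
    group_freqs: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown planted role {self.role!r}")
        for f in _FREQ_FIELDS:
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.gene}: {f}={v} outside [0, 1]")
        if self.group_freqs:
            for val, over in self.group_freqs.items():
                for f, v in over.items():
                    if f not in _FREQ_FIELDS:
                        raise ValidationError(
                            f"{self.gene}: unknown frequency field {f!r} "
                            f"in group override {val!r}")
                    if not 0.0 <= v <= 1.0:
                        raise ValidationError(
                            f"{self.gene}: group override {f}={v} outside [0, 1]")


def oncogene(gene: str, freq_amp: float = 0.3, freq_over: float = 0.3,
             **kw) -> PlantedGene:
    return PlantedGene(gene=gene, role="oncogene", freq_amp=freq_amp,
                       freq_over=freq_over, **kw)


def suppressor(gene: str, freq_del: float = 0.3, freq_ns: float = 0.1,
               freq_under: float = 0.0, **kw) -> PlantedGene:
    return PlantedGene(gene=gene, role="suppressor", freq_del=freq_del,
                       freq_ns=freq_ns, freq_under=freq_under, **kw)


def silenced_suppressor(gene: str, freq_met: float = 0.3,
                        freq_under: float = 0.0, **kw) -> PlantedGene:
    """Methylation-silenced suppressor: freq_met controls co-occurring
    (methylated AND under-expressed) samples; freq_under adds independent
    under-expression on top."""
    return PlantedGene(gene=gene, role="silenced_suppressor",
                       freq_met=freq_met, freq_under=freq_under, **kw)


@dataclass(frozen=True)
class GroupSpec:
    """Sample group structure written to the clinical covariate
    ``covariate``; optional per-value survival-time ranges (uniform
    low/high, same unit as os_time) give clean quartile scenarios."""

    covariate: str
    values: tuple[str, ...]
    proportions: tuple[float, ...] | None = None
    survival_by_value: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValidationError("group structure needs >= 2 values")
        if self.proportions is not None:
            if len(self.proportions) != len(self.values):
                raise ValidationError("proportions must match values")
            if abs(sum(self.proportions) - 1.0) > 1e-9:
                raise ValidationError("proportions must sum to 1")


@dataclass(frozen=True)
class GeneratorConfig:
    cohort_id: str = "SIM"
    n_samples: int = 200
    n_genes: int = 100
    planted: tuple[PlantedGene, ...] = ()
    background: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND))
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    seed: int = 0
    z_thr: float = 2.0
    with_methylation: bool = True
    group: GroupSpec | None = None
    survival: dict = field(default_factory=lambda: dict(DEFAULT_SURVIVAL))
    external_ns: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        problems: list[str] = []
        if self.n_samples < 1 or self.n_genes < 1:
            problems.append("n_samples and n_genes must be >= 1")
        names = [p.gene for p in self.planted]
        if len(set(names)) != len(names):
            problems.append("duplicate planted gene symbols")
        if len(names) > self.n_genes:
            problems.append("more planted genes than n_genes")
        for k, v in {**self.background, **self.missingness}.items():
            if not 0.0 <= v <= 1.0:
                problems.append(f"probability {k}={v} outside [0, 1]")
        if self.background.get("amp", 0) + self.background.get("del", 0) > 1:
            problems.append("background amp + del exceed 1")
        if self.background.get("over", 0) + self.background.get("under", 0) > 1:
            problems.append("background over + under exceed 1")
        for p in self.planted:
            if p.freq_amp + p.freq_del > 1:
                problems.append(f"{p.gene}: freq_amp + freq_del exceed 1")
            if p.freq_over + p.freq_under > 1:
                problems.append(f"{p.gene}: freq_over + freq_under exceed 1")
        if problems:
            raise ValidationError("invalid generator config: "
                                  + "; ".join(problems))

    @property
    def genes(self) -> list[str]:
        planted = [p.gene for p in self.planted]
        fillers = [f"G{i:04d}" for i in range(1, self.n_genes - len(planted) + 1)]
        clash = set(planted) & set(fillers)
        if clash:
            raise ValidationError(
                f"planted symbols collide with filler names: {sorted(clash)[:3]}")
        return planted + fillers

    @property
    def samples(self) -> list[str]:
        return [f"{self.cohort_id}_{i:04d}" for i in range(1, self.n_samples + 1)]


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def _freq_matrix(config: GeneratorConfig, fld: str, bg_key: str,
                 group_of_sample: np.ndarray | None) -> np.ndarray:
    """Per-gene, per-sample Bernoulli frequency for one alteration kind."""
    G, S = config.n_genes, config.n_samples
    f = np.full((G, S), float(config.background.get(bg_key, 0.0)))
    for gi, p in enumerate(config.planted):
        f[gi, :] = getattr(p, fld)
        if p.group_freqs and group_of_sample is not None:
            for val, over in p.group_freqs.items():
                if fld in over:
                    f[gi, group_of_sample == val] = over[fld]
    return f


def generate_cohort(config: GeneratorConfig,
                    ) -> tuple[CohortDataset, pd.DataFrame]:
    """Generate one cohort and its truth table.

    The truth table holds the realized per-gene alteration counts (ns, M,
    T_met, D, T_cnv, A, O, T_exp, U recounted from the emitted matrices
    with plain array operations, mirroring the default calling config)
    plus each gene's planted role — the bookkeeping oracle for the
    counting and scoring pipeline.
    """
    genes = config.genes
    samples = config.samples
    G, S = len(genes), len(samples)

    # clinical stream: group assignment and survival times
    rng_cli = _rng(config, "clinical")
    group_of_sample = None
    clin_cols: dict[str, object] = {}
    if config.group is not None:
        g = config.group
        props = g.proportions or tuple(1 / len(g.values) for _ in g.values)
        group_of_sample = rng_cli.choice(np.array(g.values, dtype=object),
                                         size=S, p=props)
        clin_cols[g.covariate] = group_of_sample
    surv = config.survival
    if surv.get("dist") == "lognormal":
        times = rng_cli.lognormal(surv.get("mean_log", 6.5),
                                  surv.get("sigma_log", 0.8), size=S)
    elif surv.get("dist") == "exponential":
        times = rng_cli.exponential(surv.get("scale", 700.0), size=S)
    elif surv.get("dist") == "uniform":
        times = rng_cli.uniform(surv.get("low", 0.0), surv.get("high", 2000.0),
                                size=S)
    else:
        raise ValidationError(f"unknown survival dist {surv.get('dist')!r}")
    if config.group is not None and config.group.survival_by_value:
        for val, (lo, hi) in config.group.survival_by_value.items():
            mask = group_of_sample == val
            times[mask] = rng_cli.uniform(lo, hi, size=int(mask.sum()))
    clinical = ClinicalTable(
        pd.DataFrame({"os_time": np.round(times, 1), **clin_cols},
                     index=pd.Index(samples, name="sample")))

    # cnv stream
    rng_cnv = _rng(config, "cnv")
    f_amp = _freq_matrix(config, "freq_amp", "amp", group_of_sample)
    f_del = _freq_matrix(config, "freq_del", "del", group_of_sample)
    u = rng_cnv.random((G, S))
    v_amp = rng_cnv.uniform(2.0, 4.0, (G, S))
    v_del = rng_cnv.uniform(-4.0, -2.0, (G, S))
    v_neu = rng_cnv.uniform(-0.9, 0.9, (G, S))
    cnv_vals = np.where(u < f_amp, v_amp,
                        np.where(u < f_amp + f_del, v_del, v_neu))
    cnv_miss = rng_cnv.random((G, S)) < config.missingness.get("cnv", 0.0)

    # expression stream
    rng_exp = _rng(config, "expression")
    f_over = _freq_matrix(config, "freq_over", "over", group_of_sample)
    f_under = _freq_matrix(config, "freq_under", "under", group_of_sample)
    u = rng_exp.random((G, S))
    margin = 0.5
    v_over = config.z_thr + margin + rng_exp.uniform(0.0, 2.5, (G, S))
    v_under = -(config.z_thr + margin + rng_exp.uniform(0.0, 2.5, (G, S)))
    b = config.z_thr - 0.1  # neutral z: standard normal truncated inside the cutoff
    v_neu = truncnorm.ppf(rng_exp.random((G, S)), -b, b)
    expr_vals = np.where(u < f_over, v_over,
                         np.where(u < f_over + f_under, v_under, v_neu))
    expr_miss = rng_exp.random((G, S)) < config.missingness.get("expression", 0.0)

    # methylation stream (+ silenced-suppressor overlay onto expression)
    met_vals = met_miss = None
    if config.with_methylation:
        rng_met = _rng(config, "methylation")
        f_met = _freq_matrix(config, "freq_met", "met", group_of_sample)
        met = rng_met.random((G, S)) < f_met
        for gi, p in enumerate(config.planted):
            if p.role == "silenced_suppressor":
                expr_vals[gi, met[gi]] = v_under[gi, met[gi]]
        met_vals = met.astype(float)
        met_miss = rng_met.random((G, S)) < config.missingness.get(
            "methylation", 0.0)

    # mutation stream
    rng_mut = _rng(config, "mutation")
    f_ns = _freq_matrix(config, "freq_ns", "ns", group_of_sample)
    ns_mask = rng_mut.random((G, S)) < f_ns
    mis_mask = rng_mut.random((G, S)) < config.background.get("missense", 0.0)
    mutations: list[MutationRecord] = []
    for gi, si in zip(*np.nonzero(ns_mask)):
        mutations.append(MutationRecord(gene=genes[gi], sample=samples[si],
                                        variant_class="Nonsense_Mutation"))
    for gi, si in zip(*np.nonzero(mis_mask)):
        mutations.append(MutationRecord(gene=genes[gi], sample=samples[si],
                                        variant_class="Missense_Mutation"))
    for gene, count in sorted(config.external_ns.items()):
        for i in range(count):
            mutations.append(MutationRecord(
                gene=gene, sample=f"CATALOG_{gene}_{i + 1}",
                variant_class="Nonsense_Mutation", source="external_catalog"))

    gidx = pd.Index(genes, name="gene")
    cnv = pd.DataFrame(np.where(cnv_miss, np.nan, np.round(cnv_vals, 4)),
                       index=gidx, columns=samples)
    expr = pd.DataFrame(np.where(expr_miss, np.nan, np.round(expr_vals, 4)),
                        index=gidx, columns=samples)
    met_df = None
    if met_vals is not None:
        met_df = pd.DataFrame(np.where(met_miss, np.nan, met_vals),
                              index=gidx, columns=samples)

    cohort = CohortDataset(cohort_id=config.cohort_id, cnv=cnv,
                           expression_z=expr, methylation_call=met_df,
                           mutations=mutations, clinical=clinical)
    truth = _truth_table(config, cohort)
    return cohort, truth


def _truth_table(config: GeneratorConfig, cohort: CohortDataset) -> pd.DataFrame:
    """Realized per-gene counts, recounted from the emitted matrices with
    plain array arithmetic (independent of :mod:`sscore.calls`)."""
    genes = config.genes
    cn = cohort.cnv.to_numpy()
    ex = cohort.expression_z.to_numpy()
    ok_cn = ~np.isnan(cn)
    ok_ex = ~np.isnan(ex)
    t = pd.DataFrame(index=pd.Index(genes, name="gene"))
    t["role"] = "null"
    for p in config.planted:
        t.loc[p.gene, "role"] = p.role
    t["A"] = (ok_cn & (cn >= 2)).sum(axis=1)
    t["D"] = (ok_cn & (cn <= -1)).sum(axis=1)
    t["T_cnv"] = ok_cn.sum(axis=1)
    t["O"] = (ok_ex & (ex >= config.z_thr)).sum(axis=1)
    t["U"] = (ok_ex & (ex <= -config.z_thr)).sum(axis=1)
    t["T_exp"] = ok_ex.sum(axis=1)
    if cohort.methylation_call is not None:
        me = cohort.methylation_call.to_numpy()
        ok_me = ~np.isnan(me)
        t["M"] = (ok_me & (me == 1.0)).sum(axis=1)
        t["T_met"] = ok_me.sum(axis=1)
    else:
        t["M"] = 0
        t["T_met"] = 0
    pairs = {(r.gene, r.sample) for r in cohort.mutations
             if r.variant_class == "Nonsense_Mutation" and r.source == "cohort"}
    ns = pd.Series([g for g, _ in pairs]).value_counts()
    t["ns"] = ns.reindex(t.index).fillna(0).astype(int)
    t["N_cohort"] = config.n_samples
    return t


def generate_multi_cohort(configs: list[GeneratorConfig],
                          ) -> dict[str, tuple[CohortDataset, pd.DataFrame]]:
    """Generate several cohorts over a shared gene universe (for the
    cross-tumor dual-behavior screen): every config must declare the same
    gene list; dual genes are planted with opposite roles in different
    configs. Returns {cohort_id: (cohort, truth)}."""
    if len(configs) < 2:
        raise ValidationError("need >= 2 cohort configs")
    ids = [c.cohort_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValidationError("cohort_ids must be unique")
    universe = configs[0].genes
    for c in configs[1:]:
        if c.genes != universe:
            raise ValidationError(
                f"cohort {c.cohort_id!r} has a different gene universe; "
                "multi-cohort generation requires a shared one")
    return {c.cohort_id: generate_cohort(c) for c in configs}


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a plain dict (YAML-friendly)."""
    d = dict(d)
    planted = tuple(
        PlantedGene(**{**p, "group_freqs": p.get("group_freqs")})
        for p in d.pop("planted", [])
    )
    group = d.pop("group", None)
    if group is not None:
        group = GroupSpec(
            covariate=group["covariate"],
            values=tuple(group["values"]),
            proportions=(tuple(group["proportions"])
                         if group.get("proportions") else None),
            survival_by_value={
                k: (float(v[0]), float(v[1]))
                for k, v in (group.get("survival_by_value") or {}).items()
            } or None,
        )
    background = {**DEFAULT_BACKGROUND, **d.pop("background", {})}
    missingness = {**DEFAULT_MISSINGNESS, **d.pop("missingness", {})}
    return GeneratorConfig(planted=planted, group=group, background=background,
                           missingness=missingness, **d)


def dual_gene_pair(gene: str, onc_freq: float = 0.3, sup_freq_del: float = 0.3,
                   sup_freq_ns: float = 0.1) -> tuple[PlantedGene, PlantedGene]:
    """Convenience: the two planted entries (oncogenic, suppressive) for
    one dual-behavior gene across two cohorts."""
    return (
        PlantedGene(gene=gene, role="dual", freq_amp=onc_freq,
                    freq_over=onc_freq),
        PlantedGene(gene=gene, role="dual", freq_del=sup_freq_del,
                    freq_ns=sup_freq_ns),
    )
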