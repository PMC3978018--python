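"""Cohort input/output: sample-level multi-omics matrices, mutation and
clinical tables, gene lists.

File conventions
----------------
Matrices are TSV with genes as rows and samples as columns; the first
column holds gene symbols, the header row holds sample identifiers.
Missing cells may be encoded as ``NA``, ``NaN`` or an empty field and are
written back as ``NA``. Missingness is preserved, never imputed: the
per-platform "informative" totals (T_cnv, T_exp, T_met) are defined per
gene as the number of non-missing cells for that gene on that platform.

The mutation table is MAF-like TSV with at least ``gene``, ``sample`` and
``variant_class`` columns plus an optional ``source`` column
(``cohort`` | ``external_catalog``, default ``cohort``). The clinical
table is TSV with ``sample``, ``os_time`` and arbitrary categorical
covariate columns. A YAML/JSON manifest names the files and the cohort.

Gene identifiers are opaque symbols; no alias resolution is attempted,
since aliasing would silently change alteration counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

MISSING_TOKENS = ("NA", "NaN", "nan", "")

MUTATION_SOURCES = ("cohort", "external_catalog")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call: gene, sample, variant classification and
    provenance (cohort sample vs external catalog such as COSMIC)."""

    gene: str
    sample: str
    variant_class: str
    source: str = "cohort"

    def __post_init__(self) -> None:
        if self.source not in MUTATION_SOURCES:
            raise ValidationError(
                f"mutation source must be one of {MUTATION_SOURCES}, "
                f"got {self.source!r} for {self.gene}/{self.sample}"
            )


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    ``data`` is indexed by sample with an ``os_time`` column (overall
    survival, units declared in ``time_unit``) and any number of
    categorical covariate columns (e.g. ER/PR status). Missing survival
    time is allowed; such samples are simply excluded from survival
    stratification.
    """

    data: pd.DataFrame
    time_unit: str = "days"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample in clinical table: {dup!r}")
        if "os_time" in self.data.columns:
            t = pd.to_numeric(self.data["os_time"], errors="coerce")
            if (t.dropna() < 0).any():
                bad = self.data.index[t < 0][0]
                raise ValidationError(f"negative survival time for sample {bad!r}")
            self.data["os_time"] = t

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c != "os_time"]


@dataclass
class CohortDataset:
    """A tumor cohort: gene x sample matrices per platform plus mutation
    and clinical tables.

    Matrices are pandas DataFrames indexed by gene with sample columns;
    each platform may cover a different subset of the cohort's genes and
    carry its own missingness pattern. ``genes`` and ``samples`` are the
    deterministic unions (input order, duplicates rejected) across
    platforms.
    """

    cohort_id: str
    cnv: pd.DataFrame
    expression_z: pd.DataFrame
    methylation_call: pd.DataFrame | None = None
    mutations: list[MutationRecord] = field(default_factory=list)
    clinical: ClinicalTable | None = None

    def __post_init__(self) -> None:
        for name, m in self._matrices():
            if m.index.duplicated().any():
                dup = m.index[m.index.duplicated()][0]
                raise ValidationError(f"duplicate gene {dup!r} in {name} matrix")
            if m.columns.duplicated().any():
                dup = m.columns[m.columns.duplicated()][0]
                raise ValidationError(f"duplicate sample {dup!r} in {name} matrix")
        samples = set(self.samples)
        for rec in self.mutations:
            if rec.source == "cohort" and rec.sample not in samples:
                raise ValidationError(
                    f"mutation record for gene {rec.gene!r} references sample "
                    f"{rec.sample!r} absent from the cohort matrices "
                    "(flag it source=external_catalog if intended)"
                )
        if self.clinical is not None:
            extra = [s for s in self.clinical.samples if s not in samples]
            if extra:
                warnings.warn(
                    f"{len(extra)} clinical samples absent from the omics "
                    f"matrices were dropped (first: {extra[0]!r})",
                    stacklevel=2,
                )
                self.clinical = ClinicalTable(
                    self.clinical.data.drop(index=extra),
                    time_unit=self.clinical.time_unit,
                )

    def _matrices(self):
        out = [("cnv", self.cnv), ("expression", self.expression_z)]
        if self.methylation_call is not None:
            out.append(("methylation", self.methylation_call))
        return out

    @property
    def genes(self) -> list[str]:
        """Gene universe: union over platforms then cohort mutations, input order."""
        seen: dict[str, None] = {}
        for _, m in self._matrices():
            for g in m.index:
                seen.setdefault(g, None)
        for rec in self.mutations:
            if rec.source == "cohort":
                seen.setdefault(rec.gene, None)
        return list(seen)

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, m in self._matrices():
            for s in m.columns:
                seen.setdefault(s, None)
        return list(seen)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def informative_counts(self, platform: str) -> pd.Series:
        """Per-gene count of non-missing cells on one platform
        (the gene-specific "informative samples" totals)."""
        m = dict(self._matrices()).get(platform)
        if m is None:
            raise KeyError(f"platform {platform!r} not present in cohort")
        return m.notna().sum(axis=1)

    def subset_samples(self, samples: list[str], cohort_id: str | None = None) -> "CohortDataset":
        """Restriction of the cohort to a sample subset.

        Matrices keep only the requested columns (in the given order),
        cohort-source mutations are filtered to those samples, external
        catalog records are kept, and the clinical table is restricted.
        """
        missing = [s for s in samples if s not in set(self.samples)]
        if missing:
            raise ValidationError(f"unknown sample(s) in subset: {missing[:3]}")

        def take(m: pd.DataFrame | None) -> pd.DataFrame | None:
            if m is None:
                return None
            cols = [s for s in samples if s in m.columns]
            return m[cols]

        keep = set(samples)
        muts = [
            r for r in self.mutations
            if r.source == "external_catalog" or r.sample in keep
        ]
        clin = None
        if self.clinical is not None:
            rows = [s for s in samples if s in self.clinical.data.index]
            clin = ClinicalTable(self.clinical.data.loc[rows],
                                 time_unit=self.clinical.time_unit)
        return CohortDataset(
            cohort_id=cohort_id or self.cohort_id,
            cnv=take(self.cnv),
            expression_z=take(self.expression_z),
            methylation_call=take(self.methylation_call),
            mutations=muts,
            clinical=clin,
        )


def _read_matrix(path: Path, name: str) -> pd.DataFrame:
    """Read a gene x sample TSV, validating identifiers and every cell.

    Cells must parse as a number or be one of the declared missing tokens;
    anything else is a hard error naming the gene and sample.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_cols = {c for c in header if header.count(c) > 1}
    if dup_cols:
        raise ValidationError(
            f"duplicate sample {sorted(dup_cols)[0]!r} in {name} file {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0,
                      keep_default_na=False)
    raw.columns = header  # undo pandas' silent dedup-mangling
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate gene {dup!r} in {name} file {path}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample {dup!r} in {name} file {path}")
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cleaned = raw[col].str.strip().replace(list(MISSING_TOKENS), np.nan)
        vals = pd.to_numeric(cleaned, errors="coerce")
        bad = vals.isna() & cleaned.notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise ValidationError(
                f"unparseable cell in {name} file {path}: gene {gene!r}, "
                f"sample {col!r}, value {raw.loc[gene, col]!r}"
            )
        out[col] = vals
    return out


def _read_mutations(path: Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "sample", "variant_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"mutation file {path} lacks required column(s): {sorted(missing)}"
        )
    if "source" not in df.columns:
        df["source"] = "cohort"
    df.loc[df["source"] == "", "source"] = "cohort"
    return [
        MutationRecord(gene=r.gene, sample=r.sample,
                       variant_class=r.variant_class, source=r.source)
        for r in df.itertuples(index=False)
    ]


def _read_clinical(path: Path, time_unit: str = "days") -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample" not in df.columns:
        raise ValidationError(f"clinical file {path} lacks a 'sample' column")
    df = df.replace(list(MISSING_TOKENS), np.nan)
    df = df.set_index("sample")
    return ClinicalTable(df, time_unit=time_unit)


def load_cohort(manifest: str | Path | dict, cohort_id: str | None = None) -> CohortDataset:
    """Load a cohort from a manifest (YAML/JSON path or dict).

    Manifest keys: ``cohort_id`` and a ``files`` map with ``cnv``,
    ``expression`` and optionally ``methylation``, ``mutations``,
    ``clinical`` paths (relative paths resolve against the manifest's
    directory). Loading is deterministic: the same files always produce
    an identical object.
    """
    base = Path(".")
    if not isinstance(manifest, dict):
        mpath = Path(manifest)
        base = mpath.parent
        with open(mpath) as fh:
            manifest = yaml.safe_load(fh)
    if "files" not in manifest:
        raise ValidationError("manifest lacks a 'files' section")
    files = {k: base / v for k, v in manifest["files"].items()}
    cid = cohort_id or manifest.get("cohort_id")
    if not cid:
        raise ValidationError("no cohort_id in manifest or arguments")
    for key in ("cnv", "expression"):
        if key not in files:
            raise ValidationError(f"manifest lacks required file entry {key!r}")
    for key, p in files.items():
        if not Path(p).exists():
            raise ValidationError(f"manifest file for {key!r} not found: {p}")
    return CohortDataset(
        cohort_id=cid,
        cnv=_read_matrix(files["cnv"], "cnv"),
        expression_z=_read_matrix(files["expression"], "expression"),
        methylation_call=(
            _read_matrix(files["methylation"], "methylation")
            if "methylation" in files else None
        ),
        mutations=_read_mutations(files["mutations"]) if "mutations" in files else [],
        clinical=(
            _read_clinical(files["clinical"],
                           time_unit=manifest.get("time_unit", "days"))
            if "clinical" in files else None
        ),
    )


def write_cohort(cohort: CohortDataset, out_dir: str | Path,
                 float_format: str = "%.6g") -> Path:
    """Write a cohort back to TSV files plus a manifest; returns the
    manifest path. Numeric content round-trips exactly at the declared
    float format; missing cells are written as ``NA``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def dump(m: pd.DataFrame, fname: str, label: str) -> None:
        m.to_csv(out / fname, sep="\t", na_rep="NA", float_format=float_format,
                 index_label="gene", lineterminator="\n")
        files[label] = fname

    dump(cohort.cnv, "cnv.tsv", "cnv")
    dump(cohort.expression_z, "expression.tsv", "expression")
    if cohort.methylation_call is not None:
        dump(cohort.methylation_call, "methylation.tsv", "methylation")
    if cohort.mutations:
        mut = pd.DataFrame(
            [(r.gene, r.sample, r.variant_class, r.source) for r in cohort.mutations],
            columns=["gene", "sample", "variant_class", "source"],
        )
        mut.to_csv(out / "mutations.tsv", sep="\t", index=False, lineterminator="\n")
        files["mutations"] = "mutations.tsv"
    if cohort.clinical is not None:
        cohort.clinical.data.to_csv(out / "clinical.tsv", sep="\t", na_rep="NA",
                                    float_format=float_format,
                                    index_label="sample", lineterminator="\n")
        files["clinical"] = "clinical.tsv"
    manifest = {"cohort_id": cohort.cohort_id, "files": files}
    if cohort.clinical is not None:
        manifest["time_unit"] = cohort.clinical.time_unit
    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return mpath


def load_gene_list(path: str | Path) -> list[str]:
    """Read a gene list, one symbol per line, ``#`` comments allowed.

    Returns a deduplicated, order-preserving list; duplicates trigger a
    warning, an empty list is an error.
    """
    seen: dict[str, None] = {}
    dups: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if not sym:
                continue
            if sym in seen:
                dups.append(sym)
            seen.setdefault(sym, None)
    if not seen:
        raise ValidationError(f"gene list {path} contains no symbols")
    if dups:
        warnings.warn(
            f"gene list {path} contains {len(dups)} duplicate symbol(s) "
            f"(first: {dups[0]!r}); duplicates were collapsed",
            stacklevel=2,
        )
    return list(seen)


def genes_missing_from(gene_list: list[str], cohort: CohortDataset) -> list[str]:
    """Which listed genes are absent from a cohort's gene universe."""
    universe = set(cohort.genes)
    return [g for g in gene_list if g not in universe]
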