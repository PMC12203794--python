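"""Shared data model and readers/writers for the pipeline's external formats.

All tabular formats are plain TSV. Methylation values are Infinium-style
beta fractions in [0, 1]; expression is on the log2(1+x) scale. Probe
manifests mirror the 450k annotation semantics: one row per probe, with
gene/region-class annotations as semicolon-joined parallel lists.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PROMOTER_CLASSES = frozenset({"TSS200", "TSS1500", "5UTR"})
REGION_CLASSES = frozenset({"TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR"})


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeRecord:
    """One methylation probe: genomic position plus gene/region annotations."""

    probe_id: str
    chrom: str
    pos: int  # 1-based bp coordinate of the interrogated CpG
    strand: str = "."
    annotations: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"probe {self.probe_id}: pos must be >= 1, got {self.pos}")
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"probe {self.probe_id}: bad strand {self.strand!r}")

    @property
    def promoter_genes(self) -> set[str]:
        return {g for g, cls in self.annotations if cls in PROMOTER_CLASSES}


class ProbeManifest:
    """Genome-ordered probe records, indexable by probe id."""

    def __init__(self, records: Iterable[ProbeRecord]):
        records = list(records)
        seen: set[str] = set()
        for r in records:
            if r.probe_id in seen:
                raise ValidationError(f"duplicate probe_id {r.probe_id!r} in manifest")
            seen.add(r.probe_id)
        # stable sort: ties at the same (chrom, pos) keep input order
        self.records: list[ProbeRecord] = sorted(records, key=lambda r: (r.chrom, r.pos))
        self._by_id: dict[str, ProbeRecord] = {r.probe_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_id

    def __getitem__(self, probe_id: str) -> ProbeRecord:
        return self._by_id[probe_id]

    def probe_ids(self) -> list[str]:
        return [r.probe_id for r in self.records]


class _Matrix:
    """Row-id x sample-id real matrix backed by a pandas DataFrame (NaN = missing)."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise ValidationError("duplicate row identifiers")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        self.df = df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self.df.equals(other.df)


class BetaMatrix(_Matrix):
    """Probe x sample methylation beta values in [0, 1]; missing allowed."""

    def __init__(self, df: pd.DataFrame):
        super().__init__(df)
        vals = self.df.to_numpy()
        bad = np.nonzero((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value out of [0,1] at probe {self.df.index[i]!r}, "
                f"sample {self.df.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.df.index)


class ExpressionMatrix(_Matrix):
    """Gene x sample expression on the log2(1+x) scale; complete and non-negative."""

    def __init__(self, df: pd.DataFrame):
        super().__init__(df)
        vals = self.df.to_numpy()
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(
                f"expression matrices must be complete; missing value at gene "
                f"{self.df.index[i]!r}, sample {self.df.columns[j]!r}"
            )
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative expression at gene {self.df.index[i]!r}, "
                f"sample {self.df.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.df.index)


@dataclass
class ClinicalTable:
    """Disease-free survival endpoint plus optional molecular subtype per sample."""

    df: pd.DataFrame  # index sample_id; columns dfs_time, dfs_event, subtype

    def __post_init__(self) -> None:
        required = {"dfs_time", "dfs_event"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns {sorted(missing)}")
        if "subtype" not in self.df.columns:
            self.df = self.df.assign(subtype=pd.NA)
        t = self.df["dfs_time"].to_numpy(float)
        e = self.df["dfs_event"].to_numpy(float)
        if (t <= 0).any():
            raise ValidationError("dfs_time must be > 0")
        if not np.isin(e, (0.0, 1.0)).all():
            raise ValidationError("dfs_event must be in {0, 1}")
        if self.df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def times_events(self, samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df.loc[list(samples)]
        return sub["dfs_time"].to_numpy(float), sub["dfs_event"].to_numpy(int)


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_symbol: str
    consequence: str  # normalised lower_snake_case SO-style term


@dataclass(frozen=True)
class CnaRecord:
    sample_id: str
    gene_symbol: str
    category: int  # -2 deep deletion ... +2 high amplification

    def __post_init__(self) -> None:
        if self.category not in {-2, -1, 0, 1, 2}:
            raise ValidationError(
                f"CNA category for {self.gene_symbol} in {self.sample_id} "
                f"must be in -2..2, got {self.category}"
            )


class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> ordered unique symbols."""

    def __init__(self, sets: Mapping[str, Sequence[str]], label: str = ""):
        self.label = label
        self.sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            ordered = list(dict.fromkeys(genes))
            if not ordered:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = ordered

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class CohortBundle:
    """One cohort's tables under a shared sample-id namespace."""

    cohort_id: str
    expression: ExpressionMatrix
    clinical: ClinicalTable
    methylation: BetaMatrix | None = None
    manifest: ProbeManifest | None = None
    mutations: list[MutationRecord] | None = None
    cnas: list[CnaRecord] | None = None

    def __post_init__(self) -> None:
        clin = set(self.clinical.sample_ids)
        expr = set(self.expression.sample_ids)
        if not expr <= clin:
            raise ValidationError(
                f"cohort {self.cohort_id}: expression samples not covered by "
                f"clinical table: {sorted(expr - clin)[:5]}"
            )


@dataclass
class PipelineConfig:
    """Every tunable threshold of the discovery cascade, with study defaults."""

    driver_gene: str = "DNMT3B"
    split_rule: str = "median"
    dmr_seed_p: float = 1e-5
    dmr_dist: int = 1000
    dmr_region_filter_p: float = 0.05
    dmr_region_filter_n: int = 2
    gene_dmr_p: float = 1e-5
    de_fc_threshold: float = 1.5
    de_adj_p: float = 0.05
    de_test: str = "welch_t"  # or "mann_whitney"
    survival_alpha: float = 0.05
    consensus_min_cohorts: int = 3
    gsea_nperm: int = 1000
    gsea_weight: float = 1.0
    gsea_nominal_p: float = 0.05
    gsea_fdr: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for key in ("dmr_seed_p", "dmr_region_filter_p", "gene_dmr_p",
                    "de_adj_p", "survival_alpha", "gsea_nominal_p", "gsea_fdr"):
            v = getattr(self, key)
            if not 0 < v <= 1:
                raise ValidationError(f"{key} must be in (0, 1], got {v}")
        if self.de_fc_threshold < 1:
            raise ValidationError("de_fc_threshold must be >= 1")
        if self.split_rule != "median":
            raise ValidationError(f"unknown split_rule {self.split_rule!r}")
        if self.de_test not in {"welch_t", "mann_whitney"}:
            raise ValidationError(f"unknown de_test {self.de_test!r}")
        for key in ("dmr_dist", "dmr_region_filter_n", "consensus_min_cohorts",
                    "gsea_nperm"):
            if getattr(self, key) < 1:
                raise ValidationError(f"{key} must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_MANIFEST_COLS = ["probe_id", "chrom", "pos", "strand", "gene", "region_class"]


def read_probe_manifest(path: str | Path) -> ProbeManifest:
    """Read a BED-like probe manifest TSV, returning records sorted by (chrom, pos).

    Multi-gene annotations are semicolon-joined parallel lists in the
    ``gene`` / ``region_class`` columns; empty fields mean intergenic.
    """
    path = Path(path)
    records: list[ProbeRecord] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MANIFEST_COLS:
            raise ParseError(f"{path}: expected header {_MANIFEST_COLS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_MANIFEST_COLS):
                raise ParseError(f"{path}:{lineno}: expected {len(_MANIFEST_COLS)} fields, "
                                 f"got {len(parts)}")
            probe_id, chrom, pos_s, strand, gene_s, cls_s = parts
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer pos {pos_s!r}") from exc
            if pos <= 0:
                raise ValidationError(f"{path}:{lineno}: pos must be positive, got {pos}")
            annotations: set[tuple[str, str]] = set()
            if gene_s:
                genes = gene_s.split(";")
                classes = cls_s.split(";")
                if len(genes) != len(classes):
                    raise ParseError(
                        f"{path}:{lineno}: gene/region_class lists have different lengths"
                    )
                annotations = set(zip(genes, classes))
            records.append(ProbeRecord(probe_id, chrom, pos, strand,
                                       frozenset(annotations)))
    return ProbeManifest(records)


def write_probe_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_MANIFEST_COLS) + "\n")
        for r in manifest:
            ann = sorted(r.annotations)
            genes = ";".join(g for g, _ in ann)
            classes = ";".join(c for _, c in ann)
            fh.write(f"{r.probe_id}\t{r.chrom}\t{r.pos}\t{r.strand}\t{genes}\t{classes}\n")


def read_matrix(path: str | Path, kind: str) -> BetaMatrix | ExpressionMatrix:
    """Read a TSV matrix (rows = probes/genes, columns = samples; "NA" missing)."""
    if kind not in {"beta", "expression"}:
        raise ValueError(f"kind must be 'beta' or 'expression', got {kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         keep_default_na=False, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from exc
    return BetaMatrix(df) if kind == "beta" else ExpressionMatrix(df)


def write_matrix(matrix: _Matrix, path: str | Path) -> None:
    """Write a matrix TSV; NaN rendered as "NA". Round-trips exactly via repr."""
    df = matrix.df
    with Path(path).open("w") as fh:
        fh.write("id\t" + "\t".join(df.columns) + "\n")
        vals = df.to_numpy()
        for rid, row in zip(df.index, vals):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(rid) + "\t" + "\t".join(cells) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read MSigDB-dialect GMT: name, description, then gene symbols."""
    sets: dict[str, list[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection:
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


def normalise_consequence(term: str) -> str:
    """Map free-text consequence spellings onto lower_snake_case SO style."""
    term = term.strip().lower()
    term = re.sub(r"[\s\-]+", "_", term)
    term = re.sub(r"_+", "_", term)
    # SO spells in-frame indels without the hyphen-underscore
    term = term.replace("in_frame_", "inframe_")
    return term


def read_mutations(path: str | Path) -> list[MutationRecord]:
    df = _read_three_col(path, ("sample", "gene", "consequence"))
    return [MutationRecord(s, g, normalise_consequence(c))
            for s, g, c in df.itertuples(index=False)]


def read_cnas(path: str | Path) -> list[CnaRecord]:
    df = _read_three_col(path, ("sample", "gene", "category"))
    out = []
    for s, g, c in df.itertuples(index=False):
        try:
            cat = int(c)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer CNA category {c!r}") from exc
        out.append(CnaRecord(s, g, cat))
    return out


def _read_three_col(path: str | Path, cols: tuple[str, str, str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(cols):
        raise ParseError(f"{path}: expected columns {list(cols)}, got {list(df.columns)}")
    if df.isin([""]).any().any():
        raise ParseError(f"{path}: empty field")
    return df


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.df.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_dmr_bed(dmrs, path: str | Path) -> None:
    """BED6+ DMR output: 0-based half-open coords, score = -log10 p_sidak."""
    with Path(path).open("w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\t"
                 "n_probes\tp_combined\tp_sidak\tdirection\tgenes\n")
        for i, d in enumerate(dmrs):
            score = -np.log10(max(d.p_sidak, 1e-300))
            genes = ";".join(sorted({g for g, _ in d.assigned_genes}))
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tDMR{i + 1}\t{score:.4f}\t.\t"
                     f"{d.n_probes}\t{d.p_combined:.6g}\t{d.p_sidak:.6g}\t"
                     f"{d.direction}\t{genes}\n")
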