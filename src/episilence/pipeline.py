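"""Orchestration of the full discovery cascade.

Order of stages: driver median split -> EWAS -> combined-p DMR calling and
promoter gene assignment -> differential expression -> intersection of
hypermethylated and downregulated genes -> multi-cohort survival consensus
-> genetic-alteration ranking -> METH/LOFDEL/CTRL stratification of the top
gene -> pre-ranked GSEA for both inactivation contrasts.

The cascade counts (hypermethylated, down/up, intersection, consensus) are
first-class report fields and one structured log line is emitted per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from . import alterations as alt
from . import diffexpr as de
from . import gsea as gs
from . import survival as sv
from .ewas import call_dmrs
from .ewas import ewas as run_ewas
from .io import (
    CohortBundle,
    GeneSetCollection,
    PipelineConfig,
    ValidationError,
    read_clinical,
    read_cnas,
    read_gmt,
    read_matrix,
    read_mutations,
    read_probe_manifest,
    write_dmr_bed,
)
from .simulate import SimulationConfig, simulate_gene_sets, simulate_multicohort

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryReport:
    """Machine-readable summary of one cascade run."""

    config: dict
    sim_config: dict | None
    n_probes_tested: int
    n_dmrs: int
    n_hypermethylated: int
    n_down: int
    n_up: int
    n_intersection: int
    n_consensus: int
    intersection_genes: list[str]
    consensus_genes: list[str]
    alteration_table: list[dict]
    top_gene: str | None
    meth_pct: float | None
    lofdel_pct: float | None
    combined_pct: float | None
    consensus_yield_pct: float | None
    stratum_contrasts: list[dict]
    subtype_composition: dict | None
    gsea_categories: list[dict]
    rng_seed: int

    def __post_init__(self) -> None:
        if self.n_intersection > min(self.n_hypermethylated, self.n_down):
            raise AssertionError("intersection exceeds its parent lists")
        if self.combined_pct is not None:
            assert abs(self.combined_pct - (self.meth_pct + self.lofdel_pct)) < 1e-9, \
                "combined % must equal METH % + LOFDEL % under disjoint strata"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def summary_text(self) -> str:
        lines = [
            "discovery cascade summary",
            f"  probes tested:          {self.n_probes_tested}",
            f"  DMRs called:            {self.n_dmrs}",
            f"  hypermethylated genes:  {self.n_hypermethylated}",
            f"  downregulated genes:    {self.n_down}",
            f"  upregulated genes:      {self.n_up}",
            f"  intersection:           {self.n_intersection}",
            f"  consensus-passing:      {self.n_consensus}"
            + (f" ({self.consensus_yield_pct:.1f}% of candidates)"
               if self.consensus_yield_pct is not None else ""),
        ]
        if self.top_gene:
            lines.append(f"  top altered gene:       {self.top_gene}")
            lines.append(f"  METH stratum:           {self.meth_pct:.1f}%")
            lines.append(f"  LOFDEL stratum:         {self.lofdel_pct:.1f}%")
            lines.append(f"  combined inactivation:  {self.combined_pct:.1f}%")
        return "\n".join(lines)


def validate_config(path: str | Path) -> tuple[PipelineConfig, SimulationConfig | None,
                                               str | None, str | None]:
    """Parse a YAML config into (pipeline, simulation, input_dir, gene_sets).

    Unknown keys anywhere are errors; an empty file yields all defaults with
    a default simulation block.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    known_top = {"pipeline", "simulation", "input_dir", "gene_sets"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    pipeline = PipelineConfig.from_mapping(raw.get("pipeline") or {})
    sim = None
    if "simulation" in raw or "input_dir" not in raw:
        sim_map = raw.get("simulation") or {}
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim_map) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        sim = SimulationConfig(**sim_map)
    return pipeline, sim, raw.get("input_dir"), raw.get("gene_sets")


def load_cohort(path: str | Path, cohort_id: str | None = None) -> CohortBundle:
    """Load one cohort directory (expression.tsv, clinical.tsv, and the
    optional methylation/manifest/mutations/cnas tables)."""
    path = Path(path)
    bundle = CohortBundle(
        cohort_id=cohort_id or path.name,
        expression=read_matrix(path / "expression.tsv", "expression"),
        clinical=read_clinical(path / "clinical.tsv"),
    )
    if (path / "methylation.tsv").exists():
        bundle.methylation = read_matrix(path / "methylation.tsv", "beta")
        bundle.manifest = read_probe_manifest(path / "manifest.tsv")
    if (path / "mutations.tsv").exists():
        bundle.mutations = read_mutations(path / "mutations.tsv")
    if (path / "cnas.tsv").exists():
        bundle.cnas = read_cnas(path / "cnas.tsv")
    return bundle


def load_cohorts(indir: str | Path) -> list[CohortBundle]:
    dirs = sorted(p for p in Path(indir).iterdir() if p.is_dir())
    if not dirs:
        raise ValidationError(f"no cohort directories under {indir}")
    return [load_cohort(p) for p in dirs]


def run_discovery(config: PipelineConfig,
                  cohorts: Sequence[CohortBundle] | None = None,
                  sim_config: SimulationConfig | None = None,
                  gene_sets: GeneSetCollection | None = None,
                  outdir: str | Path | None = None,
                  force: bool = False) -> DiscoveryReport:
    """Run the full cascade; if ``cohorts`` is None they are simulated from
    ``sim_config``. Intermediates and the report are written under
    ``outdir`` when given (refusing to overwrite an existing report unless
    ``force``)."""
    if outdir is not None:
        outdir = Path(outdir)
        if (outdir / "report.json").exists() and not force:
            raise ValidationError(f"{outdir}/report.json exists; use force to overwrite")
        outdir.mkdir(parents=True, exist_ok=True)

    if cohorts is None:
        if sim_config is None:
            sim_config = SimulationConfig(rng_seed=config.rng_seed)
        cohorts = [b for b, _ in simulate_multicohort(sim_config)]
        if gene_sets is None:
            gene_sets = simulate_gene_sets(sim_config)
    cohort0 = next((c for c in cohorts if c.methylation is not None), None)
    if cohort0 is None:
        raise ValidationError("no cohort carries methylation data")

    # stage 1: driver split
    groups = de.split_by_driver(cohort0.expression, config.driver_gene)
    logger.info("stage=driver_split cohort=%s n_high=%d n_low=%d",
                cohort0.cohort_id, sum(g == "high" for g in groups.values()),
                sum(g == "low" for g in groups.values()))

    # stage 2: EWAS + DMRs + gene assignment
    ewas_res = run_ewas(cohort0.methylation, groups, cohort0.manifest)
    dmrs, gene_calls = call_dmrs(ewas_res, cohort0.manifest, config)
    logger.info("stage=ewas_dmr n_probes=%d n_dmrs=%d n_hyper_genes=%d",
                len(ewas_res), len(dmrs), len(gene_calls))

    # stage 3: differential expression + intersection
    de_res = de.differential_expression(cohort0.expression, groups, config)
    n_down = int((de_res["call"] == "down").sum())
    n_up = int((de_res["call"] == "up").sum())
    intersection = de.intersect_silenced(gene_calls, de_res)
    logger.info("stage=diffexpr n_down=%d n_up=%d n_intersection=%d",
                n_down, n_up, len(intersection))

    # stage 4: multi-cohort survival consensus
    consensus_genes: list[str] = []
    surv_results: list[sv.GeneSurvivalResult] = []
    if intersection:
        surv_results, calls = sv.gene_survival_screen(cohorts, intersection, config)
        consensus_genes = sorted(c.gene for c in calls if c.passes)
    logger.info("stage=survival n_candidates=%d n_consensus=%d",
                len(intersection), len(consensus_genes))
    yield_pct = (100.0 * len(consensus_genes) / len(intersection)
                 if intersection else None)

    # stage 5: alteration ranking over the candidate genes
    alteration_table: list[dict] = []
    top_gene = None
    if intersection and cohort0.mutations is not None and cohort0.cnas is not None:
        freqs = alt.alteration_frequencies(cohort0.mutations, cohort0.cnas,
                                           cohort0.expression.sample_ids,
                                           intersection)
        alteration_table = [dataclasses.asdict(f) for f in freqs]
        if freqs and freqs[0].f_total > 0:
            top_gene = freqs[0].gene
    logger.info("stage=alterations top_gene=%s", top_gene)

    # stage 6: stratification + summaries + GSEA for the top gene
    meth_pct = lofdel_pct = combined_pct = None
    stratum_contrasts: list[dict] = []
    subtype_composition = None
    gsea_categories: list[dict] = []
    if top_gene is not None:
        assignment = alt.stratify_target(cohort0, groups, top_gene, config)
        n_all = len(assignment.strata)
        meth = assignment.samples("METH")
        lofdel = assignment.samples("LOFDEL")
        ctrl = assignment.samples("CTRL")
        meth_pct = 100.0 * len(meth) / n_all
        lofdel_pct = 100.0 * len(lofdel) / n_all
        combined_pct = meth_pct + lofdel_pct
        summaries = alt.stratum_summaries(assignment, cohort0.clinical)
        stratum_contrasts = [dataclasses.asdict(c) for c in summaries.contrasts]
        subtype_composition = {
            s: {k: float(v) for k, v in row.items()}
            for s, row in summaries.subtype_composition.iterrows()}
        logger.info("stage=stratify meth=%d lofdel=%d ctrl=%d",
                    len(meth), len(lofdel), len(ctrl))
        if gene_sets is not None and len(meth) >= 2 and len(lofdel) >= 2 \
                and len(ctrl) >= 2:
            ranked_meth = gs.rank_genes(cohort0.expression, meth, ctrl)
            ranked_lofdel = gs.rank_genes(cohort0.expression, lofdel, ctrl)
            res_m = gs.permutation_significance(
                ranked_meth, gene_sets, nperm=config.gsea_nperm,
                seed=config.rng_seed, weight=config.gsea_weight,
                nominal_p=config.gsea_nominal_p, fdr=config.gsea_fdr)
            res_l = gs.permutation_significance(
                ranked_lofdel, gene_sets, nperm=config.gsea_nperm,
                seed=config.rng_seed + 1, weight=config.gsea_weight,
                nominal_p=config.gsea_nominal_p, fdr=config.gsea_fdr)
            dual = gs.dual_contrast_report(res_m, res_l)
            gsea_categories = dual.to_dict(orient="records")
            logger.info("stage=gsea n_sets=%d n_significant_meth=%d",
                        len(res_m), sum(r.significant for r in res_m))
            if outdir is not None:
                gs.results_frame(res_m).to_csv(outdir / "gsea_meth.tsv",
                                               sep="\t", index=False)
                gs.results_frame(res_l).to_csv(outdir / "gsea_lofdel.tsv",
                                               sep="\t", index=False)
                dual.to_csv(outdir / "gsea_dual.tsv", sep="\t", index=False)

    report = DiscoveryReport(
        config=dataclasses.asdict(config),
        sim_config=dataclasses.asdict(sim_config) if sim_config else None,
        n_probes_tested=len(ewas_res),
        n_dmrs=len(dmrs),
        n_hypermethylated=len(gene_calls),
        n_down=n_down,
        n_up=n_up,
        n_intersection=len(intersection),
        n_consensus=len(consensus_genes),
        intersection_genes=intersection,
        consensus_genes=consensus_genes,
        alteration_table=alteration_table,
        top_gene=top_gene,
        meth_pct=meth_pct,
        lofdel_pct=lofdel_pct,
        combined_pct=combined_pct,
        consensus_yield_pct=yield_pct,
        stratum_contrasts=stratum_contrasts,
        subtype_composition=subtype_composition,
        gsea_categories=gsea_categories,
        rng_seed=config.rng_seed,
    )

    if outdir is not None:
        ewas_res.to_csv(outdir / "ewas.tsv", sep="\t", index=False)
        write_dmr_bed(dmrs, outdir / "dmrs.bed")
        de_res.to_csv(outdir / "diffexpr.tsv", sep="\t", index=False)
        if surv_results:
            sv.survival_results_frame(surv_results).to_csv(
                outdir / "survival.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(report.to_json() + "\n")
        (outdir / "report.txt").write_text(report.summary_text() + "\n")
    return report


def run_discovery_from_config(config_path: str | Path,
                              outdir: str | Path | None = None,
                              force: bool = False) -> DiscoveryReport:
    pipeline, sim, input_dir, gmt_path = validate_config(config_path)
    cohorts = load_cohorts(input_dir) if input_dir else None
    gene_sets = read_gmt(gmt_path) if gmt_path else None
    return run_discovery(pipeline, cohorts=cohorts, sim_config=sim,
                         gene_sets=gene_sets, outdir=outdir, force=force)
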