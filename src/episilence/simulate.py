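"""Multi-cohort synthetic data with planted ground truth.

The generator emulates the statistical structure the discovery cascade is
designed to detect: a bimodally expressed driver gene; contiguous promoter
probe windows whose methylation rises in driver-high samples for a set of
planted target genes; correlated downregulation of those targets; relapse
hazard tied to the functional activity of the targets; and loss-of-function
(LOF) mutations / deep deletions of a designated target planted mutually
exclusively with the methylation-silenced samples.

Hazard is driven by *functional* target expression: the measured mean
log2 expression over planted targets, minus ``expr_log2fc`` for samples
carrying a LOF/deep deletion of the designated target. Mutated transcripts
remain expressed at normal mRNA levels, but the protein is inactive, so a
genetic hit confers the same relapse risk as the full epigenetic silencing
programme.

Determinism: one RNG stream per (cohort, table) derived by counter-based
seeding, so adding or regenerating one table never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .io import (
    BetaMatrix,
    ClinicalTable,
    CnaRecord,
    CohortBundle,
    ExpressionMatrix,
    GeneSetCollection,
    MutationRecord,
    ProbeManifest,
    ProbeRecord,
    ValidationError,
    write_clinical,
    write_gmt,
    write_matrix,
    write_probe_manifest,
)

LOF_CONSEQUENCES_PLANTED = (
    "stop_gained",
    "frameshift_variant",
    "start_lost",
    "inframe_deletion",
)

_PROMOTER_CLASS_CYCLE = ("TSS1500", "TSS200", "5UTR")
_SUBTYPES = ("luminal-A", "luminal-B", "HER2-enriched", "basal-like")
# subtype mix differs between driver-high and driver-low tumours
_SUBTYPE_P_HIGH = (0.15, 0.05, 0.25, 0.55)
_SUBTYPE_P_LOW = (0.50, 0.30, 0.10, 0.10)

# table ids for counter-based per-(cohort, table) RNG streams
_T_BETA, _T_EXPR, _T_CLIN, _T_MUT, _T_SUBTYPE = 1, 2, 3, 4, 5
_T_UNIVERSE = 10_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults are the planted-effect conditions the pipeline is evaluated
    under: a balanced bimodal driver, beta shift 0.3 over 8-probe promoter
    windows, one log2 unit of target downregulation with tight within-group
    spread (strongly bimodal silencing, GATA3-like), protective hazard
    coefficient -0.7 per SD of functional target expression, 30% censoring,
    and 8 cohorts of 300 samples of which only cohort 0 carries methylome
    and genomic tables.
    """

    n_samples: int = 300
    frac_driver_high: float = 0.5
    n_genes: int = 300
    n_target_genes: int = 10
    probes_per_promoter: int = 8
    probe_spacing_bp: int = 100
    delta_beta: float = 0.3
    beta_noise_kappa: float = 50.0
    expr_log2fc: float = 1.0
    expr_noise_sd: float = 0.25
    hazard_coef: float = -0.7
    baseline_hazard: float = 0.05
    censor_rate: float = 0.3
    frac_lofdel: float = 0.1
    n_cohorts: int = 8
    rng_seed: int = 0

    # base promoter methylation range; delta_beta must fit above it
    base_beta_low: float = 0.15
    base_beta_high: float = 0.35
    probe_jitter: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.frac_driver_high < 1:
            raise ValidationError("frac_driver_high must be in (0, 1)")
        if self.n_target_genes > self.n_genes - 1:
            raise ValidationError("n_target_genes must leave room for the driver")
        if self.delta_beta < 0:
            raise ValidationError("delta_beta must be >= 0")
        top = self.base_beta_high + self.probe_jitter + self.delta_beta
        if top >= 1:
            raise ValidationError(
                f"delta_beta={self.delta_beta} pushes planted beta means to "
                f"{top:.3f} >= 1; reduce delta_beta or the base range"
            )
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must be in [0, 1)")
        if not 0 <= self.frac_lofdel < 1:
            raise ValidationError("frac_lofdel must be in [0, 1)")
        if self.n_cohorts < 1:
            raise ValidationError("n_cohorts must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth for one cohort."""

    driver_high_samples: set[str]
    target_genes: list[str]
    designated_target: str
    meth_silenced_samples: set[str]
    lofdel_samples: set[str]
    effect_sizes: dict[str, float]  # gene -> planted log2 fold change (down > 0)

    def __post_init__(self) -> None:
        overlap = self.meth_silenced_samples & self.lofdel_samples
        if overlap:
            raise AssertionError(f"planted METH/LOFDEL overlap: {sorted(overlap)[:5]}")

    def to_json(self) -> dict:
        return {
            "driver_high_samples": sorted(self.driver_high_samples),
            "target_genes": list(self.target_genes),
            "designated_target": self.designated_target,
            "meth_silenced_samples": sorted(self.meth_silenced_samples),
            "lofdel_samples": sorted(self.lofdel_samples),
            "effect_sizes": self.effect_sizes,
        }


@dataclass(frozen=True)
class _GeneUniverse:
    driver: str
    targets: tuple[str, ...]
    background: tuple[str, ...]
    target_base_expr: np.ndarray
    background_base_expr: np.ndarray
    target_base_beta: np.ndarray
    background_base_beta: np.ndarray

    @property
    def genes(self) -> list[str]:
        return [self.driver, *self.targets, *self.background]


def _gene_universe(cfg: SimulationConfig) -> _GeneUniverse:
    """Gene names and per-gene baselines, shared across all cohorts."""
    rng = np.random.default_rng([cfg.rng_seed % (2**31), _T_UNIVERSE])
    n_bg = cfg.n_genes - 1 - cfg.n_target_genes
    targets = tuple(f"TSG{i + 1:03d}" for i in range(cfg.n_target_genes))
    background = tuple(f"BG{i + 1:04d}" for i in range(n_bg))
    return _GeneUniverse(
        driver="DNMT3B",
        targets=targets,
        background=background,
        target_base_expr=rng.uniform(5.0, 8.0, cfg.n_target_genes),
        background_base_expr=rng.uniform(1.0, 8.0, n_bg),
        target_base_beta=rng.uniform(cfg.base_beta_low, cfg.base_beta_high,
                                     cfg.n_target_genes),
        background_base_beta=rng.uniform(cfg.base_beta_low, cfg.base_beta_high, n_bg),
    )


def build_manifest(cfg: SimulationConfig) -> ProbeManifest:
    """Deterministic probe manifest: every non-driver gene gets a promoter
    window of ``probes_per_promoter`` probes spaced ``probe_spacing_bp``
    apart (classes cycling TSS1500/TSS200/5UTR) plus two Body probes 5 kb
    downstream. Genes are laid out 100 kb apart over five chromosomes."""
    uni = _gene_universe(cfg)
    records: list[ProbeRecord] = []
    genes = [*uni.targets, *uni.background]
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi % 5 + 1}"
        tss = 1_000_000 + (gi // 5) * 100_000
        for k in range(cfg.probes_per_promoter):
            cls = _PROMOTER_CLASS_CYCLE[k % len(_PROMOTER_CLASS_CYCLE)]
            records.append(ProbeRecord(
                probe_id=f"cg_{gene}_p{k:02d}", chrom=chrom,
                pos=tss + k * cfg.probe_spacing_bp, strand="+",
                annotations=frozenset({(gene, cls)}),
            ))
        for k in range(2):
            records.append(ProbeRecord(
                probe_id=f"cg_{gene}_b{k:02d}", chrom=chrom,
                pos=tss + 5_000 + k * cfg.probe_spacing_bp, strand="+",
                annotations=frozenset({(gene, "Body")}),
            ))
    return ProbeManifest(records)


def _cohort_rng(cfg: SimulationConfig, cohort_index: int, table: int) -> np.random.Generator:
    return np.random.default_rng([cfg.rng_seed % (2**31), cohort_index, table])


def _beta_draw(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Support-respecting beta noise: Beta(mu*kappa, (1-mu)*kappa)."""
    mu = np.clip(mu, 1e-3, 1 - 1e-3)
    return rng.beta(mu * kappa, (1 - mu) * kappa)


def _censor_rate_root(lam: np.ndarray, target: float) -> float:
    """Exponential censoring rate mu with E[mu/(lam+mu)] = target."""
    def f(log_mu: float) -> float:
        mu = np.exp(log_mu)
        return float(np.mean(mu / (lam + mu))) - target
    return float(np.exp(optimize.brentq(f, -40.0, 40.0, xtol=1e-12)))


def simulate_cohort(cfg: SimulationConfig, cohort_index: int,
                    with_omics: bool | None = None) -> tuple[CohortBundle, GroundTruth]:
    """Simulate one cohort; deterministic given (rng_seed, cohort_index).

    ``with_omics`` controls whether methylation/mutation/CNA tables are
    generated (default: only for cohort 0, mirroring a design where a single
    cohort carries the methylome and genomic characterisation).
    """
    if with_omics is None:
        with_omics = cohort_index == 0
    uni = _gene_universe(cfg)
    samples = [f"C{cohort_index}S{i + 1:04d}" for i in range(cfg.n_samples)]

    # --- driver split -----------------------------------------------------
    rng_expr = _cohort_rng(cfg, cohort_index, _T_EXPR)
    n_high = int(round(cfg.frac_driver_high * cfg.n_samples))
    n_high = min(max(n_high, 1), cfg.n_samples - 1)
    high_idx = rng_expr.choice(cfg.n_samples, size=n_high, replace=False)
    is_high = np.zeros(cfg.n_samples, dtype=bool)
    is_high[high_idx] = True
    driver_high = {samples[i] for i in np.nonzero(is_high)[0]}

    # --- expression -------------------------------------------------------
    driver_expr = np.where(is_high,
                           rng_expr.normal(6.0, 0.5, cfg.n_samples),
                           rng_expr.normal(2.0, 0.5, cfg.n_samples))
    target_expr = (uni.target_base_expr[:, None]
                   - cfg.expr_log2fc * is_high[None, :]
                   + rng_expr.normal(0.0, cfg.expr_noise_sd,
                                     (cfg.n_target_genes, cfg.n_samples)))
    bg_expr = (uni.background_base_expr[:, None]
               + rng_expr.normal(0.0, cfg.expr_noise_sd,
                                 (len(uni.background), cfg.n_samples)))
    expr = np.vstack([driver_expr[None, :], target_expr, bg_expr])
    expr = np.maximum(expr, 0.0)
    expression = ExpressionMatrix(pd.DataFrame(expr, index=uni.genes, columns=samples))

    # --- mutually exclusive LOF / deep deletion ---------------------------
    rng_mut = _cohort_rng(cfg, cohort_index, _T_MUT)
    designated = uni.targets[0] if uni.targets else ""
    low_order = [s for s in samples if s not in driver_high]
    n_lofdel = int(round(cfg.frac_lofdel * len(low_order)))
    lofdel_samples: set[str] = set()
    mutations: list[MutationRecord] = []
    cnas: list[CnaRecord] = []
    if with_omics and designated and n_lofdel:
        picked = rng_mut.choice(len(low_order), size=n_lofdel, replace=False)
        lofdel_list = [low_order[i] for i in picked]
        lofdel_samples = set(lofdel_list)
        for s in lofdel_list:
            if rng_mut.random() < 0.8:
                cons = LOF_CONSEQUENCES_PLANTED[
                    rng_mut.integers(len(LOF_CONSEQUENCES_PLANTED))]
                mutations.append(MutationRecord(s, designated, cons))
            else:
                cnas.append(CnaRecord(s, designated, -2))
    if with_omics:
        # benign noise records: passenger missense and shallow CNAs
        n_noise = max(1, cfg.n_samples // 20)
        for i in rng_mut.choice(cfg.n_samples, size=n_noise, replace=False):
            gene = uni.genes[int(rng_mut.integers(1, len(uni.genes)))]
            mutations.append(MutationRecord(samples[int(i)], gene, "missense_variant"))
        for i in rng_mut.choice(cfg.n_samples, size=n_noise, replace=False):
            gene = uni.genes[int(rng_mut.integers(1, len(uni.genes)))]
            cnas.append(CnaRecord(samples[int(i)], gene,
                                  int(rng_mut.choice([-1, 1]))))

    # --- methylation ------------------------------------------------------
    methylation = manifest = None
    if with_omics:
        manifest = build_manifest(cfg)
        rng_beta = _cohort_rng(cfg, cohort_index, _T_BETA)
        probe_ids = manifest.probe_ids()
        base_beta = {g: b for g, b in zip(uni.targets, uni.target_base_beta)}
        base_beta.update({g: b for g, b in
                          zip(uni.background, uni.background_base_beta)})
        target_set = set(uni.targets)
        base = np.empty(len(probe_ids))
        planted = np.zeros(len(probe_ids), dtype=bool)
        for pi, rec in enumerate(manifest):
            (gene, cls), = rec.annotations
            base[pi] = base_beta[gene]
            planted[pi] = gene in target_set and cls in _PROMOTER_CLASS_CYCLE
        jitter = rng_beta.uniform(-cfg.probe_jitter, cfg.probe_jitter, len(probe_ids))
        mus = ((base + jitter)[:, None]
               + cfg.delta_beta * np.outer(planted, is_high))
        beta_vals = _beta_draw(rng_beta, mus, cfg.beta_noise_kappa)
        methylation = BetaMatrix(pd.DataFrame(beta_vals, index=probe_ids,
                                              columns=samples))

    # --- survival ---------------------------------------------------------
    rng_clin = _cohort_rng(cfg, cohort_index, _T_CLIN)
    if cfg.n_target_genes:
        functional = target_expr.mean(axis=0).copy()
        lofdel_mask = np.fromiter((s in lofdel_samples for s in samples),
                                  bool, cfg.n_samples)
        functional -= cfg.expr_log2fc * lofdel_mask
        sd = functional.std()
        z = (functional - functional.mean()) / sd if sd > 0 else np.zeros_like(functional)
    else:
        z = np.zeros(cfg.n_samples)
    lam = cfg.baseline_hazard * np.exp(cfg.hazard_coef * z)
    event_t = rng_clin.exponential(1.0 / lam)
    if cfg.censor_rate > 0:
        mu = _censor_rate_root(lam, cfg.censor_rate)
        censor_t = rng_clin.exponential(1.0 / mu, cfg.n_samples)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
    else:
        time, event = event_t, np.ones(cfg.n_samples, dtype=int)
    time = np.maximum(time, 1e-9)

    rng_sub = _cohort_rng(cfg, cohort_index, _T_SUBTYPE)
    subtype = np.where(
        is_high,
        rng_sub.choice(_SUBTYPES, cfg.n_samples, p=_SUBTYPE_P_HIGH),
        rng_sub.choice(_SUBTYPES, cfg.n_samples, p=_SUBTYPE_P_LOW),
    )
    clinical = ClinicalTable(pd.DataFrame(
        {"dfs_time": time, "dfs_event": event, "subtype": subtype},
        index=pd.Index(samples, name="sample_id")))

    bundle = CohortBundle(
        cohort_id=f"cohort{cohort_index}",
        expression=expression,
        clinical=clinical,
        methylation=methylation,
        manifest=manifest,
        mutations=mutations if with_omics else None,
        cnas=cnas if with_omics else None,
    )
    planted = cfg.expr_log2fc if cfg.expr_log2fc else 0.0
    truth = GroundTruth(
        driver_high_samples=driver_high,
        target_genes=list(uni.targets),
        designated_target=designated,
        meth_silenced_samples=set(driver_high) if (with_omics and cfg.delta_beta > 0)
        else set(),
        lofdel_samples=lofdel_samples,
        effect_sizes={g: planted for g in uni.targets},
    )
    return bundle, truth


def simulate_multicohort(cfg: SimulationConfig) -> list[tuple[CohortBundle, GroundTruth]]:
    """All cohorts share the gene universe; only cohort 0 carries the
    methylome and the mutation/CNA tables."""
    return [simulate_cohort(cfg, i) for i in range(cfg.n_cohorts)]


def simulate_gene_sets(cfg: SimulationConfig, n_random_sets: int = 20,
                       set_size: int = 15) -> GeneSetCollection:
    """GMT companion: the planted-target set plus size-matched random sets."""
    uni = _gene_universe(cfg)
    rng = np.random.default_rng([cfg.rng_seed % (2**31), _T_UNIVERSE + 1])
    sets: dict[str, list[str]] = {}
    if uni.targets:
        sets["PLANTED_TARGETS"] = list(uni.targets)
    bg = list(uni.background)
    size = min(set_size, len(bg))
    for i in range(n_random_sets):
        picked = rng.choice(len(bg), size=size, replace=False)
        sets[f"RANDOM_SET_{i + 1:02d}"] = [bg[j] for j in sorted(picked)]
    return GeneSetCollection(sets, label="SYNTH")


def write_bundle(bundle: CohortBundle, truth: GroundTruth, outdir: str | Path) -> None:
    """Persist one cohort as the pipeline's TSV inputs + ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.expression, outdir / "expression.tsv")
    write_clinical(bundle.clinical, outdir / "clinical.tsv")
    if bundle.methylation is not None:
        write_matrix(bundle.methylation, outdir / "methylation.tsv")
    if bundle.manifest is not None:
        write_probe_manifest(bundle.manifest, outdir / "manifest.tsv")
    if bundle.mutations is not None:
        with (outdir / "mutations.tsv").open("w") as fh:
            fh.write("sample\tgene\tconsequence\n")
            for m in bundle.mutations:
                fh.write(f"{m.sample_id}\t{m.gene_symbol}\t{m.consequence}\n")
    if bundle.cnas is not None:
        with (outdir / "cnas.tsv").open("w") as fh:
            fh.write("sample\tgene\tcategory\n")
            for c in bundle.cnas:
                fh.write(f"{c.sample_id}\t{c.gene_symbol}\t{c.category}\n")
    with (outdir / "ground_truth.json").open("w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)


def write_simulation(cfg: SimulationConfig, outdir: str | Path) -> None:
    """Write every cohort plus the shared GMT under ``outdir``."""
    outdir = Path(outdir)
    for i, (bundle, truth) in enumerate(simulate_multicohort(cfg)):
        write_bundle(bundle, truth, outdir / bundle.cohort_id)
    write_gmt(simulate_gene_sets(cfg), outdir / "gene_sets.gmt")
    with (outdir / "sim_config.json").open("w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1, sort_keys=True)
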