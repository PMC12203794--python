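"""Loss-of-function classification, genetic-alteration frequencies, and the
mutually exclusive METH / LOFDEL / CTRL strata.

LOF consequences are the closed vocabulary of truncating / protein-altering
terms (stop gained, start lost, frameshift, in-frame indels, protein
altering); missense is deliberately excluded because its functional impact
is not resolvable without further annotation. "Deleterious CNA" means deep
deletion (category -2) only.

Strata for a target gene:
  LOFDEL - samples with a LOF mutation or deep deletion of the target;
  METH   - driver-high samples whose target promoter mean beta exceeds the
           90th percentile of the driver-low population and whose target
           expression is below the cohort median, excluding LOFDEL samples
           (genetic evidence takes precedence, keeping strata disjoint);
  CTRL   - driver-low samples with no genetic target alteration;
  the remainder is unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import promoter_mean_beta
from .io import CnaRecord, CohortBundle, MutationRecord, PipelineConfig, ValidationError
from .survival import cox_fit, logrank_test

logger = logging.getLogger(__name__)

LOF_VOCABULARY = frozenset({
    "stop_gained",
    "start_lost",
    "frameshift_variant",
    "inframe_deletion",
    "inframe_insertion",
    "protein_altering_variant",
})

_KNOWN_NON_LOF = frozenset({
    "missense_variant", "synonymous_variant", "intron_variant",
    "splice_region_variant", "stop_lost", "5_prime_utr_variant",
    "3_prime_utr_variant", "upstream_gene_variant", "downstream_gene_variant",
})

DEEP_DELETION = -2


def classify_lof(consequence: str) -> bool:
    """True iff the normalised consequence term is in the LOF vocabulary.

    Unknown terms classify as False with a logged warning, never an error.
    """
    if consequence in LOF_VOCABULARY:
        return True
    if consequence not in _KNOWN_NON_LOF:
        logger.warning("unknown consequence term %r treated as non-LOF", consequence)
    return False


@dataclass(frozen=True)
class AlterationFrequency:
    gene: str
    f_lof: float
    f_del: float
    f_total: float  # union of LOF and deep-deletion carriers


def alteration_frequencies(mutations: Sequence[MutationRecord],
                           cnas: Sequence[CnaRecord],
                           sample_universe: Sequence[str],
                           genes: Sequence[str],
                           rank_by: str = "f_total") -> list[AlterationFrequency]:
    """Per-gene alteration fractions over the full sample universe, ranked
    descending by ``rank_by`` with ties broken by gene symbol. f_total uses
    union semantics: a sample with both a LOF and a deep deletion counts
    once."""
    universe = set(sample_universe)
    if not universe:
        raise ValidationError("sample universe is empty")
    wanted = set(genes)
    lof_carriers: dict[str, set[str]] = {g: set() for g in genes}
    del_carriers: dict[str, set[str]] = {g: set() for g in genes}
    for m in mutations:
        if m.gene_symbol in wanted and m.sample_id in universe \
                and classify_lof(m.consequence):
            lof_carriers[m.gene_symbol].add(m.sample_id)
    for c in cnas:
        if c.gene_symbol in wanted and c.sample_id in universe \
                and c.category == DEEP_DELETION:
            del_carriers[c.gene_symbol].add(c.sample_id)
    n = len(universe)
    out = [AlterationFrequency(
        gene=g,
        f_lof=len(lof_carriers[g]) / n,
        f_del=len(del_carriers[g]) / n,
        f_total=len(lof_carriers[g] | del_carriers[g]) / n,
    ) for g in genes]
    out.sort(key=lambda a: (-getattr(a, rank_by), a.gene))
    return out


@dataclass
class StratumAssignment:
    target_gene: str
    driver_gene: str
    strata: dict[str, str]  # sample -> METH | LOFDEL | CTRL | unassigned

    def samples(self, stratum: str) -> list[str]:
        return [s for s, g in self.strata.items() if g == stratum]

    def __post_init__(self) -> None:
        meth = set(self.samples("METH"))
        lofdel = set(self.samples("LOFDEL"))
        ctrl = set(self.samples("CTRL"))
        if meth & lofdel or ctrl & (meth | lofdel):
            raise AssertionError("strata are not mutually exclusive")


def stratify_target(bundle: CohortBundle, driver_groups: Mapping[str, str],
                    target: str, config: PipelineConfig | None = None,
                    meth_beta_quantile: float = 0.9) -> StratumAssignment:
    """Assign every expression sample to METH / LOFDEL / CTRL / unassigned."""
    config = config or PipelineConfig()
    if bundle.methylation is None or bundle.manifest is None:
        raise ValidationError("stratification requires a methylome")
    if bundle.mutations is None or bundle.cnas is None:
        raise ValidationError("stratification requires mutation and CNA tables")
    samples = bundle.expression.sample_ids

    altered: set[str] = set()
    for m in bundle.mutations:
        if m.gene_symbol == target and classify_lof(m.consequence):
            altered.add(m.sample_id)
    for c in bundle.cnas:
        if c.gene_symbol == target and c.category == DEEP_DELETION:
            altered.add(c.sample_id)

    prom_beta = promoter_mean_beta(bundle.methylation, bundle.manifest, target)
    if target not in bundle.expression.df.index:
        raise ValidationError(f"target {target!r} absent from expression")
    expr = bundle.expression.df.loc[target]
    expr_median = float(expr.median())
    low_samples = [s for s in samples if driver_groups.get(s) == "low"]
    if not low_samples:
        raise ValidationError("no driver-low samples: METH threshold undefined")
    beta_thresh = float(np.quantile(prom_beta.loc[low_samples].dropna().to_numpy(),
                                    meth_beta_quantile))

    strata: dict[str, str] = {}
    for s in samples:
        if s in altered:
            strata[s] = "LOFDEL"
        elif (driver_groups.get(s) == "high"
              and not np.isnan(prom_beta.get(s, np.nan))
              and prom_beta[s] > beta_thresh
              and expr[s] < expr_median):
            strata[s] = "METH"
        elif driver_groups.get(s) == "low":
            strata[s] = "CTRL"
        else:
            strata[s] = "unassigned"
    if "CTRL" not in strata.values():
        raise ValidationError("empty CTRL stratum: contrasts undefined")
    return StratumAssignment(target_gene=target, driver_gene=config.driver_gene,
                             strata=strata)


@dataclass
class StratumContrast:
    stratum: str
    n: int
    logrank_chi2: float
    logrank_p: float
    hr_vs_ctrl: float
    cox_p: float
    small_sample: bool = False


@dataclass
class StratumSummaries:
    contrasts: list[StratumContrast]
    subtype_composition: pd.DataFrame  # strata x subtypes, percentages

    def contrast(self, stratum: str) -> StratumContrast:
        return next(c for c in self.contrasts if c.stratum == stratum)


def stratum_summaries(assignment: StratumAssignment, clinical) -> StratumSummaries:
    """Pairwise survival contrasts (METH vs CTRL, LOFDEL vs CTRL) and the
    per-stratum molecular-subtype composition (% summing to 100)."""
    ctrl = assignment.samples("CTRL")
    if not ctrl:
        raise ValidationError("empty CTRL stratum")
    t_ctrl, e_ctrl = clinical.times_events(ctrl)
    contrasts: list[StratumContrast] = []
    for stratum in ("METH", "LOFDEL"):
        members = assignment.samples(stratum)
        if not members:
            continue
        t, e = clinical.times_events(members)
        small = len(members) < 5
        try:
            chi2, lr_p = logrank_test((t, e), (t_ctrl, e_ctrl))
        except ValidationError:
            chi2, lr_p = float("nan"), float("nan")
        try:
            ind = np.concatenate([np.ones(len(t)), np.zeros(len(t_ctrl))])
            cox = cox_fit(np.concatenate([t, t_ctrl]),
                          np.concatenate([e, e_ctrl]), ind, standardize=False)
            hr, cox_p = cox.hr, cox.p
        except ValidationError:
            hr, cox_p = float("nan"), float("nan")
        contrasts.append(StratumContrast(stratum, len(members), chi2, lr_p,
                                         hr, cox_p, small_sample=small))
    if not contrasts:
        raise ValidationError("need at least two non-empty strata")

    rows = {}
    for stratum in ("CTRL", "METH", "LOFDEL"):
        members = assignment.samples(stratum)
        if not members:
            continue
        subs = clinical.df.loc[members, "subtype"].dropna()
        if len(subs):
            pct = subs.value_counts(normalize=True) * 100.0
        else:
            pct = pd.Series(dtype=float)
        rows[stratum] = pct
    comp = pd.DataFrame(rows).T.fillna(0.0)
    return StratumSummaries(contrasts=contrasts, subtype_composition=comp)
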