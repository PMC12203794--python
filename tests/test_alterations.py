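import logging

import numpy as np
import pandas as pd
import pytest

from episilence import (
    PipelineConfig,
    alteration_frequencies,
    classify_lof,
    split_by_driver,
    stratify_target,
    stratum_summaries,
)
from episilence.alterations import LOF_VOCABULARY
from episilence.io import (
    BetaMatrix,
    ClinicalTable,
    CnaRecord,
    CohortBundle,
    ExpressionMatrix,
    MutationRecord,
    ProbeManifest,
    ProbeRecord,
    ValidationError,
)


class TestClassifyLof:
    @pytest.mark.parametrize("term", sorted(LOF_VOCABULARY))
    def test_vocabulary_members_are_lof(self, term):
        assert classify_lof(term)

    def test_missense_excluded(self):
        assert not classify_lof("missense_variant")

    def test_unknown_term_warns_but_returns_false(self, caplog):
        with caplog.at_level(logging.WARNING, logger="episilence.alterations"):
            assert not classify_lof("totally_novel_term")
        assert "totally_novel_term" in caplog.text


class TestAlterationFrequencies:
    def test_no_records_all_zero(self):
        freqs = alteration_frequencies([], [], ["s1", "s2"], ["G"])
        assert freqs[0].f_lof == freqs[0].f_del == freqs[0].f_total == 0

    def test_fraction_of_full_universe(self):
        muts = [MutationRecord(f"s{i}", "G", "stop_gained") for i in range(17)]
        universe = [f"s{i}" for i in range(200)]
        freqs = alteration_frequencies(muts, [], universe, ["G"])
        assert freqs[0].f_lof == pytest.approx(0.085)

    def test_union_semantics_counts_sample_once(self):
        muts = [MutationRecord("s1", "G", "frameshift_variant")]
        cnas = [CnaRecord("s1", "G", -2)]
        freqs = alteration_frequencies(muts, cnas, ["s1", "s2"], ["G"])
        assert freqs[0].f_lof == 0.5 and freqs[0].f_del == 0.5
        assert freqs[0].f_total == 0.5  # union, not sum

    def test_complement_identity(self, rng):
        universe = [f"s{i}" for i in range(50)]
        muts = [MutationRecord(f"s{i}", "G", "stop_gained")
                for i in rng.choice(50, 12, replace=False)]
        cnas = [CnaRecord(f"s{i}", "G", -2)
                for i in rng.choice(50, 8, replace=False)]
        freqs = alteration_frequencies(muts, cnas, universe, ["G"])
        carriers = {m.sample_id for m in muts} | {c.sample_id for c in cnas}
        assert freqs[0].f_total == pytest.approx(1 - (50 - len(carriers)) / 50)

    def test_ranking_descending_with_symbol_ties(self):
        muts = [MutationRecord("s1", "B", "stop_gained"),
                MutationRecord("s1", "A", "stop_gained"),
                MutationRecord("s1", "C", "stop_gained"),
                MutationRecord("s2", "C", "stop_gained")]
        freqs = alteration_frequencies(muts, [], ["s1", "s2"], ["A", "B", "C"])
        assert [f.gene for f in freqs] == ["C", "A", "B"]

    def test_shallow_deletion_not_deleterious(self):
        cnas = [CnaRecord("s1", "G", -1)]
        freqs = alteration_frequencies([], cnas, ["s1"], ["G"])
        assert freqs[0].f_del == 0


def _toy_bundle():
    """Six samples: driver split 3/3; s1-s3 driver-high.

    target promoter beta high in s1,s2 (and s2 also mutated); target
    expression low in s1,s2,s3.
    """
    samples = [f"s{i}" for i in range(1, 7)]
    expr = ExpressionMatrix(pd.DataFrame(
        {"DNMT3B": [6, 6, 6, 2, 2, 2],
         "T": [2, 2, 2, 5, 5, 5]},
        index=samples).T)
    beta = BetaMatrix(pd.DataFrame(
        {"cgT1": [0.8, 0.8, 0.2, 0.2, 0.25, 0.15],
         "cgT2": [0.9, 0.85, 0.2, 0.2, 0.2, 0.2]},
        index=samples).T)
    manifest = ProbeManifest([
        ProbeRecord("cgT1", "chr1", 100, "+", frozenset({("T", "TSS200")})),
        ProbeRecord("cgT2", "chr1", 200, "+", frozenset({("T", "5UTR")})),
    ])
    clinical = ClinicalTable(pd.DataFrame(
        {"dfs_time": [5, 4, 6, 10, 11, 12.0],
         "dfs_event": [1, 1, 1, 0, 0, 1],
         "subtype": ["basal-like"] * 3 + ["luminal-A"] * 3},
        index=samples))
    mutations = [MutationRecord("s2", "T", "frameshift_variant"),
                 MutationRecord("s5", "T", "missense_variant")]
    cnas = [CnaRecord("s6", "T", -2), CnaRecord("s4", "T", -1)]
    return CohortBundle("toy", expr, clinical, beta, manifest, mutations, cnas)


class TestStratify:
    def test_genetic_takes_precedence_over_methylation(self):
        bundle = _toy_bundle()
        groups = split_by_driver(bundle.expression, "DNMT3B")
        a = stratify_target(bundle, groups, "T")
        # s2 is hypermethylated AND frameshift-mutated -> LOFDEL wins
        assert a.strata["s2"] == "LOFDEL"
        assert a.strata["s1"] == "METH"

    def test_ctrl_and_exclusions(self):
        bundle = _toy_bundle()
        groups = split_by_driver(bundle.expression, "DNMT3B")
        a = stratify_target(bundle, groups, "T")
        assert a.strata["s6"] == "LOFDEL"   # deep deletion
        assert a.strata["s4"] == "CTRL"     # shallow deletion is not deleterious
        assert a.strata["s5"] == "CTRL"     # missense is not LOF
        assert a.strata["s3"] == "unassigned"  # driver-high but unmethylated

    def test_mutual_exclusivity_invariant(self):
        bundle = _toy_bundle()
        groups = split_by_driver(bundle.expression, "DNMT3B")
        a = stratify_target(bundle, groups, "T")
        meth = set(a.samples("METH"))
        lofdel = set(a.samples("LOFDEL"))
        ctrl = set(a.samples("CTRL"))
        assert meth & lofdel == set()
        assert ctrl & (meth | lofdel) == set()

    def test_deterministic_and_record_order_invariant(self):
        bundle = _toy_bundle()
        groups = split_by_driver(bundle.expression, "DNMT3B")
        a1 = stratify_target(bundle, groups, "T")
        bundle.mutations = list(reversed(bundle.mutations))
        bundle.cnas = list(reversed(bundle.cnas))
        a2 = stratify_target(bundle, groups, "T")
        assert a1.strata == a2.strata

    def test_planted_recovery_on_simulation(self, small_sim, small_groups):
        _, bundle, truth = small_sim
        a = stratify_target(bundle, small_groups, truth.designated_target)
        meth = set(a.samples("METH"))
        lofdel = set(a.samples("LOFDEL"))
        def jaccard(x, y):
            return len(x & y) / len(x | y)
        assert jaccard(meth, truth.meth_silenced_samples) >= 0.9
        assert jaccard(lofdel, truth.lofdel_samples) >= 0.9


class TestStratumSummaries:
    def test_single_subtype_composition_is_100(self):
        bundle = _toy_bundle()
        groups = split_by_driver(bundle.expression, "DNMT3B")
        a = stratify_target(bundle, groups, "T")
        summaries = stratum_summaries(a, bundle.clinical)
        comp = summaries.subtype_composition
        assert comp.loc["METH", "basal-like"] == pytest.approx(100.0)
        assert comp.loc["CTRL", "luminal-A"] == pytest.approx(100.0)
        assert np.allclose(comp.sum(axis=1), 100.0)

    def test_identical_survival_gives_null_logrank(self):
        from episilence.alterations import StratumAssignment
        samples = [f"s{i}" for i in range(20)]
        # METH and CTRL get interleaved identical survival records
        strata = {s: ("METH" if i % 2 else "CTRL")
                  for i, s in enumerate(samples)}
        times = np.tile([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10], 2)
        clin = ClinicalTable(pd.DataFrame(
            {"dfs_time": np.sort(times),
             "dfs_event": 1, "subtype": "luminal-A"}, index=samples))
        a = StratumAssignment("T", "DNMT3B", strata)
        summaries = stratum_summaries(a, clin)
        c = summaries.contrast("METH")
        assert c.logrank_p > 0.9

    def test_small_stratum_flagged(self):
        bundle = _toy_bundle()
        groups = split_by_driver(bundle.expression, "DNMT3B")
        a = stratify_target(bundle, groups, "T")
        summaries = stratum_summaries(a, bundle.clinical)
        assert all(c.small_sample for c in summaries.contrasts)

    def test_planted_hazard_contrast_detected(self):
        from episilence import SimulationConfig, simulate_cohort
        cfg = SimulationConfig(n_samples=500, n_genes=60, n_target_genes=6,
                               rng_seed=31)
        bundle, truth = simulate_cohort(cfg, 0)
        groups = split_by_driver(bundle.expression, "DNMT3B")
        a = stratify_target(bundle, groups, truth.designated_target)
        summaries = stratum_summaries(a, bundle.clinical)
        assert summaries.contrast("METH").logrank_p < 0.05
        assert summaries.contrast("LOFDEL").logrank_p < 0.05
        assert summaries.contrast("METH").hr_vs_ctrl > 1
        assert summaries.contrast("LOFDEL").hr_vs_ctrl > 1
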