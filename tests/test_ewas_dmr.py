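import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episilence import (
    AcfEstimate,
    estimate_acf,
    ewas,
    find_regions,
    score_region,
    sliding_window_adjust,
    stouffer_liptak,
)
from episilence.ewas import assign_regions_to_genes, call_dmrs, total_tested_bases
from episilence.io import (
    BetaMatrix,
    ProbeManifest,
    ProbeRecord,
    ValidationError,
)


def _beta(values, probe_ids, sample_ids):
    return BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))


def _manifest(positions, chrom="chr1", annotations=None):
    anns = annotations or [frozenset()] * len(positions)
    return ProbeManifest([
        ProbeRecord(f"cg{i}", chrom, int(p), "+", anns[i])
        for i, p in enumerate(positions)
    ])


class TestEwas:
    def test_constant_probe_gives_null_result(self):
        beta = _beta([[0.5] * 6], ["cg0"], [f"s{i}" for i in range(6)])
        groups = {f"s{i}": "high" if i < 3 else "low" for i in range(6)}
        res = ewas(beta, groups, _manifest([100]))
        assert res.loc[0, "delta_beta"] == 0 and res.loc[0, "p_value"] == 1

    def test_matches_closed_form_two_sample_t(self):
        """OLS on a 0/1 indicator equals the equal-variance two-sample t."""
        hi, lo = [0.7, 0.8, 0.9], [0.1, 0.2, 0.3]
        beta = _beta([hi + lo], ["cg0"], [f"s{i}" for i in range(6)])
        groups = {f"s{i}": "high" if i < 3 else "low" for i in range(6)}
        res = ewas(beta, groups, _manifest([100]))
        t_ref, p_ref = stats.ttest_ind(hi, lo, equal_var=True)
        assert res.loc[0, "delta_beta"] == pytest.approx(0.6, abs=1e-12)
        assert res.loc[0, "t_stat"] == pytest.approx(t_ref, rel=1e-10)
        assert res.loc[0, "p_value"] == pytest.approx(p_ref, rel=1e-10)

    def test_invariant_to_sample_order(self, rng):
        vals = rng.random((5, 10))
        samples = [f"s{i}" for i in range(10)]
        groups = {s: ("high" if i % 2 else "low") for i, s in enumerate(samples)}
        man = _manifest([100 * (i + 1) for i in range(5)])
        res1 = ewas(_beta(vals, [f"cg{i}" for i in range(5)], samples), groups, man)
        perm = rng.permutation(10)
        res2 = ewas(_beta(vals[:, perm], [f"cg{i}" for i in range(5)],
                          [samples[j] for j in perm]), groups, man)
        pd.testing.assert_frame_equal(res1, res2)

    def test_insufficient_group_flagged_not_dropped(self):
        vals = np.array([[0.1, 0.2, np.nan, np.nan, 0.5, 0.6]])
        beta = _beta(vals, ["cg0"], [f"s{i}" for i in range(6)])
        groups = {f"s{i}": "high" if i < 4 else "low" for i in range(6)}
        res = ewas(beta, groups, _manifest([100]))
        assert len(res) == 1
        assert res.loc[0, "flag"] == ""  # 2 usable in high: still testable
        vals2 = np.array([[0.1, np.nan, np.nan, np.nan, 0.5, 0.6]])
        res2 = ewas(_beta(vals2, ["cg0"], [f"s{i}" for i in range(6)]),
                    groups, _manifest([100]))
        assert res2.loc[0, "flag"] == "insufficient_data"
        assert res2.loc[0, "p_value"] == 1


class TestStoufferLiptak:
    def test_identity_for_single_p(self):
        assert stouffer_liptak([0.03], np.array([[1.0]])) == pytest.approx(0.03, rel=1e-12)

    def test_symmetric_independent_pair_gives_half(self):
        sigma = np.eye(2)
        assert stouffer_liptak([0.5, 0.5], sigma) == pytest.approx(0.5, abs=1e-12)

    def test_hand_computed_correlated_pair(self):
        """p=(0.01, 0.02), rho=0.5: z=(2.3263, 2.0537), denominator sqrt(3)."""
        z = stats.norm.isf([0.01, 0.02])
        expected = stats.norm.sf(z.sum() / np.sqrt(3.0))
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        got = stouffer_liptak([0.01, 0.02], sigma)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.00572, abs=1e-4)

    def test_invalid_sigma_sum_is_error(self):
        sigma = np.array([[1.0, -1.5], [-1.5, 1.0]])
        with pytest.raises(ValidationError):
            stouffer_liptak([0.1, 0.1], sigma)


class TestAcf:
    def _results(self, pos, p, chrom="chr1"):
        return pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(len(pos))],
            "chrom": chrom, "pos": np.array(pos, dtype=np.int64),
            "delta_beta": 0.0, "t_stat": 0.0, "p_value": p, "flag": "",
        })

    def test_identical_p_degenerate_fallback(self):
        res = self._results(np.arange(1, 101) * 40, np.full(100, 0.3))
        acf = estimate_acf(res, max_lag=1000, step=50)
        assert acf.degenerate
        assert np.allclose(acf.rho, 0.99)

    def test_null_uniform_p_gives_near_zero_rho(self, rng):
        pos = np.arange(1, 10001) * 45
        res = self._results(pos, rng.uniform(size=10000))
        acf = estimate_acf(res, max_lag=1000, step=50)
        assert np.all(acf.rho <= 0.05)  # clipped at 0 from below

    def test_planted_lag_correlation_recovered(self, rng):
        """Pairs at lag 50 share a latent component with correlation 0.6."""
        n = 20000
        shared = rng.normal(size=n // 2)
        z = np.empty(n)
        z[0::2] = np.sqrt(0.6) * shared + np.sqrt(0.4) * rng.normal(size=n // 2)
        z[1::2] = np.sqrt(0.6) * shared + np.sqrt(0.4) * rng.normal(size=n // 2)
        p = stats.norm.sf(z)
        # pair members 50 bp apart; pairs 5 kb apart so they never interact
        pos = np.repeat(np.arange(n // 2) * 5000 + 1, 2)
        pos[1::2] += 50
        res = self._results(pos, p)
        acf = estimate_acf(res, max_lag=1000, step=50)
        assert acf.rho[0] == pytest.approx(0.6, abs=0.05)

    def test_too_sparse_is_error(self):
        res = self._results([100, 50000], [0.5, 0.5])
        with pytest.raises(ValidationError):
            estimate_acf(res, max_lag=1000)

    def test_sigma_lag_zero_is_one(self):
        acf = AcfEstimate(step=50, max_lag=1000, rho=np.full(20, 0.3),
                          counts=np.full(20, 100))
        assert acf.sigma(0) == 1.0
        assert acf.sigma(1) == 0.3
        assert acf.sigma(50) == 0.3
        assert acf.sigma(51) == 0.3


def _flat_acf(rho=0.0):
    return AcfEstimate(step=50, max_lag=1000, rho=np.full(20, rho),
                       counts=np.full(20, 1000))


def _frame(pos, p, delta=None, chrom=None):
    n = len(pos)
    return pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(n)],
        "chrom": chrom if chrom is not None else ["chr1"] * n,
        "pos": np.array(pos, dtype=np.int64),
        "delta_beta": delta if delta is not None else np.ones(n) * 0.1,
        "t_stat": 0.0,
        "p_value": np.asarray(p, dtype=float),
        "flag": "",
    })


class TestSlidingWindow:
    def test_isolated_probe_keeps_raw_p(self):
        res = _frame([100, 5000], [0.01, 0.3])
        adj = sliding_window_adjust(res, _flat_acf(), dist=1000)
        assert adj["p_adjusted"].tolist() == [0.01, 0.3]

    def test_adjacent_signal_reinforces_under_independence(self):
        res = _frame([100, 200, 300], [0.01, 0.01, 0.01])
        adj = sliding_window_adjust(res, _flat_acf(0.0), dist=1000)
        assert (adj["p_adjusted"] < 0.01).all()

    def test_matches_brute_force_on_toy_chromosome(self, rng):
        """Window adjustment equals an exhaustive per-probe recomputation."""
        pos = np.sort(rng.choice(np.arange(1, 3000), size=12, replace=False))
        p = rng.uniform(0.001, 0.9, size=12)
        acf = _flat_acf(0.4)
        res = _frame(pos, p)
        adj = sliding_window_adjust(res, acf, dist=1000)["p_adjusted"].to_numpy()
        for i in range(12):
            members = [j for j in range(12) if abs(pos[j] - pos[i]) <= 500]
            if len(members) == 1:
                expected = p[i]
            else:
                z = stats.norm.isf(p[members])
                sig = 0.0
                for a in members:
                    for b in members:
                        d = abs(pos[a] - pos[b])
                        sig += 1.0 if d == 0 else acf.rho[(d - 1) // 50]
                expected = stats.norm.sf(z.sum() / np.sqrt(sig))
            assert adj[i] == pytest.approx(expected, abs=1e-12)


class TestFindRegions:
    def test_no_seed_gives_empty(self):
        adj = _frame([100, 200], [0.01, 0.01])
        adj["p_adjusted"] = [0.01, 0.01]
        assert find_regions(adj) == []

    def test_gap_and_min_probe_filters(self):
        """Seeds at 100 and 5000; the gap breaks extension and the singleton
        is discarded by region_filter_n=2, leaving one region {100, 400}."""
        adj = _frame([100, 400, 5000], [1e-7, 0.01, 1e-7])
        adj["p_adjusted"] = [1e-7, 0.01, 1e-7]
        regions = find_regions(adj, seed_p=1e-5, dist=1000,
                               region_filter_p=0.05, region_filter_n=2)
        assert len(regions) == 1
        assert regions[0].probe_ids == ["cg0", "cg1"]
        assert (regions[0].start, regions[0].end) == (99, 400)

    def test_lowering_filter_p_never_grows_regions(self):
        adj = _frame([100, 200, 300, 400, 500],
                     [1e-7, 0.03, 0.2, 0.03, 1e-7])
        adj["p_adjusted"] = adj["p_value"]
        sizes = []
        for fp in (0.05, 0.02, 0.005):
            regions = find_regions(adj, seed_p=1e-5, dist=1000,
                                   region_filter_p=fp, region_filter_n=1)
            sizes.append(sorted(r.n_probes for r in regions))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_direction_from_mean_delta(self):
        adj = _frame([100, 200], [1e-7, 1e-7], delta=np.array([-0.3, 0.1]))
        adj["p_adjusted"] = adj["p_value"]
        (region,) = find_regions(adj)
        assert region.direction == "hypo"  # mean delta -0.1; ties also hypo


class TestScoreRegion:
    def test_exponent_one_keeps_p(self):
        res = _frame([100, 1100], [0.01, 0.02])
        adj = res.copy()
        adj["p_adjusted"] = adj["p_value"]
        (region,) = find_regions(adj, seed_p=0.05, dist=1000, region_filter_n=2)
        assert total_tested_bases(res) == 1000
        p_comb, p_sidak = score_region(region, res, _flat_acf())
        assert p_sidak == pytest.approx(p_comb, rel=1e-12)

    def test_sidak_arithmetic(self):
        """1 - 0.999^100 for p_combined = 0.001 at B/w = 100."""
        expected = 1 - (1 - 0.001) ** 100
        assert expected == pytest.approx(0.0952, abs=1e-4)
        got = float(-np.expm1(100 * np.log1p(-0.001)))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_sidak_never_below_combined(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 2000), 6, replace=False))
        res = _frame(pos, rng.uniform(1e-8, 0.04, 6))
        adj = res.copy()
        adj["p_adjusted"] = adj["p_value"]
        for region in find_regions(adj, seed_p=0.05, region_filter_n=2):
            p_comb, p_sidak = score_region(region, res, _flat_acf(0.2),
                                           total_bases=100000)
            assert 0 <= p_comb <= p_sidak <= 1


class TestGeneAssignment:
    def _scored(self, direction, p_sidak, probe_ids):
        from episilence.ewas import DmrRecord
        d = DmrRecord("chr1", 99, 300, probe_ids, direction)
        d.p_combined = p_sidak / 2
        d.p_sidak = p_sidak
        return d

    def test_body_only_not_called(self):
        man = _manifest([100, 200],
                        annotations=[frozenset({("G", "Body")})] * 2)
        calls = assign_regions_to_genes(
            [self._scored("hyper", 1e-9, ["cg0", "cg1"])], man, 1e-5)
        assert "G" not in calls

    def test_hypo_direction_not_called(self):
        man = _manifest([100, 200],
                        annotations=[frozenset({("G", "TSS200")})] * 2)
        calls = assign_regions_to_genes(
            [self._scored("hypo", 1e-9, ["cg0", "cg1"])], man, 1e-5)
        assert calls == {}

    def test_multi_gene_probe_fanout(self):
        ann = frozenset({("A", "TSS200"), ("B", "Body")})
        man = _manifest([100, 200], annotations=[ann, ann])
        calls = assign_regions_to_genes(
            [self._scored("hyper", 1e-9, ["cg0", "cg1"])], man, 1e-5)
        assert "A" in calls and calls["A"].hypermethylated
        assert "B" not in calls

    def test_threshold_applies_to_sidak_p(self):
        man = _manifest([100, 200],
                        annotations=[frozenset({("G", "TSS1500")})] * 2)
        calls = assign_regions_to_genes(
            [self._scored("hyper", 1e-4, ["cg0", "cg1"])], man, 1e-5)
        assert calls == {}


class TestEndToEndRecovery:
    def test_planted_targets_called(self, small_sim, small_groups):
        _, bundle, truth = small_sim
        res = ewas(bundle.methylation, small_groups, bundle.manifest)
        _, calls = call_dmrs(res, bundle.manifest)
        recovered = set(calls)
        assert len(recovered & set(truth.target_genes)) >= 0.9 * len(truth.target_genes)
        assert all(calls[g].best_p_sidak >= calls[g].supporting_regions[0].p_combined
                   for g in calls)
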