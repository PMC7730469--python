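"""Friedman / Wilcoxon / Bonferroni battery against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gaitfatigue.features import FEATURES, NormalizedFeatureTable
from gaitfatigue.io import CHANNELS
from gaitfatigue.stats import (
    CohortTable,
    bonferroni_adjust,
    friedman_test,
    normality_screen,
    run_battery,
    wilcoxon_signed_rank,
)


from _oracles import brute_friedman_statistic, brute_wilcoxon_p


def _cohort_from_blocks(block):
    """CohortTable holding the same n x 3 block for every (channel, feature)."""
    return CohortTable(
        blocks={(c, f): np.array(block, float) for c in CHANNELS for f in FEATURES},
        n_subjects=len(block),
    )


class TestFriedman:
    def test_identical_rows_give_zero_statistic(self):
        block = np.tile([1.0, 1.0, 1.0], (6, 1))
        stat, p = friedman_test(block)
        assert stat == 0.0 and p == 1.0

    def test_monotone_rows_closed_form(self):
        # 5 rows ranked 1,2,3: Q = 12/(n k (k+1)) sum R^2 - 3 n (k+1) = 10
        block = np.array([[1.0, 2.0, 3.0]]) * np.arange(1, 6)[:, None]
        stat, p = friedman_test(block)
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(float(sps.chi2.sf(10.0, 2)), rel=1e-12)
        assert p == pytest.approx(0.0067, abs=5e-4)

    def test_matches_brute_force_and_scipy(self, rng):
        for _ in range(60):
            block = rng.normal(size=(8, 3))
            if rng.random() < 0.3:
                block[:, 0] = 1.0  # baseline-like constant column
            stat, p = friedman_test(block)
            assert stat == pytest.approx(brute_friedman_statistic(block), rel=1e-12)
            s_stat, s_p = sps.friedmanchisquare(*block.T)
            assert stat == pytest.approx(float(s_stat), rel=1e-12)
            assert p == pytest.approx(float(s_p), rel=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        block = np.abs(rng.normal(size=(10, 3))) + 0.1
        stat, p = friedman_test(block)
        stat3, p3 = friedman_test(block**3)
        assert (stat, p) == (stat3, p3)

    def test_exact_null_matches_enumeration(self, rng):
        # oracle: every assignment of within-row orderings at n = 4
        n = 4
        block = rng.normal(size=(n, 3))
        stat, p_exact = friedman_test(block, method="exact")
        perms = list(itertools.permutations([1.0, 2.0, 3.0]))
        hits = total = 0
        for combo in itertools.product(perms, repeat=n):
            q = brute_friedman_statistic(np.array(combo))
            total += 1
            hits += q >= stat - 1e-9
        assert p_exact == pytest.approx(hits / total, rel=1e-12)

    def test_exact_refuses_ties(self):
        block = np.array([[1.0, 1.0, 2.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            friedman_test(block, method="exact")

    def test_discreteness_of_exact_null_at_study_size(self):
        # at n = 18 no attainable significance level sits near 0.05: the
        # level jumps from ~0.0552 (Q >= 5.78) to ~0.0448 (Q >= 6.33)
        from gaitfatigue.stats import _friedman_exact_sf
        qs, sf = _friedman_exact_sf(18)
        below = max(lv for lv in sf if lv < 0.05)
        above = min(lv for lv in sf if lv >= 0.05)
        assert below == pytest.approx(0.04483, abs=2e-4)
        assert above == pytest.approx(0.05524, abs=2e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 3)))
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, np.nan, 2.0], [1, 2, 3]]))


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        a = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = a - np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(2 / 64, rel=1e-12)

    def test_identical_samples_degenerate(self):
        a = np.arange(8.0)
        res = wilcoxon_signed_rank(a, a)
        assert res.degenerate and res.pvalue == 1.0 and res.n_zeros == 8

    def test_zero_differences_discarded(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.n_zeros == 2 and res.n_used == 5

    def test_matches_enumeration_oracle(self, rng):
        for n in (5, 8, 10, 12):
            for _ in range(8):
                a = rng.normal(size=n)
                b = a + rng.normal(scale=0.8, size=n)
                if np.all(a - b == 0):
                    continue
                res = wilcoxon_signed_rank(a, b)
                assert res.method == "exact"
                assert res.pvalue == pytest.approx(brute_wilcoxon_p(a, b), rel=1e-12)

    def test_exact_handles_tied_ranks(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.5, 0.5, -0.5, 1.5, 1.5, -1.5])
        res = wilcoxon_signed_rank(a, b)
        assert res.pvalue == pytest.approx(brute_wilcoxon_p(a, b), rel=1e-12)

    def test_large_n_matches_scipy_normal_approximation(self, rng):
        a = rng.normal(size=60)
        b = a + rng.normal(scale=0.5, size=60)
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "approx"
        ref = sps.wilcoxon(a, b, correction=False, mode="approx",
                           zero_method="wilcox")
        assert res.pvalue == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize("raw,adj", [(0.006, 0.018), (0.17, 0.51),
                                         (0.5, 1.0), (0.0, 0.0), (1.0, 1.0)])
    def test_adjustment(self, raw, adj):
        assert bonferroni_adjust(raw, 3) == pytest.approx(adj, rel=1e-12)

    def test_monotone_and_capped(self):
        grid = np.linspace(0, 1, 101)
        adj = [bonferroni_adjust(p, 3) for p in grid]
        assert all(x <= y for x, y in zip(adj, adj[1:]))
        assert max(adj) == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5)
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, m=0)


class TestNormalityScreen:
    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(5)
        hits = sum(normality_screen(rng.normal(size=50))[1] > 0.05
                   for _ in range(200))
        assert hits >= 180

    def test_skewed_samples_usually_fail(self):
        rng = np.random.default_rng(6)
        hits = sum(normality_screen(rng.exponential(size=50))[1] < 0.05
                   for _ in range(200))
        assert hits >= 180

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError):
            normality_screen([3.0, 3.0, 3.0, 3.0])


class TestBattery:
    def _tables(self, rng, n=10, bump=None):
        tables = []
        for s in range(n):
            ratios = {}
            for w, (lo, hi) in (("baseline", (1.0, 1.0)), ("min30", (0.9, 1.1)),
                                ("min60", (0.9, 1.1))):
                vals = rng.uniform(lo, hi, size=(9, 10)) if lo < hi else np.ones((9, 10))
                ratios[w] = pd.DataFrame(vals, index=list(CHANNELS),
                                         columns=list(FEATURES))
            if bump:
                ch, f, w, v = bump
                ratios[w].loc[ch, f] += v
            tables.append(NormalizedFeatureTable(subject_id=f"S{s}", ratios=ratios))
        return tables

    def test_posthoc_only_for_significant_blocks(self, rng):
        tables = self._tables(rng, bump=("gz", "rms", "min60", 0.5))
        cohort = CohortTable.from_subject_tables(tables)
        report = run_battery(cohort)
        assert report.friedman_p.shape == (10, 9)
        assert ("gz", "rms") in report.significant_blocks()
        tested = set(map(tuple, report.posthoc[["channel", "feature"]].to_numpy()))
        assert tested == set(report.significant_blocks())
        gz = report.posthoc.query("channel == 'gz' and feature == 'rms'")
        assert len(gz) == 3
        sig = gz.set_index("contrast")["significant"]
        assert sig["baseline-min60"] and sig["min30-min60"]

    def test_adjusted_p_consistency(self, rng):
        tables = self._tables(rng, bump=("gz", "rms", "min60", 0.5))
        report = run_battery(CohortTable.from_subject_tables(tables))
        assert (report.posthoc["adjusted_p"] <=
                np.minimum(1.0, 3 * report.posthoc["raw_p"]) + 1e-12).all()
        assert (report.posthoc["adjusted_p"] >= report.posthoc["raw_p"]).all()
        assert report.posthoc_alpha == pytest.approx(0.05 / 3)

    def test_listwise_exclusion(self, rng):
        tables = self._tables(rng)
        tables[3].ratios["min30"].loc["ax", "mad"] = np.nan
        cohort = CohortTable.from_subject_tables(tables)
        assert cohort.blocks[("ax", "mad")].shape[0] == 9
        assert cohort.blocks[("ax", "rms")].shape[0] == 10
        assert cohort.exclusions[("ax", "mad")] == ["S3"]

    def test_single_cycle_windows_make_ec_and_rms_agree(self, rng):
        # with one cycle per window the EC aggregate is exactly the square
        # of the RMS aggregate, a strictly monotone map, so the rank-based
        # omnibus must coincide; multi-cycle averaging breaks this (see
        # features tests for the non-identity counterexample)
        rms = np.abs(rng.normal(1.0, 0.3, size=(12, 3))) + 0.2
        rms[:, 0] = 1.0
        ec = rms**2
        stat_r, p_r = friedman_test(rms)
        stat_e, p_e = friedman_test(ec)
        assert stat_r == pytest.approx(stat_e, rel=1e-12)
        assert p_r == pytest.approx(p_e, rel=1e-12)

    def test_mean_ec_and_mean_rms_ranks_can_differ(self):
        # two cycles per window: window A cycles {1, 3}, window B {2.2, 2.2}
        # mean RMS orders A < B while mean EC orders A > B
        mean_rms_a, mean_rms_b = 2.0, 2.2
        mean_ec_a, mean_ec_b = (1 + 9) / 2, (2.2**2 + 2.2**2) / 2
        assert mean_rms_a < mean_rms_b
        assert mean_ec_a > mean_ec_b
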