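import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimem.windows import (WindowError, adjust_fdr, assign_window_ids,
                            benjamini_hochberg, build_windows, local_fdr_tail,
                            score_windows, tile_chromosome, WindowResult)
from epimem.windows import test_window as window_test


def probe_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])


class TestTiling:
    def test_exact_multiple(self):
        wins = tile_chromosome("chr1", 150_000, 50_000)
        assert [(s, e) for _, s, e in wins] == [(0, 50_000), (50_000, 100_000),
                                                (100_000, 150_000)]

    def test_truncated_last_window(self):
        wins = tile_chromosome("chr1", 120_000, 50_000)
        assert wins[-1][1:] == (100_000, 120_000)

    @given(length=st.integers(1, 10_000), window=st.integers(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_partition_property(self, length, window):
        wins = tile_chromosome("chr1", length, window)
        assert sum(e - s for _, s, e in wins) == length
        assert wins[0][1] == 0 and wins[-1][2] == length
        for (_, _, e1), (_, s2, _) in zip(wins, wins[1:]):
            assert e1 == s2


class TestAssignment:
    def test_half_open_boundary(self):
        probes = probe_frame([("a", "chr1", 49_969, 50_029),   # midpoint 49999
                              ("b", "chr1", 49_970, 50_030)])  # midpoint 50000
        ids = assign_window_ids(probes, {"chr1": 150_000}, 50_000)
        assert ids.tolist() == ["chr1:0-50000", "chr1:50000-100000"]

    def test_probe_beyond_chromosome_error(self):
        probes = probe_frame([("a", "chr1", 149_990, 150_050)])
        with pytest.raises(WindowError, match="beyond chromosome"):
            assign_window_ids(probes, {"chr1": 150_000}, 50_000)

    def test_each_probe_in_exactly_one_window(self, rng):
        starts = rng.integers(0, 119_000, size=200)
        probes = probe_frame([(f"p{i}", "chr1", int(s), int(s) + 60)
                              for i, s in enumerate(starts)])
        wins = build_windows(probes, {"chr1": 120_000}, 50_000)
        all_members = [p for w in wins for p in w.probe_ids]
        assert sorted(all_members) == sorted(probes["probe_id"])

    def test_windows_never_span_chromosomes(self):
        probes = probe_frame([("a", "chr1", 10, 70), ("b", "chr2", 10, 70)])
        wins = build_windows(probes, {"chr1": 60_000, "chr2": 60_000}, 50_000)
        assert all(w.end <= 60_000 for w in wins)
        assert len(wins) == 4  # two truncated tails


def wilcoxon_oracle(values, mu_ref):
    """Exact two-sided p by enumerating all 2^n sign assignments of the
    absolute differences (requires no zeros and no ties)."""
    d = np.asarray(values, dtype=float) - mu_ref
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    n = len(d)
    dist = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)]
    dist = np.array(dist)
    p_low = np.mean(dist <= w_obs)
    p_high = np.mean(dist >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_symmetric_case_p_one(self):
        # enumeration over 2^4 sign assignments: W+ = 5 is the median
        p, testable = window_test([-4, -1, 2, 3], 0.0)
        assert testable and p == 1.0

    def test_six_positive_distinct(self):
        # all-positive: P(W+ >= 21) = 1/64 each tail -> two-sided 2/64
        p, _ = window_test([1, 2, 3, 4, 5, 6], 0.0)
        assert p == pytest.approx(2 / 64)

    def test_all_equal_reference_warns_p_one(self):
        with pytest.warns(UserWarning, match="reference mean"):
            p, testable = window_test([2.0, 2.0, 2.0], 2.0)
        assert p == 1.0 and testable

    def test_untestable_below_min_probes(self):
        p, testable = window_test([1.0, 2.0], 0.0, min_probes=3)
        assert not testable and np.isnan(p)

    def test_missing_values_dropped(self):
        p_clean, _ = window_test([1, 2, 3, 4, 5, 6], 0.0)
        p_nan, _ = window_test([1, 2, 3, 4, 5, 6, np.nan], 0.0)
        assert p_nan == p_clean

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_matches_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 11))
        # continuous draws: no zeros, ties almost surely absent
        values = r.normal(0.5, 1.0, n)
        mu = 0.0
        p_impl, _ = window_test(values, mu, min_probes=1)
        assert p_impl == pytest.approx(wilcoxon_oracle(values, mu), abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        values = rng.normal(0.2, 1.0, 60)
        p, testable = window_test(values, 0.0)
        assert testable and 0.0 < p <= 1.0

    def test_ties_handled(self):
        values = [1.0, 1.0, -1.0, 2.0, 3.0, -2.0, 4.0, 4.0]
        p, testable = window_test(values, 0.0)
        assert testable and 0.0 < p <= 1.0


class TestFdr:
    def test_bh_hand_computed(self):
        # step-up: q(i) = min over j>=i of m*p(j)/j -> all 0.04
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert benjamini_hochberg([]).size == 0
        assert local_fdr_tail([]).size == 0

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(benjamini_hochberg(p), q_sm)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bh_properties(self, p):
        q = benjamini_hochberg(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # order-preserving

    def test_bh_rejects_bad_p(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_local_fdr_null_is_high(self, rng):
        fdr = local_fdr_tail(rng.uniform(size=500))
        assert np.median(fdr) > 0.5

    def test_local_fdr_signal_detected(self, rng):
        p = np.r_[rng.uniform(size=450), rng.uniform(size=50) * 1e-8]
        fdr = local_fdr_tail(p)
        assert fdr[450:].max() < 0.05
        assert np.all((fdr >= 0) & (fdr <= 1))

    def test_local_fdr_monotone_in_p(self, rng):
        p = rng.uniform(size=300) ** 2
        fdr = local_fdr_tail(p)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-12)

    def test_adjust_dispatch(self, rng):
        p = rng.uniform(size=50)
        assert np.allclose(adjust_fdr(p, "bh"), benjamini_hochberg(p))
        with pytest.raises(ValueError, match="unknown FDR method"):
            adjust_fdr(p, "bonferroni")


def make_result(wid, mean, p, mu_ref=0.0, testable=True):
    return WindowResult(window_id=wid, condition="c", mean_signal=mean,
                        p_value=p, mu_ref=mu_ref, testable=testable)


class TestScoring:
    def test_non_significant_scores_zero(self):
        r = make_result("w1", 5.0, 0.5)
        score_windows([r], alpha=0.05)
        assert r.score == 0 and r.q_value == 0.5

    def test_significant_above_scores_plus_one(self):
        r = make_result("w1", 1.0, 0.01)
        score_windows([r], alpha=0.05)
        assert r.score == 1

    def test_significant_below_scores_minus_one(self):
        r = make_result("w1", -1.0, 0.01)
        score_windows([r], alpha=0.05)
        assert r.score == -1

    def test_mean_at_reference_tie_rule(self):
        r = make_result("w1", 0.0, 0.001, mu_ref=0.0)
        score_windows([r], alpha=0.05)
        assert r.score == 0

    def test_untestable_excluded_from_fdr_pool(self):
        good = [make_result(f"w{i}", 1.0, 0.01) for i in range(4)]
        bad = make_result("wx", np.nan, np.nan, testable=False)
        score_windows(good + [bad], alpha=0.05)
        assert np.isnan(bad.q_value) and bad.score == 0
        assert all(r.q_value == pytest.approx(0.01) for r in good)

    def test_score_respects_per_window_reference(self):
        hi = make_result("w1", 2.0, 0.001, mu_ref=3.0)   # below its reference
        lo = make_result("w2", 2.0, 0.001, mu_ref=1.0)   # above its reference
        score_windows([hi, lo], alpha=0.05)
        assert hi.score == -1 and lo.score == 1
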