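import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from epimem.compare import (CompareError, EnrichmentResult, common_fraction,
                            hypergeometric_upper_tail, intersect_dmrs,
                            overlap_with_degs)
from epimem.compare import test_direction_enrichment as direction_enrichment
from epimem.compare import test_overlap_enrichment as overlap_enrichment


def hypergeom_tail_fraction(N, K, n, k):
    """Exact upper tail as a Fraction from the combinatorial sum."""
    total = comb(N, n)
    return sum(Fraction(comb(K, j) * comb(N - K, n - j), total)
               for j in range(k, min(K, n) + 1))


def hypergeom_tail_enumeration(N, K, n, k):
    """Brute force over every C(N, n) draw of a labelled population."""
    population = [1] * K + [0] * (N - K)
    hits = sum(1 for draw in itertools.combinations(population, n)
               if sum(draw) >= k)
    return Fraction(hits, comb(N, n))


class TestHypergeometricTail:
    def test_four_choose_two(self):
        # all C(4,2)=6 draws; only one contains both successes
        assert hypergeometric_upper_tail(4, 2, 2, 2) == pytest.approx(1 / 6)

    def test_k_zero_certain(self):
        assert hypergeometric_upper_tail(100, 30, 10, 0) == 1.0

    def test_ten_choose_five(self):
        assert hypergeometric_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_impossible_k_rejected(self):
        with pytest.raises(CompareError):
            hypergeometric_upper_tail(10, 3, 4, 5)

    def test_invalid_population_rejected(self):
        with pytest.raises(CompareError):
            hypergeometric_upper_tail(10, 12, 4, 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_combinatorial_sum_up_to_25(self, seed):
        r = np.random.default_rng(seed)
        N = int(r.integers(2, 26))
        K = int(r.integers(0, N + 1))
        n = int(r.integers(0, N + 1))
        k = int(r.integers(max(0, n + K - N), min(K, n) + 1))
        exact = float(hypergeom_tail_fraction(N, K, n, k))
        assert hypergeometric_upper_tail(N, K, n, k) == pytest.approx(exact, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_draw_enumeration_small(self, seed):
        r = np.random.default_rng(100 + seed)
        N = int(r.integers(2, 13))
        K = int(r.integers(0, N + 1))
        n = int(r.integers(0, N + 1))
        k = int(r.integers(max(0, n + K - N), min(K, n) + 1))
        exact = float(hypergeom_tail_enumeration(N, K, n, k))
        assert hypergeometric_upper_tail(N, K, n, k) == pytest.approx(exact, rel=1e-12)

    def test_min_support_k_is_one(self):
        # k at its minimum possible value: tail holds all the mass
        assert hypergeometric_upper_tail(10, 8, 6, 4) == 1.0


class TestIntersect:
    def test_conserved(self):
        common, _ = intersect_dmrs({"A": {"w1": "hyper"}, "B": {"w1": "hyper"}})
        assert common.loc[0, "status"] == "conserved"

    def test_inversed(self):
        common, _ = intersect_dmrs({"A": {"w1": "hyper"}, "B": {"w1": "hypo"}})
        assert common.loc[0, "status"] == "inversed"

    def test_disjoint_sets_empty(self):
        common, exclusive = intersect_dmrs({"A": {"w1": "hyper"}, "B": {"w2": "hypo"}})
        assert common.empty
        assert exclusive == {"A": ["w1"], "B": ["w2"]}

    def test_symmetry(self):
        a = {"w1": "hyper", "w2": "hypo", "w3": "hyper"}
        b = {"w2": "hyper", "w3": "hyper", "w4": "hypo"}
        ab, _ = intersect_dmrs({"A": a, "B": b})
        ba, _ = intersect_dmrs({"B": b, "A": a})
        assert set(ab["window_id"]) == set(ba["window_id"])
        assert dict(zip(ab["window_id"], ab["status"])) == \
            dict(zip(ba["window_id"], ba["status"]))

    def test_conserved_plus_inversed_equals_common(self):
        r = np.random.default_rng(0)
        sets = {exp: {f"w{i}": ("hyper" if r.random() < 0.6 else "hypo")
                      for i in r.choice(60, size=30, replace=False)}
                for exp in "ABC"}
        common, _ = intersect_dmrs(sets)
        n_cons = (common["status"] == "conserved").sum()
        n_inv = (common["status"] == "inversed").sum()
        assert n_cons + n_inv == len(common)

    def test_three_way_conserved_requires_all_agree(self):
        sets = {"A": {"w": "hyper"}, "B": {"w": "hyper"}, "C": {"w": "hypo"}}
        common, _ = intersect_dmrs(sets)
        assert common.loc[0, "n_experiments"] == 3
        assert common.loc[0, "status"] == "inversed"

    def test_single_experiment_rejected(self):
        with pytest.raises(CompareError):
            intersect_dmrs({"A": {"w1": "hyper"}})

    def test_common_fraction_printed_values(self):
        assert common_fraction(502, 871) == 57.6
        assert common_fraction(161, 871) == 18.4


class TestOverlapEnrichment:
    def test_saturated_overlap(self):
        uni = [f"w{i}" for i in range(20)]
        res = overlap_enrichment(uni, uni, uni)
        assert res.k == res.n and res.p_value == pytest.approx(1.0)

    def test_small_exact_case(self):
        uni = [f"w{i}" for i in range(10)]
        a = uni[:4]
        b = uni[:3]
        res = overlap_enrichment(a, b, uni)
        exact = float(hypergeom_tail_enumeration(10, 4, 3, 3))
        assert res.p_value == pytest.approx(exact, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(CompareError):
            overlap_enrichment(["w1"], ["w1"], [])

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(CompareError):
            overlap_enrichment(["w99"], ["w1"], ["w1"])

    def test_null_p_roughly_uniform(self):
        uni = [f"w{i}" for i in range(60)]
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            a = r.choice(uni, size=15, replace=False)
            b = r.choice(uni, size=15, replace=False)
            ps.append(overlap_enrichment(a, b, uni).p_value)
        ps = np.array(ps)
        # discrete upper-tail p-values are super-uniform under the null
        assert (ps <= 0.05).mean() <= 0.08
        assert ps.mean() > 0.4


class TestDirectionEnrichment:
    def make_common(self, directions_conserved, directions_inversed):
        rows = []
        for i, d in enumerate(directions_conserved):
            rows.append({"window_id": f"c{i}", "n_experiments": 2,
                         "status": "conserved", "direction_A": d, "direction_B": d})
        for i, d in enumerate(directions_inversed):
            rows.append({"window_id": f"i{i}", "n_experiments": 2,
                         "status": "inversed", "direction_A": d,
                         "direction_B": "hypo" if d == "hyper" else "hyper"})
        return pd.DataFrame(rows)

    def test_all_hyper_p_one(self):
        common = self.make_common(["hyper"] * 5, ["hyper"] * 5)
        res = direction_enrichment(common, "A")
        assert res.K == res.N and res.p_value == pytest.approx(1.0)

    def test_brute_force_at_n20(self):
        common = self.make_common(["hyper"] * 10, ["hypo"] * 10)
        res = direction_enrichment(common, "A")
        exact = float(hypergeom_tail_fraction(20, 10, 10, 10))
        assert res.p_value == pytest.approx(exact, rel=1e-12)
        assert exact == pytest.approx(1 / comb(20, 10))

    def test_minimum_k_p_one(self):
        common = self.make_common(["hypo"] * 8, ["hyper"] * 4)
        res = direction_enrichment(common, "A")
        assert res.p_value == pytest.approx(1.0)

    def test_empty_common_rejected(self):
        with pytest.raises(CompareError):
            direction_enrichment(pd.DataFrame(), "A")


class TestDegOverlap:
    def test_empty_deg_list(self):
        table, results, dropped = overlap_with_degs(
            {"g1": "hyper"}, pd.DataFrame(columns=["gene_id", "direction"]),
            ["g1", "g2"])
        assert table.to_numpy().sum() == 0 and results == {} and dropped == 0

    def test_all_degs_in_hyper_dmrs(self):
        universe = [f"g{i}" for i in range(20)]
        dmr_genes = {g: "hyper" for g in universe[:5]}
        degs = pd.DataFrame({"gene_id": universe[:5], "direction": ["up"] * 5})
        table, results, _ = overlap_with_degs(dmr_genes, degs, universe)
        assert table.loc["hyper", "up"] == 5
        exact = float(hypergeom_tail_fraction(20, 5, 5, 5))
        assert results["hyper"].p_value == pytest.approx(exact, rel=1e-12)

    def test_degs_outside_universe_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            _, _, dropped = overlap_with_degs(
                {"g1": "hyper"},
                pd.DataFrame({"gene_id": ["g1", "gZ"], "direction": ["up", "down"]}),
                ["g1", "g2"])
        assert dropped == 1

    def test_null_scatter_rarely_significant(self):
        universe = [f"g{i}" for i in range(200)]
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            dmr_genes = {g: ("hyper" if r.random() < 0.5 else "hypo")
                         for g in r.choice(universe, size=40, replace=False)}
            degs = pd.DataFrame({"gene_id": r.choice(universe, size=30, replace=False),
                                 "direction": "up"})
            _, results, _ = overlap_with_degs(dmr_genes, degs, universe)
            if any(res.p_value < 0.05 for res in results.values()):
                hits += 1
        assert hits <= 10  # p > 0.05 in >= 90% of null seeds, with slack


def test_enrichment_result_invariants():
    with pytest.raises(CompareError):
        EnrichmentResult(N=10, K=4, n=3, k=5, p_value=0.1)
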