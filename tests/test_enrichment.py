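import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossclust import (GeneSetCollection, RankedList, bh_adjust, enrichment_score,
                        filter_gene_set, nes_and_pvalue, permutation_null,
                        run_enrichment)
from crossclust.enrichment import _es_batch, pair_rng


def naive_es(genes, scores, members, weight=1.0):
    """Independent brute-force oracle, recomputing both running sums
    from their definitions at every position (naive, quadratic)."""
    n = len(genes)
    hits = [g in members for g in genes]
    k = sum(hits)
    n_r = sum(abs(scores[i]) ** weight for i in range(n) if hits[i])
    if n_r == 0:
        weights = [1.0] * n
        n_r = float(k)
    else:
        weights = [abs(s) ** weight for s in scores]
    best, best_abs = 0.0, -1.0
    for i in range(n):
        p_hit = sum(weights[j] for j in range(i + 1) if hits[j]) / n_r
        p_miss = sum(1 for j in range(i + 1) if not hits[j]) / (n - k)
        dev = p_hit - p_miss
        if abs(dev) > best_abs:
            best_abs, best = abs(dev), dev
    return best


def _random_instance(rng, n_max=50, k_max=10):
    n = int(rng.integers(5, n_max + 1))
    k = int(rng.integers(1, min(k_max, n - 1) + 1))
    genes = [f"g{i:03d}" for i in range(n)]
    scores = rng.normal(size=n)
    ranked = RankedList.from_scores(zip(genes, scores))
    members = set(rng.choice(ranked.genes, size=k, replace=False))
    return ranked, members


class TestEnrichmentScore:
    def test_single_top_hit_es_plus_one(self):
        ranked = RankedList.from_scores({"g1": 2.0, "g2": 1.0, "g3": -1.0, "g4": -2.0})
        es, le = enrichment_score(ranked, ["g1"])
        assert es == 1.0 and le == ["g1"]

    def test_single_bottom_hit_es_minus_one(self):
        ranked = RankedList.from_scores({"g1": 2.0, "g2": 1.0, "g3": -1.0, "g4": -2.0})
        es, le = enrichment_score(ranked, ["g4"])
        assert es == -1.0 and le == ["g4"]

    def test_uniform_scores_two_thirds(self):
        ranked = RankedList.from_scores({"g1": 1.0, "g2": 1.0, "g3": 1.0, "g4": 1.0})
        es, _ = enrichment_score(ranked, ["g2"])
        assert es == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_set_equals_universe_rejected(self):
        ranked = RankedList.from_scores({"g1": 2.0, "g2": 1.0})
        with pytest.raises(ValueError, match="universe"):
            enrichment_score(ranked, ["g1", "g2"])

    def test_empty_intersection_rejected(self):
        ranked = RankedList.from_scores({"g1": 2.0, "g2": 1.0})
        with pytest.raises(ValueError, match="empty"):
            enrichment_score(ranked, ["zz"])

    def test_all_zero_member_scores_uniform_fallback(self):
        ranked = RankedList.from_scores({"g1": 2.0, "g2": 0.0, "g3": 0.0, "g4": -1.0})
        es, _ = enrichment_score(ranked, ["g2"])
        oracle = naive_es(ranked.genes, list(ranked.scores), {"g2"})
        assert es == pytest.approx(oracle, abs=1e-12)

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ranked, members = _random_instance(rng)
            es, _ = enrichment_score(ranked, members)
            assert es == pytest.approx(
                naive_es(ranked.genes, list(ranked.scores), members), abs=1e-12)

    def test_antisymmetry_under_list_reversal(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ranked, members = _random_instance(rng)
            es, _ = enrichment_score(ranked, members)
            flipped = RankedList.from_scores(
                [(g, -s) for g, s in ranked.entries])
            es_rev, _ = enrichment_score(flipped, members)
            assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_leading_edge_subset_of_set(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            ranked, members = _random_instance(rng)
            es, le = enrichment_score(ranked, members)
            assert set(le) <= members
            assert abs(es) <= 1.0 + 1e-12


class TestBatchES:
    def test_batch_matches_single(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            ranked, members = _random_instance(rng)
            absw = np.abs(ranked.scores)
            pos = np.sort([ranked.genes.index(g) for g in members])[None, :]
            es_b = _es_batch(absw, pos, len(ranked))[0]
            es, _ = enrichment_score(ranked, members)
            assert es_b == pytest.approx(es, abs=1e-12)


class TestFilterGeneSet:
    UNIVERSE = [f"g{i:03d}" for i in range(600)]

    def test_size_14_rejected(self):
        assert filter_gene_set(self.UNIVERSE[:14], self.UNIVERSE, 15, 500) is None

    def test_size_15_kept(self):
        assert filter_gene_set(self.UNIVERSE[:15], self.UNIVERSE, 15, 500) is not None

    def test_size_500_kept(self):
        assert filter_gene_set(self.UNIVERSE[:500], self.UNIVERSE, 15, 500) is not None

    def test_size_501_rejected(self):
        assert filter_gene_set(self.UNIVERSE[:501], self.UNIVERSE, 15, 500) is None

    def test_intersection_before_threshold(self):
        # nominal 20 members but only 14 in the universe -> rejected
        members = self.UNIVERSE[:14] + [f"x{i}" for i in range(6)]
        assert filter_gene_set(members, self.UNIVERSE, 15, 500) is None

    def test_bad_window(self):
        with pytest.raises(ValueError):
            filter_gene_set(self.UNIVERSE[:20], self.UNIVERSE, 10, 5)


class TestPermutationNull:
    def test_determinism(self):
        ranked = RankedList.from_scores(
            {f"g{i:02d}": float(s) for i, s in
             enumerate(np.random.default_rng(0).normal(size=30))})
        a = permutation_null(ranked, 5, 200, seed=9)
        b = permutation_null(ranked, 5, 200, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_bounds(self):
        ranked = RankedList.from_scores(
            {f"g{i:02d}": float(s) for i, s in
             enumerate(np.random.default_rng(1).normal(size=25))})
        null = permutation_null(ranked, 4, 300, seed=0)
        assert np.all(np.abs(null) <= 1.0 + 1e-12)

    def test_n_perm_minimum(self):
        ranked = RankedList.from_scores({"g1": 1.0, "g2": 0.5, "g3": -0.5})
        with pytest.raises(ValueError):
            permutation_null(ranked, 1, 50)

    def test_matches_exhaustive_enumeration(self):
        ranked = RankedList.from_scores({"g1": 2.0, "g2": 1.0, "g3": -0.5, "g4": -2.0})
        exact = sorted(enrichment_score(ranked, list(pair))[0]
                       for pair in itertools.combinations(ranked.genes, 2))
        null = permutation_null(ranked, 2, 6000, seed=3)
        # every sampled ES is one of the 6 enumerated values
        assert all(any(abs(e - x) < 1e-9 for x in exact) for e in null)
        for x in set(exact):
            freq = np.mean([abs(e - x) < 1e-9 for e in null])
            expected = sum(abs(v - x) < 1e-9 for v in exact) / 6
            assert freq == pytest.approx(expected, abs=0.03)


class TestNesAndPvalue:
    def test_boundary_add_one(self):
        null = np.full(499, 0.4)
        nes, p = nes_and_pvalue(0.8, null)
        assert p == pytest.approx(1 / 500)
        assert nes == pytest.approx(2.0)

    def test_zero_es(self):
        assert nes_and_pvalue(0.0, np.array([0.1, -0.2])) == (0.0, 1.0)

    def test_empty_same_sign_subset(self):
        nes, p = nes_and_pvalue(0.5, np.array([-0.1, -0.2, -0.3]))
        assert math.isnan(nes)
        assert p == pytest.approx(1 / 4)

    def test_p_never_zero(self):
        rng = np.random.default_rng(23)
        null = rng.normal(scale=0.2, size=999)
        _, p = nes_and_pvalue(0.99, null)
        assert p >= 1 / 1000


class TestBHAdjust:
    def test_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(p=st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=1, max_size=30))
    def test_bounds_property(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)


class TestRunEnrichment:
    def _inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(80)]
        ranked = {t: RankedList.from_scores(
            {g: float(s) for g, s in zip(genes, rng.normal(size=80))})
            for t in ["t1", "t2"]}
        sets = GeneSetCollection(sets={
            "s1": list(rng.choice(genes, 20, replace=False)),
            "s2": list(rng.choice(genes, 25, replace=False)),
            "tiny": list(rng.choice(genes, 5, replace=False)),
        })
        return sets, ranked

    def test_results_and_rejections_cover_pairs(self):
        sets, ranked = self._inputs()
        results, rejections = run_enrichment(sets, ranked, n_perm=100, seed=1)
        pairs = {(r.source_cluster, r.target_cluster) for r in results}
        rej = {(r.source_cluster, r.target_cluster) for r in rejections}
        assert rej == {("tiny", "t1"), ("tiny", "t2")}
        assert pairs == {("s1", "t1"), ("s1", "t2"), ("s2", "t1"), ("s2", "t2")}

    def test_order_independence_of_pair_streams(self):
        sets, ranked = self._inputs()
        fwd, _ = run_enrichment(sets, ranked, n_perm=100, seed=5)
        rev, _ = run_enrichment(sets, dict(reversed(ranked.items())), n_perm=100, seed=5)
        by_pair_fwd = {(r.source_cluster, r.target_cluster): (r.es, r.nes, r.p) for r in fwd}
        by_pair_rev = {(r.source_cluster, r.target_cluster): (r.es, r.nes, r.p) for r in rev}
        assert by_pair_fwd == by_pair_rev

    def test_pair_rng_deterministic(self):
        a = pair_rng(3, "t", "s").random(4)
        b = pair_rng(3, "t", "s").random(4)
        np.testing.assert_array_equal(a, b)
        c = pair_rng(3, "t", "s2").random(4)
        assert not np.array_equal(a, c)

    def test_bh_scope_global(self):
        sets, ranked = self._inputs()
        results, _ = run_enrichment(sets, ranked, n_perm=100, seed=1, bh_scope="global")
        assert all(np.isfinite(r.padj) for r in results)
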