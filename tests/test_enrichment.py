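"""The weighted running-sum enrichment statistic, its permutation null,
and the hypergeometric over-representation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aneupipe.enrichment import (RankedList, _null_es, enrichment_score,
                                 gsea_permutation, leading_edge,
                                 ora_hypergeometric, rank_by_coefficient)


def es_oracle(scores, member, weight=1.0):
    """Independent brute-force running sum, computed step by step."""
    scores = np.asarray(scores, float)
    member = np.asarray(member, bool)
    n_hit = member.sum()
    n_miss = len(scores) - n_hit
    total = np.sum(np.abs(scores[member]) ** weight)
    running, acc = [], 0.0
    for s, m in zip(scores, member):
        acc += (abs(s) ** weight) / total if m else -1.0 / n_miss
        running.append(acc)
    running = np.asarray(running)
    mx, mn = running.max(), running.min()
    return (mx if abs(mx) >= abs(mn) else mn), running


def make_ranked(scores, prefix="g"):
    genes = [f"{prefix}{i}" for i in range(len(scores))]
    return RankedList(genes, np.asarray(scores, float))


class TestEnrichmentScore:
    def test_top_heavy_set_hand_computed(self):
        ranked = make_ranked([3, 2, 1, -1, -2])
        es, running = enrichment_score(ranked, {"g0", "g1"})
        assert es == pytest.approx(1.0)
        assert running == pytest.approx([0.6, 1.0, 2 / 3, 1 / 3, 0.0])

    def test_bottom_set_hand_computed(self):
        ranked = make_ranked([3, 2, 1, -1, -2])
        es, running = enrichment_score(ranked, {"g4"})
        assert es == pytest.approx(-1.0)
        assert running == pytest.approx([-0.25, -0.5, -0.75, -1.0, 0.0])

    def test_zero_score_hit_mass_rejected(self):
        ranked = make_ranked([2, 1, 0, -1, -2])
        with pytest.raises(ValueError, match="zero total hit mass"):
            enrichment_score(ranked, {"g2"})

    def test_full_or_disjoint_set_rejected(self):
        ranked = make_ranked([2, 1, -1])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"g0", "g1", "g2"})
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"absent"})

    def test_matches_oracle_on_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(5, 51))
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            member = np.zeros(n, bool)
            member[rng.choice(n, size=k, replace=False)] = True
            weight = float(rng.choice([0.0, 0.5, 1.0]))
            if np.sum(np.abs(scores[member]) ** weight) == 0:
                continue
            ranked = make_ranked(scores)
            gene_set = {g for g, m in zip(ranked.genes, member) if m}
            es, running = enrichment_score(ranked, gene_set, weight)
            es_ref, running_ref = es_oracle(scores, member, weight)
            assert es == pytest.approx(es_ref)
            assert running == pytest.approx(running_ref)

    def test_reversal_negates_unweighted_es(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = 20
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            members = set(rng.choice(n, size=k, replace=False).tolist())
            fwd = make_ranked(scores)
            rev = RankedList(fwd.genes[::-1], scores[::-1])
            gene_set = {f"g{i}" for i in members}
            es_f, run_f = enrichment_score(fwd, gene_set, weight=0.0)
            es_r, _ = enrichment_score(rev, gene_set, weight=0.0)
            assert abs(es_f) == pytest.approx(abs(es_r))
            if abs(run_f.max()) != pytest.approx(abs(run_f.min())):
                # off exact extremum ties the sign must flip too
                assert es_f == pytest.approx(-es_r)

    def test_complement_set_has_opposite_extrema(self):
        """Unweighted, the complement's running sum is the negation of the
        set's, so their extrema swap sign."""
        rng = np.random.default_rng(2)
        n = 12
        scores = np.sort(rng.normal(size=n))[::-1]
        members = set(rng.choice(n, size=5, replace=False).tolist())
        ranked = make_ranked(scores)
        gene_set = {f"g{i}" for i in members}
        complement = set(ranked.genes) - gene_set
        _, run_a = enrichment_score(ranked, gene_set, weight=0.0)
        _, run_b = enrichment_score(ranked, complement, weight=0.0)
        assert run_a.max() == pytest.approx(-run_b.min())
        assert run_a.min() == pytest.approx(-run_b.max())

    def test_fast_null_formula_matches_full_running_sum(self):
        """The hit-position-only ES used for the permutation null equals
        the full running-sum computation for arbitrary subsets."""
        rng = np.random.default_rng(3)
        n = 30
        scores = np.sort(rng.normal(size=n))[::-1]
        ranked = make_ranked(scores)
        for k in (1, 3, 10, 29):
            null = _null_es(scores, k, 50, 1.0,
                            np.random.default_rng(99))
            check_rng = np.random.default_rng(99)
            pos = np.argsort(check_rng.random((50, n)), axis=1)[:, :k]
            pos.sort(axis=1)
            for row in range(50):
                gene_set = {f"g{i}" for i in pos[row]}
                es, run = enrichment_score(ranked, gene_set, 1.0)
                assert abs(null[row]) == pytest.approx(abs(es))
                if abs(run.max()) != pytest.approx(abs(run.min())):
                    assert null[row] == pytest.approx(es)


class TestRankByCoefficient:
    def make_records(self, beta2, flags=None):
        genes = list(beta2)
        return pd.DataFrame({
            "beta2": [beta2[g] for g in genes],
            "flag": ["" for _ in genes] if flags is None
            else [flags.get(g, "") for g in genes],
        }, index=pd.Index(genes, name="gene"))

    def test_descending_order(self):
        ranked = rank_by_coefficient(
            self.make_records({"a": 2.0, "b": -1.0, "c": 0.5}))
        assert ranked.genes == ["a", "c", "b"]

    def test_ties_broken_lexicographically(self):
        ranked = rank_by_coefficient(
            self.make_records({"zz": 1.0, "aa": 1.0, "mm": 1.0}))
        assert ranked.genes == ["aa", "mm", "zz"]

    def test_flagged_records_excluded(self):
        ranked = rank_by_coefficient(
            self.make_records({"a": 2.0, "b": 1.0},
                              flags={"b": "separation"}))
        assert ranked.genes == ["a"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_by_coefficient(self.make_records({}))


class TestGseaPermutation:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        ranked = make_ranked(np.sort(rng.normal(size=100))[::-1])
        sets = {"s1": [f"g{i}" for i in range(0, 30, 3)],
                "s2": [f"g{i}" for i in range(50, 80, 2)]}
        a = gsea_permutation(ranked, sets, nperm=200, seed=5)
        b = gsea_permutation(ranked, sets, nperm=200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_top_set_significant(self):
        rng = np.random.default_rng(6)
        scores = np.sort(rng.normal(size=200))[::-1] + \
            np.linspace(2, 0, 200)
        ranked = make_ranked(scores)
        sets = {"planted": [f"g{i}" for i in range(12)]}
        sets.update({f"rand{j}": [f"g{i}" for i in
                                  rng.choice(200, 12, replace=False)]
                     for j in range(10)})
        res = gsea_permutation(ranked, sets, nperm=1000, seed=7)
        assert res.loc["planted", "es"] > 0
        assert res.loc["planted", "q"] < 0.05

    def test_small_set_flagged(self):
        ranked = make_ranked(np.arange(50, 0, -1, dtype=float))
        res = gsea_permutation(ranked, {"tiny": ["g1", "g2"]}, nperm=100,
                               seed=0)
        assert res.loc["tiny", "flag"] == "size"
        assert np.isnan(res.loc["tiny", "es"])

    def test_p_floor_and_nes_sign(self):
        rng = np.random.default_rng(8)
        ranked = make_ranked(np.sort(rng.normal(size=80))[::-1])
        sets = {f"s{j}": [f"g{i}" for i in rng.choice(80, 10,
                                                      replace=False)]
                for j in range(5)}
        res = gsea_permutation(ranked, sets, nperm=200, seed=9)
        ok = res[res["flag"] == ""]
        assert (ok["p_perm"] >= 1.0 / 201).all()
        assert (np.sign(ok["nes"]) == np.sign(ok["es"])).all()
        assert (ok["es"].abs() <= 1.0).all()

    def test_null_p_calibration(self):
        """Random sets on random scores: the permutation p rejects at
        roughly its nominal rate."""
        rng = np.random.default_rng(10)
        ranked = make_ranked(np.sort(rng.normal(size=300))[::-1])
        sets = {f"s{j}": [f"g{i}" for i in rng.choice(300, 10,
                                                      replace=False)]
                for j in range(150)}
        res = gsea_permutation(ranked, sets, nperm=400, seed=11)
        rate = (res["p_perm"] < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 150) + 0.01

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """On an 8-gene list every k-subset is enumerable, so the
        Monte-Carlo tail must sit within sampling error of the exact
        same-sign tail."""
        rng = np.random.default_rng(12)
        scores = np.sort(rng.normal(size=8))[::-1]
        ranked = make_ranked(scores)
        for k in (2, 3):
            gene_set = set(ranked.genes[:k])           # top-k set
            es_obs, _ = enrichment_score(ranked, gene_set)
            null = []
            for combo in itertools.combinations(range(8), k):
                subset = {f"g{i}" for i in combo}
                es, _ = enrichment_score(ranked, subset)
                null.append(es)
            null = np.asarray(null)
            same = null[null >= 0] if es_obs >= 0 else null[null < 0]
            exact = np.mean(np.abs(same) >= abs(es_obs))
            res = gsea_permutation(ranked, {"s": sorted(gene_set)},
                                   nperm=4000, seed=13, min_size=k)
            mc = res.loc["s", "p_perm"]
            se = np.sqrt(max(exact * (1 - exact), 0.01) / 4000)
            assert abs(mc - exact) < 3 * se + 2 / 4000

    def test_leading_edge_subset_of_set(self):
        ranked = make_ranked([3, 2, 1, -1, -2])
        gene_set = {"g0", "g1", "g3"}
        es, running = enrichment_score(ranked, gene_set)
        le = leading_edge(ranked, gene_set, running, es)
        assert set(le) <= gene_set
        assert le == ["g0", "g1"]


class TestOra:
    def test_no_overlap_p_near_one(self):
        universe = {f"g{i}" for i in range(1000)}
        res = ora_hypergeometric({"g1", "g2"}, universe,
                                 {"s": ["g900", "g901", "g902"]})
        assert res.loc["s", "p"] > 0.99

    def test_complete_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(1000)}
        hits = {f"g{i}" for i in range(10)}
        res = ora_hypergeometric(hits, universe, {"s": sorted(hits)})
        expected = stats.hypergeom.sf(9, 1000, 10, 10)
        assert res.loc["s", "p"] == pytest.approx(expected)
        assert res.loc["s", "overlap"] == 10

    def test_uniform_under_random_hits(self):
        rng = np.random.default_rng(14)
        universe = {f"g{i}" for i in range(200)}
        gene_set = {f"g{i}" for i in range(40)}
        ps = []
        for _ in range(200):
            hits = {f"g{i}" for i in rng.choice(200, 30, replace=False)}
            ps.append(ora_hypergeometric(hits, universe,
                                         {"s": sorted(gene_set)})
                      .loc["s", "p"])
        # discrete p-values are super-uniform: check the rejection rate
        # does not exceed nominal by more than sampling error
        assert (np.asarray(ps) < 0.05).mean() < 0.05 + \
            3 * np.sqrt(0.05 * 0.95 / 200)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(set(), set(), {"s": ["g1"]})
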