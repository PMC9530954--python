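"""Enrichment: running-sum oracles, permutation nulls, hubs, ORA."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adsubtypes import gsea
from adsubtypes.errors import ConfigError


def make_ranked(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    order = np.argsort([-s for s in scores], kind="stable")
    return gsea.RankedList(
        genes=[genes[i] for i in order],
        scores=np.array(sorted(scores, reverse=True), dtype=float),
        metric="given",
    )


def es_oracle(ranked, members, weight):
    """Independent position-by-position walk of the running sum."""
    hits = [g in set(members) for g in ranked.genes]
    n = len(hits)
    nh = sum(hits)
    total = sum(abs(s) ** weight for s, h in zip(ranked.scores, hits) if h)
    running, cur, best = [], 0.0, 0.0
    for s, h in zip(ranked.scores, hits):
        if h:
            cur += (abs(s) ** weight) / total if total > 0 else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        running.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best, running


class TestRankMetric:
    def test_signal_to_noise_direct_formula(self):
        matrix = pd.DataFrame(
            [[3.0, 4.0, 5.0, 1.0, 2.0, 3.0]],
            index=["g1"],
            columns=list("abcdef"),
        )
        ranked = gsea.rank_metric(matrix, ["a", "b", "c"], ["d", "e", "f"])
        # means 4 and 2, sds 1 and 1 (floor 0.2*|mean| inactive) -> (4-2)/2 = 1
        assert ranked.scores[0] == pytest.approx(1.0)

    def test_sd_floor_guards_small_variances(self):
        # sds 0.5 with means 4 and 2: floors 0.8 and 0.4 -> (4-2)/(0.8+0.5)
        matrix = pd.DataFrame(
            [[4.0, 4.5, 3.5, 2.0, 2.5, 1.5]],
            index=["g1"],
            columns=list("abcdef"),
        )
        ranked = gsea.rank_metric(matrix, ["a", "b", "c"], ["d", "e", "f"])
        assert ranked.scores[0] == pytest.approx(2.0 / 1.3)

    def test_identical_groups_zero_metric_id_tiebreak(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, size=(5, 3))
        matrix = pd.DataFrame(
            np.hstack([base, base]),
            index=["gE", "gA", "gC", "gB", "gD"],
            columns=list("abcdef"),
        )
        ranked = gsea.rank_metric(matrix, ["a", "b", "c"], ["d", "e", "f"])
        np.testing.assert_allclose(ranked.scores, 0.0)
        assert ranked.genes == sorted(ranked.genes)

    def test_zero_sd_floored_no_division_error(self):
        matrix = pd.DataFrame(
            [[10.0] * 6], index=["g1"], columns=list("abcdef")
        )
        ranked = gsea.rank_metric(matrix, ["a", "b", "c"], ["d", "e", "f"])
        assert ranked.scores[0] == 0.0

    def test_small_group_rejected_with_name(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"], columns=list("abcd"))
        with pytest.raises(ConfigError, match="group_b"):
            gsea.rank_metric(matrix, ["a", "b", "c"], ["d"])


class TestEnrichmentScore:
    def test_top_two_of_five_unweighted_walk(self):
        ranked = make_ranked([5, 4, 3, 2, 1])
        es, running = gsea.enrichment_score(ranked, ["g0", "g1"], weight=0)
        assert es == pytest.approx(1.0)
        np.testing.assert_allclose(running, [0.5, 1.0, 1.0 - 1 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_bottom_two_mirror_case(self):
        ranked = make_ranked([5, 4, 3, 2, 1])
        es, _ = gsea.enrichment_score(ranked, ["g3", "g4"], weight=0)
        assert es == pytest.approx(-1.0)

    @given(
        st.integers(4, 12),
        st.integers(1, 6),
        st.integers(0, 10_000),
        st.sampled_from([0.0, 1.0]),
    )
    def test_matches_independent_walk_oracle(self, n, set_size, seed, weight):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, size=n)
        ranked = make_ranked(list(scores))
        members = list(rng.choice(ranked.genes, size=min(set_size, n - 1), replace=False))
        es, running = gsea.enrichment_score(ranked, members, weight=weight)
        es_ref, running_ref = es_oracle(ranked, members, weight)
        assert es == pytest.approx(es_ref, abs=1e-12)
        np.testing.assert_allclose(running, running_ref, atol=1e-12)

    def test_running_sum_returns_to_zero(self):
        rng = np.random.default_rng(5)
        ranked = make_ranked(list(rng.normal(0, 2, size=50)))
        _, running = gsea.enrichment_score(ranked, ranked.genes[3:10], weight=1.0)
        assert abs(running[-1]) <= 1e-9

    def test_positive_rescaling_leaves_es_unchanged(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(0, 1, size=20)
        members = [f"g{i}" for i in (1, 4, 7, 11)]
        for weight in (0.0, 1.0):
            es1, _ = gsea.enrichment_score(make_ranked(list(scores)), members, weight)
            es2, _ = gsea.enrichment_score(make_ranked(list(scores * 7.5)), members, weight)
            assert es1 == pytest.approx(es2, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        ranked = make_ranked([3, 2, 1])
        with pytest.raises(ConfigError):
            gsea.enrichment_score(ranked, ranked.genes)
        with pytest.raises(ConfigError):
            gsea.enrichment_score(ranked, ["not_there"])


class TestSignificance:
    def _matrix(self, seed=0, n_genes=30, shift_genes=8, n_per=3, effect=2.0):
        rng = np.random.default_rng(seed)
        cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
        vals = rng.normal(0, 1, size=(n_genes, 2 * n_per))
        vals[:shift_genes, :n_per] += effect
        return pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=cols), cols

    def test_three_vs_three_enumerates_all_twenty_splits(self):
        matrix, cols = self._matrix(seed=1)
        res = gsea.gsea_significance(
            matrix, cols[:3], cols[3:], [f"g{i}" for i in range(8)],
            n_permutations=20, seed=1,
        )
        assert res.exhaustive
        assert len(res.es_permuted) == comb(6, 3)
        # p computed over the full enumeration (add-one smoothed)
        assert 0 < res.p_nominal <= 1

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(2)
        n_per = 20
        cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
        vals = rng.normal(0, 0.5, size=(100, 2 * n_per))
        vals[:15, :n_per] += 1.0
        matrix = pd.DataFrame(vals, index=[f"g{i}" for i in range(100)], columns=cols)
        res = gsea.gsea_significance(
            matrix, cols[:n_per], cols[n_per:], [f"g{i}" for i in range(15)],
            n_permutations=99, seed=2,
        )
        assert res.es > 0
        assert res.p_nominal <= 0.05
        assert res.nes > 1

    def test_null_labels_give_uniformish_p(self):
        ps = []
        for seed in range(10):
            matrix, cols = self._matrix(seed=seed, shift_genes=0, n_per=10, effect=0)
            res = gsea.gsea_significance(
                matrix, cols[:10], cols[10:], [f"g{i}" for i in range(6)],
                n_permutations=49, seed=seed,
            )
            ps.append(res.p_nominal)
        assert min(ps) > 0.001
        assert np.mean(ps) > 0.2


class TestLeadingEdgeAndHubs:
    def test_leading_edge_of_top_two_case(self):
        ranked = make_ranked([5, 4, 3, 2, 1])
        es, running = gsea.enrichment_score(ranked, ["g0", "g1"], weight=0)
        res = gsea.GseaResult("s", es, 0, 0, 0, [], running)
        assert gsea.leading_edge(res, ranked, ["g0", "g1"]) == ["g0", "g1"]

    def test_negative_es_mirror_leading_edge(self):
        ranked = make_ranked([5, 4, 3, 2, 1])
        es, running = gsea.enrichment_score(ranked, ["g3", "g4"], weight=0)
        res = gsea.GseaResult("s", es, 0, 0, 0, [], running)
        assert gsea.leading_edge(res, ranked, ["g3", "g4"]) == ["g3", "g4"]

    def test_member_after_peak_excluded(self):
        ranked = make_ranked([5, 4, 3, 2, 1])
        members = ["g0", "g4"]  # g4 ranks after the running-sum peak
        es, running = gsea.enrichment_score(ranked, members, weight=0)
        res = gsea.GseaResult("s", es, 0, 0, 0, [], running)
        le = gsea.leading_edge(res, ranked, members)
        assert "g0" in le and "g4" not in le

    def test_hub_selection_caps_at_k_and_orders_by_metric(self):
        scores = list(np.linspace(5, 0.5, 15))
        ranked = make_ranked(scores)
        members = ranked.genes[:15]
        with pytest.raises(ConfigError):
            gsea.enrichment_score(ranked, members)  # covers whole list
        ranked = make_ranked(scores + [-1.0] * 5)
        members = ranked.genes[:15]
        es, running = gsea.enrichment_score(ranked, members, weight=1)
        res = gsea.GseaResult("s", es, 0, 0, 0, [], running)
        res.leading_edge = gsea.leading_edge(res, ranked, members)
        hubs = gsea.select_hub_genes(res, ranked, k=10)
        assert len(hubs) == 10
        mags = [abs(s) for _, s in hubs]
        assert mags == sorted(mags, reverse=True)

    def test_hub_selection_takes_all_when_fewer_than_k(self):
        ranked = make_ranked([5, 4, 3, 2, 1, -1, -2])
        members = ranked.genes[:4]
        es, running = gsea.enrichment_score(ranked, members, weight=1)
        res = gsea.GseaResult("s", es, 0, 0, 0, [], running)
        res.leading_edge = gsea.leading_edge(res, ranked, members)
        hubs = gsea.select_hub_genes(res, ranked, k=10)
        assert len(hubs) == len(res.leading_edge) <= 4

    def test_equal_metric_ties_break_by_gene_id(self):
        ranked = gsea.RankedList(
            genes=["gA", "gB", "gC", "gD"],
            scores=np.array([2.0, 2.0, 1.0, -1.0]),
            metric="given",
        )
        es, running = gsea.enrichment_score(ranked, ["gA", "gB"], weight=1)
        res = gsea.GseaResult("s", es, 0, 0, 0, [], running)
        res.leading_edge = gsea.leading_edge(res, ranked, ["gA", "gB"])
        hubs1 = gsea.select_hub_genes(res, ranked, k=1)
        hubs2 = gsea.select_hub_genes(res, ranked, k=1)
        assert hubs1 == hubs2 == [("gA", 2.0)]


def ora_oracle(universe, set_size, selected, overlap):
    total = comb(universe, selected)
    favourable = sum(
        comb(set_size, k) * comb(universe - set_size, selected - k)
        for k in range(overlap, min(set_size, selected) + 1)
    )
    return favourable / total


class TestOra:
    def _collection(self, genes):
        from adsubtypes.io import GeneSet, GeneSetCollection

        return GeneSetCollection({"s": GeneSet("s", "", tuple(genes))})

    def test_exact_tail_sum_example(self):
        universe = [f"u{i}" for i in range(20)]
        gene_set = universe[:5]
        selected = universe[2:5] + universe[10:12]  # overlap 3
        res = gsea.ora_test(selected, self._collection(gene_set), universe)
        assert res.loc["s", "overlap"] == 3
        assert res.loc["s", "p"] == pytest.approx(1126 / 15504, abs=1e-12)
        assert res.loc["s", "p"] == pytest.approx(ora_oracle(20, 5, 5, 3), abs=1e-12)

    def test_zero_overlap_p_at_most_one(self):
        universe = [f"u{i}" for i in range(30)]
        res = gsea.ora_test(universe[10:12], self._collection(universe[:3]), universe)
        assert res.loc["s", "overlap"] == 0
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_selected_equals_set_matches_bruteforce(self):
        universe = [f"u{i}" for i in range(12)]
        gene_set = universe[:4]
        res = gsea.ora_test(gene_set, self._collection(gene_set), universe)
        assert res.loc["s", "p"] == pytest.approx(ora_oracle(12, 4, 4, 4), abs=1e-14)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ConfigError):
            gsea.ora_test(["x"], self._collection(["u0"]), ["u0", "u1"])
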