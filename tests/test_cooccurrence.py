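"""Pair similarity, greedy phrase clustering and the word network."""

import math

import pytest

import annocloud as ac
from annocloud.errors import InvalidThreshold
from oracles import brute_greedy_cluster, brute_pair_similarities, random_corpus


def corpus_of(texts_by_node):
    return ac.build_corpus(
        [ac.RawDocument(n, [t] if isinstance(t, str) else t)
         for n, t in texts_by_node.items()]
    )


def sims_of(corpus, selection):
    stats = ac.count_words(corpus, selection)
    return {
        (p.first, p.second): p
        for p in ac.pair_scores(corpus, selection, stats)
    }


class TestPairSimilarity:
    def test_single_document_saturation(self):
        corpus = corpus_of({"A": "aq bq"})
        sims = sims_of(corpus, {"A"})
        assert sims[("aq", "bq")].similarity == 1.0
        assert sims[("aq", "bq")].n_joint == 1

    def test_four_node_hand_enumeration(self):
        # "aq bq" adjacent in 2 of 4 nodes; aq present in 2, bq in all 4
        corpus = corpus_of(
            {"1": "aq bq", "2": "aq bq", "3": "bq cq", "4": "cq bq"}
        )
        sims = sims_of(corpus, set("1234"))
        p = sims[("aq", "bq")]
        assert p.n_joint == 2
        assert p.similarity == pytest.approx((2 / 4) / ((2 / 4) * (4 / 4)))

    def test_half_and_half_construction(self):
        n = 5
        texts = {f"P{i}": "aq bq" for i in range(n)}
        texts.update({f"Q{i}": "bq" for i in range(n)})
        corpus = corpus_of(texts)
        sims = sims_of(corpus, set(texts))
        assert sims[("aq", "bq")].similarity == pytest.approx(1.0)

    def test_adjacency_never_spans_attribute_boundaries(self):
        corpus = corpus_of({"A": ["aq bq", "cq dq"]})
        sims = sims_of(corpus, {"A"})
        assert ("bq", "cq") not in sims
        assert ("aq", "bq") in sims and ("cq", "dq") in sims

    def test_order_matters(self):
        corpus = corpus_of({"A": "aq bq", "B": "bq aq"})
        sims = sims_of(corpus, {"A", "B"})
        assert sims[("aq", "bq")].n_joint == 1
        assert sims[("bq", "aq")].n_joint == 1

    def test_matches_brute_force_on_random_corpora(self):
        for seed in range(60):
            corpus, selection = random_corpus(seed)
            expected_sims, expected_joint = brute_pair_similarities(
                corpus, selection
            )
            got = sims_of(corpus, selection)
            assert set(got) == set(expected_sims)
            for pair, p in got.items():
                assert p.similarity == pytest.approx(expected_sims[pair])
                assert p.n_joint == expected_joint[pair]

    def test_similarity_bounded_by_selection_size(self):
        for seed in range(60):
            corpus, selection = random_corpus(seed)
            stats = ac.count_words(corpus, selection)
            for p in ac.pair_scores(corpus, selection, stats):
                assert 0 < p.similarity <= stats.sel_tot
                assert p.n_joint >= 1

    def test_position_mode_on_hand_corpus(self):
        # one node "aq bq aq": slots (aq,bq),(bq,aq); tokens aq:2 bq:1 of 3
        corpus = corpus_of({"A": "aq bq aq"})
        stats = ac.count_words(corpus, {"A"})
        sims = {
            (p.first, p.second): p.similarity
            for p in ac.pair_scores(corpus, {"A"}, stats, pair_prob="position")
        }
        expected = (1 / 2) / ((2 / 3) * (1 / 3))
        assert sims[("aq", "bq")] == pytest.approx(expected)
        assert sims[("bq", "aq")] == pytest.approx(expected)


class TestGreedyCluster:
    def test_threshold_too_high_yields_singletons_by_font(self):
        pairs = [ac.PairScore("aq", "bq", 1, 2.0)]
        sizes = {"aq": 20, "bq": 40, "cq": 30}
        cc = ac.greedy_cluster(pairs, sizes, sizes, threshold=10.0)
        assert cc.word_lists() == [["bq"], ["cq"], ["aq"]]

    def test_single_possible_merge(self):
        pairs = [ac.PairScore("origin", "recognit", 2, 1.5)]
        sizes = {"origin": 30, "recognit": 30}
        cc = ac.greedy_cluster(pairs, ["origin", "recognit"], sizes, 1.0)
        assert cc.word_lists() == [["origin", "recognit"]]

    def test_invalid_threshold(self):
        with pytest.raises(InvalidThreshold):
            ac.greedy_cluster([], ["aq"], {"aq": 12}, threshold=0.0)

    def test_chain_merge_preserves_order(self):
        pairs = [
            ac.PairScore("aq", "bq", 3, 3.0),
            ac.PairScore("bq", "cq", 2, 2.0),
        ]
        sizes = {"aq": 12, "bq": 12, "cq": 12}
        cc = ac.greedy_cluster(pairs, sizes, sizes, 1.0)
        assert cc.word_lists() == [["aq", "bq", "cq"]]

    def test_merged_word_reachable_only_via_cluster_ends(self):
        # after (aq,bq) merges, the pair (xq,aq) needs aq first-of-cluster;
        # aq is, so [xq, aq, bq]; but (yq,bq) can no longer fire.
        pairs = [
            ac.PairScore("aq", "bq", 5, 5.0),
            ac.PairScore("xq", "aq", 1, 2.0),
            ac.PairScore("yq", "bq", 1, 3.0),
        ]
        words = ["aq", "bq", "xq", "yq"]
        sizes = dict.fromkeys(words, 12)
        cc = ac.greedy_cluster(pairs, words, sizes, 1.0)
        assert [sorted(c) for c in map(sorted, cc.word_lists())].count(["yq"]) == 1
        assert ["xq", "aq", "bq"] in cc.word_lists()

    def test_matches_brute_force_oracle_on_random_corpora(self):
        """Step-for-step equivalence with an independent implementation."""
        for seed in range(200):
            corpus, selection = random_corpus(seed)
            stats = ac.count_words(corpus, selection)
            if not stats.sel_w:
                continue
            cloud = ac.build_simple_cloud(corpus, selection)
            pairs = ac.pair_scores(corpus, selection, stats)
            for threshold in (0.5, 1.0, 2.0):
                cc = ac.greedy_cluster(
                    pairs, cloud.stems(), cloud.fonts(), threshold, cloud.scores()
                )
                expected = brute_greedy_cluster(
                    pairs, cloud.stems(), cloud.fonts(), threshold, cloud.scores()
                )
                assert cc.word_lists() == expected

    def test_partition_and_adjacency_conservation(self):
        for seed in range(100):
            corpus, selection = random_corpus(seed)
            stats = ac.count_words(corpus, selection)
            if not stats.sel_w:
                continue
            cloud = ac.build_simple_cloud(corpus, selection)
            pairs = ac.pair_scores(corpus, selection, stats)
            observed = {(p.first, p.second) for p in pairs}
            cc = ac.greedy_cluster(pairs, cloud.stems(), cloud.fonts(), 1.0)
            flat = [w for c in cc.word_lists() for w in c]
            assert sorted(flat) == sorted(cloud.stems())
            for cluster in cc.word_lists():
                for a, b in zip(cluster, cluster[1:]):
                    assert (a, b) in observed

    def test_threshold_monotonicity(self):
        for seed in range(60):
            corpus, selection = random_corpus(seed)
            stats = ac.count_words(corpus, selection)
            if not stats.sel_w:
                continue
            cloud = ac.build_simple_cloud(corpus, selection)
            pairs = ac.pair_scores(corpus, selection, stats)
            counts = [
                len(ac.greedy_cluster(pairs, cloud.stems(), cloud.fonts(), t).clusters)
                for t in (0.25, 0.5, 1.0, 2.0, 4.0)
            ]
            assert counts == sorted(counts)


class TestOrderClusters:
    def cluster(self, words, sizes, scores=None):
        return ac.WordCluster(
            list(words), list(sizes), list(scores or [0.0] * len(words))
        )

    def test_three_four_five_triangle(self):
        two = self.cluster(["aq", "bq"], [3, 4])
        one = self.cluster(["cq"], [4])
        assert ac.order_clusters([one, two]) == [two, one]

    def test_all_singletons_follow_font_order(self):
        cs = [self.cluster([w], [s]) for w, s in [("aq", 10), ("bq", 30), ("cq", 20)]]
        assert [c.words for c in ac.order_clusters(cs)] == [["bq"], ["cq"], ["aq"]]

    def test_norm_tie_prefers_more_words(self):
        one = self.cluster(["zq"], [5])
        two = self.cluster(["aq", "bq"], [3, 4])
        assert ac.order_clusters([one, two]) == [two, one]


class TestWordNetwork:
    def test_empty(self):
        g = ac.build_word_network([], [], {})
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_chain_has_adjacent_edges_only(self):
        corpus = corpus_of({"A": "aq bq cq"})
        stats = ac.count_words(corpus, {"A"})
        pairs = ac.pair_scores(corpus, {"A"}, stats)
        g = ac.build_word_network(pairs, stats.sel_w, {"aq": 12, "bq": 12, "cq": 12})
        assert sorted(g.edges) == [("aq", "bq"), ("bq", "cq")]
        assert not g.has_edge("aq", "cq")

    def test_bidirectional_pairs_collapse_keeping_both_directions(self):
        pairs = [
            ac.PairScore("aq", "bq", 2, 3.0),
            ac.PairScore("bq", "aq", 1, 1.5),
        ]
        g = ac.build_word_network(pairs, ["aq", "bq"], {"aq": 12, "bq": 20})
        assert g.number_of_edges() == 1
        d = g["aq"]["bq"]
        assert d["similarity"] == 3.0
        assert d["sim_forward"] == 3.0 and d["sim_reverse"] == 1.5
        assert d["n_joint"] == 3
        assert g.nodes["bq"]["size"] == 20

    def test_isolated_nodes_are_words_with_no_surviving_neighbour(self):
        for seed in range(40):
            corpus, selection = random_corpus(seed)
            stats = ac.count_words(corpus, selection)
            if not stats.sel_w:
                continue
            pairs = ac.pair_scores(corpus, selection, stats)
            sizes = dict.fromkeys(stats.sel_w, 12)
            g = ac.build_word_network(pairs, stats.sel_w, sizes)
            assert set(g.nodes) == set(stats.sel_w)
            paired = {p.first for p in pairs} | {p.second for p in pairs}
            for w in g.nodes:
                if w in paired:
                    assert g.degree(w) >= 1
                else:
                    assert g.degree(w) == 0
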