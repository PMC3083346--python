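"""Ordered word-pair similarity, greedy phrase clustering, word networks.

Every ordered pair of words that appear immediately next to each other in at
least one selected node's annotation gets a similarity score: the ratio of
the observed joint probability of the pair to the probability expected if
the two words occurred independently. Clusters are then grown greedily —
each word starts alone; the most similar eligible pair of clusters is
concatenated, where inter-cluster similarity is that of the last word of the
first cluster and the first word of the second, preserving left-to-right
phrase order — until no pair reaches the user threshold. Because this
clustering is non-overlapping, a word with several phrase partners shows
only one of them; the word-similarity network shows them all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .cloud_core import WordStats
from .errors import InvalidThreshold
from .text_pipeline import TokenisedCorpus

DEFAULT_THRESHOLD = 1.0


@dataclass(frozen=True)
class PairScore:
    """An ordered adjacent pair and its observed/expected probability ratio."""

    first: str
    second: str
    n_joint: int
    similarity: float


def pair_scores(
    corpus: TokenisedCorpus,
    selection: set[str],
    stats: WordStats,
    pair_prob: str = "node",
) -> list[PairScore]:
    """Score every ordered pair adjacent in at least one selected node.

    Adjacency is evaluated on the processed token stream (after stopword
    removal and stemming) and never spans an attribute-string boundary.

    ``pair_prob='node'`` (default) uses node-presence probabilities over the
    selection, consistent with the presence counts used for sizing:
    sim = (n_joint/sel_tot) / ((sel_w1/sel_tot) * (sel_w2/sel_tot)), with
    n_joint the number of selected nodes where ``first`` immediately precedes
    ``second``. ``pair_prob='position'`` instead uses adjacent-slot and
    token-occurrence probabilities.
    """
    if pair_prob not in ("node", "position"):
        raise ValueError(f"unknown pair_prob: {pair_prob!r}")
    docs = [corpus.documents[n] for n in sorted(selection)]

    if pair_prob == "node":
        n_joint: dict[tuple[str, str], int] = {}
        for doc in docs:
            seen: set[tuple[str, str]] = set()
            for seg in doc.segments():
                for a, b in zip(seg, seg[1:]):
                    seen.add((a, b))
            for pair in seen:
                n_joint[pair] = n_joint.get(pair, 0) + 1
        sel_tot = stats.sel_tot
        out = []
        for (a, b), n in sorted(n_joint.items()):
            p_joint = n / sel_tot
            p_a = stats.sel_w[a] / sel_tot
            p_b = stats.sel_w[b] / sel_tot
            out.append(PairScore(a, b, n, p_joint / (p_a * p_b)))
        return out

    # position mode: probabilities over adjacent slots / token occurrences
    slot_counts: dict[tuple[str, str], int] = {}
    tok_counts: dict[str, int] = {}
    n_slots = 0
    n_tokens = 0
    for doc in docs:
        for seg in doc.segments():
            n_tokens += len(seg)
            for t in seg:
                tok_counts[t] = tok_counts.get(t, 0) + 1
            n_slots += max(len(seg) - 1, 0)
            for a, b in zip(seg, seg[1:]):
                slot_counts[(a, b)] = slot_counts.get((a, b), 0) + 1
    out = []
    for (a, b), n in sorted(slot_counts.items()):
        p_joint = n / n_slots
        p_a = tok_counts[a] / n_tokens
        p_b = tok_counts[b] / n_tokens
        out.append(PairScore(a, b, n, p_joint / (p_a * p_b)))
    return out


@dataclass
class WordCluster:
    """An ordered run of words with their font-size (and raw-score) vectors."""

    words: list[str]
    size_vector: list[int]
    score_vector: list[float] = field(default_factory=list)

    @property
    def norm(self) -> float:
        """Euclidean length of the font-size vector."""
        return math.sqrt(sum(s * s for s in self.size_vector))


@dataclass
class ClusteredCloud:
    """Ordered clusters of ordered words; every cloud word appears once."""

    clusters: list[WordCluster]
    threshold: float
    entry_map: dict = field(default_factory=dict)  # stem -> CloudEntry

    def word_lists(self) -> list[list[str]]:
        return [list(c.words) for c in self.clusters]


def _cluster_sort_key(cluster: WordCluster):
    # norm desc, more words first, raw-score norm desc, then first stem.
    score_norm = math.sqrt(sum(s * s for s in cluster.score_vector))
    return (-cluster.norm, -len(cluster.words), -score_norm, cluster.words[0])


def order_clusters(clusters: Iterable[WordCluster]) -> list[WordCluster]:
    """Sort clusters by descending L2 norm of their word size vectors.

    Ties go to the cluster with more words, then the larger raw-score norm,
    then lexicographically by first stem — so an all-singleton clustering
    reproduces the simple layout's order exactly.
    """
    return sorted(clusters, key=_cluster_sort_key)


def greedy_cluster(
    pairs: Iterable[PairScore],
    words: Iterable[str],
    sizes: Mapping[str, int],
    threshold: float = DEFAULT_THRESHOLD,
    scores: Mapping[str, float] | None = None,
) -> ClusteredCloud:
    """Greedy order-preserving agglomeration of words into phrase clusters.

    Start from singletons; repeatedly merge the eligible cluster pair (A, B)
    — eligible when the ordered pair (last word of A, first word of B) was
    observed with similarity >= threshold — picking the highest similarity,
    ties broken by higher n_joint, then lexicographically on (first, second)
    stem. Merging concatenates A then B, preserving internal order.
    """
    if threshold <= 0:
        raise InvalidThreshold(f"threshold must be > 0, got {threshold}")
    scores = scores or {}
    eligible = {
        (p.first, p.second): p for p in pairs if p.similarity >= threshold
    }
    clusters: list[list[str]] = [[w] for w in sorted(set(words))]

    while True:
        best = None  # (key, i, j)
        for i, a in enumerate(clusters):
            for j, b in enumerate(clusters):
                if i == j:
                    continue
                p = eligible.get((a[-1], b[0]))
                if p is None:
                    continue
                key = (-p.similarity, -p.n_joint, p.first, p.second)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        merged = clusters[i] + clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)

    built = [
        WordCluster(c, [sizes[w] for w in c], [scores.get(w, 0.0) for w in c])
        for c in clusters
    ]
    return ClusteredCloud(order_clusters(built), threshold)


def build_word_network(
    pairs: Iterable[PairScore],
    words: Iterable[str],
    sizes: Mapping[str, int],
) -> nx.Graph:
    """Words as nodes (``size`` attribute), qualifying pairs as edges.

    When both orders (a, b) and (b, a) were observed the edge is collapsed
    to one undirected edge carrying the larger ``similarity``; the directed
    values survive as ``sim_forward``/``sim_reverse`` (forward = from the
    lexicographically smaller endpoint) alongside the summed ``n_joint``.
    """
    g = nx.Graph()
    for w in sorted(set(words)):
        g.add_node(w, size=int(sizes[w]))
    for p in sorted(pairs, key=lambda p: (p.first, p.second)):
        u, v = sorted((p.first, p.second))
        forward = p.first == u
        if g.has_edge(u, v):
            data = g[u][v]
            data["similarity"] = max(data["similarity"], p.similarity)
            data["sim_forward" if forward else "sim_reverse"] = p.similarity
            data["n_joint"] += p.n_joint
        else:
            g.add_edge(
                u,
                v,
                similarity=p.similarity,
                sim_forward=p.similarity if forward else 0.0,
                sim_reverse=0.0 if forward else p.similarity,
                n_joint=p.n_joint,
            )
    return g


def build_clustered_cloud(
    corpus: TokenisedCorpus,
    selection: set[str],
    k: float = 0.0,
    threshold: float = DEFAULT_THRESHOLD,
    min_font: int = 12,
    max_font: int = 64,
    count_mode: str = "presence",
    pair_prob: str = "node",
) -> ClusteredCloud:
    """Convenience pipeline: simple cloud -> pair scores -> greedy clusters."""
    from .cloud_core import build_simple_cloud, count_words

    cloud = build_simple_cloud(corpus, selection, k, min_font, max_font, count_mode)
    if not cloud.entries:
        return ClusteredCloud([], threshold)
    stats = count_words(corpus, selection, "presence")
    pairs = pair_scores(corpus, selection, stats, pair_prob)
    clustered = greedy_cluster(
        pairs, cloud.stems(), cloud.fonts(), threshold, cloud.scores()
    )
    clustered.entry_map = {e.stem: e for e in cloud.entries}
    return clustered
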