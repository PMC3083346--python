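"""Independent brute-force re-implementations used as test oracles.

These deliberately recompute everything from scratch with naive data
structures; they share no code with the package internals they check.
"""

from __future__ import annotations

import math
import random

from annocloud import RawDocument, TextConfig, build_corpus

VOCAB = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")


def random_corpus(seed, max_nodes=5, vocab=VOCAB, extra_network_nodes=2):
    """A small random corpus plus a random non-empty selection.

    Nodes carry 1-2 attribute strings of 0-6 vocabulary words each; a few
    extra non-selected nodes make the network strictly larger than the
    selection so network weighting has an effect.
    """
    rng = random.Random(seed)
    n_sel = rng.randint(1, max_nodes)
    n_extra = rng.randint(0, extra_network_nodes)
    docs = []
    for i in range(n_sel + n_extra):
        texts = [
            " ".join(rng.choice(vocab) for _ in range(rng.randint(0, 6)))
            for _ in range(rng.randint(1, 2))
        ]
        docs.append(RawDocument(f"N{i}", texts))
    corpus = build_corpus(docs, TextConfig())
    selection = {f"N{i}" for i in range(n_sel)}
    return corpus, selection


def brute_pair_similarities(corpus, selection):
    """Node-presence pair similarities by direct enumeration."""
    sel_docs = [corpus.documents[n] for n in selection]
    sel_tot = len(sel_docs)
    presence: dict[str, int] = {}
    joint: dict[tuple[str, str], int] = {}
    for doc in sel_docs:
        words = set()
        pairs_here = set()
        for seg in doc.segments():
            words.update(seg)
            for i in range(len(seg) - 1):
                pairs_here.add((seg[i], seg[i + 1]))
        for w in words:
            presence[w] = presence.get(w, 0) + 1
        for p in pairs_here:
            joint[p] = joint.get(p, 0) + 1
    sims = {}
    for (a, b), n in joint.items():
        sims[(a, b)] = (n / sel_tot) / ((presence[a] / sel_tot) * (presence[b] / sel_tot))
    return sims, joint


def brute_greedy_cluster(pairs, words, sizes, threshold, scores=None):
    """Step-for-step brute-force greedy clustering.

    Recomputes the full candidate list from scratch at every step, sorts it,
    and takes the head; returns ordered lists of word lists.
    """
    scores = scores or {}
    lookup = {}
    for p in pairs:
        if p.similarity >= threshold:
            lookup[(p.first, p.second)] = (p.similarity, p.n_joint)
    clusters = [(w,) for w in sorted(set(words))]
    while True:
        candidates = []
        for a in clusters:
            for b in clusters:
                if a is b:
                    continue
                hit = lookup.get((a[-1], b[0]))
                if hit is not None:
                    sim, nj = hit
                    candidates.append((-sim, -nj, a[-1], b[0], a, b))
        if not candidates:
            break
        candidates.sort()
        _, _, _, _, a, b = candidates[0]
        clusters = [c for c in clusters if c is not a and c is not b] + [a + b]

    def key(c):
        font_norm = math.sqrt(sum(sizes[w] ** 2 for w in c))
        score_norm = math.sqrt(sum(scores.get(w, 0.0) ** 2 for w in c))
        return (-font_norm, -len(c), -score_norm, c[0])

    return [list(c) for c in sorted(clusters, key=key)]
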