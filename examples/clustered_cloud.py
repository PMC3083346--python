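"""Group cloud words into phrase clusters by co-occurrence.

Every ordered pair of words adjacent in at least one selected node gets a
similarity score (observed joint probability over the probability expected
under independence); clusters grow greedily from the most similar pairs,
preserving left-to-right word order, until no pair reaches the threshold.
"""

import annocloud as ac

net, selection = ac.generate_fixture(seed=1)
corpus = ac.build_corpus(net.documents(["name"]))
selection = set(selection)

stats = ac.count_words(corpus, selection)
pairs = ac.pair_scores(corpus, selection, stats)
print("ordered adjacent pairs (n_joint = selected nodes where observed):")
for p in sorted(pairs, key=lambda p: -p.similarity):
    print(f"  {p.first:>14} -> {p.second:<14} n_joint={p.n_joint}  "
          f"similarity={p.similarity:.2f}")

cc = ac.build_clustered_cloud(corpus, selection, threshold=1.0)
print(f"\n{len(cc.clusters)} clusters at threshold {cc.threshold} "
      "(ordered by L2 norm of the font-size vector):")
for i, cluster in enumerate(cc.clusters, 1):
    phrase = " ".join(cc.entry_map[w].display for w in cluster.words)
    print(f"  {i}. [{phrase}]  norm={cluster.norm:.1f}")

# Similarity 2.0 means the pair co-occurs twice as often as independence
# predicts. Clustering is non-overlapping, so the shared words "complex
# component" end up in exactly one cluster — here with "minichromosome
# maintenance" — even though they also follow "origin recognition".
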