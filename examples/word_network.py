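"""Export the word-similarity network, which shows every phrase partner.

Unlike the non-overlapping clustered layout, the word network represents
each word as a node (sized by frequency) and each qualifying ordered pair
as an edge carrying the similarity score, so a word shared by several
phrases shows all of its associations.
"""

from pathlib import Path

import annocloud as ac

net, selection = ac.generate_fixture(seed=1)
corpus = ac.build_corpus(net.documents(["name"]))
selection = set(selection)

stats = ac.count_words(corpus, selection)
cloud = ac.build_simple_cloud(corpus, selection)
pairs = ac.pair_scores(corpus, selection, stats)
g = ac.build_word_network(pairs, cloud.stems(), cloud.fonts())

print(f"word network: {g.number_of_nodes()} words, {g.number_of_edges()} edges")
for u, v, d in sorted(g.edges(data=True)):
    print(f"  {u:>14} -- {v:<14} similarity={d['similarity']:.2f}")
print(f"\nneighbours of 'complex': {sorted(g.neighbors('complex'))}")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
ac.write_word_network(g, out / "word_network.graphml")
print(f"wrote {out / 'word_network.graphml'} (node size + edge similarity "
      "as GraphML data keys)")

# 'complex' neighbours both 'recognit' (origin recognition ...) and
# 'mainten' (minichromosome maintenance ...): the network layout shows both
# phrase contexts at once.
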