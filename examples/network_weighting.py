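"""Show how the normalization coefficient k re-ranks generic words.

The score interpolates between the word's relative frequency inside the
selection (k=0) and its enrichment over the whole network (k=1):

    score(w) = (1-k) * sel_w/sel_tot + k * (sel_w/sel_tot) / (net_w/net_tot)

Words that are also common in the background gain least as k grows.
"""

import annocloud as ac

net, selection = ac.generate_fixture(seed=1)
corpus = ac.build_corpus(net.documents(["name"]))
stats = ac.count_words(corpus, set(selection))

print(f"selection: {stats.sel_tot} nodes; network: {stats.net_tot} nodes\n")
words = sorted(stats.sel_w, key=lambda w: (-stats.sel_w[w], w))
print(f"{'word':<16}{'sel_w':>6}{'net_w':>6}" + "".join(
    f"{'k=' + str(k):>9}" for k in (0.0, 0.5, 1.0)))
for w in words:
    row = f"{corpus.display(w):<16}{stats.sel_w[w]:>6}{stats.net_w[w]:>6}"
    for k in (0.0, 0.5, 1.0):
        row += f"{ac.word_score(stats, w, k):>9.3f}"
    print(row)

# "complex" appears in every selected node but also on some background
# nodes, so its enrichment at k=1 is lower than that of words found only in
# the selection (e.g. "origin", enriched 20/8 = 2.5-fold at k=1 here).
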