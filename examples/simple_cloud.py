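"""Build a frequency-sized tag cloud for a dense protein cluster.

Generates the bundled synthetic network — a clique of DNA-replication
proteins named after the "origin recognition complex component" and
"minichromosome maintenance complex component" phrase families, embedded in
unrelated background nodes — and summarizes the clique's names.
"""

import annocloud as ac

net, selection = ac.generate_fixture(seed=1)
corpus = ac.build_corpus(net.documents(["name"]))
cloud = ac.build_simple_cloud(corpus, set(selection), k=0.0)

print(f"{len(selection)} selected nodes of {len(net.nodes)}; "
      f"{len(cloud)} distinct word stems\n")
print(f"{'display':<16}{'stem':<16}{'score':>8}{'font':>6}")
for e in cloud.entries:
    print(f"{e.display:<16}{e.stem:<16}{e.score:>8.3f}{e.font:>6}")

# The score at k=0 is the fraction of selected nodes containing the word;
# font size maps the score range onto [12, 64]. "complex" and "component"
# occur in every selected name (both phrase families share them), so they
# score 1.0 and get the largest font.
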