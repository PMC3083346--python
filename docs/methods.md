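# Methods

## Model and procedure

`annocloud` summarizes the textual annotations of a node selection (a
sub-network) as a tag cloud. The unit of counting is the *word stem*: input
strings are tokenized on separation characters, lowercased, cleared of
flagged words and numeric tokens, and mapped through the Porter stemming
algorithm so inflectional variants (cell/cells) share one entry. Each stem
keeps its most frequently observed surface form for display.

Sizes come from node-presence counts. For a word *w*:

    score(w) = (1 - k) * sel_w/sel_tot + k * (sel_w/sel_tot) / (net_w/net_tot)

with `sel_w` = selected nodes containing *w*, `sel_tot` = selected nodes,
`net_w`/`net_tot` = the same over the entire network, and `k ∈ [0, 1]` the
network normalization coefficient. **This closed form is an
interpretation**: the published description of network weighting names
exactly these symbols and the intent (penalize words frequent outside the
selection) but not the formula. The linear interpolation was chosen because
it uses each symbol once, reduces exactly to the relative selection
frequency at `k = 0`, equals the selection-over-network enrichment ratio at
`k = 1`, and is finite for every tabulated word (`net_w ≥ sel_w > 0`).
Consequences worth knowing:

- For fixed counts the score is non-decreasing in `k` (the enrichment ratio
  is always ≥ the plain frequency since `net_w/net_tot ≤ 1`).
- With the whole network selected, the enrichment term is exactly 1 and
  `score = (1 - k)·r + k`: affine in the plain frequency `r`, so rank order
  and font sizes do not change with `k < 1`; at `k = 1` all scores collapse
  to 1 and every word gets the maximum font.

Fonts are an affine map of the score range onto `[min_font, max_font]`
(default 12–64), rounded half-up; an all-equal score vector (including a
single-word cloud) maps to `max_font`. Ties in cloud order are broken
lexicographically by stem, so output is deterministic.

## Co-occurrence similarity and clustering

Each ordered pair `(w1, w2)` adjacent in ≥ 1 selected node gets

    sim(w1, w2) = (n_joint/sel_tot) / ((sel_w1/sel_tot) · (sel_w2/sel_tot))

with `n_joint` the number of selected nodes where `w1` immediately precedes
`w2`. Probabilities are node-presence probabilities over the selection —
the same space as the sizing counts. A position-based alternative
(`pair_prob=position`: adjacent-slot and token-occurrence probabilities) is
exposed but not the default. Two further conventions, documented because the
alternatives are defensible: adjacency is computed **after** stopword
removal and stemming (the displayed stems are what co-occur, so "origin of
recognition" yields origin → recognition), and adjacency never crosses the
boundary between two attribute strings of the same node (unrelated
annotations do not form phrases).

Clustering is greedy and order-preserving: every word starts as a
singleton; the eligible cluster pair with the highest similarity is
concatenated, where eligibility means the ordered pair (last word of A,
first word of B) was observed with similarity ≥ the threshold; repeat until
no pair qualifies. Ties are broken by higher `n_joint`, then
lexicographically on the pair — reproducibility again. The default
threshold is 1.0: a pair must co-occur at least as often as independence
predicts. Clusters are ordered by descending Euclidean (L2) norm of their
font-size vectors, ties by more words first, then by the L2 norm of the
raw-score vector, then by first stem. The raw-score tie-break is
deliberate: integer font rounding can erase small score differences, and
without it an all-singleton clustering (unreachable threshold) could order
two equal-font words differently from the simple layout. With it, the
degenerate clustering reproduces the simple layout's order exactly.

The word-similarity network keeps what the non-overlapping clustering
discards: every word is a node (`size` = font), every qualifying ordered
pair an edge (`similarity`). When both orders of a pair were observed the
edge is collapsed to one undirected edge carrying the larger similarity;
both directed values survive as `sim_forward`/`sim_reverse` (forward = from
the lexicographically smaller endpoint) and `n_joint` is summed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 0.0 | network normalization coefficient; 0 = selection frequency only, 1 = enrichment ratio only |
| `threshold` | 1.0 | minimum pair similarity for a cluster merge (> 0) |
| `min_font`, `max_font` | 12, 64 | font range in points |
| `count_mode` | `presence` | `presence` counts nodes; `occurrence` counts token multiplicity (totals become token counts) |
| `pair_prob` | `node` | probability space of the similarity ratio |
| `delimiters` | whitespace + ASCII punctuation | separation characters (hyphen splits) |
| `drop_numbers` | true | drop integer/decimal tokens |
| `use_stemming` | true | Porter conflation on/off |

The stopword list is bundled and versioned (≈130 common English words, one
per line, `#` comments) so identical inputs give identical clouds across
installations; it can be replaced or extended per run. The published method
does not enumerate its flagged-word list or delimiter set — the bundled
defaults are a pinned choice, not a reconstruction.

## Synthetic fixture

`generate_fixture(seed, n_cluster_nodes=8, n_background_nodes=12)` builds
the worked example: a clique of "DNA replication" proteins whose `name`
attributes alternate between the phrase families *origin recognition
complex component i* and *minichromosome maintenance complex component i*,
plus background nodes with unrelated functional names (a few reuse generic
words like "complex"/"subunit" so network weighting has something to
penalize), sparsely wired and lightly linked to the clique. It is a pure
function of its arguments. It emulates the *structure* that makes the
method informative — shared words across phrase families, generic words in
the background — not real annotation text: vocabulary is tiny, names are
noise-free and phrase order is perfectly regular. Passing tests on it
demonstrate the mechanics (ranking, clustering, network construction), not
robustness to the heterogeneous, typo-ridden annotations of real databases.

## Numerical choices and degenerate inputs

- Font rounding is half-away-from-zero via `floor(x + 0.5)`.
- Empty selection raises; a selection whose nodes carry no text yields an
  empty cloud with a warning (legal input). Selected nodes without text
  still count in `sel_tot` — they are part of the denominator as defined.
- All orderings (cloud, merge choice, cluster order, writer output) carry
  total tie-breaks; repeated runs are byte-identical.
- Similarity is bounded by `sel_tot` (attained when a pair and both words
  occur in exactly one node); raising the merge threshold never decreases
  the number of clusters.

## Scope and limitations

- The greedy clustering considers only adjacency (bigrams); longer-range
  co-occurrence within a phrase is visible only in the word network.
- A word inside a cluster can merge further only via its cluster's ends —
  a direct consequence of the last/first similarity rule.
- English-only stemming and stopwords; no phrase detection beyond
  adjacency, no spell correction.
- SVG output is a simple left-to-right, line-wrapped rendering with one
  palette color per cluster; only the per-word font size carries meaning.
  GraphML/SIF exports leave graph layout to the consumer.
- Problem sizes throughout the tests and the acceptance script (≤ 20-node
  fixtures, ≤ 5-node random corpora over a 6-word vocabulary, 100–200
  seeds) were chosen to exercise every code path exhaustively; the
  pipeline itself is linear in total text size except for the greedy
  merge, which is quadratic in cluster count per step and intended for
  cloud-sized vocabularies (hundreds of words).
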