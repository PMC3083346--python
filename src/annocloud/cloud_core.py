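"""Word counting, network-weighted scoring and font scaling.

The size of a word in the cloud derives from how many selected nodes contain
it. Optional network weighting compares that selection frequency with the
word's frequency over the whole network, penalizing words that are common
everywhere; the mix is controlled by the normalization coefficient k in
[0, 1]:

    score(w) = (1 - k) * sel_w/sel_tot  +  k * (sel_w/sel_tot) / (net_w/net_tot)

where sel_w is the number of selected nodes containing w, sel_tot the number
of selected nodes, and net_w/net_tot the same over the entire network. At
k=0 this is the plain relative selection frequency; at k=1 it is the
enrichment ratio of the selection over the network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .errors import (
    EmptySelection,
    InvalidCoefficient,
    InvalidRange,
    UnknownNode,
    UnknownWord,
)
from .text_pipeline import TokenisedCorpus

DEFAULT_MIN_FONT = 12
DEFAULT_MAX_FONT = 64


@dataclass
class WordStats:
    """Per-word selection/network counts plus the two totals.

    In the default ``presence`` counting mode sel_w/net_w are node counts
    (a word repeated inside one node counts once) and the totals are node
    counts. In ``occurrence`` mode they are token-occurrence counts and the
    totals are token counts.
    """

    sel_w: dict[str, int] = field(default_factory=dict)
    net_w: dict[str, int] = field(default_factory=dict)
    sel_tot: int = 0
    net_tot: int = 0
    count_mode: str = "presence"

    def words(self) -> list[str]:
        return list(self.sel_w)


def count_words(
    corpus: TokenisedCorpus,
    selection: set[str],
    count_mode: str = "presence",
) -> WordStats:
    """Count word presence over the selection and the whole corpus.

    Only words present in at least one selected node enter the table, so
    ``0 < sel_w <= net_w`` holds for every tabulated word. Selected nodes
    with no text still contribute to ``sel_tot``.
    """
    if not selection:
        raise EmptySelection("the node selection is empty")
    missing = sorted(set(selection) - corpus.node_ids())
    if missing:
        raise UnknownNode(f"selected node(s) not in corpus: {', '.join(missing)}")
    if count_mode not in ("presence", "occurrence"):
        raise ValueError(f"unknown count_mode: {count_mode!r}")

    sel_w: dict[str, int] = {}
    net_w: dict[str, int] = {}
    sel_tot = 0
    net_tot = 0
    for node_id, doc in corpus.documents.items():
        in_sel = node_id in selection
        if count_mode == "presence":
            net_tot += 1
            sel_tot += in_sel
            units: Mapping[str, int] = dict.fromkeys(doc.tokens, 1)
        else:
            net_tot += len(doc.tokens)
            sel_tot += len(doc.tokens) if in_sel else 0
            units = {}
            for t in doc.tokens:
                units[t] = units.get(t, 0) + 1
        for word, n in units.items():
            net_w[word] = net_w.get(word, 0) + n
            if in_sel:
                sel_w[word] = sel_w.get(word, 0) + n

    net_w = {w: n for w, n in net_w.items() if w in sel_w}
    return WordStats(sel_w, net_w, sel_tot, net_tot, count_mode)


def word_score(stats: WordStats, word: str, k: float) -> float:
    """Network-weighted size score of ``word`` (see module docstring)."""
    if not 0.0 <= k <= 1.0:
        raise InvalidCoefficient(f"k must lie in [0, 1], got {k}")
    if word not in stats.sel_w:
        raise UnknownWord(f"word not in statistics table: {word!r}")
    sel_freq = stats.sel_w[word] / stats.sel_tot
    net_freq = stats.net_w[word] / stats.net_tot
    return (1.0 - k) * sel_freq + k * sel_freq / net_freq


def word_scores(stats: WordStats, k: float) -> dict[str, float]:
    """Scores for every tabulated word."""
    return {w: word_score(stats, w, k) for w in stats.sel_w}


def scale_fonts(
    scores: Mapping[str, float],
    min_font: int = DEFAULT_MIN_FONT,
    max_font: int = DEFAULT_MAX_FONT,
) -> dict[str, int]:
    """Affine map of [min score, max score] onto [min_font, max_font].

    Rounded to the nearest integer (half away from zero). When every score
    is equal — including a single-word cloud — all words get ``max_font``.
    """
    if min_font <= 0 or max_font <= 0 or min_font > max_font:
        raise InvalidRange(f"invalid font range [{min_font}, {max_font}]")
    if not scores:
        return {}
    lo = min(scores.values())
    hi = max(scores.values())
    if hi == lo:
        return {w: max_font for w in scores}
    span = max_font - min_font
    return {
        w: int(math.floor(min_font + span * (s - lo) / (hi - lo) + 0.5))
        for w, s in scores.items()
    }


@dataclass(frozen=True)
class CloudEntry:
    stem: str
    display: str
    score: float
    font: int


@dataclass
class TagCloud:
    """Words ordered by descending raw score (ties lexicographic by stem)."""

    entries: list[CloudEntry]

    def stems(self) -> list[str]:
        return [e.stem for e in self.entries]

    def fonts(self) -> dict[str, int]:
        return {e.stem: e.font for e in self.entries}

    def scores(self) -> dict[str, float]:
        return {e.stem: e.score for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def build_simple_cloud(
    corpus: TokenisedCorpus,
    selection: set[str],
    k: float = 0.0,
    min_font: int = DEFAULT_MIN_FONT,
    max_font: int = DEFAULT_MAX_FONT,
    count_mode: str = "presence",
) -> TagCloud:
    """The basic layout: all selection words, largest (most frequent) first."""
    stats = count_words(corpus, selection, count_mode)
    scores = word_scores(stats, k)
    if not scores:
        warnings.warn(
            "selection contains no attribute text; cloud is empty", stacklevel=2
        )
        return TagCloud([])
    fonts = scale_fonts(scores, min_font, max_font)
    order = sorted(scores, key=lambda w: (-scores[w], w))
    return TagCloud(
        [CloudEntry(w, corpus.display(w), scores[w], fonts[w]) for w in order]
    )
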