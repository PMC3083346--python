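"""Turn raw node-attribute strings into per-node ordered token lists.

The pipeline is: split on delimiter characters, lowercase, drop flagged
(stop) words and purely numeric tokens, and optionally conflate words that
share a Porter stem. A :class:`StemTable` remembers which surface forms were
observed for each stem so clouds can display a human-readable form ("cell")
rather than a truncated stem ("replic" -> displays "replication").
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from . import _porter

#: Default separation characters: Unicode whitespace plus ASCII punctuation.
DEFAULT_DELIMITERS: frozenset[str] = frozenset(string.whitespace + string.punctuation)

_NUMBER_RE = re.compile(r"^[+-]?\d+(\.\d+)?$")


def default_stopwords() -> frozenset[str]:
    """The bundled English stopword list (lowercased)."""
    text = resources.files("annocloud.data").joinpath("stopwords.txt").read_text()
    return _parse_stopwords(text.splitlines())


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword file: one word per line, ``#`` comments allowed."""
    with open(path, encoding="utf-8") as fh:
        return _parse_stopwords(fh)


def _parse_stopwords(lines: Iterable[str]) -> frozenset[str]:
    words = set()
    for line in lines:
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.add(word)
    return frozenset(words)


def tokenize(
    text: str,
    delimiters: Iterable[str] | None = None,
    *,
    lowercase: bool = True,
) -> list[str]:
    """Split ``text`` into maximal runs of non-delimiter characters.

    Total on strings: empty or all-delimiter input yields ``[]``. Tokens are
    lowercased unless ``lowercase=False`` (used internally to preserve the
    surface casing recorded in the stem table).
    """
    delims = DEFAULT_DELIMITERS if delimiters is None else frozenset(delimiters)
    tokens: list[str] = []
    current: list[str] = []
    for ch in text:
        if ch in delims:
            if current:
                tokens.append("".join(current))
                current = []
        else:
            current.append(ch)
    if current:
        tokens.append("".join(current))
    if lowercase:
        tokens = [t.lower() for t in tokens]
    return tokens


def filter_tokens(
    tokens: Sequence[str],
    stoplist: frozenset[str] | set[str],
    drop_numbers: bool = True,
) -> list[str]:
    """Remove flagged words and (optionally) integer/decimal tokens.

    Membership is tested on the lowercased token; relative order of the
    survivors is preserved.
    """
    out = []
    for tok in tokens:
        low = tok.lower()
        if low in stoplist:
            continue
        if drop_numbers and _NUMBER_RE.match(low):
            continue
        out.append(tok)
    return out


@dataclass
class StemTable:
    """Bookkeeping from stem to the surface forms observed for it."""

    surface_counts: dict[str, Counter] = field(default_factory=dict)
    stem_to_display: dict[str, str] = field(default_factory=dict)

    def record(self, stem: str, surface: str) -> None:
        self.surface_counts.setdefault(stem, Counter())[surface] += 1

    def display(self, stem: str) -> str:
        return self.stem_to_display.get(stem, stem)


def stem_tokens(tokens: Sequence[str], table: StemTable | None = None) -> list[str]:
    """Replace each token by its Porter stem, recording surface forms.

    Tokens may carry their original casing; the stem is computed on the
    lowercased form and the original surface form is counted in ``table``.
    """
    out = []
    for tok in tokens:
        s = _porter.stem(tok.lower())
        if table is not None:
            table.record(s, tok)
        out.append(s)
    return out


def choose_display_forms(table: StemTable) -> StemTable:
    """Pick each stem's display form: most frequent surface form, ties broken
    by shortest then lexicographic (case-insensitively, then by raw string)."""
    for stem, counts in table.surface_counts.items():
        best = min(
            counts.items(),
            key=lambda kv: (-kv[1], len(kv[0]), kv[0].lower(), kv[0]),
        )
        table.stem_to_display[stem] = best[0]
    return table


@dataclass(frozen=True)
class RawDocument:
    """One node's raw annotation: one text per selected attribute, flattened
    over list-typed attribute values in list order. ``texts`` may be empty."""

    node_id: str
    texts: tuple[str, ...]

    def __init__(self, node_id: str, texts: Iterable[str] = ()):  # noqa: D107
        object.__setattr__(self, "node_id", node_id)
        object.__setattr__(self, "texts", tuple(texts))


@dataclass(frozen=True)
class TokenisedDocument:
    """A node's processed token stream.

    ``boundaries`` are positions in ``tokens`` where one attribute string
    ended and the next began; downstream adjacency never spans a boundary.
    """

    node_id: str
    tokens: tuple[str, ...]
    boundaries: tuple[int, ...] = ()

    def segments(self) -> Iterator[tuple[str, ...]]:
        """Yield the maximal token runs that lie within one attribute string."""
        prev = 0
        for b in self.boundaries:
            yield self.tokens[prev:b]
            prev = b
        yield self.tokens[prev:]


@dataclass
class TextConfig:
    """Options for the text pipeline (the External Interface knobs)."""

    delimiters: frozenset[str] = DEFAULT_DELIMITERS
    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    drop_numbers: bool = True
    use_stemming: bool = True


@dataclass
class TokenisedCorpus:
    """Per-node token lists plus the shared stem/display table."""

    documents: dict[str, TokenisedDocument]
    stem_table: StemTable

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.documents

    def node_ids(self) -> set[str]:
        return set(self.documents)

    def display(self, stem: str) -> str:
        return self.stem_table.display(stem)


def build_corpus(
    documents: Iterable[RawDocument],
    config: TextConfig | None = None,
) -> TokenisedCorpus:
    """Run the full pipeline over raw documents.

    Raises ``ValueError`` on a duplicate node id; empty ``texts`` are legal
    and yield an empty token list.
    """
    cfg = config or TextConfig()
    table = StemTable()
    docs: dict[str, TokenisedDocument] = {}
    for raw in documents:
        if not raw.node_id:
            raise ValueError("node_id must be non-empty")
        if raw.node_id in docs:
            raise ValueError(f"duplicate node id in corpus: {raw.node_id!r}")
        tokens: list[str] = []
        boundaries: list[int] = []
        for text in raw.texts:
            surfaces = tokenize(text, cfg.delimiters, lowercase=False)
            surfaces = filter_tokens(surfaces, cfg.stopwords, cfg.drop_numbers)
            if cfg.use_stemming:
                stems = stem_tokens(surfaces, table)
            else:
                stems = []
                for s in surfaces:
                    low = s.lower()
                    table.record(low, s)
                    stems.append(low)
            if tokens and stems:
                boundaries.append(len(tokens))
            tokens.extend(stems)
        docs[raw.node_id] = TokenisedDocument(
            raw.node_id, tuple(tokens), tuple(boundaries)
        )
    choose_display_forms(table)
    return TokenisedCorpus(docs, table)
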