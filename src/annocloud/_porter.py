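"""Porter stemming algorithm (1980), as used to conflate word variants.

Implements the original published rules. ``y`` counts as a consonant at the
start of a word or after a vowel; the measure m of a stem is the number of
VC sequences in its [C](VC)^m[V] decomposition.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    n = 0
    i = 0
    L = len(stem)
    while i < L and _is_cons(stem, i):
        i += 1
    while i < L:
        while i < L and not _is_cons(stem, i):
            i += 1
        if i >= L:
            break
        n += 1
        while i < L and _is_cons(stem, i):
            i += 1
    return n


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant, final consonant not w, x or y
    if len(word) < 3:
        return False
    L = len(word)
    return (
        _is_cons(word, L - 3)
        and not _is_cons(word, L - 2)
        and _is_cons(word, L - 1)
        and word[-1] not in "wxy"
    )


# (suffix, replacement) rule tables; within a step only the longest matching
# suffix is considered, and the rule fires only if m(stem) passes the bound.
_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _longest_rule(word: str, rules) -> tuple[str, str] | None:
    best = None
    for suf, rep in rules:
        if word.endswith(suf) and (best is None or len(suf) > len(best[0])):
            best = (suf, rep)
    return best


def stem(word: str) -> str:
    """Return the Porter stem of ``word`` (compared case-insensitively)."""
    w = word.lower()
    if len(w) <= 2:
        return w

    # Step 1a: plurals
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # Step 1b: -ed / -ing
    cleanup = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        w = w[:-2]
        cleanup = True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = w[:-3]
        cleanup = True
    if cleanup:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_cons(w) and w[-1] not in "lsz":
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"

    # Step 1c: y -> i
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    rule = _longest_rule(w, _STEP2)
    if rule is not None:
        suf, rep = rule
        if _measure(w[: -len(suf)]) > 0:
            w = w[: -len(suf)] + rep

    # Step 3
    rule = _longest_rule(w, _STEP3)
    if rule is not None:
        suf, rep = rule
        if _measure(w[: -len(suf)]) > 0:
            w = w[: -len(suf)] + rep

    # Step 4
    rule = _longest_rule(w, [(s, "") for s in _STEP4])
    if rule is not None:
        suf, _ = rule
        base = w[: -len(suf)]
        if _measure(base) > 1 and (suf != "ion" or base.endswith(("s", "t"))):
            w = base

    # Step 5a
    if w.endswith("e"):
        base = w[:-1]
        m = _measure(base)
        if m > 1 or (m == 1 and not _ends_cvc(base)):
            w = base

    # Step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w
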