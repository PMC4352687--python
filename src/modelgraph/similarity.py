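"""Name similarity for cross-format entity matching.

Two encodings of the same model name their entities almost, but not
exactly, alike ("Cdc2" vs "cdc2_k", "M phase" vs "m_phase").  Matching
therefore case-folds and stems both names and compares them by
normalized Levenshtein distance:

    sim(a, b) = 1 - lev(stem(fold(a)), stem(fold(b))) / max(|a'|, |b'|)

where a', b' are the stemmed forms.  Identical names give 1.0, fully
dissimilar names approach 0.0.

The stemmer is a self-contained implementation of the classic Porter
suffix-stripping algorithm; edit distance comes from edlib.
"""

from __future__ import annotations

import edlib

__all__ = ["levenshtein", "porter_stem", "fold_name", "name_similarity"]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


# ----------------------------------------------------------------------
# Porter stemmer
# ----------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions ("VC" blocks)."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        vowel = not _is_cons(stem, i)
        if prev_vowel and not vowel:
            m += 1
        prev_vowel = vowel
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


def _replace(word: str, suffix: str, repl: str, min_measure: int) -> str | None:
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_measure - 1:
        return stem + repl
    return word


def porter_stem(word: str) -> str:
    """Porter-stem a single lower-case token."""
    w = word
    if len(w) <= 2:
        return w

    # step 1a: plurals
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # step 1b: -ed / -ing
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        stem = None
        if w.endswith("ed") and _has_vowel(w[:-2]):
            stem = w[:-2]
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            stem = w[:-3]
        if stem is not None:
            w = stem
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and not w.endswith(("l", "s", "z")):
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # step 1c: y -> i
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suffix, repl in (
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ):
        out = _replace(w, suffix, repl, 1)
        if out is not None:
            w = out
            break

    # step 3
    for suffix, repl in (
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ):
        out = _replace(w, suffix, repl, 1)
        if out is not None:
            w = out
            break

    # step 4
    for suffix in (
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ):
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) > 1:
                w = stem
            break
    else:
        if w.endswith("ion"):
            stem = w[:-3]
            if _measure(stem) > 1 and stem and stem[-1] in "st":
                w = stem

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem
    # step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]
    return w


def fold_name(name: str) -> str:
    """Case-fold an entity name and stem each alphabetic run."""
    out = []
    token = []
    for ch in name.lower():
        if ch.isalpha():
            token.append(ch)
        else:
            if token:
                out.append(porter_stem("".join(token)))
                token = []
            out.append(ch)
    if token:
        out.append(porter_stem("".join(token)))
    return "".join(out)


def name_similarity(a: str, b: str) -> float:
    """Normalized similarity of two entity names in [0, 1]."""
    fa, fb = fold_name(a), fold_name(b)
    if not fa and not fb:
        return 1.0
    denom = max(len(fa), len(fb))
    return 1.0 - levenshtein(fa, fb) / denom
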