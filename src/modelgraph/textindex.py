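"""Small TF-IDF full-text index over resource description text.

Annotation resources carry a free-text description (ontology term label
and definition, protein record description, ...).  Queries such as
"which resources mention *m-phase inducer phosphatase*" are answered by
this index: conjunctive token matching with TF-IDF ranking.

Scoring is deliberately plain (this replaces a full ranked-retrieval
engine): for a document d and query tokens q_1..q_k that all occur in d,

    score(d) = sum_i (1 + log tf(q_i, d)) * (1 + log((1 + N) / (1 + df(q_i))))

with natural logarithms, N the number of indexed documents and df the
document frequency.  The smoothed idf stays strictly positive even for
a token present in every document, so term frequency always
discriminates.  Documents missing any query token are excluded.
Ties are broken by the caller-supplied document key.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from typing import Any, Hashable

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lower-case tokens split on any non-alphanumeric character."""
    return _TOKEN_RE.findall(text.lower())


class TextIndex:
    """Inverted index with log-scaled TF-IDF ranking."""

    def __init__(self) -> None:
        self._tf: dict[Hashable, Counter] = {}
        self._df: Counter = Counter()
        self._frozen = False

    def add(self, key: Hashable, text: str) -> None:
        if self._frozen:
            raise RuntimeError("index is frozen")
        counts = Counter(tokenize(text))
        if key in self._tf:  # re-adding replaces the old document
            for tok in self._tf[key]:
                self._df[tok] -= 1
        self._tf[key] = counts
        for tok in counts:
            self._df[tok] += 1

    def freeze(self) -> None:
        self._frozen = True

    def __len__(self) -> int:
        return len(self._tf)

    def search(self, query: str) -> list[tuple[Hashable, float]]:
        """Documents containing *all* query tokens, best score first."""
        tokens = tokenize(query)
        if not tokens:
            raise ValueError("empty text query")
        n_docs = len(self._tf)
        scored: list[tuple[Hashable, float]] = []
        for key, tf in self._tf.items():
            if all(tf[tok] > 0 for tok in tokens):
                score = sum(
                    (1.0 + math.log(tf[tok]))
                    * (1.0 + math.log((1 + n_docs) / (1 + self._df[tok])))
                    for tok in tokens
                )
                scored.append((key, score))
        scored.sort(key=lambda kv: (-kv[1], str(kv[0])))
        return scored
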