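"""POS-filtered frequency representations of documents.

A document is reduced to its 10 most frequent nouns, 10 most frequent verbs
and 10 most frequent adjectives — at most 30 words standing for the text.
Tagging is delegated to any callable honoring the tagger contract: it maps a
token list to a token list of the same length and order, filling only the
``pos`` field.  The package ships a deterministic dictionary-based tagger;
any external tagger can be wrapped to the same contract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .corpus_io import Corpus, CorpusError, Token, tokenize

__all__ = [
    "TaggerContract",
    "DictionaryTagger",
    "TextRepresentation",
    "tag",
    "extract_representation",
    "represent_document",
    "represent_corpus",
]

TaggerContract = Callable[[Sequence[Token]], list[Token]]

_CATEGORIES = ("NOUN", "VERB", "ADJ")


class DictionaryTagger:
    """Deterministic tagger: normalized word -> POS, unknown words -> OTHER."""

    def __init__(self, pos_dictionary: Mapping[str, str]):
        self.pos_dictionary = dict(pos_dictionary)

    def __call__(self, tokens: Sequence[Token]) -> list[Token]:
        return [
            t.with_pos(self.pos_dictionary.get(t.normalized, "OTHER")) for t in tokens
        ]


@dataclass(frozen=True)
class TextRepresentation:
    """Up to 10 (word, frequency) pairs per POS category for one document."""

    doc_id: str
    nouns: tuple[tuple[str, int], ...]
    verbs: tuple[tuple[str, int], ...]
    adjectives: tuple[tuple[str, int], ...]

    @property
    def words(self) -> list[str]:
        """All representation words, category by category.

        A word selected under two categories appears once per category.
        """
        return [w for cat in (self.nouns, self.verbs, self.adjectives) for w, _ in cat]

    @property
    def weighted_words(self) -> list[tuple[str, int]]:
        return [
            (w, f) for cat in (self.nouns, self.verbs, self.adjectives) for w, f in cat
        ]

    @property
    def is_empty(self) -> bool:
        return not (self.nouns or self.verbs or self.adjectives)


def tag(tokens: Sequence[Token], tagger: TaggerContract) -> list[Token]:
    """Apply a tagger, enforcing the contract (same length, order, words)."""
    tagged = tagger(tokens)
    if len(tagged) != len(tokens):
        raise CorpusError(
            f"tagger returned {len(tagged)} tokens for {len(tokens)} inputs"
        )
    for before, after in zip(tokens, tagged):
        if (before.normalized, before.position) != (after.normalized, after.position):
            raise CorpusError("tagger must modify only the pos field")
    return tagged


def _top_k(counter: Counter, k: int | None) -> tuple[tuple[str, int], ...]:
    items = sorted(counter.items(), key=lambda item: (-item[1], item[0]))
    return tuple(items if k is None else items[:k])


def extract_representation(
    tokens: Sequence[Token], k: int | None = 10, doc_id: str = ""
) -> TextRepresentation:
    """Keep the k most frequent words per POS category.

    Frequencies are over normalized forms; ties at the cut are broken
    alphabetically so the representation is deterministic.  Categories with
    fewer than k distinct words keep all of them; ``k=None`` keeps every
    word (the full per-category vocabulary).
    """
    if k is not None and k < 1:
        raise CorpusError("k must be positive")
    counters = {cat: Counter() for cat in _CATEGORIES}
    for t in tokens:
        if t.pos in counters:
            counters[t.pos][t.normalized] += 1
    return TextRepresentation(
        doc_id=doc_id,
        nouns=_top_k(counters["NOUN"], k),
        verbs=_top_k(counters["VERB"], k),
        adjectives=_top_k(counters["ADJ"], k),
    )


def represent_document(
    raw_text: str, tagger: TaggerContract, k: int | None = 10, doc_id: str = ""
) -> TextRepresentation:
    return extract_representation(tag(tokenize(raw_text), tagger), k=k, doc_id=doc_id)


def represent_corpus(
    corpus: Corpus, tagger: TaggerContract, k: int | None = 10
) -> list[TextRepresentation]:
    return [
        represent_document(d.raw_text, tagger, k=k, doc_id=d.doc_id) for d in corpus
    ]
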