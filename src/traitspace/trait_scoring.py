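"""Trait lexicon and document-vs-trait similarity scoring.

Thirteen psychological dimensions are each defined by a short seed-word
list: four personality-disorder dimensions (depressivity DEP, paranoid PPD,
narcissistic NPD, schizoid SCHYZO) and nine facets of vengeful behavior
(Hopeless, Lonely, Helpless, Pain, Revengeful, Chaotic, Unsafe, Abandoned,
Humiliated).  A document's score on a dimension is the cosine, in the
semantic space, between the document's representation words and the
dimension's seed words — by default between the two centroids.  The higher
the score, the more strongly the dimension is expressed in the text.

Out-of-vocabulary words are dropped and counted, never silently zeroed; a
cell where no seed word or no representation word is in the space is left
undefined (NaN) rather than given a fake value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .representation import TextRepresentation
from .semantic_space import SemanticSpace, cosine

__all__ = [
    "TraitVector",
    "TraitLexicon",
    "ScoreMatrix",
    "UndefinedScoreError",
    "builtin_lexicon",
    "load_lexicon",
    "score_text",
    "score_corpus",
]


class UndefinedScoreError(ValueError):
    """No usable in-vocabulary words on one side of a score."""


@dataclass(frozen=True)
class TraitVector:
    """A named psychological dimension defined by its seed words."""

    name: str
    seed_words: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.seed_words:
            raise ValueError(f"trait {self.name!r} has no seed words")
        if len(set(self.seed_words)) != len(self.seed_words):
            raise ValueError(f"trait {self.name!r} has duplicate seed words")
        if any(w != w.casefold() for w in self.seed_words):
            raise ValueError(f"trait {self.name!r} seed words must be lowercase")


@dataclass(frozen=True)
class TraitLexicon:
    """An ordered collection of trait vectors."""

    traits: tuple[TraitVector, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in lexicon")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    def __iter__(self) -> Iterator[TraitVector]:
        return iter(self.traits)

    def __len__(self) -> int:
        return len(self.traits)

    def __getitem__(self, key: int | str) -> TraitVector:
        if isinstance(key, int):
            return self.traits[key]
        for t in self.traits:
            if t.name == key:
                return t
        raise KeyError(key)


# The 13 built-in dimensions with their exact seed lists, in fixed order.
# Seed words may legitimately recur across traits (e.g. "lonely" belongs to
# DEP, SCHYZO and Lonely).
_BUILTIN: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("DEP", ("sad", "lonely", "hopeless", "worthless")),
    ("PPD", ("suspicious", "hypersensitive", "wronged", "hostile")),
    ("NPD", ("arrogant", "manipulative", "egocentric", "insensitive")),
    ("SCHYZO", ("detached", "avoidant", "lonely", "indifferent")),
    ("Hopeless", ("hopeless", "desperate")),
    ("Lonely", ("lonely", "lonesome")),
    ("Helpless", ("helpless", "defenseless")),
    ("Pain", ("pain", "misery", "agony")),
    ("Revengeful", ("revengeful", "vengeful", "vindictive")),
    ("Chaotic", ("chaotic", "disordered")),
    ("Unsafe", ("unsafe", "insecure")),
    ("Abandoned", ("abandoned", "deserted")),
    ("Humiliated", ("humiliated", "shamed")),
)


def builtin_lexicon() -> TraitLexicon:
    """The 13 built-in trait vectors in their fixed order."""
    return TraitLexicon(
        traits=tuple(TraitVector(name=n, seed_words=w) for n, w in _BUILTIN)
    )


def load_lexicon(csv_path: str | Path) -> TraitLexicon:
    """Load a custom lexicon from a two-column CSV ``trait,word``.

    Trait order follows first appearance; words are lowercased.  This is the
    hook for scoring against alternative psychological theorizations.
    """
    order: list[str] = []
    words: dict[str, list[str]] = {}
    with open(csv_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if rows and [c.strip().lower() for c in rows[0]] == ["trait", "word"]:
        rows = rows[1:]
    for row in rows:
        if len(row) != 2:
            raise ValueError(f"lexicon rows must be 'trait,word'; got {row!r}")
        trait, word = row[0].strip(), row[1].strip().casefold()
        if trait not in words:
            order.append(trait)
            words[trait] = []
        if word not in words[trait]:
            words[trait].append(word)
    return TraitLexicon(
        traits=tuple(TraitVector(name=t, seed_words=tuple(words[t])) for t in order)
    )


@dataclass
class ScoreMatrix:
    """Documents x traits score table.

    ``scores`` is indexed by doc_id with one column per trait in lexicon
    order; NaN marks an undefined cell.  ``seed_oov`` counts, per cell, the
    trait seed words missing from the space; ``rep_oov`` counts each
    document's representation words missing from the space.
    """

    scores: pd.DataFrame
    labels: pd.Series | None = None
    seed_oov: pd.DataFrame | None = None
    rep_oov: pd.Series | None = None
    mode: str = "centroid"

    @property
    def trait_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def doc_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        """Flat frame with doc_id and label columns, for write_scores."""
        frame = self.scores.copy()
        frame.insert(0, "doc_id", frame.index)
        labels = (
            self.labels.reindex(frame.index)
            if self.labels is not None
            else pd.Series(index=frame.index, dtype=object)
        )
        frame.insert(1, "label", labels)
        return frame.reset_index(drop=True)


def _mean_vector(space: SemanticSpace, entries: Sequence[tuple[str, float]]):
    """Weighted mean vector of in-vocabulary words; returns (vec, n_oov)."""
    vecs, weights, n_oov = [], [], 0
    for word, w in entries:
        if word in space:
            vecs.append(space.vector(word))
            weights.append(w)
        else:
            n_oov += 1
    if not vecs:
        return None, n_oov
    stacked = np.asarray(vecs, dtype=np.float64)
    wts = np.asarray(weights, dtype=np.float64)
    return (stacked * wts[:, None]).sum(axis=0) / wts.sum(), n_oov


def _rep_entries(
    rep: TextRepresentation, frequency_weighted: bool
) -> list[tuple[str, float]]:
    if frequency_weighted:
        return [(w, float(f)) for w, f in rep.weighted_words]
    return [(w, 1.0) for w in rep.words]


def score_text(
    space: SemanticSpace,
    rep: TextRepresentation,
    trait: TraitVector,
    mode: str = "centroid",
    frequency_weighted: bool = False,
) -> float:
    """Similarity of one document representation to one trait.

    ``centroid`` (default): cosine between the mean vector of in-vocabulary
    representation words and the mean vector of in-vocabulary seed words.
    ``mean_pairwise``: average cosine over all in-vocabulary (rep, seed)
    pairs.  Raises :class:`UndefinedScoreError` when either side has no
    in-vocabulary word.
    """
    if mode not in ("centroid", "mean_pairwise"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    if rep.is_empty:
        raise UndefinedScoreError(f"document {rep.doc_id!r} has an empty representation")
    rep_words = [(w, wt) for w, wt in _rep_entries(rep, frequency_weighted) if w in space]
    seed_words = [w for w in trait.seed_words if w in space]
    if not rep_words:
        raise UndefinedScoreError(
            f"document {rep.doc_id!r}: no representation word in vocabulary"
        )
    if not seed_words:
        raise UndefinedScoreError(f"trait {trait.name!r}: all seed words OOV")
    if mode == "centroid":
        rep_vec, _ = _mean_vector(space, rep_words)
        seed_vec, _ = _mean_vector(space, [(w, 1.0) for w in seed_words])
        return cosine(rep_vec, seed_vec)
    sims = [
        cosine(space.vector(w), space.vector(s))
        for w, _ in rep_words
        for s in seed_words
    ]
    return float(np.mean(sims))


def score_corpus(
    space: SemanticSpace,
    reps: Sequence[TextRepresentation],
    lexicon: TraitLexicon | None = None,
    mode: str = "centroid",
    frequency_weighted: bool = False,
    labels: Mapping[str, str] | pd.Series | None = None,
) -> ScoreMatrix:
    """Score every document against every trait.

    Undefined cells become NaN without aborting the batch; the OOV report
    records how many seed words per trait (and representation words per
    document) were missing from the space.
    """
    lexicon = lexicon or builtin_lexicon()
    doc_ids = [r.doc_id for r in reps]
    names = lexicon.names
    values = np.full((len(reps), len(lexicon)), np.nan)
    seed_oov = np.zeros((len(reps), len(lexicon)), dtype=np.int64)
    rep_oov = np.zeros(len(reps), dtype=np.int64)
    for i, rep in enumerate(reps):
        rep_oov[i] = sum(1 for w in rep.words if w not in space)
        for j, trait in enumerate(lexicon):
            seed_oov[i, j] = sum(1 for w in trait.seed_words if w not in space)
            try:
                values[i, j] = score_text(
                    space, rep, trait, mode=mode, frequency_weighted=frequency_weighted
                )
            except UndefinedScoreError:
                pass  # leave NaN
    label_series = None
    if labels is not None:
        label_series = pd.Series(dict(labels), name="label", dtype=object).reindex(
            doc_ids
        )
    return ScoreMatrix(
        scores=pd.DataFrame(values, index=doc_ids, columns=names),
        labels=label_series,
        seed_oov=pd.DataFrame(seed_oov, index=doc_ids, columns=names),
        rep_oov=pd.Series(rep_oov, index=doc_ids, name="rep_oov"),
        mode=mode,
    )
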