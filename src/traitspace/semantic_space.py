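"""Count-based distributional semantic spaces.

Word meaning is represented by windowed co-occurrence counts over a
background corpus, reweighted by positive pointwise mutual information
(PPMI) and optionally compressed by truncated SVD; similarity between words
is the cosine of their vectors.  This is the canonical count-based
vector-space pipeline: a word that appears with "anxious" six times and with
"angry" three times gets raw coordinates (6, 3) on those two dimensions.

Windows are symmetric, span ``window`` tokens to each side of the target,
and never cross document boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, tokenize

__all__ = [
    "SpaceConfig",
    "CooccurrenceMatrix",
    "SemanticSpace",
    "OOVWordError",
    "SpaceError",
    "build_cooccurrence",
    "weight",
    "build_space",
    "similarity",
    "neighbors",
    "cosine",
    "save_space",
    "load_space",
]


class SpaceError(ValueError):
    """Raised for invalid space configurations or degenerate inputs."""


class OOVWordError(KeyError):
    """A queried word is not in the space's vocabulary."""

    def __init__(self, word: str):
        super().__init__(word)
        self.word = word

    def __str__(self) -> str:
        return f"word {self.word!r} is not in the vocabulary"


@dataclass(frozen=True)
class SpaceConfig:
    """Configuration of a semantic space.

    window
        Tokens counted to each side of the target (default 3).
    weighting
        ``ppmi`` (default) or ``raw`` counts.
    svd_dim
        If set, reduce vectors to this rank by truncated SVD; ``None``
        keeps the full weighted co-occurrence rows.
    min_count
        Words occurring fewer times than this in the corpus are dropped
        from the vocabulary after counting (default 2).
    seed
        Reserved for randomized decompositions; the exact LAPACK SVD used
        here is deterministic regardless.
    """

    window: int = 3
    weighting: str = "ppmi"
    svd_dim: int | None = None
    min_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise SpaceError("window must be >= 1")
        if self.weighting not in ("ppmi", "raw"):
            raise SpaceError(f"unknown weighting {self.weighting!r}")
        if self.svd_dim is not None and self.svd_dim < 1:
            raise SpaceError("svd_dim must be positive")
        if self.min_count < 0:
            raise SpaceError("min_count must be >= 0")


@dataclass
class CooccurrenceMatrix:
    """Symmetric window co-occurrence counts with zero diagonal."""

    vocabulary: list[str]
    counts: np.ndarray  # square, nonnegative integers

    def __post_init__(self) -> None:
        n = len(self.vocabulary)
        if self.counts.shape != (n, n):
            raise SpaceError("counts shape does not match vocabulary size")

    @property
    def index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocabulary)}


@dataclass
class SemanticSpace:
    """Vocabulary plus one real vector per word."""

    vocabulary: list[str]
    vectors: np.ndarray  # (n_words, dim)
    config: SpaceConfig
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocabulary):
            raise SpaceError("one vector per vocabulary word required")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise OOVWordError(word) from None


def _doc_token_ids(corpus: Corpus) -> tuple[list[str], list[np.ndarray]]:
    """Normalized tokens of every document, mapped to full-vocabulary ids."""
    docs = [[t.normalized for t in tokenize(d.raw_text)] for d in corpus]
    vocab = sorted({w for doc in docs for w in doc})
    index = {w: i for i, w in enumerate(vocab)}
    ids = [np.array([index[w] for w in doc], dtype=np.int64) for doc in docs]
    return vocab, ids


def build_cooccurrence(corpus: Corpus, config: SpaceConfig) -> CooccurrenceMatrix:
    """Count symmetric windowed co-occurrences over a corpus.

    Every ordered pair of tokens at distance 1..window within the same
    document increments both ``counts[i, j]`` and ``counts[j, i]``.  The
    diagonal is zeroed (a word is not its own context) and words with
    corpus frequency below ``min_count`` are dropped after counting.
    """
    if len(corpus) == 0:
        raise SpaceError("corpus is empty")
    vocab, doc_ids = _doc_token_ids(corpus)
    n = len(vocab)
    counts = np.zeros((n, n), dtype=np.int64)
    freq = np.zeros(n, dtype=np.int64)
    for ids in doc_ids:
        np.add.at(freq, ids, 1)
        for d in range(1, config.window + 1):
            if len(ids) <= d:
                break
            i, j = ids[:-d], ids[d:]
            np.add.at(counts, (i, j), 1)
            np.add.at(counts, (j, i), 1)
    np.fill_diagonal(counts, 0)

    keep = np.flatnonzero(freq >= config.min_count)
    if keep.size == 0:
        raise SpaceError(
            f"vocabulary is empty after applying min_count={config.min_count}"
        )
    vocabulary = [vocab[i] for i in keep]
    return CooccurrenceMatrix(vocabulary=vocabulary, counts=counts[np.ix_(keep, keep)])


def weight(cooc: CooccurrenceMatrix | np.ndarray, scheme: str = "ppmi") -> np.ndarray:
    """Association-weight a co-occurrence matrix.

    ``ppmi``: w[i,j] = max(0, log2(c[i,j] * T / (r[i] * r[j]))) with T the
    total count and r the row sums; ``raw``: identity.
    """
    counts = cooc.counts if isinstance(cooc, CooccurrenceMatrix) else cooc
    c = np.asarray(counts, dtype=np.float64)
    if scheme == "raw":
        return c.copy()
    if scheme != "ppmi":
        raise SpaceError(f"unknown weighting {scheme!r}")
    total = c.sum()
    if total == 0:
        raise SpaceError("cannot PPMI-weight an all-zero co-occurrence matrix")
    row = c.sum(axis=1)
    expected = np.outer(row, row)
    w = np.zeros_like(c)
    mask = (c > 0) & (expected > 0)
    w[mask] = np.log2(c[mask] * total / expected[mask])
    np.clip(w, 0.0, None, out=w)
    return w


def build_space(corpus: Corpus, config: SpaceConfig) -> SemanticSpace:
    """Build a semantic space: count, weight, optionally SVD-reduce."""
    cooc = build_cooccurrence(corpus, config)
    vectors = weight(cooc, config.weighting)
    if config.svd_dim is not None:
        k = config.svd_dim
        if k > len(cooc.vocabulary):
            raise SpaceError(
                f"svd_dim={k} exceeds vocabulary size {len(cooc.vocabulary)}"
            )
        # Full LAPACK SVD: deterministic, exact; desk-scale vocabularies only.
        u, s, _ = np.linalg.svd(vectors, full_matrices=False)
        vectors = u[:, :k] * s[:k]
    return SemanticSpace(vocabulary=cooc.vocabulary, vectors=vectors, config=config)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; 0.0 if either vector has zero norm."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def similarity(space: SemanticSpace, word_a: str, word_b: str) -> float:
    """Cosine similarity between two vocabulary words (OOV raises)."""
    return cosine(space.vector(word_a), space.vector(word_b))


def neighbors(
    space: SemanticSpace,
    word: str,
    n: int,
    pos_filter: str | None = None,
    pos_lookup: Mapping[str, str] | None = None,
) -> list[tuple[str, float]]:
    """Top-n most similar other words, ties broken alphabetically.

    With ``pos_filter`` set, only words whose ``pos_lookup`` entry matches
    are eligible.
    """
    target = space.vector(word)
    if pos_filter is not None and pos_lookup is None:
        raise SpaceError("pos_filter requires a pos_lookup mapping")
    candidates = []
    for other in space.vocabulary:
        if other == word:
            continue
        if pos_filter is not None and pos_lookup.get(other) != pos_filter:
            continue
        candidates.append((other, cosine(target, space.vector(other))))
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return candidates[:n]


def save_space(space: SemanticSpace, prefix: str | Path) -> None:
    """Serialize a space as vocab list + whitespace matrix + JSON config."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    Path(f"{prefix}.vocab.txt").write_text(
        "\n".join(space.vocabulary) + "\n", encoding="utf-8"
    )
    np.savetxt(f"{prefix}.vectors.txt", space.vectors, fmt="%.17g")
    Path(f"{prefix}.json").write_text(
        json.dumps(
            {
                "window": space.config.window,
                "weighting": space.config.weighting,
                "svd_dim": space.config.svd_dim,
                "min_count": space.config.min_count,
                "seed": space.config.seed,
            },
            indent=2,
        ),
        encoding="utf-8",
    )


def load_space(prefix: str | Path) -> SemanticSpace:
    prefix = Path(prefix)
    vocabulary = Path(f"{prefix}.vocab.txt").read_text(encoding="utf-8").split()
    vectors = np.loadtxt(f"{prefix}.vectors.txt", ndmin=2)
    cfg = json.loads(Path(f"{prefix}.json").read_text(encoding="utf-8"))
    return SemanticSpace(
        vocabulary=vocabulary, vectors=vectors, config=SpaceConfig(**cfg)
    )
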