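"""Synthetic corpora with planted co-occurrence and trait-enrichment structure.

Real inputs to this pipeline are (i) a large background corpus from which
the semantic space is learned and (ii) a labeled collection in which a few
positive-class documents are lexically tilted toward certain psychological
vocabulary.  Neither can ship with the package, so this module generates
both with known ground truth:

* Background documents are sampled token-by-token from a unigram mixture of
  abstract filler words (``w012``-style), high-frequency function-word
  stand-ins, the 36 distinct trait seed words, and per-trait context words.
  Whenever a seed word is emitted, the following ``neighborhood_window``
  positions are redrawn, with probability ``neighborhood_strength``, from
  that seed's planted context neighborhood — a first-order dependence that
  is exactly what windowed co-occurrence counting measures.  Seeds of the
  same trait share one neighborhood, so their vectors become similar.
* Labeled documents use the same process; in positive documents each
  content-word (noun/verb/adjective) draw is replaced with probability
  ``enrichment_theta`` by a word from the target trait's pool (its seeds
  plus their context words).  theta = 0 is the exchangeable null; theta = 1
  makes every content word come from the trait pool.

All vocabularies are abstract tokens plus the lexicon seed words; no real
violent text is embedded.  The POS dictionary used for generation doubles
as the deterministic fixture tagger's dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, Document
from .trait_scoring import TraitLexicon, builtin_lexicon

__all__ = [
    "GeneratorConfig",
    "SyntheticBundle",
    "default_generator_config",
    "generate_background",
    "generate_labeled",
    "make_fixture_bundle",
]

FIXTURE_SIZES = ("tiny", "small", "paper_shaped")


def _letters(i: int) -> str:
    """Base-26 letter code; synthetic words must be all-letters so the
    tokenizer keeps them whole."""
    digits = []
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        digits.append(chr(ord("a") + r))
    return "".join(reversed(digits))


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of a synthetic study.

    vocab_size counts the abstract filler words; the distinct trait seed
    words and the planted context words are always part of the vocabulary
    on top of it, so every trait stays scoreable even in tiny fixtures.
    """

    trait_neighborhoods: Mapping[str, tuple[str, ...]]  # seed word -> context words
    pos_dictionary: Mapping[str, str]  # full vocabulary -> NOUN/VERB/ADJ/OTHER
    vocab_size: int = 200
    n_background_docs: int = 200
    doc_length: int = 2000
    labeled_doc_length: int = 150
    enrichment_theta: float = 0.0
    n_positive: int = 6
    n_comparison: int = 200
    seed: int = 0
    neighborhood_strength: float = 0.9
    neighborhood_window: int = 3
    lexical_mass: float = 0.25  # unigram mass on seeds + context words

    def __post_init__(self) -> None:
        if not 0.0 <= self.enrichment_theta <= 1.0:
            raise ValueError("enrichment_theta must lie in [0, 1]")
        if not 0.0 <= self.neighborhood_strength <= 1.0:
            raise ValueError("neighborhood_strength must lie in [0, 1]")
        vocab = set(self.pos_dictionary)
        for seed_word, context in self.trait_neighborhoods.items():
            if seed_word not in vocab:
                raise ValueError(f"neighborhood seed {seed_word!r} not in vocabulary")
            for w in context:
                if w not in vocab:
                    raise ValueError(
                        f"neighborhood of {seed_word!r} references OOV word {w!r}"
                    )


@dataclass
class SyntheticBundle:
    """A background corpus, a labeled corpus, and the truth that made them."""

    background: Corpus
    labeled: Corpus
    truth: GeneratorConfig


def default_generator_config(
    planted_traits: Sequence[str] = ("Revengeful", "DEP"),
    ctx_per_trait: int = 6,
    lexicon: TraitLexicon | None = None,
    **overrides,
) -> GeneratorConfig:
    """Build a config with one shared context neighborhood per planted trait.

    Every distinct seed word of the full lexicon enters the vocabulary;
    seeds of each planted trait share ``ctx_per_trait`` context words so
    that they acquire similar vectors in the learned space.  Fillers get a
    Zipf-flavored unigram distribution with a small block of high-frequency
    OTHER-tagged function-word stand-ins.
    """
    lexicon = lexicon or builtin_lexicon()
    vocab_size = int(overrides.pop("vocab_size", 200))

    pos_dictionary: dict[str, str] = {}
    n_stop = max(4, vocab_size // 10)
    content_pos = ("NOUN", "VERB", "ADJ")
    for i in range(vocab_size):
        word = f"fil{_letters(i)}"
        pos_dictionary[word] = "OTHER" if i < n_stop else content_pos[i % 3]

    # Seed words: the Pain facet is nominal, everything else adjectival.
    for trait in lexicon:
        pos = "NOUN" if trait.name == "Pain" else "ADJ"
        for w in trait.seed_words:
            pos_dictionary.setdefault(w, pos)

    trait_neighborhoods: dict[str, list[str]] = {}
    for trait_name in planted_traits:
        trait = lexicon[trait_name]
        context = []
        for j in range(ctx_per_trait):
            w = f"ctx{trait_name.lower()}{_letters(j)}"
            pos_dictionary[w] = content_pos[j % 3]
            context.append(w)
        for seed_word in trait.seed_words:
            trait_neighborhoods.setdefault(seed_word, [])
            trait_neighborhoods[seed_word].extend(context)

    return GeneratorConfig(
        trait_neighborhoods={
            k: tuple(dict.fromkeys(v)) for k, v in trait_neighborhoods.items()
        },
        pos_dictionary=pos_dictionary,
        vocab_size=vocab_size,
        **overrides,
    )


class _Model:
    """Arrays precomputed from a config for fast vectorized sampling."""

    def __init__(self, config: GeneratorConfig, lexicon: TraitLexicon | None = None):
        self.config = config
        self.lexicon = lexicon or builtin_lexicon()
        self.words = sorted(config.pos_dictionary)
        self.index = {w: i for i, w in enumerate(self.words)}
        pos = config.pos_dictionary

        fillers = [w for w in self.words if pos[w] == "OTHER"]
        lexical = sorted(
            set(config.trait_neighborhoods)
            | {w for ctx in config.trait_neighborhoods.values() for w in ctx}
            | {w for t in self.lexicon for w in t.seed_words}
        )
        content_fillers = [
            w for w in self.words if pos[w] != "OTHER" and w not in lexical
        ]

        # Unigram distribution: Zipf-ish within each block, fixed block masses.
        p = np.zeros(len(self.words))
        for block, mass in (
            (fillers, 0.35),
            (content_fillers, 1.0 - 0.35 - config.lexical_mass),
            (lexical, config.lexical_mass),
        ):
            if not block:
                continue
            w = 1.0 / (np.arange(len(block)) + 2.0)
            w /= w.sum()
            for word, wt in zip(block, w):
                p[self.index[word]] = mass * wt
        self.unigram = p / p.sum()

        self.neighborhood_ids = {
            self.index[s]: np.array([self.index[c] for c in ctx], dtype=np.int64)
            for s, ctx in config.trait_neighborhoods.items()
            if len(ctx) > 0
        }
        self.content_ids = np.array(
            [self.index[w] for w in self.words if pos[w] != "OTHER"], dtype=np.int64
        )

    def trait_pool(self, trait_name: str) -> np.ndarray:
        """Word ids a positive document's enriched draws come from."""
        trait = self.lexicon[trait_name]
        pool = list(trait.seed_words)
        for s in trait.seed_words:
            pool.extend(self.config.trait_neighborhoods.get(s, ()))
        return np.array(
            sorted({self.index[w] for w in pool if w in self.index}), dtype=np.int64
        )

    def sample(
        self,
        rng: np.random.Generator,
        n_docs: int,
        length: int,
        theta_rows: np.ndarray | None = None,
        trait_pool: np.ndarray | None = None,
    ) -> np.ndarray:
        """Sample an (n_docs, length) matrix of word ids."""
        cfg = self.config
        base = rng.choice(len(self.words), size=(n_docs, length), p=self.unigram)
        out = base.copy()
        # First-order neighborhood structure: positions after a seed word
        # are redrawn from its context neighborhood.
        for sid, nb in self.neighborhood_ids.items():
            rows, cols = np.nonzero(base == sid)
            for d in range(1, cfg.neighborhood_window + 1):
                ok = cols + d < length
                r, c = rows[ok], cols[ok] + d
                hit = rng.random(r.size) < cfg.neighborhood_strength
                out[r[hit], c[hit]] = nb[rng.integers(0, len(nb), size=int(hit.sum()))]
        if theta_rows is not None and trait_pool is not None and theta_rows.any():
            content = np.isin(out, self.content_ids)
            chosen = content & (rng.random(out.shape) < theta_rows[:, None])
            n_rep = int(chosen.sum())
            if n_rep:
                out[chosen] = trait_pool[rng.integers(0, len(trait_pool), size=n_rep)]
        return out

    def to_documents(
        self, matrix: np.ndarray, ids: Sequence[str], labels: Sequence[str | None]
    ) -> list[Document]:
        return [
            Document(
                doc_id=doc_id,
                raw_text=" ".join(self.words[t] for t in row),
                label=label,
            )
            for doc_id, label, row in zip(ids, labels, matrix)
        ]


def generate_background(config: GeneratorConfig) -> Corpus:
    """Sample the background corpus the semantic space is learned from."""
    model = _Model(config)
    rng = np.random.default_rng([config.seed, 0])
    matrix = model.sample(rng, config.n_background_docs, config.doc_length)
    ids = [f"bg{i:04d}" for i in range(config.n_background_docs)]
    return Corpus(model.to_documents(matrix, ids, [None] * len(ids)))


def generate_labeled(config: GeneratorConfig, trait: str) -> Corpus:
    """Sample the labeled collection: enriched positives, null comparisons.

    Which documents are positive is itself randomized (seeded), so under
    theta = 0 labels are exchangeable even through doc_id tie-breaking.
    """
    if config.n_positive < 1:
        raise ValueError("n_positive must be >= 1")
    model = _Model(config)
    model.lexicon[trait]  # raises KeyError for an unknown trait
    rng = np.random.default_rng([config.seed, 1])
    n_total = config.n_positive + config.n_comparison
    positive_idx = set(
        rng.choice(n_total, size=config.n_positive, replace=False).tolist()
    )
    theta_rows = np.array(
        [
            config.enrichment_theta if i in positive_idx else 0.0
            for i in range(n_total)
        ]
    )
    matrix = model.sample(
        rng,
        n_total,
        config.labeled_doc_length,
        theta_rows=theta_rows,
        trait_pool=model.trait_pool(trait),
    )
    width = max(4, len(str(n_total - 1)))
    ids = [f"d{i:0{width}d}" for i in range(n_total)]
    labels = ["positive" if i in positive_idx else "comparison" for i in range(n_total)]
    return Corpus(model.to_documents(matrix, ids, labels))


_FIXTURES = {
    "tiny": dict(
        vocab_size=50,
        n_background_docs=30,
        doc_length=2000,
        labeled_doc_length=120,
        n_positive=6,
        n_comparison=24,
    ),
    "small": dict(
        vocab_size=500,
        n_background_docs=300,
        doc_length=4000,
        labeled_doc_length=150,
        n_positive=6,
        n_comparison=200,
    ),
    "paper_shaped": dict(
        vocab_size=300,
        n_background_docs=400,
        doc_length=2000,
        labeled_doc_length=150,
        n_positive=6,
        n_comparison=2000,
    ),
}


def make_fixture_bundle(
    size: str = "small",
    seed: int = 0,
    trait: str = "Revengeful",
    enrichment_theta: float = 0.8,
) -> SyntheticBundle:
    """One call from nothing to a complete synthetic study.

    tiny: 50 filler words / 30 background documents (unit tests);
    small: 500 / 300 (integration); paper_shaped: 6 positives vs 2000
    comparison documents (screening-metric tests at reduced scale).
    """
    if size not in _FIXTURES:
        raise ValueError(f"size must be one of {FIXTURE_SIZES}")
    config = default_generator_config(
        planted_traits=(trait, "DEP") if trait != "DEP" else ("DEP", "Revengeful"),
        seed=seed,
        enrichment_theta=enrichment_theta,
        **_FIXTURES[size],
    )
    return SyntheticBundle(
        background=generate_background(config),
        labeled=generate_labeled(config, trait),
        truth=config,
    )
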