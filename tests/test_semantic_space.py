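"""Co-occurrence counting, PPMI weighting, and cosine similarity queries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitspace.corpus_io import Corpus, Document
from traitspace.semantic_space import (
    OOVWordError,
    SpaceConfig,
    SpaceError,
    build_cooccurrence,
    build_space,
    cosine,
    load_space,
    neighbors,
    save_space,
    similarity,
    weight,
)

from oracles import brute_cooccurrence


def corpus_of(*texts):
    return Corpus([Document(f"d{i}", t) for i, t in enumerate(texts)])


RAW0 = SpaceConfig(weighting="raw", min_count=0)


class TestCooccurrence:
    def test_adjacent_pairs_counted_both_ways(self):
        cooc = build_cooccurrence(
            corpus_of("sad lonely sad"), SpaceConfig(window=1, min_count=0)
        )
        i = cooc.index
        assert cooc.counts[i["sad"], i["lonely"]] == 2
        assert cooc.counts[i["lonely"], i["sad"]] == 2
        assert cooc.counts[i["sad"], i["sad"]] == 0

    def test_windows_do_not_cross_documents(self):
        cooc = build_cooccurrence(
            corpus_of("a b", "c d"), SpaceConfig(window=3, min_count=0)
        )
        i = cooc.index
        assert cooc.counts[i["b"], i["c"]] == 0

    def test_min_count_drops_rare_words(self):
        cooc = build_cooccurrence(
            corpus_of("sad sad lonely sad rare"), SpaceConfig(window=1, min_count=2)
        )
        assert "rare" not in cooc.vocabulary
        assert "sad" in cooc.vocabulary

    def test_empty_vocabulary_after_filter_errors(self):
        with pytest.raises(SpaceError):
            build_cooccurrence(corpus_of("a b c"), SpaceConfig(min_count=5))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(st.sampled_from("abcde"), min_size=1, max_size=12),
            min_size=1,
            max_size=4,
        ),
        st.integers(min_value=1, max_value=4),
    )
    def test_counts_match_brute_force_enumeration(self, docs, window):
        corpus = Corpus([Document(f"d{i}", " ".join(doc)) for i, doc in enumerate(docs)])
        cooc = build_cooccurrence(corpus, SpaceConfig(window=window, min_count=0))
        oracle = brute_cooccurrence(docs, window)
        i = cooc.index
        assert np.array_equal(cooc.counts, cooc.counts.T)
        assert np.all(np.diag(cooc.counts) == 0)
        for a in cooc.vocabulary:
            for b in cooc.vocabulary:
                if a != b:
                    assert cooc.counts[i[a], i[b]] == oracle.get((a, b), 0)


class TestWeighting:
    def test_ppmi_closed_form(self):
        counts = np.array([[0, 4], [4, 0]])
        w = weight(counts, "ppmi")
        # T=8, r=[4,4]: log2(4*8/16) = 1 off-diagonal
        assert w[0, 1] == pytest.approx(1.0)
        assert w[1, 0] == pytest.approx(1.0)
        assert w[0, 0] == 0.0

    def test_ppmi_clamps_negative_association(self):
        counts = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]])
        # cell (0,1): c*T = 22 < r0*r1 = 36 -> clamped to 0
        w = weight(counts, "ppmi")
        assert w[0, 1] == 0.0
        assert np.all(w >= 0.0)

    def test_raw_is_identity(self):
        counts = np.array([[0, 3], [3, 0]])
        assert np.array_equal(weight(counts, "raw"), counts)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(SpaceError):
            weight(np.zeros((2, 2)), "ppmi")

    def test_raw_cosine_scale_invariant(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 10, (6, 6))
        counts = counts + counts.T
        np.fill_diagonal(counts, 0)
        w1 = weight(counts, "raw")
        w7 = weight(counts * 7, "raw")
        for i in range(6):
            for j in range(6):
                assert cosine(w1[i], w1[j]) == pytest.approx(
                    cosine(w7[i], w7[j]), abs=1e-12
                )


class TestBuildSpace:
    def test_raw_vector_coordinates_are_cooccurrence_counts(self):
        # "depressed" seen with "anxious" six times and "angry" three times
        corpus = corpus_of(*(["depressed anxious"] * 6 + ["depressed angry"] * 3))
        space = build_space(corpus, SpaceConfig(window=1, weighting="raw", min_count=0))
        vec = space.vector("depressed")
        coords = dict(zip(space.vocabulary, vec))
        assert coords["anxious"] == 6
        assert coords["angry"] == 3

    def test_full_rank_svd_preserves_cosines(self, tiny_bundle):
        corpus = Corpus(tiny_bundle.background.documents[:5])
        plain = build_space(corpus, SpaceConfig(min_count=2))
        reduced = build_space(
            corpus, SpaceConfig(min_count=2, svd_dim=len(plain.vocabulary))
        )
        rng = np.random.default_rng(0)
        words = rng.choice(plain.vocabulary, size=(30, 2))
        for a, b in words:
            assert similarity(plain, a, b) == pytest.approx(
                similarity(reduced, a, b), abs=1e-8
            )

    def test_svd_dim_too_large_errors(self):
        with pytest.raises(SpaceError):
            build_space(corpus_of("a b a b"), SpaceConfig(min_count=0, svd_dim=99))

    def test_deterministic_rebuild(self, tiny_bundle):
        corpus = Corpus(tiny_bundle.background.documents[:4])
        s1 = build_space(corpus, SpaceConfig())
        s2 = build_space(corpus, SpaceConfig())
        assert s1.vocabulary == s2.vocabulary
        assert np.array_equal(s1.vectors, s2.vectors)


class TestSimilarity:
    def test_self_similarity_is_one(self, tiny_space):
        word = tiny_space.vocabulary[0]
        assert similarity(tiny_space, word, word) == pytest.approx(1.0)

    def test_symmetry(self, tiny_space):
        rng = np.random.default_rng(1)
        for a, b in rng.choice(tiny_space.vocabulary, size=(25, 2)):
            assert abs(
                similarity(tiny_space, a, b) - similarity(tiny_space, b, a)
            ) < 1e-12

    def test_disjoint_profiles_are_orthogonal(self):
        space = build_space(corpus_of("a b", "c d"), RAW0)
        assert similarity(space, "a", "c") == 0.0

    def test_oov_error_names_the_word(self, tiny_space):
        with pytest.raises(OOVWordError, match="zzzmissing"):
            similarity(tiny_space, "zzzmissing", tiny_space.vocabulary[0])

    def test_planted_synonyms_are_close(self, small_bundle):
        """Seeds sharing a planted context neighborhood develop cosine > 0.8."""
        space = build_space(small_bundle.background, SpaceConfig())
        assert similarity(space, "revengeful", "vindictive") > 0.8


class TestNeighbors:
    def test_large_n_returns_all_other_words(self):
        space = build_space(corpus_of("a b c a b c"), RAW0)
        result = neighbors(space, "a", n=100)
        assert len(result) == len(space.vocabulary) - 1

    def test_identical_vectors_tie_break_alphabetically(self):
        space = build_space(corpus_of("a q", "b q"), RAW0)
        result = neighbors(space, "q", n=2)
        assert [w for w, _ in result] == ["a", "b"]

    def test_planted_neighbor_ranks_first(self, tiny_space):
        """The nearest neighbor of a planted seed, verified by exhaustive
        cosine scan, is another member of its planted neighborhood."""
        target = tiny_space.vector("revengeful")
        best, best_sim = None, -2.0
        for w in tiny_space.vocabulary:  # independent scan
            if w == "revengeful":
                continue
            s = cosine(target, tiny_space.vector(w))
            if s > best_sim or (s == best_sim and w < best):
                best, best_sim = w, s
        result = neighbors(tiny_space, "revengeful", n=1)
        assert result[0][0] == best
        planted = {"vengeful", "vindictive"} | {
            w for w in tiny_space.vocabulary if w.startswith("ctxrevengeful")
        }
        assert best in planted

    def test_pos_filter_restricts_candidates(self, tiny_space, tiny_bundle):
        lookup = tiny_bundle.truth.pos_dictionary
        result = neighbors(tiny_space, "revengeful", n=5, pos_filter="NOUN",
                           pos_lookup=lookup)
        assert all(lookup[w] == "NOUN" for w, _ in result)


def test_space_serialization_roundtrip(tmp_path, tiny_space):
    save_space(tiny_space, tmp_path / "space")
    back = load_space(tmp_path / "space")
    assert back.vocabulary == tiny_space.vocabulary
    assert np.array_equal(back.vectors, tiny_space.vectors)
    assert back.config == tiny_space.config
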