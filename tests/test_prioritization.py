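"""Classifier ranking, steps-to-identify-all, and rank aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitspace.prioritization import (
    ModelSpec,
    fit_and_score,
    mean_rank_ensemble,
    random_baseline_steps,
    rank_descending,
    rank_documents,
    screening_report,
    steps_to_identify_all,
)
from traitspace.trait_scoring import ScoreMatrix, builtin_lexicon


def series(mapping):
    return pd.Series(mapping)


class TestRankDescending:
    def test_sorting(self):
        ranks = rank_descending(series({"a": 0.9, "b": 0.1, "c": 0.5}))
        assert ranks.to_dict() == {"a": 1, "c": 2, "b": 3}

    def test_all_equal_follows_doc_id_order(self):
        ranks = rank_descending(series({"c": 0.5, "a": 0.5, "b": 0.5}))
        assert ranks.to_dict() == {"a": 1, "b": 2, "c": 3}

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_ranks_are_a_permutation(self, probs):
        s = pd.Series(probs, index=[f"d{i:02d}" for i in range(len(probs))])
        ranks = rank_descending(s)
        assert sorted(ranks) == list(range(1, len(probs) + 1))


class TestStepsToIdentifyAll:
    def test_printed_rank_profile(self):
        """Six positives at ranks {1,2,69,79,119,228} in a 6062-document
        collection are all found after reading 228 texts."""
        n = 6062
        positive_ranks = [1, 2, 69, 79, 119, 228]
        ranks = pd.Series(np.arange(1, n + 1), index=[f"d{i:05d}" for i in range(n)])
        labels = pd.Series("comparison", index=ranks.index)
        labels[ranks.isin(positive_ranks)] = "positive"
        assert steps_to_identify_all(ranks, labels) == 228

    def test_best_case_equals_number_of_positives(self):
        ranks = series({"a": 1, "b": 2, "c": 3, "d": 4})
        labels = series({"a": "positive", "b": "positive", "c": "comparison",
                         "d": "comparison"})
        assert steps_to_identify_all(ranks, labels) == 2

    def test_max_rank_rule(self):
        ranks = pd.Series(np.arange(1, 1001), index=[f"d{i:04d}" for i in range(1000)])
        labels = pd.Series("comparison", index=ranks.index)
        labels[ranks.isin([5, 100])] = "positive"
        assert steps_to_identify_all(ranks, labels) == 100

    def test_invariant_to_shuffling_later_comparisons(self):
        ranks = series({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5})
        labels = series({"a": "positive", "b": "positive", "c": "comparison",
                         "d": "comparison", "e": "comparison"})
        before = steps_to_identify_all(ranks, labels)
        shuffled = series({"a": 1, "b": 2, "c": 5, "d": 3, "e": 4})
        assert steps_to_identify_all(shuffled, labels) == before

    def test_no_positives_rejected(self):
        ranks = series({"a": 1})
        with pytest.raises(ValueError):
            steps_to_identify_all(ranks, series({"a": "comparison"}))


class TestMeanRankEnsemble:
    def test_identity_on_identical_inputs(self):
        r = series({"a": 2, "b": 1, "c": 3})
        assert mean_rank_ensemble([r, r, r]).to_dict() == r.to_dict()

    def test_hand_computed_example(self):
        ra = series({"a": 1, "b": 2, "c": 3})
        rb = series({"a": 3, "b": 1, "c": 2})
        # means: a=2.0, b=1.5, c=2.5 -> b first
        assert mean_rank_ensemble([ra, rb]).to_dict() == {"b": 1, "a": 2, "c": 3}

    def test_single_list_is_identity(self):
        r = series({"a": 1, "b": 2})
        assert mean_rank_ensemble([r]).to_dict() == r.to_dict()

    def test_output_is_permutation(self):
        rng = np.random.default_rng(0)
        idx = [f"d{i}" for i in range(20)]
        lists = [
            pd.Series(rng.permutation(20) + 1, index=idx) for _ in range(3)
        ]
        out = mean_rank_ensemble(lists)
        assert sorted(out) == list(range(1, 21))

    def test_mismatched_documents_rejected(self):
        with pytest.raises(ValueError):
            mean_rank_ensemble([series({"a": 1}), series({"b": 1})])


def test_random_baseline_closed_form_matches_simulation():
    """m(N+1)/(m+1) equals the simulated expected max position of m
    positives placed uniformly among N documents."""
    m, n = 5, 100
    expected = random_baseline_steps(m, n)
    assert expected == pytest.approx(5 * 101 / 6)
    rng = np.random.default_rng(12)
    draws = rng.random((100_000, n)).argpartition(m - 1, axis=1)[:, :m]
    simulated = (draws.max(axis=1) + 1).mean()
    assert simulated == pytest.approx(expected, rel=0.01)


def _separable_matrix(n_pos=6, n_comp=34, shift=6.0, seed=0):
    rng = np.random.default_rng(seed)
    names = builtin_lexicon().names
    values = rng.normal(size=(n_pos + n_comp, 13))
    values[:n_pos, :4] += shift  # positives shifted well clear on four traits
    idx = [f"d{i:03d}" for i in range(n_pos + n_comp)]
    labels = pd.Series(["positive"] * n_pos + ["comparison"] * n_comp, index=idx)
    return (
        ScoreMatrix(scores=pd.DataFrame(values, index=idx, columns=names),
                    labels=labels),
        labels,
    )


class TestFitAndScore:
    @pytest.mark.parametrize("kind", ["logistic", "tree", "knn"])
    def test_separable_classes_fully_ordered(self, kind):
        matrix, labels = _separable_matrix()
        probs = fit_and_score(matrix, spec=ModelSpec(kind=kind, seed=3))
        pos = probs[labels == "positive"]
        comp = probs[labels != "positive"]
        assert pos.min() > comp.max()

    @pytest.mark.parametrize("kind", ["logistic", "tree", "knn"])
    def test_constant_features_give_equal_probabilities(self, kind):
        names = builtin_lexicon().names
        idx = [f"d{i}" for i in range(12)]
        matrix = ScoreMatrix(
            scores=pd.DataFrame(0.3, index=idx, columns=names),
            labels=pd.Series(["positive"] * 3 + ["comparison"] * 9, index=idx),
        )
        probs = fit_and_score(matrix, spec=ModelSpec(kind=kind, seed=0))
        assert probs.nunique() == 1

    def test_deterministic(self):
        matrix, _ = _separable_matrix(shift=1.0)
        a = fit_and_score(matrix, spec=ModelSpec(kind="tree", seed=5))
        b = fit_and_score(matrix, spec=ModelSpec(kind="tree", seed=5))
        assert a.equals(b)

    def test_cv_mode_produces_out_of_fold_probabilities(self):
        matrix, labels = _separable_matrix(n_pos=10, n_comp=40)
        probs = fit_and_score(matrix, spec=ModelSpec(kind="logistic", seed=1),
                              mode="cv")
        assert probs.index.equals(matrix.scores.index)
        assert probs.between(0, 1).all()

    def test_single_class_rejected(self):
        names = builtin_lexicon().names
        idx = ["a", "b"]
        matrix = ScoreMatrix(
            scores=pd.DataFrame(0.0, index=idx, columns=names),
            labels=pd.Series(["comparison", "comparison"], index=idx),
        )
        with pytest.raises(ValueError):
            fit_and_score(matrix)

    def test_undefined_cells_imputed_not_fatal(self):
        matrix, labels = _separable_matrix()
        matrix.scores.iloc[2, 5] = np.nan
        probs = fit_and_score(matrix, spec=ModelSpec(kind="logistic", seed=0))
        assert probs.notna().all()


class TestRankDocumentsAndReport:
    def test_all_models_plus_ensemble(self):
        matrix, labels = _separable_matrix()
        results = rank_documents(matrix, seed=2)
        assert [r.model_name for r in results] == ["BLR", "TRE", "KNN", "MEAN"]
        for r in results:
            assert sorted(r.ranks) == list(range(1, 41))
            assert r.steps_to_identify_all == 6  # perfectly separable

    def test_screening_report_fractions_round_to_whole_percent(self):
        from traitspace.prioritization import RankingResult

        def result(name, steps, n):
            ranks = pd.Series(np.arange(1, n + 1), index=[f"d{i}" for i in range(n)])
            return RankingResult(name, None, ranks, steps, 100.0 * steps / n)

        report = screening_report(
            [result("TRE", 228, 6062), result("MEAN", 210, 6062)],
            n_docs=6062,
            n_positive=6,
        )
        tre = report.set_index("model").loc["TRE"]
        mean = report.set_index("model").loc["MEAN"]
        assert tre["fraction_pct"] == pytest.approx(100 * 228 / 6062)
        assert tre["fraction_rounded_pct"] == 4
        assert mean["fraction_rounded_pct"] == 3
        assert tre["random_baseline_steps"] == pytest.approx(6 * 6063 / 7)
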