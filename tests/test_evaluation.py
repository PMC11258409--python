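"""Strict-span scoring, dictionary extractor, mean-centering, Wilcoxon tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cuitrans import (
    AnnotatedCorpus,
    Annotation,
    CorpusValidationError,
    Document,
    dictionary_extractor,
    evaluate_strict,
    mean_center,
    wilcoxon_bonferroni,
)

from conftest import NL_CLEAN


def ann(doc, cui, start, end, text="x"):
    return Annotation(doc, cui, start, end, text)


class TestEvaluateStrict:
    def test_perfect_predictions(self):
        ref = [ann("d", "C1", 0, 4), ann("d", "C2", 10, 14)]
        m = evaluate_strict(ref, list(ref))
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)
        assert m.precision == m.recall == m.f1 == 1.0

    def test_half_right(self):
        ref = [ann("d", "C1", 0, 4), ann("d", "C2", 10, 14)]
        pred = [ann("d", "C1", 0, 4), ann("d", "C9", 10, 14)]
        m = evaluate_strict(ref, pred)
        assert (m.tp, m.fp, m.fn) == (1, 1, 1)
        assert m.precision == 0.5 and m.recall == 0.5 and m.f1 == 0.5

    def test_empty_predictions_zero_by_convention(self):
        ref = [ann("d", "C1", 0, 4)]
        m = evaluate_strict(ref, [])
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    def test_location_must_match_exactly(self):
        ref = [ann("d", "C1", 0, 4)]
        for bad in (ann("d", "C1", 0, 5), ann("d", "C1", 1, 4),
                    ann("e", "C1", 0, 4)):
            m = evaluate_strict(ref, [bad])
            assert m.tp == 0

    def test_one_to_one_matching_of_duplicates(self):
        ref = [ann("d", "C1", 0, 4)]
        pred = [ann("d", "C1", 0, 4), ann("d", "C1", 0, 4)]
        m = evaluate_strict(ref, pred)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_permutation_invariance(self):
        ref = [ann("d", "C1", 0, 4), ann("d", "C2", 5, 9), ann("d", "C3", 10, 14)]
        pred = [ann("d", "C2", 5, 9), ann("d", "C4", 10, 14)]
        base = evaluate_strict(ref, pred)
        for rp in itertools.permutations(ref):
            for pp in itertools.permutations(pred):
                assert evaluate_strict(list(rp), list(pp)) == base

    def test_overlap_mode_relaxes_location_only(self):
        ref = [ann("d", "C1", 0, 4)]
        pred_shifted = [ann("d", "C1", 2, 6)]
        assert evaluate_strict(ref, pred_shifted).tp == 0
        assert evaluate_strict(ref, pred_shifted, mode="overlap").tp == 1
        pred_wrong_cui = [ann("d", "C9", 0, 4)]
        assert evaluate_strict(ref, pred_wrong_cui, mode="overlap").tp == 0

    def test_invalid_prediction_against_corpus_rejected(self):
        corpus = AnnotatedCorpus("c", "nl", [Document("d", "short")], [])
        with pytest.raises(CorpusValidationError):
            evaluate_strict([], [ann("d", "C1", 0, 99, "nope")], corpus=corpus)

    def test_f1_symmetric_and_equal_when_p_equals_r(self):
        m = evaluate_strict(
            [ann("d", "C1", 0, 4), ann("d", "C2", 5, 9)],
            [ann("d", "C1", 0, 4), ann("d", "C3", 5, 9)],
        )
        assert m.precision == m.recall == m.f1


class TestDictionaryExtractor:
    def _corpus(self, text):
        return AnnotatedCorpus("c", "nl", [Document("d1", text)], [])

    def test_empty_lexicon_yields_nothing(self):
        assert dictionary_extractor(self._corpus("any text"), {}) == []

    def test_finds_term_at_published_offsets(self):
        out = dictionary_extractor(
            self._corpus(NL_CLEAN), {"niervergroting": "C0542518"}
        )
        assert [(a.cui, a.span_start, a.span_end) for a in out] == [
            ("C0542518", 11, 25)
        ]

    def test_longest_match_wins(self):
        out = dictionary_extractor(
            self._corpus("severe kidney enlargement observed"),
            {"kidney": "C0022646", "kidney enlargement": "C0542518"},
        )
        assert [a.cui for a in out] == ["C0542518"]

    def test_word_boundaries_respected(self):
        out = dictionary_extractor(self._corpus("osteokidneyosis"), {"kidney": "C1"})
        assert out == []

    def test_case_sensitivity_flag(self):
        corpus = self._corpus("Kidney failure")
        assert dictionary_extractor(corpus, {"kidney": "C1"},
                                    case_sensitive=True) == []
        out = dictionary_extractor(corpus, {"kidney": "C1"}, case_sensitive=False)
        assert [a.span_text for a in out] == ["Kidney"]


class TestMeanCenter:
    def test_two_values_center_symmetrically(self):
        df = pd.DataFrame({
            "corpus": ["mm", "mm"], "model": ["a", "b"],
            "metric": ["f1", "f1"], "value": [0.5, 0.7],
        })
        out = mean_center(df)
        assert list(out["centered"]) == pytest.approx([-0.1, 0.1])

    def test_corpora_centered_independently_to_zero_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "corpus": np.repeat(["mm", "sc", "mt"], 15),
            "model": np.tile(np.repeat(["a", "b", "c", "d", "e"], 3), 3),
            "metric": np.tile(["f1", "p", "r"], 15),
            "value": rng.uniform(0, 1, 45),
        })
        out = mean_center(df)
        for (_, _), group in out.groupby(["corpus", "metric"]):
            assert abs(group["centered"].mean()) < 1e-12
        # brute-force group-mean subtraction matches
        for i, row in out.iterrows():
            mask = (df["corpus"] == row["corpus"]) & (df["metric"] == row["metric"])
            assert row["centered"] == pytest.approx(
                row["value"] - df.loc[mask, "value"].mean()
            )

    def test_within_group_differences_unchanged(self):
        df = pd.DataFrame({
            "corpus": ["mm"] * 4, "metric": ["f1"] * 4,
            "value": [0.2, 0.4, 0.9, 0.3],
        })
        out = mean_center(df)
        raw = df["value"].to_numpy()
        cen = out["centered"].to_numpy()
        assert np.allclose(raw[:, None] - raw[None, :], cen[:, None] - cen[None, :])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mean_center(pd.DataFrame(columns=["corpus", "metric", "value"]))


# -- exhaustive rank-sum null oracle --------------------------------------

def oracle_ranksum_p(x, y):
    """Two-sided exact rank-sum p-value by enumerating all assignments of
    the pooled ranks to the first group (no ties allowed)."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in x)
    n = len(x)
    stats_all = [
        sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)
    ]
    mean = (n * (len(pooled) + 1)) / 2
    extreme = sum(
        1 for s in stats_all if abs(s - mean) >= abs(observed - mean) - 1e-12
    )
    return extreme / len(stats_all)


class TestWilcoxonBonferroni:
    def test_separated_groups_exact_p(self):
        result = wilcoxon_bonferroni({"lo": [1, 2, 3], "hi": [4, 5, 6]})
        assert result.comparisons[0].p_raw == pytest.approx(0.1)
        assert result.comparisons[0].p_adjusted == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        result = wilcoxon_bonferroni({"a": [1, 2, 3], "b": [1, 2, 3]})
        c = result.comparisons[0]
        assert c.p_adjusted >= result.alpha
        assert not c.significant

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_small_n_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 8, size=2)
        pooled = rng.choice(1000, size=nx + ny, replace=False).astype(float)
        x, y = list(pooled[:nx]), list(pooled[nx:])
        result = wilcoxon_bonferroni({"x": x, "y": y})
        assert result.comparisons[0].p_raw == pytest.approx(
            oracle_ranksum_p(x, y), abs=1e-12
        )

    def test_three_groups_bonferroni_times_three(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        result = wilcoxon_bonferroni(groups)
        assert result.n_comparisons == 3
        for c in result.comparisons:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))

    def test_paired_mode_identical_and_shifted(self):
        same = wilcoxon_bonferroni({"a": [1, 2, 3], "b": [1, 2, 3]}, paired=True)
        assert same.comparisons[0].p_raw == 1.0
        shifted = wilcoxon_bonferroni(
            {"a": [1, 2, 3, 4, 5, 6], "b": [2, 3, 4, 5, 6, 7]}, paired=True
        )
        assert shifted.comparisons[0].p_raw < 0.1

    def test_small_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="tiny"):
            wilcoxon_bonferroni({"tiny": [1.0], "ok": [1, 2, 3]})

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal"):
            wilcoxon_bonferroni({"a": [1, 2, 3], "b": [1, 2]}, paired=True)
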