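import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexread.lexicon import Lexicon, LexiconEntry
from lexread.osc import (
    DegenerateEmbeddingError,
    OscScorer,
    TargetNotInLexiconError,
    compute_osc,
    compute_osc_table,
    cosine_similarity,
    extract_relatives,
)
from oracles import brute_force_osc


class TestCosine:
    def test_identity_orthogonal_and_diagonal(self):
        v = np.array([0.3, -2.0, 5.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 1], [1, 0]) == pytest.approx(
            1 / math.sqrt(2), abs=1e-6
        )

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateEmbeddingError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            cosine_similarity([1.0, 0.0], [1.0, 0.0, 0.0])


class TestRelatives:
    def test_substring_match_any_position(self, cup_lexicon):
        rels = [e.word for e in extract_relatives("cup", cup_lexicon)]
        assert rels == ["cup", "cupboard", "cupid"]

    def test_isolated_word_is_own_relative(self):
        lex = Lexicon(
            LexiconEntry(w, 1.0, np.ones(2)) for w in ["qzx", "cup", "cat"]
        )
        assert [e.word for e in extract_relatives("qzx", lex)] == ["qzx"]

    def test_missing_target_raises(self, cup_lexicon):
        with pytest.raises(TargetNotInLexiconError):
            extract_relatives("mug", cup_lexicon)

    def test_infix_and_suffix_matches_included(self):
        lex = Lexicon(
            LexiconEntry(w, 1.0, np.ones(2))
            for w in ["out", "outage", "about", "routed"]
        )
        assert [e.word for e in extract_relatives("out", lex)] == [
            "about",
            "out",
            "outage",
            "routed",
        ]


class TestComputeOsc:
    def test_hand_example(self):
        # relatives: self f=10 cos=1; other f=5 cos=0.5
        v = np.array([1.0, 0.0])
        other = np.array([0.5, np.sqrt(3) / 2])  # cos = 0.5 with v
        lex = Lexicon(
            [LexiconEntry("ab", 10.0, v), LexiconEntry("abc", 5.0, other)]
        )
        r = compute_osc("ab", lex)
        assert r.osc == pytest.approx(0.833333, abs=1e-6)
        assert not r.degenerate_flag

    def test_isolated_word_scores_one_and_flags_degenerate(self):
        lex = Lexicon(
            LexiconEntry(w, 5.0, np.array([1.0, float(i)]))
            for i, w in enumerate(["aa", "bb", "cc"])
        )
        r = compute_osc("aa", lex)
        assert r.osc == pytest.approx(1.0)
        assert r.degenerate_flag
        assert r.n_relatives == 1

    def test_collinear_relatives_score_one(self):
        v = np.array([1.0, 2.0])
        lex = Lexicon(
            [
                LexiconEntry("ab", 10.0, 3.0 * v),
                LexiconEntry("abc", 2.0, 0.5 * v),
            ]
        )
        r = compute_osc("ab", lex)
        assert r.osc == pytest.approx(1.0)
        assert r.degenerate_flag

    def test_missing_embedding_flags_row(self):
        lex = Lexicon(
            [LexiconEntry("ab", 1.0, None), LexiconEntry("abc", 1.0, np.ones(2))]
        )
        r = compute_osc("ab", lex)
        assert r.missing_flag and math.isnan(r.osc)

    def test_all_zero_frequencies_fall_back_to_unweighted_mean(self):
        v = np.array([1.0, 0.0])
        other = np.array([0.0, 1.0])
        lex = Lexicon(
            [LexiconEntry("ab", 0.0, v), LexiconEntry("abc", 0.0, other)]
        )
        r = compute_osc("ab", lex)
        assert r.zero_frequency_fallback
        assert r.osc == pytest.approx(0.5)


class TestTableAndScorer:
    def test_table_oracle_equivalence_on_random_lexicons(self, lexicon_factory):
        rng = np.random.default_rng(7)
        for _ in range(10):
            lex, words, freqs, vecs = lexicon_factory(rng, n_words=25)
            table = compute_osc_table(lex).set_index("word")
            for t in words:
                expected, k = brute_force_osc(words, freqs, vecs, t)
                assert table.loc[t, "osc"] == pytest.approx(expected, abs=1e-12)
                assert table.loc[t, "n_relatives"] == k

    def test_missing_row_does_not_disturb_others(self, lexicon_factory):
        rng = np.random.default_rng(3)
        lex, words, freqs, vecs = lexicon_factory(rng, n_words=20, allow_missing=True)
        table = compute_osc_table(lex).set_index("word")
        for t in words:
            if vecs[t] is None:
                assert bool(table.loc[t, "missing_flag"])
            else:
                expected, _ = brute_force_osc(words, freqs, vecs, t)
                assert table.loc[t, "osc"] == pytest.approx(expected, abs=1e-12)

    def test_empty_target_list_gives_empty_table(self, cup_lexicon):
        assert len(compute_osc_table(cup_lexicon, targets=[])) == 0

    def test_scorer_transform_matches_table(self, cup_lexicon):
        scorer = OscScorer().fit(cup_lexicon)
        vals = scorer.transform(["cup", "cut"])
        table = scorer.score_table(["cup", "cut"])
        np.testing.assert_allclose(vals, table["osc"].to_numpy())

    def test_scorer_sklearn_params_roundtrip(self):
        s = OscScorer(degenerate_tol=1e-6)
        assert OscScorer(**s.get_params()).degenerate_tol == 1e-6


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=25, deadline=None)
def test_scale_invariance(scale):
    """Rescaling every embedding by a positive constant leaves scores fixed."""
    rng = np.random.default_rng(11)
    words = ["ab", "abc", "abd", "xy"]
    vecs = [rng.normal(size=6) for _ in words]
    freqs = [5.0, 2.0, 9.0, 1.0]
    base = Lexicon(
        LexiconEntry(w, f, v) for w, f, v in zip(words, freqs, vecs)
    )
    scaled = Lexicon(
        LexiconEntry(w, f, scale * v) for w, f, v in zip(words, freqs, vecs)
    )
    for t in words:
        assert abs(compute_osc(t, base).osc - compute_osc(t, scaled).osc) < 1e-12


@given(bump=st.floats(min_value=1.0, max_value=500.0))
@settings(max_examples=25, deadline=None)
def test_monotonicity_in_relative_frequency(bump):
    """Raising the weight of an above-score relative raises the score."""
    rng = np.random.default_rng(5)
    vecs = {w: rng.normal(size=8) for w in ["ab", "abc", "abd"]}
    freqs = {"ab": 10.0, "abc": 4.0, "abd": 6.0}

    def osc_with(freq_abc):
        lex = Lexicon(
            LexiconEntry(w, freq_abc if w == "abc" else freqs[w], vecs[w])
            for w in vecs
        )
        return compute_osc("ab", lex)

    base = osc_with(freqs["abc"])
    cos_abc = dict((w, c) for w, _, c in base.relatives)["abc"]
    moved = osc_with(freqs["abc"] + bump).osc
    if cos_abc > base.osc:
        assert moved > base.osc
    elif cos_abc < base.osc:
        assert moved < base.osc


def test_convex_combination_bounds(lexicon_factory):
    """Scores lie between the smallest and largest relative cosine."""
    rng = np.random.default_rng(13)
    lex, words, freqs, vecs = lexicon_factory(rng, n_words=30)
    for t in words:
        r = compute_osc(t, lex)
        cosines = [c for _, _, c in r.relatives]
        assert min(cosines) - 1e-12 <= r.osc <= max(cosines) + 1e-12
        assert -1.0 - 1e-12 <= r.osc <= 1.0 + 1e-12
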