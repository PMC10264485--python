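import math

import numpy as np
import pandas as pd
import pytest

from lexread.gam import PenalizedGAM
from lexread.measures import compute_measures
from lexread.osc import compute_osc_table
from lexread.synthetic import (
    GroundTruth,
    SyntheticConfig,
    make_corpus,
    make_eyetracking_dataset,
    make_lexicon,
    make_markov_corpus,
    make_spr_dataset,
    modelling_records,
)


def generate(cfg, kind="eyetracking"):
    rng = np.random.default_rng(cfg.seed)
    lex, truth = make_lexicon(cfg, rng)
    sents, truth = make_corpus(cfg, truth, rng)
    maker = make_eyetracking_dataset if kind == "eyetracking" else make_spr_dataset
    table, truth = maker(cfg, (lex, truth), (sents, truth), rng)
    return lex, sents, table, truth


class TestLexiconGeneration:
    def test_full_coherence_gives_consistency_one_for_stems(self):
        cfg = SyntheticConfig(seed=1, n_families=20, coherence=1.0)
        lex, truth = make_lexicon(cfg, np.random.default_rng(1))
        stems = truth.lexicon_truth[truth.lexicon_truth.is_stem]
        np.testing.assert_allclose(stems["osc"], 1.0, atol=1e-9)

    def test_zero_coherence_stem_score_near_frequency_share(self):
        cfg = SyntheticConfig(
            seed=2, n_families=40, coherence=0.0, embedding_dim=300,
            family_size_min=10, family_size_max=10,
        )
        lex, truth = make_lexicon(cfg, np.random.default_rng(2))
        lt = truth.lexicon_truth
        shares, oscs = [], []
        for fam, grp in lt.groupby("family"):
            stem = grp[grp.is_stem].iloc[0]
            shares.append(stem.frequency / grp.frequency.sum())
            oscs.append(stem.osc)
        # non-self cosines average ~0 at d=300, so E[osc] ~ self share
        assert abs(np.mean(np.array(oscs) - np.array(shares))) < 0.03

    def test_generator_truth_matches_scoring_module(self):
        cfg = SyntheticConfig(seed=3, n_families=25)
        lex, truth = make_lexicon(cfg, np.random.default_rng(3))
        table = compute_osc_table(lex).set_index("word")
        for row in truth.lexicon_truth.itertuples():
            assert table.loc[row.word, "osc"] == pytest.approx(row.osc, abs=1e-10)

    def test_single_member_families_are_exact_atoms_at_one(self):
        cfg = SyntheticConfig(seed=4, n_families=30, family_size_min=1,
                              family_size_max=3)
        lex, truth = make_lexicon(cfg, np.random.default_rng(4))
        lt = truth.lexicon_truth
        singles = lt.groupby("family").filter(lambda g: len(g) == 1)
        assert len(singles) > 0
        np.testing.assert_allclose(singles["osc"], 1.0, atol=1e-12)

    def test_same_seed_is_bit_identical(self):
        cfg = SyntheticConfig(seed=5, n_families=15)
        _, t1 = make_lexicon(cfg, np.random.default_rng(5))
        _, t2 = make_lexicon(cfg, np.random.default_rng(5))
        pd.testing.assert_frame_equal(t1.lexicon_truth, t2.lexicon_truth)


class TestCorpus:
    def test_deterministic_chain_has_zero_surprisal(self):
        states = ["a", "b", "c"]
        T = np.zeros((3, 4))
        T[0, 1] = T[1, 2] = T[2, 3] = 1.0  # a->b->c->end
        # build sentences by hand through the same truth convention
        sents, truth, T2, pi = make_markov_corpus(
            3, 60, alpha=100.0, end_probability=0.0001, seed=0, states=states
        )
        # surprisal of a forced transition is exactly -log(1) = 0 only for a
        # deterministic chain; here check the generic identity instead:
        for row, (sid, pos) in zip(
            truth.itertuples(), truth[["sentence_id", "position"]].values
        ):
            s = sents[sid]
            if pos == 1:
                assert row.surprisal == pytest.approx(-np.log(pi[states.index(s[0])]))

    def test_two_state_symmetric_chain_gives_log_two(self):
        cfg = SyntheticConfig(seed=6, n_families=2, family_size_min=1,
                              family_size_max=1, dirichlet_alpha=1e6,
                              n_sentences=10)
        rng = np.random.default_rng(6)
        lex, truth = make_lexicon(cfg, rng)
        sents, truth = make_corpus(cfg, truth, rng)
        non_initial = truth.token_truth[truth.token_truth.position > 1]
        # huge concentration => transitions essentially uniform over 2 states
        np.testing.assert_allclose(non_initial["surprisal"], math.log(2), atol=0.01)

    def test_token_truth_aligns_with_sentences(self):
        cfg = SyntheticConfig(seed=7, n_families=30, n_sentences=12)
        rng = np.random.default_rng(7)
        lex, truth = make_lexicon(cfg, rng)
        sents, truth = make_corpus(cfg, truth, rng)
        for row in truth.token_truth.itertuples():
            assert sents[row.sentence_id][row.position - 1] == row.word
        assert (truth.token_truth["surprisal"] >= 0).all()


class TestReadingDatasets:
    def test_round_trip_gaze_is_exact(self):
        cfg = SyntheticConfig(seed=8, n_subjects=4, n_sentences=15)
        _, _, fixations, truth = generate(cfg)
        meas = compute_measures(fixations).set_index(
            ["subject_id", "sentence_id", "word_index"]
        )
        rec = truth.records
        checked = 0
        for row in rec.itertuples():
            key = (row.subject_id, row.sentence_id, row.position)
            if row.skipped:
                assert key not in meas.index or math.isnan(
                    meas.loc[key, "gaze"]
                ) or meas.loc[key, "skipped_flag"]
                continue
            assert meas.loc[key, "gaze"] == row.intended_gaze
            checked += 1
        assert checked > 300

    def test_no_splits_or_regressions_collapses_measures(self):
        cfg = SyntheticConfig(seed=9, n_subjects=3, n_sentences=10,
                              p_skip=0.0, p_refixation=0.0, p_regression=0.0)
        _, _, fixations, truth = generate(cfg)
        meas = compute_measures(fixations)
        np.testing.assert_allclose(meas["gaze"], meas["right_bounded"])
        np.testing.assert_allclose(meas["gaze"], meas["regression_path"])

    def test_regressions_inflate_go_past_beyond_gaze(self):
        cfg = SyntheticConfig(seed=10, n_subjects=5, n_sentences=20,
                              p_regression=0.5)
        _, _, fixations, truth = generate(cfg)
        meas = compute_measures(fixations)
        ok = meas.dropna(subset=["gaze"])
        assert (ok["regression_path"] > ok["gaze"] + 1e-9).mean() > 0.2

    def test_noiseless_limit_recovers_planted_coefficients(self):
        cfg = SyntheticConfig(
            seed=11, n_subjects=6, n_sentences=40, surface_form="linear",
            residual_sd=0.0, subject_sd=0.0, word_sd=0.0,
            p_skip=0.0,
        )
        _, _, table, truth = generate(cfg, kind="spr")
        rec = modelling_records(truth)
        m = PenalizedGAM(interaction_form="linear", random_effects=False).fit(
            rec, rec["log_dv"]
        )
        got = m.fit_result_.parametric.set_index("term")["estimate"]
        expected = {
            "Intercept": cfg.beta_intercept,
            "length": cfg.beta_length,
            "log_frequency": cfg.beta_log_frequency,
            "position": cfg.beta_position,
            "osc": cfg.beta_osc,
            "surprisal": cfg.beta_surprisal,
            "osc_x_surprisal": cfg.beta_interaction,
        }
        for term, val in expected.items():
            assert got[term] == pytest.approx(val, abs=1e-6)

    def test_spr_table_layout(self):
        cfg = SyntheticConfig(seed=12, n_subjects=2, n_sentences=5)
        _, _, table, truth = generate(cfg, kind="spr")
        assert list(table.columns) == [
            "subject_id", "sentence_id", "position", "word", "rt"
        ]
        assert (table["rt"] > 0).all()

    def test_fixation_streams_are_reproducible(self):
        cfg = SyntheticConfig(seed=13, n_subjects=3, n_sentences=8)
        _, _, f1, _ = generate(cfg)
        _, _, f2, _ = generate(cfg)
        pd.testing.assert_frame_equal(f1, f2)


class TestConfigValidation:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(residual_sd=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(coherence=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(surface_form="quadratic")
        with pytest.raises(ValueError):
            SyntheticConfig(p_skip=1.2)

    def test_dip_surface_needs_a_centre(self):
        truth = GroundTruth(config=SyntheticConfig(surface_form="dip"))
        with pytest.raises(ValueError):
            truth.surface(np.array([0.4]), np.array([3.0]))

    def test_too_many_families_for_stem_space_raises(self):
        cfg = SyntheticConfig(n_families=200, stem_length_min=2, stem_length_max=2)
        with pytest.raises(ValueError):
            make_lexicon(cfg, np.random.default_rng(0))
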