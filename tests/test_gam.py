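import numpy as np
import pandas as pd
import pytest

from lexread.gam import (
    ModelSpec,
    PenalizedGAM,
    build_design,
    compare_forms,
    fit_penalized,
    model_criticism,
)
from oracles import ols_coefficients


def toy_records(n=120, seed=0, with_groups=True):
    rng = np.random.default_rng(seed)
    rec = pd.DataFrame(
        {
            "length": rng.integers(2, 9, n).astype(float),
            "log_frequency": rng.normal(8, 2, n),
            "position": rng.integers(1, 10, n).astype(float),
            "osc": rng.uniform(0, 1, n),
            "surprisal": rng.uniform(0, 10, n),
        }
    )
    if with_groups:
        rec["subject_id"] = [f"s{i % 6}" for i in range(n)]
        rec["word_type"] = [f"w{i % 15}" for i in range(n)]
    rec["log_dv"] = (
        5.4
        + 0.01 * rec["length"]
        - 0.01 * rec["log_frequency"]
        + 0.02 * rec["osc"] * rec["surprisal"]
        + rng.normal(0, 0.2, n)
    )
    return rec


class TestDesign:
    def test_tensor_block_has_constrained_dimension(self):
        d = build_design(toy_records(), ModelSpec(k_osc=5, k_surprisal=5))
        te = next(t for t in d.terms if t.name == "te(osc,surprisal)")
        assert te.size == 5 * 5 - 1  # one sum-to-zero constraint
        assert len(te.penalties) == 2

    def test_linear_interaction_has_three_columns(self):
        d = build_design(toy_records(), ModelSpec(interaction_form="linear"))
        li = next(t for t in d.terms if t.name == "linear_interaction")
        assert li.size == 3

    def test_random_effect_blocks_have_one_column_per_level(self):
        d = build_design(toy_records(), ModelSpec())
        assert next(t for t in d.terms if t.name == "s(subject)").size == 6
        assert next(t for t in d.terms if t.name == "s(word)").size == 15

    def test_constant_covariate_raises(self):
        rec = toy_records().assign(osc=0.5)
        with pytest.raises(ValueError, match="unique values"):
            build_design(rec, ModelSpec())

    def test_too_small_basis_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(k_osc=3)

    def test_nonfinite_covariate_raises(self):
        rec = toy_records()
        rec.loc[0, "surprisal"] = np.inf
        with pytest.raises(ValueError):
            build_design(rec, ModelSpec())


class TestPenalizedFit:
    def test_zero_smoothing_equals_ols_on_expanded_basis(self):
        rng = np.random.default_rng(4)
        n = 50
        rec = toy_records(n=n, seed=4, with_groups=False)
        y = rng.normal(5.4, 0.3, n)
        m = PenalizedGAM(
            interaction_form="tensor", k_osc=4, k_surprisal=4,
            random_effects=False, fixed_lambdas=0.0,
        ).fit(rec, y)
        beta = ols_coefficients(m.design_.X, y)
        np.testing.assert_allclose(m.coef_, beta, atol=1e-8)

    def test_fitted_plus_residuals_reconstruct_response(self):
        rec = toy_records(seed=5)
        m = fit_penalized(rec)
        np.testing.assert_allclose(
            m.fitted_ + m.residuals_, rec["log_dv"], atol=1e-10
        )

    def test_residuals_orthogonal_to_unpenalized_columns(self):
        rec = toy_records(seed=6)
        m = fit_penalized(rec)
        Xu = m.design_.X[:, :4]
        assert np.abs(Xu.T @ m.residuals_).max() < 1e-8

    def test_constant_dv_gives_intercept_only_fit(self):
        rec = toy_records(seed=7)
        m = PenalizedGAM().fit(rec, np.full(len(rec), 5.0))
        assert m.deviance_explained_ == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(m.fitted_, 5.0, atol=1e-8)

    def test_infinite_smoothing_collapses_to_bilinear_null_space(self):
        rec = toy_records(seed=8, with_groups=False)
        m = PenalizedGAM(
            random_effects=False, fixed_lambdas=1e8
        ).fit(rec, rec["log_dv"])
        sg = m.predict_surface(n_grid=12)
        span = sg.fit.max() - sg.fit.min()
        assert np.abs(np.diff(sg.fit, 2, axis=0)).max() < 1e-3 * max(span, 1e-6)
        assert np.abs(np.diff(sg.fit, 2, axis=1)).max() < 1e-3 * max(span, 1e-6)

    def test_deviance_explained_nesting(self):
        # a bilinear signal lies in the tensor span: the tensor fit cannot
        # explain less when both are unpenalized
        rec = toy_records(seed=9, with_groups=False)
        te = PenalizedGAM(random_effects=False, fixed_lambdas=0.0).fit(
            rec, rec["log_dv"]
        )
        lin = PenalizedGAM(
            interaction_form="linear", random_effects=False
        ).fit(rec, rec["log_dv"])
        assert te.deviance_explained_ >= lin.deviance_explained_ - 1e-10

    def test_edf_bounded_by_block_dimension(self):
        rec = toy_records(seed=10)
        m = fit_penalized(rec)
        for t in m.design_.terms:
            assert m.edf_[t.name] <= t.size + 1e-8

    def test_summary_tables_have_expected_terms(self):
        rec = toy_records(seed=11)
        m = fit_penalized(rec)
        fr = m.fit_result_
        assert fr.parametric["term"].tolist() == [
            "Intercept", "length", "log_frequency", "position"
        ]
        assert set(fr.smooth["term"]) == {
            "te(osc,surprisal)", "s(subject)", "s(word)"
        }
        assert 0.0 <= fr.deviance_explained <= 1.0

    def test_mismatched_lengths_raise(self):
        rec = toy_records()
        with pytest.raises(ValueError):
            PenalizedGAM().fit(rec, np.zeros(3))


class TestSurface:
    def test_single_point_grid_matches_predict_at_means(self):
        rec = toy_records(seed=12)
        m = fit_penalized(rec)
        og = np.array([rec["osc"].mean()])
        sg_grid = np.array([rec["surprisal"].mean()])
        sg = m.predict_surface(osc_grid=og, surprisal_grid=sg_grid)
        point = pd.DataFrame(
            {
                "osc": og, "surprisal": sg_grid,
                "length": [rec["length"].mean()],
                "log_frequency": [rec["log_frequency"].mean()],
                "position": [rec["position"].mean()],
            }
        )
        assert sg.fit[0, 0] == pytest.approx(m.predict(point)[0], abs=1e-10)

    def test_extrapolation_flagged_outside_observed_range(self):
        rec = toy_records(seed=13)
        m = fit_penalized(rec)
        sg = m.predict_surface(
            osc_grid=np.array([-0.5, 0.5]),
            surprisal_grid=np.array([5.0, 99.0]),
        )
        assert sg.extrapolated[0, 0] and sg.extrapolated[1, 1]
        assert not sg.extrapolated[1, 0]
        assert np.isfinite(sg.fit).all()

    def test_rug_carries_training_points(self):
        rec = toy_records(seed=14)
        m = fit_penalized(rec)
        sg = m.predict_surface(n_grid=5)
        assert sg.rug.shape == (len(rec), 2)

    def test_long_format_export_is_rectangular(self):
        rec = toy_records(seed=15)
        sg = fit_penalized(rec).predict_surface(n_grid=7)
        frame = sg.to_frame()
        assert len(frame) == 49
        assert {"osc", "surprisal", "fit", "se", "extrapolated"} <= set(frame)


class TestComparisonAndCriticism:
    def test_equivalent_forms_give_f_near_zero(self):
        # force the tensor term to (near) linearity: no evidence either way
        rec = toy_records(seed=16)
        comp = compare_forms(rec, ModelSpec(), null_calibration="f")
        te_rss, lin_rss = comp.tensor_fit.rss_, comp.linear_fit.rss_
        if comp.inconclusive:
            assert comp.preferred_form == "linear"
        else:
            assert comp.F >= 0.0

    def test_forced_linearity_is_inconclusive(self):
        rec = toy_records(seed=17)
        te = PenalizedGAM(fixed_lambdas=[1e8, 1e8, 1.0, 1.0]).fit(
            rec, rec["log_dv"]
        )
        assert te.interaction_edf_ - 3.0 < 1.0  # collapsed to its null space

    def test_planted_outliers_are_exactly_the_removed_set(self):
        rec = toy_records(n=400, seed=18, with_groups=False)
        spec = ModelSpec(interaction_form="linear", random_effects=False)
        idx = [10, 50, 90, 130, 170]
        rec.loc[idx, "log_dv"] += 3.0  # gross outliers
        trimmed, refit, removed = model_criticism(rec, spec=spec)
        assert removed == len(idx)
        kept = set(map(tuple, trimmed[["osc", "surprisal"]].round(9).values))
        for i in idx:
            assert (
                round(rec.loc[i, "osc"], 9),
                round(rec.loc[i, "surprisal"], 9),
            ) not in kept

    def test_infinite_threshold_keeps_fit_unchanged(self):
        rec = toy_records(seed=19)
        m = fit_penalized(rec)
        trimmed, refit, removed = model_criticism(
            rec, model=m, threshold=np.inf
        )
        assert removed == 0 and refit is m
        assert len(trimmed) == len(rec)

    def test_pathological_trim_raises(self):
        rec = toy_records(n=60, seed=20, with_groups=False)
        spec = ModelSpec(interaction_form="linear", random_effects=False)
        with pytest.raises(RuntimeError):
            model_criticism(rec, spec=spec, threshold=0.01)


def test_sklearn_clone_compatibility():
    from sklearn.base import clone

    m = PenalizedGAM(k_osc=6, smoothing_selection="reml")
    c = clone(m)
    assert c.k_osc == 6 and c.smoothing_selection == "reml"
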