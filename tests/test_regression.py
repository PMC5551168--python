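"""Model fitting, block Wald tests, backward selection, fixture ingestion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from tractrisk.errors import (
    ChainOrderError,
    ConfigurationError,
    RankDeficiencyError,
    SeparationError,
)
from tractrisk.pipeline import default_model_specs
from tractrisk.regression import (
    ModelSpec,
    VariableBlock,
    backward_select,
    block_p_value,
    encode_design,
    fit_chain,
    fit_linear,
    fit_logistic,
    model_from_table,
    spec_from_model,
)
from tractrisk.synthgen import simulate_survey


def _spec(outcome, family, blocks):
    return ModelSpec(outcome=outcome, family=family, blocks=blocks,
                     response_column=outcome)


class TestEncodeDesign:
    def test_reference_cell_coding(self):
        df = pd.DataFrame({
            "y": [0, 1, 0, 1],
            "sex": ["female", "male", "female", "male"],
            "grade": ["a", "b", "c", "a"],
        })
        spec = _spec("y", "logistic", [
            VariableBlock("sex", "categorical", ["male"], "female"),
            VariableBlock("grade", "categorical", ["b", "c"], "a"),
        ])
        X, y, _ = encode_design(df, spec)
        assert list(X.columns) == ["sex[male]", "grade[b]", "grade[c]"]
        # all-reference individual -> all-zero covariate row
        assert X.iloc[0].tolist() == [0.0, 0.0, 0.0]
        assert X.iloc[1].tolist() == [1.0, 1.0, 0.0]

    def test_empty_category_is_named(self):
        df = pd.DataFrame({"y": [0, 1], "sex": ["female", "female"]})
        spec = _spec("y", "logistic",
                     [VariableBlock("sex", "categorical", ["male"], "female")])
        with pytest.raises(ConfigurationError, match="male"):
            encode_design(df, spec)

    def test_missing_rows_dropped(self):
        df = pd.DataFrame({"y": [0, 1, 1], "x": [1.0, np.nan, 0.0]})
        spec = _spec("y", "logistic", [VariableBlock("x", "continuous")])
        X, y, _ = encode_design(df, spec)
        assert len(X) == 2


class TestFitLogistic:
    def test_two_by_two_matches_log_odds_ratio(self):
        rows = [(1, 1)] * 40 + [(1, 0)] * 60 + [(0, 1)] * 25 + [(0, 0)] * 75
        df = pd.DataFrame(rows, columns=["x", "y"])
        spec = _spec("y", "logistic", [VariableBlock("x", "binary")])
        X, y, _ = encode_design(df, spec)
        model = fit_logistic(X, y, spec)
        assert model.block("x").terms["1"].value == pytest.approx(
            np.log(2), abs=1e-6
        )

    def test_constant_response_is_separation(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0]})
        with pytest.raises(SeparationError):
            fit_logistic(X, np.ones(3))

    def test_perfectly_separated_predictor_detected(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        X = pd.DataFrame({"x": x})
        with pytest.raises(SeparationError):
            fit_logistic(X, x.copy())

    def test_wald_interval_covers_null_slope(self):
        rng = np.random.default_rng(42)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            x = rng.normal(size=5000)
            y = rng.random(5000) < 0.3  # independent of x
            model = fit_logistic(pd.DataFrame({"x": x}), y.astype(float))
            t = model.block("x").terms["x"]
            hits += abs(t.value) < 2 * t.se
        assert hits / n_reps > 0.91  # nominal ~95.4% for +/-2 SE


class TestFitLinear:
    def test_exact_fit_recovered(self):
        x = np.linspace(-2, 3, 40)
        df = pd.DataFrame({"x": x, "y": 2 * x + 3})
        spec = _spec("y", "linear", [VariableBlock("x", "continuous")])
        X, y, _ = encode_design(df, spec)
        model = fit_linear(X, y, spec)
        assert model.intercept == pytest.approx(3.0, abs=1e-10)
        assert model.block("x").terms["x"].value == pytest.approx(2.0, abs=1e-10)

    def test_duplicated_column_names_collinear_culprit(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = X["a"]
        with pytest.raises(RankDeficiencyError) as err:
            fit_linear(X, rng.normal(size=30))
        assert "b" in err.value.columns or "a" in err.value.columns

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(200, 4)),
                         columns=["a", "b", "c", "d"])
        y = rng.normal(size=200)
        model = fit_linear(X, y)
        Xc = np.column_stack([np.ones(200), X.to_numpy()])
        beta = np.linalg.pinv(Xc) @ y
        got = [model.intercept] + [model.block(c).terms[c].value
                                   for c in X.columns]
        np.testing.assert_allclose(got, beta, atol=1e-8)


class TestBlockPValue:
    def test_single_df_block_equals_coefficient_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=800)
        y = (rng.random(800) < expit(0.5 * x)).astype(float)
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        t = model.block("x").terms["x"]
        assert block_p_value(model, "x") == pytest.approx(t.p, abs=1e-10)

    def test_null_block_p_is_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(500):
            g = rng.choice(["a", "b", "c"], size=400)
            y = (rng.random(400) < 0.4).astype(float)
            df = pd.DataFrame({"g": g, "y": y})
            spec = _spec("y", "logistic",
                         [VariableBlock("g", "categorical", ["b", "c"], "a")])
            X, yy, _ = encode_design(df, spec)
            ps.append(block_p_value(fit_logistic(X, yy, spec), "g"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_huge_effect_has_vanishing_p(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20_000)
        y = (rng.random(20_000) < expit(2.0 * x)).astype(float)
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        assert block_p_value(model, "x") < 1e-10

    def test_unknown_variable_rejected(self):
        rng = np.random.default_rng(6)
        model = fit_logistic(pd.DataFrame({"x": rng.normal(size=100)}),
                             (rng.random(100) < 0.5).astype(float))
        with pytest.raises(ValueError):
            block_p_value(model, "not_there")


def _strong_survey(rng, n=4000, noise=True):
    x = rng.choice(["lo", "hi"], size=n)
    g = rng.choice(["a", "b", "c"], size=n)  # pure noise block
    p = expit(-0.5 + 1.2 * (x == "hi"))
    y = (rng.random(n) < p).astype(float)
    df = pd.DataFrame({"x": x, "g": g, "y": y})
    blocks = [VariableBlock("x", "categorical", ["hi"], "lo")]
    if noise:
        blocks.append(VariableBlock("g", "categorical", ["b", "c"], "a"))
    return df, _spec("y", "logistic", blocks)


class TestBackwardSelect:
    def test_strong_spec_returned_intact(self):
        df, spec = _strong_survey(np.random.default_rng(7), noise=False)
        model = backward_select(df, spec)
        assert model.predictors == ["x"] and model.dropped == []

    def test_largest_p_removed_first(self):
        rng = np.random.default_rng(8)
        n = 3000
        df = pd.DataFrame({
            "x": rng.choice(["lo", "hi"], size=n),
            "g1": rng.choice(["a", "b"], size=n),
            "g2": rng.choice(["a", "b"], size=n),
        })
        df["y"] = (rng.random(n) < expit(1.0 * (df.x == "hi"))).astype(float)
        spec = _spec("y", "logistic", [
            VariableBlock("x", "categorical", ["hi"], "lo"),
            VariableBlock("g1", "categorical", ["b"], "a"),
            VariableBlock("g2", "categorical", ["b"], "a"),
        ])
        # both noise blocks go, and the first removal is the block whose
        # full-model p was largest
        full = fit_logistic(*encode_design(df, spec)[:2], spec=spec)
        worst = max(("g1", "g2"), key=lambda v: full.block(v).block_p)
        model = backward_select(df, spec)
        assert {d["variable"] for d in model.dropped} == {"g1", "g2"}
        assert model.dropped[0]["variable"] == worst
        assert model.predictors == ["x"]

    def test_selection_is_idempotent(self):
        df, spec = _strong_survey(np.random.default_rng(9))
        model = backward_select(df, spec)
        again = backward_select(df, spec_from_model(model))
        assert again.predictors == model.predictors
        assert again.dropped == []

    def test_all_blocks_removed_yields_intercept_only(self):
        rng = np.random.default_rng(10)
        n = 2000
        df = pd.DataFrame({"g": rng.choice(["a", "b"], size=n),
                           "y": (rng.random(n) < 0.4).astype(float)})
        spec = _spec("y", "logistic",
                     [VariableBlock("g", "categorical", ["b"], "a")])
        model = backward_select(df, spec)
        if not model.blocks:  # g is noise, removed with prob ~0.95
            p = df["y"].mean()
            assert model.intercept == pytest.approx(np.log(p / (1 - p)))


class TestPublishedFixture:
    def test_headline_coefficients(self, table1):
        dia = model_from_table(table1, "diabetes")
        assert dia.block("sex").terms["male"].value == 0.21
        assert dia.block("bmi_category").terms["obese"].value == 0.91
        assert dia.block("exercise_any_30d").terms["1"].value == -0.083
        ex = model_from_table(table1, "exercise")
        assert ex.block("race_ethnicity").terms["hispanic"].value == -0.35

    def test_ns_and_na_terms_absent(self, table1):
        bmi = model_from_table(table1, "bmi")
        assert "race_ethnicity" not in bmi.predictors  # published NS
        ex = model_from_table(table1, "exercise")
        for v in ("exercise_any_30d", "fruitveg_5plus", "bmi_category"):
            assert v not in ex.predictors  # N/A by chain order
        assert bmi.family == "linear" and ex.family == "logistic"

    def test_intercept_flagged_uncalibrated(self, table1):
        assert model_from_table(table1, "fruitveg").intercept_calibrated is False

    def test_unknown_outcome_rejected(self, table1):
        with pytest.raises(ConfigurationError):
            model_from_table(table1, "smoking")


class TestFitChain:
    def test_later_stage_predictor_rejected(self):
        specs = default_model_specs()
        specs[0].blocks.append(VariableBlock("diabetes", "binary"))
        with pytest.raises(ChainOrderError):
            fit_chain(pd.DataFrame(), specs)

    def test_structure_recovery_at_full_survey_size(self, big_city, truth):
        truth_nonzero = {
            m.outcome: set(m.predictors) - {"smoking"} | (
                {"smoking"} if "smoking" in m.predictors else set()
            )
            for m in truth.models
            if m.outcome in ("exercise", "fruitveg", "bmi", "diabetes")
        }
        reps = 12
        stage_hits = {o: 0 for o in truth_nonzero}
        for rep in range(reps):
            survey = simulate_survey(big_city, truth, 15_814, rng_seed=500 + rep)
            models = fit_chain(survey, default_model_specs())
            for m in models:
                if set(m.predictors) == truth_nonzero[m.outcome]:
                    stage_hits[m.outcome] += 1
        for outcome, hits in stage_hits.items():
            assert hits >= 10, f"{outcome}: {hits}/{reps}"
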