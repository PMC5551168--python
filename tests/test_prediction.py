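"""Chain application, calibration, BMI categorization, Monte Carlo."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from tractrisk.errors import ConfigurationError
from tractrisk.prediction import (
    calibrate_chain,
    calibrate_intercept,
    categorize_bmi,
    chain_predict,
    eligible_population,
    expected_chain_probabilities,
    linear_predictor,
    monte_carlo,
    predict_probability,
)
from tractrisk.regression import (
    Coefficient,
    FittedModel,
    TermBlock,
    model_from_table,
)


def _logistic(outcome, intercept, blocks=(), calibrated=True, se=None):
    return FittedModel(outcome=outcome, family="logistic",
                       intercept=intercept, intercept_se=se,
                       blocks=list(blocks), intercept_calibrated=calibrated)


def _binary_block(var, coef, se=None):
    return TermBlock(variable=var, kind="binary",
                     terms={"1": Coefficient(value=coef, se=se)})


class TestEligibility:
    def test_threshold_inclusive_at_21(self):
        pop = pd.DataFrame({"age_years": [20, 21, 35]})
        assert len(eligible_population(pop)) == 2

    def test_all_minors_leaves_empty(self):
        pop = pd.DataFrame({"age_years": [5, 17]})
        assert eligible_population(pop).empty

    def test_idempotent(self):
        pop = pd.DataFrame({"age_years": [20, 21, 90]})
        once = eligible_population(pop)
        pd.testing.assert_frame_equal(once, eligible_population(once))


class TestLinearPredictor:
    def test_reference_profile_equals_intercept(self, table1):
        model = model_from_table(table1, "diabetes")
        ind = {"sex": "female", "age_band": "80-99",
               "race_ethnicity": "white_nh", "income_collapsed": "ge_35k",
               "smoking": "never", "alcohol_any_30d": 0,
               "exercise_any_30d": 0, "bmi_category": "underweight"}
        assert linear_predictor(model, ind) == model.intercept

    def test_male_obese_published_sum(self, table1):
        model = model_from_table(table1, "diabetes")  # intercept 0
        ind = {"sex": "male", "age_band": "80-99",
               "race_ethnicity": "white_nh", "income_collapsed": "ge_35k",
               "smoking": "never", "alcohol_any_30d": 0,
               "exercise_any_30d": 0, "bmi_category": "obese"}
        assert linear_predictor(model, ind) == pytest.approx(0.21 + 0.91)
        # ... and the matching probability
        assert predict_probability(model, ind) == pytest.approx(
            expit(1.12), abs=1e-3
        )

    def test_exercise_shifts_diabetes_by_published_coefficient(self, table1):
        model = model_from_table(table1, "diabetes")
        base = {"sex": "female", "age_band": "80-99",
                "race_ethnicity": "white_nh", "income_collapsed": "ge_35k",
                "smoking": "never", "alcohol_any_30d": 0,
                "exercise_any_30d": 0, "bmi_category": "normal"}
        active = dict(base, exercise_any_30d=1)
        delta = linear_predictor(model, active) - linear_predictor(model, base)
        assert delta == pytest.approx(-0.083)

    def test_unseen_category_named(self, table1):
        model = model_from_table(table1, "exercise")
        ind = {"sex": "male", "age_band": "18-29", "race_ethnicity": "martian",
               "income_collapsed": "ge_35k", "education": "gt_highschool",
               "smoking": "never", "alcohol_any_30d": 0}
        with pytest.raises(ConfigurationError, match="martian"):
            linear_predictor(model, ind)

    def test_probability_requires_logistic(self):
        lin = FittedModel(outcome="bmi", family="linear", intercept=25.0,
                          blocks=[])
        with pytest.raises(ConfigurationError, match="predict_value"):
            predict_probability(lin, {})

    def test_zero_linear_predictor_is_half(self):
        m = _logistic("exercise", 0.0)
        assert predict_probability(m, {}) == 0.5


class TestCategorizeBmi:
    @pytest.mark.parametrize("value,expect", [
        (30.0, "obese"), (29.999, "overweight"), (25.0, "overweight"),
        (24.999, "normal"), (18.5, "normal"), (18.499, "underweight"),
    ])
    def test_threshold_membership(self, value, expect):
        assert categorize_bmi(value) == expect

    def test_non_finite_rejected(self):
        with pytest.raises(ConfigurationError):
            categorize_bmi(float("nan"))


def _flat_population(n, tract="t0"):
    return pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(n)],
        "tract_id": tract,
        "age_years": 40,
    })


class TestChainPredict:
    def test_zero_slope_chain_reproduces_intercept_probabilities(self):
        pop = _flat_population(200)
        models = {
            "exercise": _logistic("exercise", logit(0.6)),
            "fruitveg": _logistic("fruitveg", logit(0.2)),
            "diabetes": _logistic("diabetes", logit(0.1)),
        }
        out = chain_predict(models, pop, rng_seed=1)
        assert np.allclose(out["p_exercise"], 0.6)
        assert np.allclose(out["p_fruitveg"], 0.2)
        assert np.allclose(out["p_diabetes"], 0.1)

    def test_same_seed_identical_draws(self):
        pop = _flat_population(500)
        models = {"exercise": _logistic("exercise", 0.3)}
        a = chain_predict(models, pop, rng_seed=2)
        b = chain_predict(models, pop, rng_seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_uncalibrated_intercept_refused(self, table1):
        pop = _flat_population(10)
        models = {"exercise": model_from_table(table1, "exercise")}
        with pytest.raises(ConfigurationError, match="uncalibrated"):
            chain_predict(models, pop, rng_seed=0)

    def test_high_risk_profile_outranks_reference(self, table1):
        model = model_from_table(table1, "diabetes")
        object.__setattr__(model, "intercept_calibrated", True)
        cols = ["sex", "age_band", "race_ethnicity", "income_collapsed",
                "smoking", "alcohol_any_30d", "exercise_any_30d",
                "bmi_category"]
        high = pd.DataFrame([["male", "70-79", "white_nh", "lt_25k", "never",
                              0, 0, "obese"]] * 50, columns=cols)
        ref = pd.DataFrame([["female", "80-99", "white_nh", "ge_35k", "never",
                             0, 0, "underweight"]] * 50, columns=cols)
        for frame in (high, ref):
            frame["tract_id"] = "t0"
        p_high = chain_predict({"diabetes": model}, high, 3)["p_diabetes"]
        p_ref = chain_predict({"diabetes": model}, ref, 3)["p_diabetes"]
        assert p_high.mean() > p_ref.mean()

    def test_two_stage_chain_matches_exact_enumeration(self):
        # exercise -> diabetes toy chain, checked against the law of total
        # probability evaluated by hand
        pop = _flat_population(4)
        ex = _logistic("exercise", logit(0.7))
        dia = _logistic("diabetes", logit(0.2),
                        [_binary_block("exercise_any_30d", -1.0)])
        probs = expected_chain_probabilities(
            {"exercise": ex, "diabetes": dia}, pop
        )
        expect = 0.7 * expit(logit(0.2) - 1.0) + 0.3 * 0.2
        assert np.allclose(probs["p_diabetes"], expect)


class TestCalibration:
    def test_zero_coefficients_closed_form(self):
        pop = _flat_population(50)
        model = _logistic("exercise", 5.0, calibrated=False)
        out = calibrate_intercept(model, pop, 0.3)
        assert out.intercept == pytest.approx(float(logit(0.3)), abs=1e-6)

    def test_target_met_within_tolerance(self):
        rng = np.random.default_rng(4)
        pop = _flat_population(300)
        pop["x"] = rng.normal(size=300)
        model = FittedModel(
            outcome="exercise", family="logistic", intercept=0.0,
            blocks=[TermBlock(variable="x", kind="continuous",
                              terms={"x": Coefficient(value=0.8)})],
            intercept_calibrated=False,
        )
        out = calibrate_intercept(model, pop, 0.42)
        lp = out.intercept + 0.8 * pop["x"]
        assert abs(expit(lp).mean() - 0.42) < 1e-6

    def test_matches_grid_search_oracle(self):
        pop = pd.DataFrame({"x": [-1.0, 0.0, 1.0], "tract_id": "t0",
                            "age_years": 30})
        model = FittedModel(
            outcome="exercise", family="logistic", intercept=0.0,
            blocks=[TermBlock(variable="x", kind="continuous",
                              terms={"x": Coefficient(value=1.0)})],
            intercept_calibrated=False,
        )
        out = calibrate_intercept(model, pop, 0.6)
        grid = np.linspace(-10, 10, 200_001)
        means = expit(grid[:, None] + np.array([-1.0, 0.0, 1.0])).mean(axis=1)
        oracle = grid[np.argmin(np.abs(means - 0.6))]
        assert out.intercept == pytest.approx(oracle, abs=1e-4)

    def test_target_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            calibrate_intercept(_logistic("exercise", 0.0), _flat_population(5),
                                1.5)

    def test_chain_calibration_hits_every_stage_target(self, table1):
        rng = np.random.default_rng(5)
        n = 400
        pop = pd.DataFrame({
            "tract_id": "t0", "age_years": 50,
            "sex": rng.choice(["female", "male"], n),
            "age_band": rng.choice(["30-39", "50-59", "70-79"], n),
            "race_ethnicity": rng.choice(["white_nh", "hispanic"], n),
            "income_collapsed": rng.choice(["lt_25k", "ge_35k"], n),
            "education": rng.choice(["lt_highschool", "gt_highschool"], n),
            "smoking": rng.choice(["never", "former", "current"], n),
            "alcohol_any_30d": rng.integers(0, 2, n),
        })
        models = {o: model_from_table(table1, o)
                  for o in ("exercise", "fruitveg", "bmi", "diabetes")}
        targets = {"exercise": 0.649, "fruitveg": 0.179, "diabetes": 0.111}
        cal = calibrate_chain(models, pop, targets, bmi_target_mean=27.0)
        probs = expected_chain_probabilities(cal, pop)
        for stage, target in targets.items():
            assert probs[f"p_{stage}"].mean() == pytest.approx(target, abs=1e-6)
        assert probs["bmi_expected"].mean() == pytest.approx(27.0, abs=1e-9)


class TestMonteCarlo:
    def test_zero_probability_chain_never_fires(self):
        pop = _flat_population(100)
        models = {"exercise": _logistic("exercise", -700.0)}
        mc = monte_carlo(models, pop, n_reps=20, rng_seed=1,
                         outcomes=("exercise",))
        assert all((r.reps == 0.0).all() for r in mc)

    def test_rep_mean_matches_half_coin(self):
        pop = _flat_population(100)
        models = {"exercise": _logistic("exercise", 0.0)}  # p = 0.5 for all
        mc = monte_carlo(models, pop, n_reps=1000, rng_seed=2,
                         outcomes=("exercise",))
        [r] = mc
        tol = 3 * (0.05 / np.sqrt(1000))
        assert abs(r.reps.mean() - 0.5) < tol

    def test_rep_variance_is_poisson_binomial(self):
        rng = np.random.default_rng(3)
        pop = _flat_population(1000)
        pop["x"] = rng.normal(size=1000)
        model = FittedModel(
            outcome="exercise", family="logistic", intercept=0.2,
            blocks=[TermBlock(variable="x", kind="continuous",
                              terms={"x": Coefficient(value=1.0)})],
        )
        p = expit(0.2 + pop["x"].to_numpy())
        expect_var = float((p * (1 - p)).sum() / 1000**2)
        mc = monte_carlo({"exercise": model}, pop, n_reps=1000, rng_seed=4,
                         outcomes=("exercise",))
        [r] = mc
        assert abs(r.reps.var(ddof=1) - expect_var) / expect_var < 0.2
        # expectation consistency: rep mean near mean probability
        se = np.sqrt(expect_var / 1000)
        assert abs(r.reps.mean() - p.mean()) < 3 * se

    def test_coefficient_draw_requires_standard_errors(self, table1):
        pop = _flat_population(50)
        model = _logistic("exercise", 0.0)
        with pytest.raises(ConfigurationError, match="SE"):
            monte_carlo({"exercise": model}, pop, n_reps=10,
                        mode="coefficient-draw", rng_seed=5,
                        outcomes=("exercise",))

    def test_coefficient_draw_spreads_with_uncertainty(self):
        pop = _flat_population(400)
        model = _logistic("exercise", 0.0, se=0.3)
        mc = monte_carlo({"exercise": model}, pop, n_reps=400,
                         mode="coefficient-draw", rng_seed=6,
                         outcomes=("exercise",))
        [r] = mc
        # every rep is a mean probability; spread driven by intercept SE
        assert 0.02 < r.reps.std(ddof=1) < 0.15
        assert abs(r.reps.mean() - 0.5) < 0.02

    def test_too_few_reps_rejected(self):
        with pytest.raises(ConfigurationError):
            monte_carlo({"exercise": _logistic("exercise", 0.0)},
                        _flat_population(5), n_reps=1, rng_seed=0)
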