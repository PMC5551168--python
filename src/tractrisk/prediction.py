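"""Applying the fitted model chain to a tract-resolved population.

The chain runs in the fixed order smoking -> alcohol -> exercise ->
fruit/vegetable -> BMI -> diabetes; each binary outcome is computed as an
inverse-logit probability given demographics and the individual's *drawn*
upstream outcomes, BMI is predicted deterministically (its residual
uncertainty is not propagated) and then categorized, and the BMI category
feeds the diabetes stage. Predictions are restricted to adults old enough
for every modeled behavior (age 21 and over by default).

Uncertainty is propagated to tract-level prevalences by Monte Carlo, in one
of two modes:

* ``outcome-draw`` (default) — each replicate re-draws every individual's
  binary outcomes through the chain (Bernoulli at the chain probabilities)
  and records each tract's realized prevalence;
* ``coefficient-draw`` — each replicate perturbs every model's coefficients
  by independent normal draws at their standard errors and records each
  tract's mean predicted probability (upstream states integrated out by the
  law of total probability).

Published coefficient tables carry no intercepts, so logistic intercepts
must first be calibrated against stated marginal prevalences
(:func:`calibrate_intercept` / :func:`calibrate_chain`); the chain refuses
to run a model whose intercept is uncalibrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigurationError
from .regression import LINEAR, LOGISTIC, FittedModel
from .rngtools import derive_seed

logger = logging.getLogger(__name__)

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
SMOKING_CATEGORIES = ("never", "former", "current")

#: chain stages in execution order: outcome name -> column written.
CHAIN_COLUMNS = {
    "smoking_ever": "smoking_ever",
    "smoking_current": "smoking_current",
    "alcohol": "alcohol_any_30d",
    "exercise": "exercise_any_30d",
    "fruitveg": "fruitveg_5plus",
    "bmi": "bmi_value",
    "diabetes": "diabetes",
}
_STAGE_ORDER = list(CHAIN_COLUMNS)


def eligible_population(pop: pd.DataFrame, min_age: int = 21) -> pd.DataFrame:
    """Restrict to individuals aged ``min_age`` and older (inclusive)."""
    keep = pop["age_years"] >= min_age
    removed = int((~keep).sum())
    if removed:
        logger.info("eligibility filter: removed %d individuals under %d",
                    removed, min_age)
    out = pop[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("eligibility filter left an empty population")
    return out


def categorize_bmi(value: float) -> str:
    """WHO-style BMI classes: <18.5, [18.5,25), [25,30), >=30 kg/m^2."""
    if not np.isfinite(value):
        raise ConfigurationError(f"non-finite BMI value {value!r}")
    if value >= 30:
        return "obese"
    if value >= 25:
        return "overweight"
    if value >= 18.5:
        return "normal"
    return "underweight"


def categorize_bmi_codes(values: np.ndarray) -> np.ndarray:
    """Vectorized BMI class codes (index into :data:`BMI_CATEGORIES`)."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ConfigurationError("non-finite BMI values")
    return np.searchsorted([18.5, 25.0, 30.0], values, side="right")


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------

def linear_predictor(model: FittedModel, individual) -> float:
    """Intercept plus matched-category coefficients for one individual.

    Reference categories contribute zero; an unseen category raises an
    error naming it.
    """
    lp = model.intercept
    for block in model.blocks:
        if block.variable not in individual:
            raise ConfigurationError(
                f"individual lacks field {block.variable!r} required by "
                f"model {model.outcome!r}"
            )
        val = individual[block.variable]
        if block.kind == "categorical":
            try:
                lp += block.coefficient(val)
            except KeyError as exc:
                raise ConfigurationError(str(exc)) from exc
        elif block.kind == "binary":
            lp += block.terms["1"].value * float(val)
        else:
            lp += block.terms[block.variable].value * float(val)
    return float(lp)


def linear_predictor_frame(model: FittedModel, df: pd.DataFrame) -> np.ndarray:
    """Vectorized linear predictor over an individual-row frame."""
    lp = np.full(len(df), model.intercept, dtype=float)
    for block in model.blocks:
        if block.variable not in df.columns:
            raise ConfigurationError(
                f"population lacks field {block.variable!r} required by "
                f"model {model.outcome!r}"
            )
        col = df[block.variable]
        if block.kind == "categorical":
            mapping = {c: t.value for c, t in block.terms.items()}
            if block.reference is not None:
                mapping[block.reference] = 0.0
            vals = col.map(mapping)
            if vals.isna().any():
                bad = sorted(set(col[vals.isna()].astype(str)))
                raise ConfigurationError(
                    f"unseen categories {bad} for variable {block.variable!r}"
                )
            lp += vals.to_numpy(dtype=float)
        elif block.kind == "binary":
            lp += block.terms["1"].value * col.to_numpy(dtype=float)
        else:
            lp += block.terms[block.variable].value * col.to_numpy(dtype=float)
    return lp


def predict_probability(model: FittedModel, individual) -> float:
    """Inverse-logit of the linear predictor (logistic models only)."""
    if model.family != LOGISTIC:
        raise ConfigurationError(
            f"model {model.outcome!r} is {model.family}; use predict_value"
        )
    return float(expit(linear_predictor(model, individual)))


def predict_value(model: FittedModel, individual) -> float:
    if model.family != LINEAR:
        raise ConfigurationError(
            f"model {model.outcome!r} is {model.family}; use predict_probability"
        )
    return linear_predictor(model, individual)


# ---------------------------------------------------------------------------
# compiled chain engine
# ---------------------------------------------------------------------------

def models_by_outcome(models) -> dict[str, FittedModel]:
    if isinstance(models, dict):
        return dict(models)
    return {m.outcome: m for m in models}


class _CompiledModel:
    """One chain model pre-compiled against a fixed population frame.

    Static blocks (variables already on the frame) are folded into a cached
    base linear predictor via integer category codes, so replicates only pay
    for the dynamic (chain-drawn) terms. Coefficient perturbation rebuilds
    the per-category coefficient vectors from their standard errors.
    """

    def __init__(self, model: FittedModel, df: pd.DataFrame, produced: set[str]):
        self.model = model
        self.family = model.family
        self.intercept = float(model.intercept)
        self.intercept_se = model.intercept_se
        self.n = len(df)
        # static categorical: (codes, coef-per-code, se-per-code)
        self.cat_blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        # static numeric: (values, coef, se)
        self.num_blocks: list[tuple[np.ndarray, float, float]] = []
        # dynamic: (variable, kind, coef-structure, se-structure)
        self.dynamic: list[tuple[str, str, np.ndarray | float, np.ndarray | float]] = []
        for block in model.blocks:
            if block.variable in produced:
                if block.variable == "smoking":
                    coefs = np.zeros(len(SMOKING_CATEGORIES))
                    ses = np.zeros(len(SMOKING_CATEGORIES))
                    for i, cat in enumerate(SMOKING_CATEGORIES):
                        if cat in block.terms:
                            coefs[i] = block.terms[cat].value
                            ses[i] = block.terms[cat].se or 0.0
                    self.dynamic.append(("smoking", "codes", coefs, ses))
                elif block.variable == "bmi_category":
                    coefs = np.zeros(len(BMI_CATEGORIES))
                    ses = np.zeros(len(BMI_CATEGORIES))
                    for i, cat in enumerate(BMI_CATEGORIES):
                        if cat in block.terms:
                            coefs[i] = block.terms[cat].value
                            ses[i] = block.terms[cat].se or 0.0
                    self.dynamic.append(("bmi_category", "codes", coefs, ses))
                elif block.kind == "binary":
                    t = block.terms["1"]
                    self.dynamic.append(
                        (block.variable, "binary", t.value, t.se or 0.0)
                    )
                else:
                    raise ConfigurationError(
                        f"unsupported dynamic predictor {block.variable!r} "
                        f"({block.kind}) in model {model.outcome!r}"
                    )
                continue
            if block.variable not in df.columns:
                raise ConfigurationError(
                    f"missing upstream field {block.variable!r} for model "
                    f"{model.outcome!r}: not on the population and not "
                    "produced by an earlier chain stage"
                )
            col = df[block.variable]
            if block.kind == "categorical":
                cats = ([block.reference] if block.reference is not None else []) \
                    + [c for c in block.terms if c != block.reference]
                pos = {c: i for i, c in enumerate(cats)}
                codes = col.map(pos)
                if codes.isna().any():
                    bad = sorted(set(col[codes.isna()].astype(str)))
                    raise ConfigurationError(
                        f"unseen categories {bad} for variable {block.variable!r}"
                    )
                coefs = np.zeros(len(cats))
                ses = np.zeros(len(cats))
                for c, t in block.terms.items():
                    coefs[pos[c]] = t.value
                    ses[pos[c]] = t.se or 0.0
                self.cat_blocks.append(
                    (codes.to_numpy(dtype=np.intp), coefs, ses)
                )
            else:
                key = "1" if block.kind == "binary" else block.variable
                t = block.terms[key]
                self.num_blocks.append(
                    (col.to_numpy(dtype=float), t.value, t.se or 0.0)
                )
        self._base = None

    def base_lp(self) -> np.ndarray:
        if self._base is None:
            lp = np.full(self.n, self.intercept)
            for codes, coefs, _ in self.cat_blocks:
                lp += coefs[codes]
            for values, coef, _ in self.num_blocks:
                lp += coef * values
            self._base = lp
        return self._base

    def dynamic_coef(self, variable: str):
        for var, kind, coef, _ in self.dynamic:
            if var == variable:
                return coef
        return None

    def perturbed(self, rng: np.random.Generator) -> "_CompiledModel":
        """Copy with every coefficient jittered by N(0, SE)."""
        out = object.__new__(_CompiledModel)
        out.model = self.model
        out.family = self.family
        out.n = self.n
        out.intercept_se = self.intercept_se
        if self.intercept_se is None:
            raise ConfigurationError(
                f"model {self.model.outcome!r} has no intercept SE; "
                "coefficient-draw mode requires fitted standard errors"
            )
        out.intercept = self.intercept + rng.normal(0.0, self.intercept_se)
        out.cat_blocks = []
        for codes, coefs, ses in self.cat_blocks:
            if (ses[coefs != 0] == 0).any():
                raise ConfigurationError(
                    f"model {self.model.outcome!r} lacks SEs; cannot perturb"
                )
            out.cat_blocks.append(
                (codes, coefs + rng.normal(0.0, 1.0, len(coefs)) * ses, ses)
            )
        out.num_blocks = [
            (values, coef + rng.normal(0.0, se), se)
            for values, coef, se in self.num_blocks
        ]
        out.dynamic = [
            (var, kind,
             coef + (rng.normal(0.0, 1.0, len(se)) * se if kind == "codes"
                     else rng.normal(0.0, se)),
             se)
            for var, kind, coef, se in self.dynamic
        ]
        out._base = None
        return out


class ChainEngine:
    """The model chain compiled against one population frame."""

    def __init__(self, models, population: pd.DataFrame,
                 require_calibrated: bool = True):
        self.df = population
        self.models = models_by_outcome(models)
        unknown = set(self.models) - set(CHAIN_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown chain outcomes {sorted(unknown)}")
        if "smoking_current" in self.models and "smoking_ever" not in self.models:
            raise ConfigurationError(
                "smoking_current requires a smoking_ever model"
            )
        self.stages = [s for s in _STAGE_ORDER if s in self.models]
        produced: set[str] = set()
        self.compiled: dict[str, _CompiledModel] = {}
        for stage in self.stages:
            model = self.models[stage]
            if require_calibrated and model.family == LOGISTIC \
                    and not model.intercept_calibrated:
                raise ConfigurationError(
                    f"model {model.outcome!r} has an uncalibrated intercept; "
                    "run intercept calibration before prediction"
                )
            self.compiled[stage] = _CompiledModel(model, population, produced)
            produced.add(CHAIN_COLUMNS[stage])
            if stage == "smoking_current":
                produced.add("smoking")
            if stage == "bmi":
                produced.add("bmi_category")

    # -- drawing ------------------------------------------------------------
    def _dynamic_lp(self, cm: _CompiledModel, state: dict) -> np.ndarray:
        lp = cm.base_lp().copy()
        for var, kind, coef, _ in cm.dynamic:
            if var not in state:
                raise ConfigurationError(f"missing upstream field {var!r}")
            if kind == "codes":
                lp += np.asarray(coef)[state[var]]
            else:
                lp += coef * state[var]
        return lp

    def run_draw(self, rng: np.random.Generator,
                 bmi_noise_sd: float | None = None) -> dict[str, np.ndarray]:
        """One pass through the chain, drawing each binary outcome.

        Returns probability arrays (``p_<outcome>``), drawn 0/1 arrays (under
        the chain column names), and BMI value/category codes. BMI is
        deterministic unless ``bmi_noise_sd`` is given (used when simulating
        survey observations, where the residual is part of the data).
        """
        state: dict[str, np.ndarray] = {}
        out: dict[str, np.ndarray] = {}
        for stage in self.stages:
            cm = self.compiled[stage]
            if stage == "bmi":
                value = self._dynamic_lp(cm, state)
                if bmi_noise_sd:
                    value = value + rng.normal(0.0, bmi_noise_sd, cm.n)
                codes = categorize_bmi_codes(value)
                state["bmi_category"] = codes
                out["bmi_value"] = value
                out["bmi_category_code"] = codes
                continue
            p = expit(self._dynamic_lp(cm, state))
            draw = (rng.random(cm.n) < p).astype(np.int8)
            col = CHAIN_COLUMNS[stage]
            out[f"p_{stage}"] = p
            out[col] = draw
            state[col] = draw
            if stage == "smoking_current":
                ever = state["smoking_ever"]
                state["smoking"] = ever * (1 + draw)  # 0 never,1 former,2 current
                out["smoking_code"] = state["smoking"]
        return out

    # -- expectation --------------------------------------------------------
    def run_expect(self) -> dict[str, np.ndarray]:
        """Exact chain probabilities with drawn upstream states integrated out.

        Enumerates the (exercise, fruit/veg) combinations by the law of total
        probability; smoking and alcohol must be carried on the population
        (the default), not drawn, for this mode.
        """
        for stage in ("smoking_ever", "smoking_current", "alcohol"):
            if stage in self.stages:
                raise ConfigurationError(
                    "expectation mode requires smoking/alcohol carried on the "
                    "population, not drawn from upstream models"
                )
        out: dict[str, np.ndarray] = {}
        cm_ex = self.compiled.get("exercise")
        p_ex = expit(cm_ex.base_lp()) if cm_ex else None
        if p_ex is not None:
            out["p_exercise"] = p_ex

        def _p_given(cm, ex=None, fv=None, bmi_codes=None):
            lp = cm.base_lp().copy()
            for var, kind, coef, _ in cm.dynamic:
                if var == "exercise_any_30d":
                    lp = lp + coef * ex
                elif var == "fruitveg_5plus":
                    lp = lp + coef * fv
                elif var == "bmi_category":
                    lp = lp + np.asarray(coef)[bmi_codes]
                else:
                    raise ConfigurationError(
                        f"unsupported dynamic predictor {var!r} in "
                        "expectation mode"
                    )
            return lp

        cm_fv = self.compiled.get("fruitveg")
        p_fv_given = {}
        if cm_fv is not None:
            for a in (0, 1):
                p_fv_given[a] = expit(_p_given(cm_fv, ex=a))
            if p_ex is not None:
                out["p_fruitveg"] = (
                    p_ex * p_fv_given[1] + (1 - p_ex) * p_fv_given[0]
                )
            else:
                out["p_fruitveg"] = p_fv_given[0]

        def _combo_weight(a, b):
            if p_ex is None:
                wa = 1.0 if a == 0 else 0.0
            else:
                wa = p_ex if a else 1 - p_ex
            if cm_fv is None:
                wb = 1.0 if b == 0 else 0.0
            else:
                wb = p_fv_given[a] if b else 1 - p_fv_given[a]
            return wa * wb

        cm_bmi = self.compiled.get("bmi")
        bmi_codes = {}
        if cm_bmi is not None:
            expected = np.zeros(cm_bmi.n)
            for a in (0, 1):
                for b in (0, 1):
                    v = _p_given(cm_bmi, ex=a, fv=b)
                    bmi_codes[(a, b)] = categorize_bmi_codes(v)
                    w = _combo_weight(a, b)
                    expected += np.asarray(w) * v
            out["bmi_expected"] = expected

        cm_d = self.compiled.get("diabetes")
        if cm_d is not None:
            p = np.zeros(cm_d.n)
            for a in (0, 1):
                for b in (0, 1):
                    w = _combo_weight(a, b)
                    if np.all(np.asarray(w) == 0.0):
                        continue
                    codes = bmi_codes.get((a, b))
                    p += np.asarray(w) * expit(
                        _p_given(cm_d, ex=a, fv=b, bmi_codes=codes)
                    )
            out["p_diabetes"] = p
        return out


# ---------------------------------------------------------------------------
# public chain prediction
# ---------------------------------------------------------------------------

def chain_predict(
    models,
    population: pd.DataFrame,
    rng_seed: int = 0,
    mode: str = "draw",
) -> pd.DataFrame:
    """Per-individual chain predictions on an eligible population.

    ``mode='draw'`` draws each binary outcome (probabilities are conditional
    on the individual's drawn upstream states); ``mode='expect'`` returns
    exact probabilities with upstream states integrated out. Reproducible
    from ``rng_seed``.
    """
    engine = ChainEngine(models, population)
    id_cols = [c for c in ("synthetic_id", "individual_id", "tract_id")
               if c in population.columns]
    out = population[id_cols].copy() if id_cols else pd.DataFrame(
        index=population.index
    )
    if mode == "draw":
        rng = np.random.default_rng(derive_seed(rng_seed, "chain_predict"))
        res = engine.run_draw(rng)
        if "bmi_category_code" in res:
            res["bmi_category"] = np.array(BMI_CATEGORIES)[
                res.pop("bmi_category_code")
            ]
        if "smoking_code" in res:
            res["smoking"] = np.array(SMOKING_CATEGORIES)[res.pop("smoking_code")]
    elif mode == "expect":
        res = engine.run_expect()
        if "bmi_expected" in res:
            res["bmi_category"] = np.array(BMI_CATEGORIES)[
                categorize_bmi_codes(res["bmi_expected"])
            ]
    else:
        raise ConfigurationError(f"unknown prediction mode {mode!r}")
    for k, v in res.items():
        out[k] = v
    return out


def expected_chain_probabilities(models, population: pd.DataFrame) -> pd.DataFrame:
    """Exact per-individual outcome probabilities (upstream integrated out)."""
    return chain_predict(models, population, mode="expect")


# ---------------------------------------------------------------------------
# intercept calibration
# ---------------------------------------------------------------------------

def calibrate_intercept(
    model: FittedModel,
    population: pd.DataFrame,
    target_prevalence: float,
) -> FittedModel:
    """Choose the logistic intercept so the population-mean predicted
    probability equals ``target_prevalence`` (monotone root finding, 1e-6).

    The population must already carry every covariate the model retains
    (use :func:`calibrate_chain` to calibrate a whole chain).
    """
    if model.family != LOGISTIC:
        raise ConfigurationError("calibrate_intercept applies to logistic models")
    if not (0.0 < target_prevalence < 1.0):
        raise ConfigurationError("target prevalence must be in (0, 1)")
    if population.empty:
        raise ConfigurationError("population is empty")
    base = replace(model, intercept=0.0)
    offsets = linear_predictor_frame(base, population)

    def gap(c):
        return float(expit(c + offsets).mean() - target_prevalence)

    c = brentq(gap, -60.0, 60.0, xtol=1e-10)
    out = replace(model, intercept=float(c), intercept_calibrated=True)
    assert abs(expit(c + offsets).mean() - target_prevalence) < 1e-6
    return out


def calibrate_chain(
    models,
    population: pd.DataFrame,
    targets: dict[str, float],
    bmi_target_mean: float | None = None,
) -> dict[str, FittedModel]:
    """Sequentially calibrate every chain intercept against stated marginal
    prevalences (proportions in (0,1)), integrating drawn upstream states
    out by the law of total probability. Deterministic.
    """
    cal = models_by_outcome(models)
    order = [s for s in _STAGE_ORDER if s in cal]
    for stage in order:
        model = cal[stage]
        if model.family == LINEAR:
            if bmi_target_mean is not None:
                engine = ChainEngine(cal, population, require_calibrated=False)
                mean = float(engine.run_expect()["bmi_expected"].mean())
                cal[stage] = replace(
                    model,
                    intercept=model.intercept + (bmi_target_mean - mean),
                    intercept_calibrated=True,
                )
            else:
                cal[stage] = replace(model, intercept_calibrated=True)
            continue
        if stage not in targets:
            raise ConfigurationError(
                f"no calibration target for chain stage {stage!r}"
            )
        target = targets[stage]
        if not (0.0 < target < 1.0):
            raise ConfigurationError(f"target for {stage!r} must be in (0, 1)")

        def gap(c, stage=stage, model=model):
            trial = dict(cal)
            trial[stage] = replace(model, intercept=float(c),
                                   intercept_calibrated=True)
            engine = ChainEngine(trial, population, require_calibrated=False)
            return float(engine.run_expect()[f"p_{stage}"].mean()) - target

        c = brentq(gap, -60.0, 60.0, xtol=1e-10)
        cal[stage] = replace(model, intercept=float(c),
                             intercept_calibrated=True)
    return cal


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloResult:
    outcome: str
    tract_id: str
    reps: np.ndarray  # per-replicate tract prevalence
    mode: str
    rng_seed: int
    n_individuals: int


def monte_carlo(
    models,
    population: pd.DataFrame,
    n_reps: int = 1000,
    mode: str = "outcome-draw",
    rng_seed: int = 0,
    outcomes: tuple[str, ...] = ("exercise", "fruitveg", "diabetes"),
) -> list[MonteCarloResult]:
    """Tract-level prevalence replicates for each binary outcome.

    See the module docstring for the two modes. Every replicate's substream
    is derived from ``rng_seed``, the mode, and the replicate index.
    """
    if n_reps < 2:
        raise ConfigurationError("n_reps must be at least 2")
    if "tract_id" not in population.columns:
        raise ConfigurationError("population lacks tract_id")
    engine = ChainEngine(models, population)
    missing = [o for o in outcomes if o not in engine.stages]
    if missing:
        raise ConfigurationError(f"no model for outcomes {missing}")
    tract_ids, tract_codes = np.unique(
        population["tract_id"].astype(str).to_numpy(), return_inverse=True
    )
    tract_sizes = np.bincount(tract_codes)
    draws = np.empty((len(outcomes), n_reps, len(tract_ids)))
    for r in range(n_reps):
        rng = np.random.default_rng(derive_seed(rng_seed, "mc", mode, r))
        if mode == "outcome-draw":
            res = engine.run_draw(rng)
            values = {o: res[CHAIN_COLUMNS[o]] for o in outcomes}
        elif mode == "coefficient-draw":
            trial = ChainEngine.__new__(ChainEngine)
            trial.df = engine.df
            trial.models = engine.models
            trial.stages = engine.stages
            trial.compiled = {
                s: cm.perturbed(rng) for s, cm in engine.compiled.items()
            }
            res = trial.run_expect()
            values = {o: res[f"p_{o}"] for o in outcomes}
        else:
            raise ConfigurationError(f"unknown Monte Carlo mode {mode!r}")
        for i, o in enumerate(outcomes):
            draws[i, r] = (
                np.bincount(tract_codes, weights=values[o],
                            minlength=len(tract_ids)) / tract_sizes
            )
    results = []
    for i, o in enumerate(outcomes):
        for j, tid in enumerate(tract_ids):
            results.append(MonteCarloResult(
                outcome=o, tract_id=str(tid), reps=draws[i, :, j].copy(),
                mode=mode, rng_seed=rng_seed,
                n_individuals=int(tract_sizes[j]),
            ))
    return results


def monte_carlo_to_frame(results: list[MonteCarloResult]) -> pd.DataFrame:
    """Compact long format: one row per (outcome, tract, rep)."""
    frames = []
    for r in results:
        frames.append(pd.DataFrame({
            "outcome": r.outcome, "tract_id": r.tract_id,
            "rep": np.arange(len(r.reps)), "prevalence": r.reps,
            "mode": r.mode,
        }))
    return pd.concat(frames, ignore_index=True)
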