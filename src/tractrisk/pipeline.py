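"""End-to-end orchestration: configuration, staged execution, manifest.

Stages run in the order

    simulate-data -> build-population -> fit-models (or load the published
    coefficient fixture) -> predict -> summarize -> export

with every intermediate serialized to the working directory as plain
CSV/JSON, so any stage can be re-run from the previous stage's files. All
randomness is derived from one master seed via stable per-stage (and
per-tract) substream labels, making the full run reproducible byte-for-byte
and tract-level work order-independent. A run manifest records the config
hash, per-stage seeds, package version, and a digest of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _stats

from . import __version__
from .errors import ConfigurationError, TractRiskError
from .microsim import AnnealConfig, build_population, constraints_from_frame, constraints_to_frame
from .prediction import (
    calibrate_chain,
    chain_predict,
    eligible_population,
    expected_chain_probabilities,
    monte_carlo,
    monte_carlo_to_frame,
)
from .regression import (
    CHAIN_ORDER,
    FittedModel,
    ModelSpec,
    VariableBlock,
    fit_chain,
    load_table1_fixture,
    model_from_table,
)
from .rngtools import derive_seed
from .summarize import (
    citywide_summary,
    comparison_report,
    export_geo,
    grid_geometries,
    load_table2_reference,
    rank_tracts,
    summaries_to_frame,
    summarize_tracts,
)
from . import synthgen
from .synthgen import (
    ADULT_AGE_BANDS,
    COLLAPSED_INCOME_BANDS,
    EDUCATION,
    GenParams,
    RACE_ETHNICITY,
    SEX,
    TrueModelSet,
    assign_upstream_behaviors,
    generate_ground_truth,
    sample_microdata,
    simulate_survey,
    tabulate_constraints,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate-data", "build-population", "fit-models", "predict",
              "summarize", "export")

#: published citywide prevalences (proportions) used as default calibration
#: targets when predicting from the coefficient-table fixture.
DEFAULT_FIXTURE_TARGETS = {"exercise": 0.649, "fruitveg": 0.179,
                           "diabetes": 0.111}


@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML-loadable.

    ``city`` selects a canned generator parameter set (``default`` for the
    31-tract gradient city, ``toy`` for the 4-tract low-diversity city).
    """

    workdir: str = "runs/demo"
    master_seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    # synthetic data
    city: str = "default"
    n_tracts: int = 31
    households_per_tract: int = 400
    microdata_fraction: float = 0.5
    survey_n: int = 15814

    # annealing
    anneal_max_proposals: int = 50_000
    anneal_stall_limit: int = 2_000
    anneal_cooling: float = 0.99
    anneal_proposals_per_temperature: int = 100

    # modeling
    use_fixture: bool = False
    fixture_targets: dict = field(
        default_factory=lambda: dict(DEFAULT_FIXTURE_TARGETS)
    )
    fixture_bmi_target_mean: float = 27.0
    alpha: float = 0.05
    chain_order: tuple[str, ...] = CHAIN_ORDER

    # prediction
    min_age: int = 21
    mc_reps: int = 1000
    mc_mode: str = "outcome-draw"

    # export
    geometry_path: str | None = None

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        if self.city not in ("default", "toy"):
            raise ConfigurationError(f"unknown city preset {self.city!r}")
        if self.mc_mode not in ("outcome-draw", "coefficient-draw"):
            raise ConfigurationError(f"unknown mc_mode {self.mc_mode!r}")
        order = [o for o in self.chain_order]
        canonical = [o for o in CHAIN_ORDER if o in order]
        if sorted(order) != sorted(set(order)) or order != canonical:
            raise ConfigurationError(
                f"chain_order {order} violates the dependency order "
                f"{list(CHAIN_ORDER)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "chain_order" in raw:
            raw["chain_order"] = tuple(raw["chain_order"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["chain_order"] = list(self.chain_order)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    config: dict
    package_version: str
    stage_seeds: dict
    stages_run: list
    timestamps: dict
    diagnostics: dict
    output_digests: dict

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def default_model_specs(chain_order=CHAIN_ORDER) -> list[ModelSpec]:
    """Candidate predictor sets mirroring the published models' candidates.

    Every stage offers the demographic blocks plus all earlier-stage
    outcomes; backward selection decides what is retained.
    """
    demo = [
        VariableBlock("sex", "categorical", [SEX[1]], SEX[0]),
        VariableBlock("age_band", "categorical", ADULT_AGE_BANDS[:-1],
                      ADULT_AGE_BANDS[-1]),
        VariableBlock("race_ethnicity", "categorical", RACE_ETHNICITY[1:],
                      RACE_ETHNICITY[0]),
        VariableBlock("income_collapsed", "categorical",
                      COLLAPSED_INCOME_BANDS[:-1], COLLAPSED_INCOME_BANDS[-1]),
        VariableBlock("education", "categorical", EDUCATION[:-1], EDUCATION[-1]),
        VariableBlock("smoking", "categorical", ["current", "former"], "never"),
        VariableBlock("alcohol_any_30d", "binary"),
    ]
    extra = {
        "exercise": [],
        "fruitveg": [VariableBlock("exercise_any_30d", "binary")],
        "bmi": [VariableBlock("exercise_any_30d", "binary"),
                VariableBlock("fruitveg_5plus", "binary")],
        "diabetes": [
            VariableBlock("exercise_any_30d", "binary"),
            VariableBlock("fruitveg_5plus", "binary"),
            VariableBlock("bmi_category", "categorical",
                          ["normal", "overweight", "obese"], "underweight"),
        ],
    }
    family = {"exercise": "logistic", "fruitveg": "logistic",
              "bmi": "linear", "diabetes": "logistic"}
    return [
        ModelSpec(outcome=o, family=family[o],
                  blocks=[dataclasses.replace(b) for b in demo] + extra[o])
        for o in chain_order
    ]


def prune_specs_to_survey(specs: list[ModelSpec],
                          survey: pd.DataFrame) -> list[ModelSpec]:
    """Drop candidate categories (and whole blocks) unobserved in the survey.

    Sparse synthetic cities may leave declared categories empty; a block
    whose non-reference categories are all unobserved is removed from the
    candidate set entirely.
    """
    out = []
    for spec in specs:
        blocks = []
        for b in spec.blocks:
            if b.kind != "categorical" or b.categories is None:
                blocks.append(b)
                continue
            counts = survey[b.variable].dropna().value_counts()
            observed = set(counts.index)
            reference = b.reference
            if reference not in observed or counts[reference] < 20:
                # reference-cell coding needs a well-populated reference (a
                # near-empty one makes every contrast unstable); fall back to
                # the most frequent observed category
                reference = counts.idxmax()
                logger.info("block %s of %s: reference %r unobserved; using "
                            "%r", b.variable, spec.outcome, b.reference,
                            reference)
            declared = list(b.categories)
            if b.reference is not None and b.reference not in declared:
                declared.append(b.reference)  # demoted reference stays a level
            cats = [c for c in declared if c in observed and c != reference]
            if cats:
                blocks.append(dataclasses.replace(b, categories=cats,
                                                  reference=reference))
            else:
                logger.info("pruning empty candidate block %s from %s",
                            b.variable, spec.outcome)
        out.append(ModelSpec(outcome=spec.outcome, family=spec.family,
                             blocks=blocks,
                             response_column=spec.response_column,
                             chain_stage=spec.chain_stage))
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _gen_params(config: PipelineConfig) -> GenParams:
    preset = GenParams.toy if config.city == "toy" else GenParams.default
    return preset(
        n_tracts=config.n_tracts,
        households_per_tract=config.households_per_tract,
        rng_seed=derive_seed(config.master_seed, "simulate-data"),
    )


def _stage_simulate(config: PipelineConfig, wd: Path, diag: dict):
    params = _gen_params(config)
    truth = TrueModelSet.default()
    pop = generate_ground_truth(params)
    assign_upstream_behaviors(
        pop, truth, derive_seed(config.master_seed, "behaviors")
    )
    pop.to_frame().to_csv(wd / "truth_population.csv", index=False)
    tables = tabulate_constraints(pop)
    constraints_to_frame(tables).to_csv(wd / "constraints.csv", index=False)
    micro = sample_microdata(
        pop, config.microdata_fraction,
        derive_seed(config.master_seed, "microdata"),
    )
    micro.to_frame().to_csv(wd / "microdata.csv", index=False)
    survey = simulate_survey(
        pop, truth, config.survey_n, derive_seed(config.master_seed, "survey")
    )
    survey.to_csv(wd / "survey.csv", index=False)
    # ground-truth tract prevalences (eligible adults, upstream integrated out)
    frame = eligible_population(pop.to_frame(), config.min_age)
    chain = {m.outcome: m for m in truth.models
             if m.outcome in ("exercise", "fruitveg", "bmi", "diabetes")}
    probs = expected_chain_probabilities(chain, frame)
    probs["tract_id"] = frame["tract_id"].to_numpy()
    truth_prev = probs.groupby("tract_id")[
        ["p_exercise", "p_fruitveg", "p_diabetes"]
    ].mean()
    truth_prev.to_csv(wd / "truth_tract_prevalence.csv")
    diag["simulate-data"] = {
        "n_households": len(pop.households),
        "n_individuals": pop.n_individuals,
        "n_microdata_households": len(micro.households),
        "survey_n": len(survey),
    }


def _stage_build(config: PipelineConfig, wd: Path, diag: dict):
    micro = pd.read_csv(wd / "microdata.csv")
    tables = constraints_from_frame(pd.read_csv(wd / "constraints.csv"))
    anneal = AnnealConfig(
        cooling=config.anneal_cooling,
        proposals_per_temperature=config.anneal_proposals_per_temperature,
        max_proposals=config.anneal_max_proposals,
        stall_limit=config.anneal_stall_limit,
        rng_seed=derive_seed(config.master_seed, "build-population"),
    )
    synth, report = build_population(micro, tables, anneal)
    synth.materialize(micro).to_csv(wd / "synthetic_population.csv", index=False)
    with open(wd / "anneal_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    diag["build-population"] = {
        "mean_relative_tae": report["mean_relative_tae"],
        "n_tracts": len(report["tracts"]),
    }


def _stage_fit(config: PipelineConfig, wd: Path, diag: dict):
    (wd / "models").mkdir(exist_ok=True)
    if config.use_fixture:
        fixture = load_table1_fixture()
        models = {o: model_from_table(fixture, o) for o in config.chain_order}
        synth = pd.read_csv(wd / "synthetic_population.csv")
        eligible = eligible_population(synth, config.min_age)
        models = calibrate_chain(
            models, eligible, config.fixture_targets,
            bmi_target_mean=config.fixture_bmi_target_mean,
        )
        diag["fit-models"] = {"source": "published coefficient fixture",
                              "calibration_targets": config.fixture_targets}
    else:
        survey = pd.read_csv(wd / "survey.csv")
        specs = prune_specs_to_survey(
            default_model_specs(config.chain_order), survey
        )
        fitted = fit_chain(survey, specs, alpha=config.alpha)
        models = {m.outcome: m for m in fitted}
        diag["fit-models"] = {
            "source": "backward selection on simulated survey",
            "n_survey": len(survey),
            "retained": {m.outcome: m.predictors for m in fitted},
            "dropped": {m.outcome: [d["variable"] for d in m.dropped]
                        for m in fitted},
        }
    for o, m in models.items():
        m.to_json(wd / "models" / f"{o}.json")


def _load_models(config: PipelineConfig, wd: Path) -> dict[str, FittedModel]:
    models = {}
    for o in config.chain_order:
        path = wd / "models" / f"{o}.json"
        if not path.exists():
            raise ConfigurationError(f"missing model file {path}")
        models[o] = FittedModel.from_json(path)
    return models


def _stage_predict(config: PipelineConfig, wd: Path, diag: dict):
    synth = pd.read_csv(wd / "synthetic_population.csv")
    eligible = eligible_population(synth, config.min_age)
    models = _load_models(config, wd)
    preds = chain_predict(
        models, eligible,
        rng_seed=derive_seed(config.master_seed, "predict"),
    )
    preds.to_csv(wd / "predictions.csv", index=False)
    mc = monte_carlo(
        models, eligible, n_reps=config.mc_reps, mode=config.mc_mode,
        rng_seed=derive_seed(config.master_seed, "monte-carlo"),
    )
    monte_carlo_to_frame(mc).to_csv(wd / "mc_reps.csv", index=False)
    diag["predict"] = {
        "n_eligible": len(eligible),
        "n_excluded_under_min_age": int(len(synth) - len(eligible)),
        "mc_reps": config.mc_reps,
        "mc_mode": config.mc_mode,
    }


def _mc_from_frame(frame: pd.DataFrame):
    from .prediction import MonteCarloResult

    results = []
    for (outcome, tract), g in frame.groupby(["outcome", "tract_id"], sort=True):
        results.append(MonteCarloResult(
            outcome=outcome, tract_id=str(tract),
            reps=g.sort_values("rep")["prevalence"].to_numpy(),
            mode=g["mode"].iloc[0], rng_seed=-1, n_individuals=0,
        ))
    return results


def _stage_summarize(config: PipelineConfig, wd: Path, diag: dict):
    frame = pd.read_csv(wd / "mc_reps.csv")
    synth = pd.read_csv(wd / "synthetic_population.csv")
    eligible = eligible_population(synth, config.min_age)
    sizes = eligible.groupby("tract_id").size().to_dict()
    mc = _mc_from_frame(frame)
    for r in mc:
        r.n_individuals = int(sizes.get(r.tract_id, 0))
    tract_summaries = summarize_tracts(mc)
    summaries_to_frame(tract_summaries).to_csv(wd / "tract_summaries.csv",
                                               index=False)
    city = citywide_summary(mc, population_sizes=sizes)
    summaries_to_frame(city).to_csv(wd / "citywide_summary.csv", index=False)
    report = comparison_report(city, load_table2_reference())
    report.to_csv(wd / "comparison_city_brfss.csv", index=False)
    with open(wd / "comparison_city_brfss.txt", "w") as fh:
        fh.write(report.to_string(index=False) + "\n")
    for outcome in ("exercise", "fruitveg", "diabetes"):
        rank_tracts(tract_summaries, outcome).to_csv(
            wd / f"ranks_{outcome}.csv", index=False
        )
    diag["summarize"] = {
        "citywide": {s.outcome: {"mean": s.mean, "lower": s.lower,
                                 "upper": s.upper} for s in city}
    }
    truth_path = wd / "truth_tract_prevalence.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path).set_index("tract_id")
        est = summaries_to_frame(tract_summaries).pivot(
            index="tract_id", columns="outcome", values="mean"
        )
        rows = {}
        for outcome in ("exercise", "fruitveg", "diabetes"):
            joined = est[outcome].to_frame("est").join(
                truth[f"p_{outcome}"].rename("truth"), how="inner"
            )
            rho = float(_stats.spearmanr(joined["est"], joined["truth"]).statistic)
            rows[outcome] = rho
        pd.DataFrame(
            {"outcome": list(rows), "spearman_vs_truth": list(rows.values())}
        ).to_csv(wd / "evaluation_vs_truth.csv", index=False)
        diag["summarize"]["spearman_vs_truth"] = rows


def _stage_export(config: PipelineConfig, wd: Path, diag: dict):
    frame = pd.read_csv(wd / "tract_summaries.csv")
    from .summarize import TractOutcomeSummary

    summaries = [
        TractOutcomeSummary(
            tract_id=row["tract_id"], outcome=row["outcome"],
            mean=row["mean"], lower=row["lower"], upper=row["upper"],
            cv=row["cv"], n_individuals=int(row["n_individuals"]),
        )
        for _, row in frame.iterrows()
    ]
    if config.geometry_path:
        with open(config.geometry_path) as fh:
            collection = json.load(fh)
        geometries = {
            f["properties"]["tract_id"]: f["geometry"]
            for f in collection["features"]
        }
    else:
        geometries = grid_geometries(sorted(frame["tract_id"].unique()))
    warn_total = 0
    for outcome in ("exercise", "fruitveg", "diabetes"):
        fc, warnings = export_geo(summaries, geometries, outcome)
        warn_total += len(warnings)
        with open(wd / f"prevalence_{outcome}.geojson", "w") as fh:
            json.dump(fc, fh, indent=1)
    diag["export"] = {"n_geometry_warnings": warn_total}


_STAGE_FUNCS = {
    "simulate-data": _stage_simulate,
    "build-population": _stage_build,
    "fit-models": _stage_fit,
    "predict": _stage_predict,
    "summarize": _stage_summarize,
    "export": _stage_export,
}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and write the run manifest.

    A stage failure aborts with the stage named; earlier intermediates stay
    on disk for resumption.
    """
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    timestamps = {"start": time.time()}
    diag: dict = {}
    run = [s for s in ALL_STAGES if s in config.stages]
    for stage in run:
        t0 = time.time()
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](config, wd, diag)
        except Exception as exc:
            raise TractRiskError(f"stage {stage!r} failed: {exc}") from exc
        timestamps[stage] = time.time() - t0
    timestamps["end"] = time.time()
    digests = {
        p.name: _digest(p)
        for p in sorted(wd.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config.config_hash,
        config=config.to_dict(),
        package_version=__version__,
        stage_seeds={s: derive_seed(config.master_seed, s) for s in run},
        stages_run=run,
        timestamps=timestamps,
        diagnostics=diag,
        output_digests=digests,
    )
    manifest.to_json(wd / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

_MICRODATA_COLUMNS = [
    "individual_id", "household_id", "sex", "age_years", "age_band",
    "race_ethnicity", "education", "employment", "ancestry",
    "head_age_band", "income_band", "tenure",
]
_CONSTRAINT_COLUMNS = [
    "tract_id", "table_name", "level", "variables", "category_key", "count",
]


def validate_inputs(config: PipelineConfig) -> dict:
    """Schema and consistency checks; errors are collected, not raised."""
    wd = Path(config.workdir)
    errors: list[str] = []
    checked: list[str] = []

    def _check_csv(name, required):
        path = wd / name
        if not path.exists():
            errors.append(f"{name}: missing")
            return None
        df = pd.read_csv(path)
        missing = [c for c in required if c not in df.columns]
        if missing:
            errors.append(f"{name}: missing columns {missing}")
            return None
        checked.append(name)
        return df

    micro = _check_csv("microdata.csv", _MICRODATA_COLUMNS)
    cons = _check_csv("constraints.csv", _CONSTRAINT_COLUMNS)
    if micro is not None and cons is not None:
        if (cons["count"] < 0).any():
            errors.append("constraints.csv: negative counts")
        for (name, variables), g in cons.groupby(["table_name", "variables"]):
            varlist = variables.split("|")
            for i, var in enumerate(varlist):
                if var not in micro.columns:
                    errors.append(
                        f"constraints.csv: table {name} uses variable {var!r} "
                        "absent from microdata"
                    )
                    continue
                have = set(micro[var].astype(str))
                used = {
                    k.split("|")[i]
                    for k, c in zip(g["category_key"], g["count"]) if c > 0
                }
                orphan = used - have
                if orphan:
                    errors.append(
                        f"constraints.csv: table {name} references categories "
                        f"{sorted(orphan)} of {var!r} absent from microdata"
                    )
    try:
        PipelineConfig(**{**config.to_dict()})
    except ConfigurationError as exc:
        errors.append(str(exc))
    report = {"ok": not errors, "errors": errors, "checked": checked}
    if errors:
        logger.error("validate_inputs: %d errors", len(errors))
    return report
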