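"""Synthetic ground truth for every pipeline stage.

Real inputs to this kind of analysis — public-use microdata with coarse
geography, small-area marginal tables, and a telephone health survey — are
restricted or unredistributable. This module generates a multi-tract city
with known structure instead: correlated demographic distributions that vary
smoothly across tracts (education, income, race/ethnicity, age and tenure
gradients emulating within-city heterogeneity), individuals grouped into
households, and behaviors/outcomes produced by a *known* chain of logistic/
linear models (smoking -> alcohol -> exercise -> fruit/vegetable -> BMI ->
diabetes). From the ground truth it derives exactly the three inputs the
pipeline consumes — per-tract constraint tables, a tract-stripped household
microdata sample, and a survey of adults — so every downstream estimate can
be checked against known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .microsim import DEFAULT_CONSTRAINT_DEFS, ConstraintDef, ConstraintTable, tabulate_table
from .prediction import ChainEngine, BMI_CATEGORIES, SMOKING_CATEGORIES
from .regression import Coefficient, FittedModel, TermBlock
from .rngtools import derive_seed

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# category spaces
# ---------------------------------------------------------------------------

AGE_BANDS = ["0-17", "18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80-99"]
ADULT_AGE_BANDS = AGE_BANDS[1:]
_AGE_BOUNDS = {
    "0-17": (0, 17), "18-29": (18, 29), "30-39": (30, 39), "40-49": (40, 49),
    "50-59": (50, 59), "60-69": (60, 69), "70-79": (70, 79), "80-99": (80, 99),
}

SEX = ["female", "male"]
RACE_ETHNICITY = ["white_nh", "black_nh", "hispanic", "other"]
EDUCATION = ["lt_highschool", "highschool", "gt_highschool"]
EMPLOYMENT = ["employed", "unemployed", "retired", "other"]
TENURE = ["own", "rent"]
ANCESTRY = ["portuguese", "cape_verdean", "latin_american", "other"]

FINE_INCOME_BANDS = ["lt_10k", "10_15k", "15_25k", "25_35k", "35_50k", "ge_50k"]
COLLAPSED_INCOME_BANDS = ["lt_25k", "25_35k", "ge_35k"]
#: finer generator bands -> the three analysis bands
INCOME_COLLAPSE = {
    "lt_10k": "lt_25k", "10_15k": "lt_25k", "15_25k": "lt_25k",
    "25_35k": "25_35k", "35_50k": "ge_35k", "ge_50k": "ge_35k",
}

#: spaces used when tabulating the default constraint tables
CATEGORY_SPACES = {
    "sex": SEX,
    "age_band": AGE_BANDS,
    "education": EDUCATION,
    "ancestry": ANCESTRY,
    "race_ethnicity": RACE_ETHNICITY,
    "employment": EMPLOYMENT,
    "head_age_band": ADULT_AGE_BANDS,
    "income_band": FINE_INCOME_BANDS,
    "tenure": TENURE,
}

_PROFILE_VARS = {
    "sex": SEX,
    "adult_age_band": ADULT_AGE_BANDS,
    "race_ethnicity": RACE_ETHNICITY,
    "education": EDUCATION,
    "income_band": FINE_INCOME_BANDS,
    "employment": EMPLOYMENT,
    "tenure": TENURE,
    "ancestry": ANCESTRY,
}


def age_to_band(age: int) -> str:
    for band, (lo, hi) in _AGE_BOUNDS.items():
        if lo <= age <= hi:
            return band
    raise ConfigurationError(f"age {age} outside 0-99")


def collapse_income(values: pd.Series) -> pd.Series:
    return values.map(INCOME_COLLAPSE)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    individual_id: str
    household_id: str
    sex: str
    age_years: int
    race_ethnicity: str
    education: str
    employment: str
    ancestry: str
    smoking: str | None = None
    alcohol_any_30d: int | None = None

    @property
    def age_band(self) -> str:
        return age_to_band(self.age_years)


@dataclass
class Household:
    household_id: str
    tract_id: str | None
    income_band: str
    tenure: str
    members: list[Individual]

    def __post_init__(self):
        if not self.members:
            raise ConfigurationError(
                f"household {self.household_id} has no members"
            )

    @property
    def head_age_band(self) -> str:
        # household head = oldest member (deterministic convention)
        return age_to_band(max(m.age_years for m in self.members))


def _households_to_frame(households, include_tract: bool) -> pd.DataFrame:
    rows = []
    for h in households:
        head_band = h.head_age_band
        for m in h.members:
            row = {
                "individual_id": m.individual_id,
                "household_id": h.household_id,
                "sex": m.sex,
                "age_years": m.age_years,
                "age_band": m.age_band,
                "race_ethnicity": m.race_ethnicity,
                "education": m.education,
                "employment": m.employment,
                "ancestry": m.ancestry,
                "head_age_band": head_band,
                "income_band": h.income_band,
                "tenure": h.tenure,
                "smoking": m.smoking,
                "alcohol_any_30d": m.alcohol_any_30d,
            }
            if include_tract:
                row["tract_id"] = h.tract_id
            rows.append(row)
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["income_collapsed"] = collapse_income(frame["income_band"])
    return frame


@dataclass
class Population:
    """Ground-truth city: households with tract labels."""

    households: list[Household]

    @property
    def individuals(self):
        for h in self.households:
            yield from h.members

    @property
    def n_individuals(self) -> int:
        return sum(len(h.members) for h in self.households)

    @property
    def tract_ids(self) -> list[str]:
        return sorted({h.tract_id for h in self.households})

    def to_frame(self) -> pd.DataFrame:
        """Flat individual-row view, household fields repeated."""
        return _households_to_frame(self.households, include_tract=True)


@dataclass
class MicrodataSample:
    """Household pool with coarse geography: tract labels stripped."""

    households: list[Household]

    def to_frame(self) -> pd.DataFrame:
        return _households_to_frame(self.households, include_tract=False)


# ---------------------------------------------------------------------------
# generation parameters
# ---------------------------------------------------------------------------

@dataclass
class GenParams:
    """City-generator settings.

    ``profiles`` holds per-tract category probabilities, one row per tract,
    for each of: sex, adult_age_band, race_ethnicity, education, income_band
    (fine bands), employment, tenure, ancestry. ``child_fraction`` is the
    probability that a non-first household member is a child (age 0-17);
    children receive the lowest education band and employment 'other'.
    """

    n_tracts: int
    households_per_tract: int | list[int]
    profiles: dict[str, np.ndarray]
    child_fraction: np.ndarray
    mean_household_size: float = 2.4
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_tracts <= 0:
            raise ConfigurationError("n_tracts must be positive")
        counts = self.households_counts()
        if any(c <= 0 for c in counts):
            raise ConfigurationError("households_per_tract must be positive")
        if self.mean_household_size < 1.0:
            raise ConfigurationError("mean_household_size must be >= 1")
        for var, cats in _PROFILE_VARS.items():
            if var not in self.profiles:
                raise ConfigurationError(f"missing profile for {var!r}")
            prof = np.asarray(self.profiles[var], dtype=float)
            if prof.shape != (self.n_tracts, len(cats)):
                raise ConfigurationError(
                    f"profile for {var!r} must have shape "
                    f"({self.n_tracts}, {len(cats)})"
                )
            if (prof < 0).any():
                raise ConfigurationError(f"negative probability in {var!r}")
            bad = np.abs(prof.sum(axis=1) - 1.0) > 1e-9
            if bad.any():
                tract = int(np.argmax(bad))
                raise ConfigurationError(
                    f"profile for variable {var!r} does not sum to 1 in "
                    f"tract {tract}"
                )
            self.profiles[var] = prof
        self.child_fraction = np.asarray(self.child_fraction, dtype=float)
        if self.child_fraction.shape != (self.n_tracts,):
            raise ConfigurationError("child_fraction must have one entry per tract")

    def households_counts(self) -> list[int]:
        if isinstance(self.households_per_tract, int):
            return [self.households_per_tract] * self.n_tracts
        if len(self.households_per_tract) != self.n_tracts:
            raise ConfigurationError(
                "households_per_tract list length must equal n_tracts"
            )
        return list(self.households_per_tract)

    # -- canned parameter sets ---------------------------------------------
    @classmethod
    def default(cls, n_tracts: int = 31, households_per_tract: int = 400,
                rng_seed: int = 0) -> "GenParams":
        """A city with smooth cross-tract gradients.

        Education, income, race/ethnicity, tenure, age structure and child
        share all vary with tract index (plus a deterministic wiggle), so
        tract-level outcome prevalences differ enough for rank-recovery
        checks. Defaults give ~1,000 residents per tract.
        """
        t = np.linspace(0.0, 1.0, n_tracts) if n_tracts > 1 else np.array([0.5])
        i = np.arange(n_tracts)

        def axis(phase):
            # independent smooth spatial axis in [0, 1] per variable group,
            # golden-angle stepped so no two axes are collinear across tracts
            return 0.5 + 0.5 * np.sin(i * 2.39996 + phase)

        def norm(cols):
            cols = [np.broadcast_to(np.asarray(c, float), (n_tracts,)) for c in cols]
            arr = np.clip(np.column_stack(cols), 1e-6, None)
            return arr / arr.sum(axis=1, keepdims=True)

        a_age = axis(1.0)        # 0 = young tract, 1 = retiree-heavy tract
        a_ses = 0.7 * t + 0.3 * axis(2.6)  # socioeconomic axis, mostly east-west
        a_race = axis(4.1)  # ethnic composition axis, independent of SES
        young = np.array([0.32, 0.22, 0.16, 0.12, 0.08, 0.06, 0.04])
        old = np.array([0.12, 0.12, 0.14, 0.16, 0.18, 0.16, 0.12])
        age_prof = np.outer(1 - a_age, young) + np.outer(a_age, old)
        profiles = {
            "sex": norm([0.51 + 0.02 * axis(0.3), 0.49 - 0.02 * axis(0.3)]),
            "adult_age_band": norm(list(age_prof.T)),
            "race_ethnicity": norm([
                0.75 - 0.35 * a_race, 0.05 + 0.08 * a_race,
                0.12 + 0.22 * a_race, 0.08 + 0.05 * a_race,
            ]),
            "education": norm([
                0.10 + 0.32 * a_ses, np.full(n_tracts, 0.35),
                0.55 - 0.32 * a_ses,
            ]),
            "income_band": norm([
                0.04 + 0.12 * a_ses, 0.05 + 0.08 * a_ses, 0.10 + 0.10 * a_ses,
                np.full(n_tracts, 0.16), 0.25 - 0.10 * a_ses,
                0.40 - 0.20 * a_ses,
            ]),
            "employment": norm([
                0.62 - 0.15 * a_ses, 0.05 + 0.10 * a_ses,
                np.full(n_tracts, 0.22), 0.11 + 0.05 * a_ses,
            ]),
            "tenure": norm([0.65 - 0.40 * a_ses, 0.35 + 0.40 * a_ses]),
            "ancestry": norm([
                0.35 - 0.10 * a_race, 0.10 + 0.10 * a_race,
                0.10 + 0.15 * a_race, 0.45 - 0.15 * a_race,
            ]),
        }
        return cls(
            n_tracts=n_tracts, households_per_tract=households_per_tract,
            profiles=profiles, child_fraction=0.40 - 0.25 * a_age,
            mean_household_size=2.4, rng_seed=rng_seed,
        )

    @classmethod
    def toy(cls, n_tracts: int = 4, households_per_tract: int = 30,
            rng_seed: int = 0) -> "GenParams":
        """A tiny, low-diversity city (small households, few occupied
        categories) for which exact constraint matching is feasible."""
        t = np.linspace(0.0, 1.0, n_tracts) if n_tracts > 1 else np.array([0.5])

        def norm(cols):
            cols = [np.broadcast_to(np.asarray(c, float), (n_tracts,)) for c in cols]
            arr = np.clip(np.column_stack(cols), 0.0, None)
            return arr / arr.sum(axis=1, keepdims=True)

        zero = np.zeros(n_tracts)
        profiles = {
            "sex": norm([0.55 - 0.1 * t, 0.45 + 0.1 * t]),
            # only three occupied age bands: 18-29, 40-49, 60-69
            "adult_age_band": norm([
                0.5 - 0.3 * t, zero, 0.3, zero, 0.2 + 0.3 * t, zero, zero,
            ]),
            "race_ethnicity": norm([np.ones(n_tracts), zero, zero, zero]),
            "education": norm([0.2 + 0.4 * t, 0.4, 0.4 - 0.4 * t]),
            "income_band": norm([
                zero, zero, 0.3 + 0.4 * t, 0.3, 0.4 - 0.4 * t, zero,
            ]),
            "employment": norm([np.ones(n_tracts), zero, zero, zero]),
            "tenure": norm([0.6 - 0.3 * t, 0.4 + 0.3 * t]),
            "ancestry": norm([0.5 + 0.2 * t, zero, zero, 0.5 - 0.2 * t]),
        }
        # single-person households keep the swap move's fixed household
        # cardinality consistent with the household-level table totals, so an
        # exact-zero TAE is reachable
        return cls(
            n_tracts=n_tracts, households_per_tract=households_per_tract,
            profiles=profiles, child_fraction=np.zeros(n_tracts),
            mean_household_size=1.0, rng_seed=rng_seed,
        )


# ---------------------------------------------------------------------------
# ground-truth generation
# ---------------------------------------------------------------------------

def _draw_cats(rng, cats, p, size):
    return [cats[i] for i in rng.choice(len(cats), size=size, p=p)]


def generate_ground_truth(params: GenParams) -> Population:
    """Generate the multi-tract city; a pure function of (params, seed).

    Each household draws tenure, income, race/ethnicity and ancestry once
    (members inherit race/ancestry with probability 0.9, giving realistic
    within-household correlation); the first member is always an adult, the
    rest are children with the tract's child fraction.
    """
    households: list[Household] = []
    counts = params.households_counts()
    for t in range(params.n_tracts):
        tract_id = f"tract{t:03d}"
        rng = np.random.default_rng(derive_seed(params.rng_seed, "gen", t))
        n_hh = counts[t]
        sizes = 1 + rng.poisson(params.mean_household_size - 1.0, n_hh)
        tenure_h = _draw_cats(rng, TENURE, params.profiles["tenure"][t], n_hh)
        income_h = _draw_cats(rng, FINE_INCOME_BANDS,
                              params.profiles["income_band"][t], n_hh)
        race_h = _draw_cats(rng, RACE_ETHNICITY,
                            params.profiles["race_ethnicity"][t], n_hh)
        anc_h = _draw_cats(rng, ANCESTRY, params.profiles["ancestry"][t], n_hh)
        n_people = int(sizes.sum())
        hh_of = np.repeat(np.arange(n_hh), sizes)
        first = np.zeros(n_people, dtype=bool)
        first[np.cumsum(sizes) - sizes] = True
        is_child = (~first) & (rng.random(n_people) < params.child_fraction[t])
        band_idx = rng.choice(
            len(ADULT_AGE_BANDS), n_people,
            p=params.profiles["adult_age_band"][t],
        )
        u = rng.random(n_people)
        lo = np.array([_AGE_BOUNDS[b][0] for b in ADULT_AGE_BANDS])[band_idx]
        hi = np.array([_AGE_BOUNDS[b][1] for b in ADULT_AGE_BANDS])[band_idx]
        ages = lo + np.floor(u * (hi - lo + 1)).astype(int)
        ages[is_child] = rng.integers(0, 18, int(is_child.sum()))
        sex_m = _draw_cats(rng, SEX, params.profiles["sex"][t], n_people)
        edu_m = _draw_cats(rng, EDUCATION, params.profiles["education"][t],
                           n_people)
        emp_m = _draw_cats(rng, EMPLOYMENT, params.profiles["employment"][t],
                           n_people)
        inherit_race = rng.random(n_people) < 0.9
        race_alt = _draw_cats(rng, RACE_ETHNICITY,
                              params.profiles["race_ethnicity"][t], n_people)
        inherit_anc = rng.random(n_people) < 0.9
        anc_alt = _draw_cats(rng, ANCESTRY, params.profiles["ancestry"][t],
                             n_people)
        person = 0
        for h in range(n_hh):
            hid = f"{tract_id}_h{h:05d}"
            members = []
            for k in range(sizes[h]):
                i = person
                person += 1
                age = int(ages[i])
                members.append(Individual(
                    individual_id=f"{hid}_p{k}",
                    household_id=hid,
                    sex=sex_m[i],
                    age_years=age,
                    race_ethnicity=race_h[h] if inherit_race[i] else race_alt[i],
                    education="lt_highschool" if age < 18 else edu_m[i],
                    employment="other" if age < 18 else emp_m[i],
                    ancestry=anc_h[h] if inherit_anc[i] else anc_alt[i],
                ))
            households.append(Household(
                household_id=hid, tract_id=tract_id,
                income_band=income_h[h], tenure=tenure_h[h], members=members,
            ))
    pop = Population(households=households)
    logger.info("generated %d households / %d individuals across %d tracts",
                len(households), pop.n_individuals, params.n_tracts)
    return pop


def tabulate_constraints(
    pop: Population,
    constraint_defs: list[ConstraintDef] | None = None,
    category_spaces: dict[str, list[str]] | None = None,
) -> list[ConstraintTable]:
    """Exact per-tract tabulation of the constraint tables.

    Defaults reproduce the thirteen-table layout: eight individual-level
    (ancestry, sex, age, education plus their crosses up to sex x age x
    education) and five household-level (head age, income, tenure and
    crosses).
    """
    defs = constraint_defs if constraint_defs is not None else DEFAULT_CONSTRAINT_DEFS
    spaces = category_spaces or CATEGORY_SPACES
    frame = pop.to_frame()
    tables = []
    for tract_id, g in frame.groupby("tract_id", sort=True):
        for d in defs:
            tables.append(tabulate_table(g, d, spaces, tract_id))
    return tables


def sample_microdata(pop: Population, fraction: float, rng_seed: int) -> MicrodataSample:
    """Independent whole-household sampling; tract labels are stripped."""
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("fraction must be in (0, 1]")
    rng = np.random.default_rng(derive_seed(rng_seed, "microdata"))
    keep = rng.random(len(pop.households)) < fraction if fraction < 1.0 \
        else np.ones(len(pop.households), dtype=bool)
    households = [
        replace(h, tract_id=None)
        for h, k in zip(pop.households, keep) if k
    ]
    if not households:
        raise ConfigurationError(
            f"fraction {fraction} produced an empty microdata sample"
        )
    return MicrodataSample(households=households)


# ---------------------------------------------------------------------------
# known generating models
# ---------------------------------------------------------------------------

def _cat_block(variable, reference, coefs: dict) -> TermBlock:
    return TermBlock(
        variable=variable, kind="categorical", reference=reference,
        terms={c: Coefficient(value=v) for c, v in coefs.items()},
    )


def _bin_block(variable, coef) -> TermBlock:
    return TermBlock(variable=variable, kind="binary",
                     terms={"1": Coefficient(value=coef)})


def _model(outcome, family, intercept, blocks) -> FittedModel:
    return FittedModel(outcome=outcome, family=family, intercept=intercept,
                       blocks=blocks, intercept_calibrated=True)


_AGE_REF = "80-99"


@dataclass
class TrueModelSet:
    """The generating chain: known coefficients in fixed dependency order."""

    models: list[FittedModel]
    bmi_noise_sd: float = 4.5

    def __post_init__(self):
        order = ["smoking_ever", "smoking_current", "alcohol", "exercise",
                 "fruitveg", "bmi", "diabetes"]
        allowed = {"sex", "age_band", "race_ethnicity", "education",
                   "employment", "ancestry", "income_collapsed", "income_band",
                   "tenure", "age_years"}
        pos = {o: order.index(o) for o in order}
        produced: set[str] = set()
        for m in sorted(self.models, key=lambda m: pos.get(m.outcome, 99)):
            if m.outcome not in pos:
                raise ConfigurationError(f"unknown chain outcome {m.outcome!r}")
            for b in m.blocks:
                if b.variable not in allowed and b.variable not in produced:
                    raise ConfigurationError(
                        f"model {m.outcome!r} uses {b.variable!r} before it "
                        "is produced: chain order violated"
                    )
            produced.add(m.response_column)
            if m.outcome == "smoking_current":
                produced.add("smoking")
            if m.outcome == "bmi":
                produced.add("bmi_category")

    def by_outcome(self) -> dict[str, FittedModel]:
        return {m.outcome: m for m in self.models}

    @classmethod
    def default(cls) -> "TrueModelSet":
        """Plausible, deliberately strong generating coefficients.

        Signs follow the epidemiology (lower income/education -> less
        exercise, more diabetes; age is the dominant diabetes predictor;
        current smokers exercise less but weigh less); magnitudes are chosen
        large enough that every truly-nonzero block is comfortably detectable
        at realistic survey sizes. Each downstream stage has exactly one
        structurally-zero candidate block (fruit/veg: alcohol; BMI:
        race/ethnicity; diabetes: education). Intercepts put citywide adult
        marginals near published city levels (exercise ~0.65, fruit/veg
        ~0.19, diabetes ~0.11, mean BMI ~27).
        """
        age = lambda c: _cat_block("age_band", _AGE_REF, c)  # noqa: E731
        models = [
            _model("smoking_ever", "logistic", -0.55, [
                _cat_block("sex", "female", {"male": 0.25}),
                age({"18-29": -0.40, "30-39": -0.10, "40-49": 0.15,
                     "50-59": 0.30, "60-69": 0.35, "70-79": 0.20}),
                _cat_block("education", "gt_highschool",
                           {"lt_highschool": 0.50, "highschool": 0.25}),
                _cat_block("income_collapsed", "ge_35k",
                           {"lt_25k": 0.30, "25_35k": 0.10}),
            ]),
            _model("smoking_current", "logistic", -0.80, [
                age({"18-29": 1.20, "30-39": 1.00, "40-49": 0.80,
                     "50-59": 0.50, "60-69": 0.10, "70-79": -0.30}),
                _cat_block("education", "gt_highschool",
                           {"lt_highschool": 0.60, "highschool": 0.30}),
                _cat_block("income_collapsed", "ge_35k",
                           {"lt_25k": 0.50, "25_35k": 0.20}),
            ]),
            _model("alcohol", "logistic", -0.10, [
                _cat_block("sex", "female", {"male": 0.40}),
                age({"18-29": 0.60, "30-39": 0.50, "40-49": 0.40,
                     "50-59": 0.30, "60-69": 0.10, "70-79": 0.00}),
                _cat_block("income_collapsed", "ge_35k",
                           {"lt_25k": -0.50, "25_35k": -0.20}),
                _cat_block("education", "gt_highschool",
                           {"lt_highschool": -0.50, "highschool": -0.25}),
            ]),
            _model("exercise", "logistic", 0.95, [
                _cat_block("sex", "female", {"male": 0.15}),
                age({"18-29": 0.50, "30-39": 0.25, "40-49": 0.10,
                     "50-59": -0.05, "60-69": -0.10, "70-79": -0.25}),
                _cat_block("race_ethnicity", "white_nh",
                           {"black_nh": -0.05, "hispanic": -0.35, "other": 0.25}),
                _cat_block("income_collapsed", "ge_35k",
                           {"lt_25k": -0.45, "25_35k": -0.15}),
                _cat_block("education", "gt_highschool",
                           {"lt_highschool": -0.55, "highschool": -0.20}),
                _cat_block("smoking", "never",
                           {"current": -0.35, "former": 0.10}),
                _bin_block("alcohol_any_30d", 0.25),
            ]),
            _model("fruitveg", "logistic", -1.55, [
                _cat_block("sex", "female", {"male": -0.30}),
                age({"18-29": -0.15, "30-39": -0.35, "40-49": -0.10,
                     "50-59": 0.05, "60-69": 0.10, "70-79": 0.15}),
                _cat_block("race_ethnicity", "white_nh",
                           {"black_nh": 0.30, "hispanic": 0.35, "other": -0.30}),
                _cat_block("income_collapsed", "ge_35k",
                           {"lt_25k": -0.25, "25_35k": -0.20}),
                _cat_block("education", "gt_highschool",
                           {"lt_highschool": -0.55, "highschool": -0.20}),
                _cat_block("smoking", "never",
                           {"current": -0.35, "former": 0.10}),
                _bin_block("exercise_any_30d", 0.45),
            ]),
            _model("bmi", "linear", 27.2, [
                _cat_block("sex", "female", {"male": 0.60}),
                age({"18-29": -1.20, "30-39": -0.30, "40-49": 0.20,
                     "50-59": 0.60, "60-69": 0.70, "70-79": 0.30}),
                _cat_block("income_collapsed", "ge_35k",
                           {"lt_25k": 0.80, "25_35k": 0.40}),
                _cat_block("education", "gt_highschool",
                           {"lt_highschool": 0.90, "highschool": 0.50}),
                _cat_block("smoking", "never",
                           {"current": -0.90, "former": 0.20}),
                _bin_block("alcohol_any_30d", -0.30),
                _bin_block("exercise_any_30d", -0.90),
                _bin_block("fruitveg_5plus", -0.50),
            ]),
            _model("diabetes", "logistic", -2.25, [
                _cat_block("sex", "female", {"male": 0.25}),
                age({"18-29": -1.65, "30-39": -0.93, "40-49": -0.29,
                     "50-59": 0.44, "60-69": 0.72, "70-79": 0.99}),
                _cat_block("race_ethnicity", "white_nh",
                           {"black_nh": 0.30, "hispanic": 0.35, "other": -0.15}),
                _cat_block("income_collapsed", "ge_35k",
                           {"lt_25k": 0.35, "25_35k": -0.10}),
                _cat_block("smoking", "never",
                           {"current": -0.25, "former": 0.25}),
                _bin_block("alcohol_any_30d", -0.36),
                _bin_block("exercise_any_30d", -0.30),
                _cat_block("bmi_category", "underweight",
                           {"normal": -0.53, "overweight": 0.054, "obese": 0.91}),
                _bin_block("fruitveg_5plus", -0.40),
            ]),
        ]
        return cls(models=models)

    @classmethod
    def null(cls, intercepts: dict[str, float] | None = None,
             bmi_intercept: float = 26.0, bmi_noise_sd: float = 4.5) -> "TrueModelSet":
        """All slopes zero: every field is an independent coin/Gaussian.

        Useful for calibration checks where the marginal prevalence equals
        the inverse-logit of the intercept exactly.
        """
        intercepts = intercepts or {}
        outs = ["smoking_ever", "smoking_current", "alcohol", "exercise",
                "fruitveg", "diabetes"]
        models = [
            _model(o, "logistic", intercepts.get(o, 0.0), []) for o in outs
        ]
        models.insert(5, _model("bmi", "linear", bmi_intercept, []))
        return cls(models=models, bmi_noise_sd=bmi_noise_sd)


# ---------------------------------------------------------------------------
# behavior assignment and survey simulation
# ---------------------------------------------------------------------------

def assign_upstream_behaviors(pop: Population, truth: TrueModelSet,
                              rng_seed: int) -> Population:
    """Draw smoking and alcohol onto every adult (18+) of the ground truth.

    These two behaviors ride along on the microdata into the synthetic
    population, mirroring how an inherited microdata product already carries
    them; downstream outcomes stay unassigned (they are what the pipeline
    predicts).
    """
    frame = pop.to_frame()
    adults = frame[frame["age_years"] >= 18]
    upstream = {m.outcome: m for m in truth.models
                if m.outcome in ("smoking_ever", "smoking_current", "alcohol")}
    engine = ChainEngine(upstream, adults)
    rng = np.random.default_rng(derive_seed(rng_seed, "behaviors"))
    res = engine.run_draw(rng)
    smoking = np.array(SMOKING_CATEGORIES)[res["smoking_code"]]
    alcohol = res["alcohol_any_30d"]
    by_id = dict(zip(adults["individual_id"], zip(smoking, alcohol)))
    for ind in pop.individuals:
        if ind.individual_id in by_id:
            s, a = by_id[ind.individual_id]
            ind.smoking = s
            ind.alcohol_any_30d = int(a)
    return pop


def simulate_survey(pop: Population, truth: TrueModelSet, n: int,
                    rng_seed: int) -> pd.DataFrame:
    """Simulate a telephone-survey extract of ``n`` adults.

    Adults (18+) are sampled without replacement; behaviors and outcomes are
    drawn sequentially through the generating chain — binary fields
    Bernoulli at the inverse-logit of their linear predictor, BMI as linear
    predictor plus Gaussian noise, diabetes conditional on the categorized
    BMI. Reproducible from ``rng_seed``.
    """
    frame = pop.to_frame()
    if n > len(frame):
        raise ConfigurationError(
            f"survey size {n} exceeds population size {len(frame)}"
        )
    adults = frame[frame["age_years"] >= 18].reset_index(drop=True)
    if n > len(adults):
        raise ConfigurationError(
            f"survey size {n} exceeds the adult population {len(adults)}"
        )
    rng = np.random.default_rng(derive_seed(rng_seed, "survey"))
    idx = rng.choice(len(adults), size=n, replace=False)
    sample = adults.iloc[np.sort(idx)].reset_index(drop=True)
    engine = ChainEngine(truth.by_outcome(), sample)
    res = engine.run_draw(rng, bmi_noise_sd=truth.bmi_noise_sd)
    out = sample.copy()
    for stage, col in (("smoking_ever", "smoking_ever"),
                       ("smoking_current", "smoking_current"),
                       ("alcohol", "alcohol_any_30d"),
                       ("exercise", "exercise_any_30d"),
                       ("fruitveg", "fruitveg_5plus"),
                       ("diabetes", "diabetes")):
        if col in res:
            out[col] = res[col]
    if "smoking_code" in res:
        out["smoking"] = np.array(SMOKING_CATEGORIES)[res["smoking_code"]]
    if "bmi_value" in res:
        out["bmi_value"] = res["bmi_value"]
        out["bmi_category"] = np.array(BMI_CATEGORIES)[res["bmi_category_code"]]
    return out
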