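"""Outcome regression models: fitting, backward selection, and ingestion of
published coefficient tables.

Each behavioral/health outcome (any exercise in the past 30 days, eating five
or more daily servings of fruit and vegetables, body mass index, diagnosed
diabetes) is modeled as a multivariable logistic or linear regression on
demographics plus earlier-stage outcomes. Categorical predictors enter as
whole *blocks* of reference-cell dummy indicators; model reduction removes
the least significant block (Wald chi-square, p > alpha) and refits until
every retained block is significant — the classic backward-selection rule.

Maximum-likelihood fitting is delegated to statsmodels (IRLS for the
logistic family, least squares for the linear family); block testing,
selection, chain orchestration and the published-table fixture are this
module's own machinery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr as _qr

from .errors import (
    ChainOrderError,
    ConfigurationError,
    ConvergenceError,
    RankDeficiencyError,
    SeparationError,
)

logger = logging.getLogger(__name__)

LOGISTIC = "logistic"
LINEAR = "linear"

#: order in which the outcome models are built; each stage may use earlier
#: stages' observed outcomes as predictors, never later ones.
CHAIN_ORDER = ("exercise", "fruitveg", "bmi", "diabetes")

#: survey/population column holding each outcome's observed value.
OUTCOME_COLUMNS = {
    "smoking_ever": "smoking_ever",
    "smoking_current": "smoking_current",
    "alcohol": "alcohol_any_30d",
    "exercise": "exercise_any_30d",
    "fruitveg": "fruitveg_5plus",
    "bmi": "bmi_value",
    "diabetes": "diabetes",
}


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class Coefficient:
    value: float
    se: float | None = None
    p: float | None = None
    significant: bool | None = None


@dataclass
class TermBlock:
    """All non-reference coefficients of one predictor.

    ``kind`` is ``categorical`` (reference-cell dummies), ``binary`` (a 0/1
    field entering as a single indicator, keyed ``"1"``) or ``continuous``
    (single slope, keyed by the variable name).
    """

    variable: str
    kind: str = "categorical"
    reference: str | None = None
    terms: dict[str, Coefficient] = field(default_factory=dict)
    block_p: float | None = None

    def coefficient(self, category: str) -> float:
        if self.kind == "categorical" and category == self.reference:
            return 0.0
        if category not in self.terms:
            raise KeyError(
                f"category {category!r} unseen for variable {self.variable!r}"
            )
        return self.terms[category].value


@dataclass
class VariableBlock:
    """Candidate predictor in a :class:`ModelSpec`."""

    variable: str
    kind: str = "categorical"
    categories: list[str] | None = None  # non-reference categories, ordered
    reference: str | None = None


@dataclass
class ModelSpec:
    outcome: str
    family: str
    blocks: list[VariableBlock]
    response_column: str | None = None
    chain_stage: int = 0

    def __post_init__(self):
        if self.family not in (LOGISTIC, LINEAR):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.response_column is None:
            self.response_column = OUTCOME_COLUMNS.get(self.outcome, self.outcome)
        for b in self.blocks:
            if b.variable == self.response_column:
                raise ConfigurationError(
                    f"outcome {self.outcome!r} listed among its own predictors"
                )
            if (
                b.kind == "categorical"
                and b.categories is not None
                and b.reference in b.categories
            ):
                raise ConfigurationError(
                    f"reference {b.reference!r} duplicated in categories of "
                    f"{b.variable!r}"
                )


@dataclass
class FittedModel:
    """A fitted (or ingested) outcome model.

    Reference categories carry an implicit coefficient of zero. ``cov`` and
    ``param_names`` retain the Wald covariance for block testing; ingested
    published models have neither (and an uncalibrated intercept).
    """

    outcome: str
    family: str
    intercept: float
    blocks: list[TermBlock]
    intercept_se: float | None = None
    intercept_calibrated: bool = True
    dropped: list[dict] = field(default_factory=list)
    n_used: int | None = None
    converged: bool = True
    chain_stage: int = 0
    response_column: str | None = None
    cov: np.ndarray | None = field(default=None, repr=False)
    param_names: list[str] | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.response_column is None:
            self.response_column = OUTCOME_COLUMNS.get(self.outcome, self.outcome)

    def block(self, variable: str) -> TermBlock:
        for b in self.blocks:
            if b.variable == variable:
                return b
        raise ValueError(f"variable {variable!r} not retained in model "
                         f"{self.outcome!r}")

    @property
    def predictors(self) -> list[str]:
        return [b.variable for b in self.blocks]

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "family": self.family,
            "response_column": self.response_column,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_calibrated": self.intercept_calibrated,
            "chain_stage": self.chain_stage,
            "n_used": self.n_used,
            "converged": self.converged,
            "dropped": self.dropped,
            "blocks": [
                {
                    "variable": b.variable,
                    "kind": b.kind,
                    "reference": b.reference,
                    "block_p": b.block_p,
                    "terms": {
                        k: {"value": c.value, "se": c.se, "p": c.p,
                            "significant": c.significant}
                        for k, c in b.terms.items()
                    },
                }
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        blocks = [
            TermBlock(
                variable=b["variable"],
                kind=b["kind"],
                reference=b.get("reference"),
                block_p=b.get("block_p"),
                terms={
                    k: Coefficient(**v) for k, v in b["terms"].items()
                },
            )
            for b in d["blocks"]
        ]
        return cls(
            outcome=d["outcome"],
            family=d["family"],
            intercept=d["intercept"],
            blocks=blocks,
            intercept_se=d.get("intercept_se"),
            intercept_calibrated=d.get("intercept_calibrated", True),
            dropped=d.get("dropped", []),
            n_used=d.get("n_used"),
            converged=d.get("converged", True),
            chain_stage=d.get("chain_stage", 0),
            response_column=d.get("response_column"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def spec_from_model(model: FittedModel) -> ModelSpec:
    """Candidate spec containing exactly the blocks a fitted model retained."""
    blocks = [
        VariableBlock(
            variable=b.variable,
            kind=b.kind,
            categories=list(b.terms) if b.kind == "categorical" else None,
            reference=b.reference,
        )
        for b in model.blocks
    ]
    return ModelSpec(
        outcome=model.outcome,
        family=model.family,
        blocks=blocks,
        response_column=model.response_column,
        chain_stage=model.chain_stage,
    )


# ---------------------------------------------------------------------------
# design encoding
# ---------------------------------------------------------------------------

def _column_name(block: VariableBlock, category: str | None = None) -> str:
    if block.kind == "categorical":
        return f"{block.variable}[{category}]"
    return block.variable


def encode_design(
    survey: pd.DataFrame,
    spec: ModelSpec,
    keep_columns: list[str] | None = None,
):
    """Reference-cell dummy coding of the candidate predictors.

    Rows with missing values in any used field are dropped (count logged).
    Returns ``(X, y, extras)`` where ``extras`` holds the complete-case
    values of ``keep_columns`` (e.g. survey weights).
    """
    keep_columns = keep_columns or []
    used = [spec.response_column] + [b.variable for b in spec.blocks] + keep_columns
    missing = [c for c in used if c not in survey.columns]
    if missing:
        raise ConfigurationError(f"survey lacks columns {missing}")
    df = survey[used].dropna()
    n_dropped = len(survey) - len(df)
    if n_dropped:
        logger.info(
            "encode_design(%s): dropped %d incomplete rows", spec.outcome, n_dropped
        )

    cols: dict[str, np.ndarray] = {}
    for b in spec.blocks:
        if b.kind == "categorical":
            observed = set(df[b.variable].unique())
            cats = b.categories
            if cats is None:
                cats = sorted(observed - {b.reference})
            unknown = observed - set(cats) - {b.reference}
            if unknown:
                raise ConfigurationError(
                    f"variable {b.variable!r}: unseen categories {sorted(unknown)}"
                )
            for cat in cats:
                ind = (df[b.variable] == cat).to_numpy(dtype=float)
                if ind.sum() == 0:
                    raise ConfigurationError(
                        f"category {cat!r} of {b.variable!r} empty after filtering"
                    )
                cols[_column_name(b, cat)] = ind
        else:
            cols[_column_name(b)] = df[b.variable].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    y = df[spec.response_column]
    extras = df[keep_columns] if keep_columns else None
    return X, y, extras


def _parse_column(name: str) -> tuple[str, str | None]:
    if name.endswith("]") and "[" in name:
        var, cat = name[:-1].split("[", 1)
        return var, cat
    return name, None


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _block_wald(params, cov, names, idx):
    b = params[idx]
    V = cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return np.nan
    return float(stats.chi2.sf(stat, df=len(idx)))


def _assemble(
    spec: ModelSpec | None,
    columns,
    params,
    bse,
    pvalues,
    cov,
    family,
    n_used,
):
    """Map a flat parameter vector back onto term blocks."""
    names = ["const"] + list(columns)
    by_col = {c: i for i, c in enumerate(names)}
    if spec is None:
        blocks_meta = [
            VariableBlock(variable=c, kind="continuous") for c in columns
        ]
        outcome, response, stage = "response", "response", 0
    else:
        blocks_meta = spec.blocks
        outcome, response, stage = spec.outcome, spec.response_column, spec.chain_stage

    blocks: list[TermBlock] = []
    for b in blocks_meta:
        if b.kind == "categorical":
            cats = b.categories
            if cats is None:
                cats = [
                    _parse_column(c)[1]
                    for c in columns
                    if _parse_column(c)[0] == b.variable
                ]
            keys = [(_column_name(b, cat), cat) for cat in cats]
        else:
            key = "1" if b.kind == "binary" else b.variable
            keys = [(_column_name(b), key)]
        idx = [by_col[col] for col, _ in keys]
        terms = {
            cat: Coefficient(
                value=float(params[by_col[col]]),
                se=float(bse[by_col[col]]),
                p=float(pvalues[by_col[col]]),
                significant=bool(pvalues[by_col[col]] < 0.05),
            )
            for col, cat in keys
        }
        blocks.append(
            TermBlock(
                variable=b.variable,
                kind=b.kind,
                reference=b.reference,
                terms=terms,
                block_p=_block_wald(params, cov, names, idx),
            )
        )
    return FittedModel(
        outcome=outcome,
        family=family,
        intercept=float(params[0]),
        intercept_se=float(bse[0]),
        blocks=blocks,
        n_used=int(n_used),
        chain_stage=stage,
        response_column=response,
        cov=np.asarray(cov),
        param_names=names,
    )


def _with_const(design: pd.DataFrame) -> pd.DataFrame:
    X = design.copy()
    X.insert(0, "const", 1.0)
    return X


def fit_logistic(
    design: pd.DataFrame,
    response,
    spec: ModelSpec | None = None,
    weights=None,
) -> FittedModel:
    """Maximum-likelihood logistic fit (IRLS, log-likelihood tolerance 1e-8).

    Raises :class:`SeparationError` on a degenerate response or (quasi-)
    separation, :class:`ConvergenceError` after 100 iterations.
    """
    y = np.asarray(response, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ConfigurationError("logistic response must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError(
            f"all responses equal {y[0]:g}: model is degenerate"
        )
    X = _with_const(design)
    glm = sm.GLM(
        y,
        X,
        family=sm.families.Binomial(),
        freq_weights=None if weights is None else np.asarray(weights, float),
    )
    try:
        res = glm.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # statsmodels raises on hard perfect separation
        if "separat" in str(exc).lower() or "Perfect" in type(exc).__name__:
            raise SeparationError(str(exc)) from exc
        raise
    if not getattr(res, "converged", True):
        raise ConvergenceError(
            f"logistic fit for {getattr(spec, 'outcome', 'response')!r} did not "
            "converge in 100 iterations"
        )
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    if len(params) > 1 and (
        np.abs(params[1:]).max() > 20 or np.sqrt(np.diag(cov)).max() > 100
    ):
        raise SeparationError(
            "implausibly large coefficients/SEs: likely (quasi-)separation"
        )
    return _assemble(
        spec, design.columns, params, np.asarray(res.bse),
        np.asarray(res.pvalues), cov, LOGISTIC, res.nobs,
    )


def fit_linear(
    design: pd.DataFrame,
    response,
    spec: ModelSpec | None = None,
    weights=None,
) -> FittedModel:
    """Least-squares linear fit; raises on a rank-deficient design."""
    y = np.asarray(response, dtype=float)
    if not np.isfinite(y).all():
        raise ConfigurationError("linear response contains non-finite values")
    X = _with_const(design)
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, _, piv = _qr(arr, mode="economic", pivoting=True)
        collinear = [X.columns[i] for i in sorted(piv[rank:])]
        raise RankDeficiencyError(collinear)
    if weights is None:
        res = sm.OLS(y, X).fit()
    else:
        res = sm.WLS(y, X, weights=np.asarray(weights, float)).fit()
    return _assemble(
        spec, design.columns, np.asarray(res.params), np.asarray(res.bse),
        np.asarray(res.pvalues), np.asarray(res.cov_params()), LINEAR, res.nobs,
    )


def block_p_value(model: FittedModel, variable: str) -> float:
    """Wald chi-square p-value that every coefficient of the block is zero.

    df = number of non-reference categories (1 for binary/continuous).
    """
    block = model.block(variable)  # raises if not retained
    if model.cov is None or model.param_names is None:
        if block.block_p is None:
            raise ValueError(
                f"model {model.outcome!r} carries no covariance for block tests"
            )
        return block.block_p
    vb = VariableBlock(
        variable=block.variable, kind=block.kind,
        categories=list(block.terms) if block.kind == "categorical" else None,
        reference=block.reference,
    )
    if block.kind == "categorical":
        cols = [_column_name(vb, c) for c in block.terms]
    else:
        cols = [_column_name(vb)]
    by = {n: i for i, n in enumerate(model.param_names)}
    idx = [by[c] for c in cols]
    params = np.zeros(len(model.param_names))
    for name, i in by.items():
        var, cat = _parse_column(name)
        if name == "const":
            params[i] = model.intercept
        else:
            b = model.block(var)
            key = cat if b.kind == "categorical" else ("1" if b.kind == "binary" else var)
            params[i] = b.terms[key].value
    return _block_wald(params, model.cov, model.param_names, idx)


# ---------------------------------------------------------------------------
# backward selection and the model chain
# ---------------------------------------------------------------------------

def _fit_spec(survey, spec, weights_column=None):
    keep = [weights_column] if weights_column else None
    X, y, extras = encode_design(survey, spec, keep_columns=keep)
    w = None if extras is None else extras[weights_column].to_numpy(float)
    fitter = fit_logistic if spec.family == LOGISTIC else fit_linear
    return fitter(X, y, spec=spec, weights=w)


def _intercept_only(survey, spec, history):
    y = survey[spec.response_column].dropna()
    if spec.family == LOGISTIC:
        p = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        intercept = float(np.log(p / (1 - p)))
        se = float(np.sqrt(1.0 / (len(y) * p * (1 - p))))
    else:
        intercept = float(y.mean())
        se = float(y.std(ddof=1) / np.sqrt(len(y)))
    return FittedModel(
        outcome=spec.outcome, family=spec.family, intercept=intercept,
        intercept_se=se, blocks=[], dropped=history, n_used=len(y),
        chain_stage=spec.chain_stage, response_column=spec.response_column,
    )


def backward_select(
    survey: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
    weights_column: str | None = None,
) -> FittedModel:
    """Block-wise backward selection.

    Repeatedly fit, test each retained block (Wald chi-square), and remove
    the block with the largest p-value whenever it exceeds ``alpha``; stop
    once every retained block is significant (or none remain). Ties in p are
    broken by earliest block order. The removal history is recorded on the
    returned model.
    """
    if not spec.blocks:
        raise ConfigurationError("spec has no candidate blocks")
    blocks = list(spec.blocks)
    history: list[dict] = []
    step = 0
    while blocks:
        cur = ModelSpec(
            outcome=spec.outcome, family=spec.family, blocks=blocks,
            response_column=spec.response_column, chain_stage=spec.chain_stage,
        )
        model = _fit_spec(survey, cur, weights_column)
        ps = np.array([model.block(b.variable).block_p for b in blocks])
        worst = int(np.argmax(ps))  # argmax takes the earliest on exact ties
        if ps[worst] > alpha:
            step += 1
            history.append(
                {"variable": blocks[worst].variable,
                 "block_p": float(ps[worst]), "step": step,
                 "reason": f"block p > {alpha:g}"}
            )
            logger.info(
                "backward_select(%s): dropping %s (p=%.4g)",
                spec.outcome, blocks[worst].variable, ps[worst],
            )
            blocks = blocks[:worst] + blocks[worst + 1:]
            continue
        model.dropped = history
        return model
    logger.warning(
        "backward_select(%s): all blocks removed; intercept-only model",
        spec.outcome,
    )
    return _intercept_only(survey, spec, history)


def fit_chain(
    survey: pd.DataFrame,
    specs: list[ModelSpec],
    alpha: float = 0.05,
    weights_column: str | None = None,
) -> list[FittedModel]:
    """Fit the ordered outcome chain, each stage by backward selection.

    Each spec may use demographics and *earlier* stages' observed outcomes as
    candidate predictors; naming a same- or later-stage outcome raises
    :class:`ChainOrderError`. Observed (not predicted) upstream outcomes are
    used during fitting.
    """
    responses = [s.response_column for s in specs]
    for i, spec in enumerate(specs):
        later = set(responses[i:])
        bad = [b.variable for b in spec.blocks if b.variable in later]
        if bad:
            raise ChainOrderError(
                f"spec {spec.outcome!r} (stage {i}) uses same/later-stage "
                f"outcomes {bad} as predictors"
            )
    models = []
    for i, spec in enumerate(specs):
        spec.chain_stage = i
        m = backward_select(survey, spec, alpha=alpha, weights_column=weights_column)
        m.chain_stage = i
        models.append(m)
    return models


# ---------------------------------------------------------------------------
# published coefficient table
# ---------------------------------------------------------------------------

@dataclass
class CoefficientTableFixture:
    """Packaged transcription of the published coefficient table.

    Four models (exercise, fruit/vegetable, BMI, diabetes) with main-effect
    coefficients, significance flags, dropped-block (NS) and chain-excluded
    (N/A) markers, and the reference groups. Intercepts were not published.
    """

    raw: dict

    @property
    def outcomes(self) -> list[str]:
        return list(self.raw["models"])

    @property
    def reference_groups(self) -> dict:
        return self.raw["reference_groups"]

    def model_entry(self, outcome: str) -> dict:
        if outcome not in self.raw["models"]:
            raise ConfigurationError(
                f"unknown outcome {outcome!r}; expected one of {self.outcomes}"
            )
        return self.raw["models"][outcome]


def load_table1_fixture() -> CoefficientTableFixture:
    path = resources.files("tractrisk.data").joinpath("table1_coefficients.json")
    return CoefficientTableFixture(raw=json.loads(path.read_text()))


def model_from_table(
    fixture: CoefficientTableFixture, outcome: str
) -> FittedModel:
    """Build a ready-made :class:`FittedModel` from the published table.

    The intercept is set to 0 and flagged uncalibrated (the source prints no
    intercepts); NS and N/A variables are absent from the term blocks and
    recorded in ``dropped``.
    """
    entry = fixture.model_entry(outcome)
    blocks = []
    for b in entry["blocks"]:
        terms = {
            cat: Coefficient(value=float(t["coef"]),
                             significant=t.get("significant"))
            for cat, t in b["terms"].items()
        }
        blocks.append(
            TermBlock(
                variable=b["variable"], kind=b["kind"],
                reference=b.get("reference"), terms=terms,
            )
        )
    dropped = [
        {"variable": v, "reason": "published: not significant (NS)"}
        for v in entry.get("not_significant", [])
    ] + [
        {"variable": v, "reason": "published: not considered (N/A, chain order)"}
        for v in entry.get("not_applicable", [])
    ]
    return FittedModel(
        outcome=outcome,
        family=entry["family"],
        intercept=0.0,
        intercept_calibrated=False,
        blocks=blocks,
        dropped=dropped,
        chain_stage=CHAIN_ORDER.index(outcome) if outcome in CHAIN_ORDER else 0,
        n_used=fixture.raw.get("n_source"),
    )
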