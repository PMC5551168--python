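"""Tract-level summaries, citywide aggregation, evaluation, and map export.

Monte Carlo prevalence replicates are reduced to per-tract means, 2.5/97.5
percentile intervals (numpy linear interpolation) and coefficients of
variation (sample standard deviation over mean — the tract-level
uncertainty measure), then aggregated to population-weighted citywide
estimates. Internal consistency against external survey estimates is judged
by 95% confidence-interval overlap (closed intervals; a shared endpoint
counts). Map-ready output is a GeoJSON FeatureCollection per outcome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .prediction import MonteCarloResult

logger = logging.getLogger(__name__)


@dataclass
class TractOutcomeSummary:
    tract_id: str
    outcome: str
    mean: float
    lower: float
    upper: float
    cv: float
    n_individuals: int

    def __post_init__(self):
        if not (self.lower <= self.mean + 1e-12 and self.mean <= self.upper + 1e-12):
            raise ConfigurationError(
                f"interval [{self.lower}, {self.upper}] does not bracket the "
                f"mean {self.mean}"
            )


@dataclass
class ReferenceEstimate:
    """A prevalence estimate with a 95% CI, in percent."""

    label: str
    outcome: str
    prevalence: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self):
        if not (self.ci_lower <= self.prevalence <= self.ci_upper):
            raise ConfigurationError(
                f"malformed interval for {self.label}/{self.outcome}: "
                f"{self.ci_lower} <= {self.prevalence} <= {self.ci_upper} fails"
            )


def load_table2_reference() -> list[ReferenceEstimate]:
    """Packaged published prevalence estimates (synthetic, city, state)."""
    path = resources.files("tractrisk.data").joinpath("table2_reference.json")
    raw = json.loads(path.read_text())
    return [ReferenceEstimate(**e) for e in raw["estimates"]]


def _cv(reps: np.ndarray) -> float:
    sd = float(np.std(reps, ddof=1))
    mean = float(np.mean(reps))
    if sd == 0.0:
        return 0.0
    if mean == 0.0:
        return 0.0
    return sd / mean


def summarize_tracts(mc: list[MonteCarloResult]) -> list[TractOutcomeSummary]:
    """Mean, 2.5/97.5 percentile interval, and CV per tract x outcome."""
    out = []
    for r in mc:
        if len(r.reps) < 2:
            raise ConfigurationError(
                f"tract {r.tract_id} outcome {r.outcome}: need >= 2 replicates"
            )
        lo, hi = np.percentile(r.reps, [2.5, 97.5])  # linear interpolation
        out.append(TractOutcomeSummary(
            tract_id=r.tract_id, outcome=r.outcome,
            mean=float(np.mean(r.reps)), lower=float(lo), upper=float(hi),
            cv=_cv(r.reps), n_individuals=r.n_individuals,
        ))
    return out


def citywide_summary(
    mc: list[MonteCarloResult],
    population_sizes: dict[str, int] | None = None,
) -> list[TractOutcomeSummary]:
    """Population-weighted citywide prevalence per replicate, then summarized.

    Weighting each tract's replicate by its population conserves the overall
    prevalence: the citywide value per replicate equals the prevalence that
    would be computed from the pooled individuals.
    """
    by_outcome: dict[str, list[MonteCarloResult]] = {}
    for r in mc:
        by_outcome.setdefault(r.outcome, []).append(r)
    out = []
    for outcome, results in by_outcome.items():
        sizes = []
        for r in results:
            if population_sizes is not None:
                if r.tract_id not in population_sizes:
                    raise ConfigurationError(
                        f"no population size for tract {r.tract_id}"
                    )
                sizes.append(population_sizes[r.tract_id])
            else:
                sizes.append(r.n_individuals)
        n_reps = {len(r.reps) for r in results}
        if len(n_reps) != 1:
            raise ConfigurationError("replicate counts differ across tracts")
        w = np.asarray(sizes, dtype=float)
        w = w / w.sum()
        reps = np.einsum("t,tr->r", w, np.vstack([r.reps for r in results]))
        lo, hi = np.percentile(reps, [2.5, 97.5])
        out.append(TractOutcomeSummary(
            tract_id="citywide", outcome=outcome,
            mean=float(np.mean(reps)), lower=float(lo), upper=float(hi),
            cv=_cv(reps), n_individuals=int(sum(sizes)),
        ))
    return out


def ci_overlap(a: ReferenceEstimate, b: ReferenceEstimate) -> bool:
    """True iff the closed intervals intersect (shared endpoint overlaps)."""
    return a.ci_lower <= b.ci_upper and b.ci_lower <= a.ci_upper


def rank_tracts(
    summaries: list[TractOutcomeSummary],
    outcome: str,
    direction: str = "ascending",
    priority_tracts: set[str] | None = None,
) -> pd.DataFrame:
    """Tracts ordered by mean prevalence (ties broken by tract id).

    With a priority set, each priority tract is flagged above/below the
    citywide (population-weighted) mean.
    """
    subset = [s for s in summaries if s.outcome == outcome
              and s.tract_id != "citywide"]
    if not subset:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    if direction not in ("ascending", "descending"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    rows = pd.DataFrame({
        "tract_id": [s.tract_id for s in subset],
        "mean": [s.mean for s in subset],
        "lower": [s.lower for s in subset],
        "upper": [s.upper for s in subset],
        "cv": [s.cv for s in subset],
        "n_individuals": [s.n_individuals for s in subset],
    })
    rows = rows.sort_values(
        ["mean", "tract_id"], ascending=[direction == "ascending", True]
    ).reset_index(drop=True)
    if priority_tracts is not None:
        w = rows["n_individuals"].to_numpy(float)
        citywide = float((rows["mean"].to_numpy() * w).sum() / w.sum())
        rows["priority"] = rows["tract_id"].isin(priority_tracts)
        rows["vs_citywide_mean"] = np.where(
            rows["mean"] > citywide, "above citywide mean",
            np.where(rows["mean"] < citywide, "below citywide mean",
                     "at citywide mean"),
        )
    return rows


def export_geo(
    summaries: list[TractOutcomeSummary],
    geometries: dict[str, dict],
    outcome: str,
) -> tuple[dict, list[str]]:
    """GeoJSON FeatureCollection for one outcome.

    ``geometries`` maps tract id to a GeoJSON geometry dict. Summarized
    tracts lacking a geometry are reported in the returned warning list and
    excluded from the collection.
    """
    from shapely.geometry import shape  # geometry validity check

    subset = [s for s in summaries if s.outcome == outcome
              and s.tract_id != "citywide"]
    if not subset:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    features = []
    warnings = []
    for s in subset:
        geom = geometries.get(s.tract_id)
        if geom is None:
            warnings.append(f"tract {s.tract_id}: no geometry; feature omitted")
            continue
        shape(geom)  # raises on malformed geometry
        features.append({
            "type": "Feature",
            "geometry": geom,
            "properties": {
                "tract_id": s.tract_id,
                "outcome": s.outcome,
                "prevalence": s.mean,
                "ci_lower": s.lower,
                "ci_upper": s.upper,
                "cv": s.cv,
                "n_individuals": s.n_individuals,
            },
        })
    for w in warnings:
        logger.warning("export_geo: %s", w)
    return {"type": "FeatureCollection", "features": features}, warnings


def grid_geometries(tract_ids: list[str], cols: int = 8,
                    cell: float = 0.01) -> dict[str, dict]:
    """Square-grid stand-in polygons for demos and tests (synthetic layout,
    not real tract boundaries)."""
    out = {}
    for i, tid in enumerate(sorted(tract_ids)):
        r, c = divmod(i, cols)
        x0, y0 = c * cell, -r * cell
        out[tid] = {
            "type": "Polygon",
            "coordinates": [[
                [x0, y0], [x0 + cell, y0], [x0 + cell, y0 - cell],
                [x0, y0 - cell], [x0, y0],
            ]],
        }
    return out


def summaries_to_frame(summaries: list[TractOutcomeSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "tract_id": s.tract_id, "outcome": s.outcome, "mean": s.mean,
        "lower": s.lower, "upper": s.upper, "cv": s.cv,
        "n_individuals": s.n_individuals,
    } for s in summaries])


def comparison_report(
    citywide: list[TractOutcomeSummary],
    references: list[ReferenceEstimate],
    against: str = "city_brfss",
) -> pd.DataFrame:
    """Synthetic citywide estimates vs published references, with overlap
    verdicts; prevalences converted to percent."""
    refs = {(r.label, r.outcome): r for r in references}
    rows = []
    for s in citywide:
        key = (against, s.outcome)
        if key not in refs:
            continue
        ours = ReferenceEstimate(
            label="this_run", outcome=s.outcome,
            prevalence=100 * s.mean, ci_lower=100 * s.lower,
            ci_upper=100 * s.upper,
        )
        ref = refs[key]
        rows.append({
            "outcome": s.outcome,
            "synthetic_prevalence_pct": ours.prevalence,
            "synthetic_ci": f"({ours.ci_lower:.1f}-{ours.ci_upper:.1f})",
            "reference": against,
            "reference_prevalence_pct": ref.prevalence,
            "reference_ci": f"({ref.ci_lower}-{ref.ci_upper})",
            "ci_overlap": ci_overlap(ours, ref),
        })
    return pd.DataFrame(rows)
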