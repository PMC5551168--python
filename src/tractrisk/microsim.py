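"""Tract-level population synthesis by combinatorial simulated annealing.

Given (a) an individual/household microdata pool with no tract labels and
(b) per-tract constraint tables (small-area target counts for categorical
cross-classifications, at individual or household level), the annealer
selects, for each tract, a multiset of microdata households — sampling with
replacement, members always travel together — that minimizes the total
absolute error (TAE)

    TAE = sum over tables  w_table * sum over cells |tabulated - target|,

the standard spatial-microsimulation fitness. Moves replace one selected
household with a uniformly drawn pool household; worsening moves are
accepted with the Metropolis probability exp(-delta/T) under geometric
cooling, which lets the search escape the local optima that plain
hill-climbing gets stuck in.

Microdata are handled as a flat DataFrame, one row per individual, with
household-level fields (household_id, head_age_band, income_band, tenure)
repeated on each member row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TractRiskError
from .rngtools import derive_seed

logger = logging.getLogger(__name__)

INDIVIDUAL = "individual"
HOUSEHOLD = "household"


@dataclass(frozen=True)
class ConstraintDef:
    """One cross-classification to constrain, at a stated level."""

    variables: tuple[str, ...]
    level: str

    def __post_init__(self):
        if self.level not in (INDIVIDUAL, HOUSEHOLD):
            raise ConfigurationError(f"unknown constraint level {self.level!r}")

    @property
    def name(self) -> str:
        return "x".join(self.variables)


#: the default 13 constraint tables: eight individual-level (ancestry, sex,
#: age, education and their sex/age/education crosses) and five
#: household-level (head-of-household age, income, tenure and crosses).
DEFAULT_CONSTRAINT_DEFS: list[ConstraintDef] = [
    ConstraintDef(("ancestry",), INDIVIDUAL),
    ConstraintDef(("sex",), INDIVIDUAL),
    ConstraintDef(("age_band",), INDIVIDUAL),
    ConstraintDef(("education",), INDIVIDUAL),
    ConstraintDef(("sex", "age_band"), INDIVIDUAL),
    ConstraintDef(("sex", "education"), INDIVIDUAL),
    ConstraintDef(("age_band", "education"), INDIVIDUAL),
    ConstraintDef(("sex", "age_band", "education"), INDIVIDUAL),
    ConstraintDef(("head_age_band",), HOUSEHOLD),
    ConstraintDef(("income_band",), HOUSEHOLD),
    ConstraintDef(("tenure",), HOUSEHOLD),
    ConstraintDef(("tenure", "head_age_band"), HOUSEHOLD),
    ConstraintDef(("income_band", "head_age_band"), HOUSEHOLD),
]


@dataclass
class ConstraintTable:
    """Target counts for one tract and one cross-classification.

    ``cells`` maps category tuples (full cross product of the declared
    category spaces, zeros included) to nonnegative target counts.
    """

    tract_id: str
    table_name: str
    level: str
    variables: tuple[str, ...]
    cells: dict[tuple, float]

    def __post_init__(self):
        for key, v in self.cells.items():
            if v < 0:
                raise ConfigurationError(
                    f"negative target {v} in table {self.table_name} "
                    f"tract {self.tract_id} cell {key}"
                )

    @property
    def total(self) -> float:
        return float(sum(self.cells.values()))


def tabulate_table(
    frame: pd.DataFrame,
    cdef: ConstraintDef,
    spaces: dict[str, list[str]],
    tract_id: str,
) -> ConstraintTable:
    """Exact tabulation of one constraint table from an individual-row frame.

    Household-level tables count each household once (via its first row).
    """
    for v in cdef.variables:
        if v not in frame.columns:
            raise ConfigurationError(f"unknown constraint variable {v!r}")
        if v not in spaces:
            raise ConfigurationError(f"no category space declared for {v!r}")
    if cdef.level == HOUSEHOLD:
        frame = frame.drop_duplicates(subset="household_id")
    counts: dict[tuple, float] = {}
    spaces_v = [spaces[v] for v in cdef.variables]
    # full cross product, zeros included
    keys = [()]
    for cats in spaces_v:
        keys = [k + (c,) for k in keys for c in cats]
    for k in keys:
        counts[k] = 0.0
    if len(frame):
        grouped = frame.groupby(list(cdef.variables), observed=True).size()
        for k, n in grouped.items():
            key = k if isinstance(k, tuple) else (k,)
            if key not in counts:
                raise ConfigurationError(
                    f"category combination {key} of {cdef.name} outside the "
                    "declared category spaces"
                )
            counts[key] = float(n)
    return ConstraintTable(
        tract_id=tract_id, table_name=cdef.name, level=cdef.level,
        variables=cdef.variables, cells=counts,
    )


# ---------------------------------------------------------------------------
# assignments and fitness
# ---------------------------------------------------------------------------

@dataclass
class TractAssignment:
    """Multiset of microdata household ids selected for one tract."""

    tract_id: str
    selected: list  # household ids, repetitions allowed


@dataclass
class SyntheticPopulation:
    assignments: list[TractAssignment]

    def materialize(self, microdata: pd.DataFrame) -> pd.DataFrame:
        """Clone selected households into a tract-labeled individual frame.

        Fresh ``synthetic_id``s are assigned; the source household id is kept
        in ``source_household_id``.
        """
        groups = {hid: g for hid, g in microdata.groupby("household_id", sort=False)}
        pieces = []
        syn_hh = 0
        for assignment in self.assignments:
            for hid in assignment.selected:
                if hid not in groups:
                    raise ConfigurationError(
                        f"household {hid!r} not present in microdata"
                    )
                g = groups[hid].copy()
                g["tract_id"] = assignment.tract_id
                g["source_household_id"] = hid
                g["household_id"] = f"syn_{syn_hh}"
                syn_hh += 1
                pieces.append(g)
        if not pieces:
            return microdata.iloc[0:0].assign(
                tract_id=None, source_household_id=None, synthetic_id=None
            )
        out = pd.concat(pieces, ignore_index=True)
        out["synthetic_id"] = [f"s{i}" for i in range(len(out))]
        return out


@dataclass
class AnnealConfig:
    """Annealing schedule and reproducibility knobs.

    The initial temperature is auto-calibrated (from 200 probe moves) so the
    initial acceptance rate of worsening moves is about
    ``target_initial_acceptance``, unless ``initial_temperature`` is given.
    """

    initial_temperature: float | None = None
    target_initial_acceptance: float = 0.8
    cooling: float = 0.99
    proposals_per_temperature: int = 100
    max_proposals: int = 50_000
    stall_limit: int = 2_000
    n_restarts: int = 1
    rng_seed: int = 0
    table_weights: dict[str, float] | None = None

    def __post_init__(self):
        if not (0.0 < self.cooling < 1.0):
            raise ConfigurationError("cooling factor must be in (0, 1)")
        for name in ("proposals_per_temperature", "max_proposals",
                     "stall_limit", "n_restarts"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class FitDiagnostics:
    tract_id: str
    initial_tae: float
    best_tae: float
    relative_tae: float
    person_target: float
    n_proposals: int
    n_accepted: int
    initial_temperature: float
    final_temperature: float
    stop_reason: str
    tae_trace: list = field(default_factory=list)  # (proposal, best_tae)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposals if self.n_proposals else 0.0


class _Workspace:
    """Precomputed per-household contributions to every constraint cell."""

    def __init__(self, microdata, tables, table_weights=None):
        tracts = {t.tract_id for t in tables}
        if len(tracts) != 1:
            raise ConfigurationError(
                f"tables must share one tract, got {sorted(map(str, tracts))}"
            )
        if microdata.empty:
            raise ConfigurationError("microdata is empty")
        self.tract_id = tables[0].tract_id
        self.hh_ids = list(dict.fromkeys(microdata["household_id"]))
        hh_pos = {h: i for i, h in enumerate(self.hh_ids)}
        n_hh = len(self.hh_ids)
        hh_row = microdata["household_id"].map(hh_pos).to_numpy()

        n_cells = sum(len(t.cells) for t in tables)
        self.target = np.empty(n_cells)
        self.weight = np.empty(n_cells)
        self.M = np.zeros((n_hh, n_cells), dtype=np.int32)
        weights = table_weights or {}
        offset = 0
        for t in tables:
            keys = list(t.cells)
            cell_pos = {k: offset + i for i, k in enumerate(keys)}
            self.target[offset:offset + len(keys)] = [t.cells[k] for k in keys]
            self.weight[offset:offset + len(keys)] = weights.get(t.table_name, 1.0)
            sub = microdata
            rows = hh_row
            if t.level == HOUSEHOLD:
                first = ~microdata["household_id"].duplicated()
                sub = microdata[first]
                rows = hh_row[first.to_numpy()]
            vals = list(zip(*(sub[v] for v in t.variables)))
            for r, key in zip(rows, vals):
                if key not in cell_pos:
                    raise ConfigurationError(
                        f"microdata category combination {key} outside table "
                        f"{t.table_name}"
                    )
                self.M[r, cell_pos[key]] += 1
            offset += len(keys)

        sizes = microdata.groupby("household_id", sort=False).size()
        self.hh_size = sizes.reindex(self.hh_ids).to_numpy()
        # person target: sum of the sex table (every person appears in it);
        # fall back to the largest individual-level one-way table.
        sex = [t for t in tables if t.variables == ("sex",)]
        if sex:
            self.person_target = sex[0].total
        else:
            oneway = [t for t in tables if t.level == INDIVIDUAL and len(t.variables) == 1]
            self.person_target = max((t.total for t in oneway), default=0.0)
        self.target_total = float(self.target.sum())

    def tae(self, counts: np.ndarray) -> float:
        return float((self.weight * np.abs(counts - self.target)).sum())

    def counts_of(self, selection: list[int]) -> np.ndarray:
        s = np.bincount(selection, minlength=self.M.shape[0]).astype(np.int64) \
            if selection else np.zeros(self.M.shape[0], dtype=np.int64)
        return s @ self.M


def total_absolute_error(
    assignment: TractAssignment,
    microdata: pd.DataFrame,
    tables: list[ConstraintTable],
    table_weights: dict[str, float] | None = None,
) -> float:
    """Weighted sum of absolute cell errors; zero iff every cell matches."""
    ws = _Workspace(microdata, tables, table_weights)
    pos = {h: i for i, h in enumerate(ws.hh_ids)}
    try:
        sel = [pos[h] for h in assignment.selected]
    except KeyError as exc:
        raise ConfigurationError(f"selected household {exc} not in microdata")
    return ws.tae(ws.counts_of(sel).astype(float))


def _initial_selection(ws: _Workspace, rng: np.random.Generator) -> list[int]:
    if ws.person_target <= 0:
        logger.warning(
            "tract %s: person target is 0; empty assignment", ws.tract_id
        )
        return []
    sel: list[int] = []
    persons = 0
    n_hh = len(ws.hh_ids)
    while persons < ws.person_target:
        h = int(rng.integers(n_hh))
        sel.append(h)
        persons += int(ws.hh_size[h])
    return sel


def initial_assignment(
    microdata: pd.DataFrame,
    tables: list[ConstraintTable],
    rng_seed: int,
) -> TractAssignment:
    """Uniform-with-replacement draw until the tract's person target is met."""
    ws = _Workspace(microdata, tables)
    sel = _initial_selection(ws, np.random.default_rng(rng_seed))
    return TractAssignment(
        tract_id=ws.tract_id, selected=[ws.hh_ids[i] for i in sel]
    )


def acceptance_probability(delta: float, temperature: float) -> float:
    """Metropolis rule: 1 for non-worsening moves, exp(-delta/T) otherwise."""
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    if delta <= 0:
        return 1.0
    return math.exp(-delta / temperature)


def _calibrate_t0(ws, sel, counts, cur_tae, rng, config) -> float:
    if config.initial_temperature is not None:
        return float(config.initial_temperature)
    n_hh = ws.M.shape[0]
    worsening = []
    for _ in range(200):
        pos = int(rng.integers(len(sel)))
        new = int(rng.integers(n_hh))
        d = ws.tae(counts - ws.M[sel[pos]] + ws.M[new]) - cur_tae
        if d > 0:
            worsening.append(d)
    if not worsening:
        return 1.0
    return float(-np.mean(worsening) / math.log(config.target_initial_acceptance))


def _anneal_once(ws: _Workspace, config: AnnealConfig,
                 rng: np.random.Generator):
    sel = _initial_selection(ws, rng)
    counts = ws.counts_of(sel).astype(float)
    cur_tae = ws.tae(counts)
    if not np.isfinite(cur_tae):
        raise TractRiskError("non-finite TAE")
    initial_tae = cur_tae
    best_tae = cur_tae
    best_sel = list(sel)
    t0 = _calibrate_t0(ws, sel, counts, cur_tae, rng, config)
    temp = t0
    n_hh = ws.M.shape[0]
    n_acc = 0
    stall = 0
    trace = [(0, best_tae)]
    n = 0
    reason = "max proposals"
    while n < config.max_proposals:
        if best_tae == 0.0:
            reason = "exact fit"
            break
        if stall >= config.stall_limit:
            reason = "stalled"
            break
        n += 1
        pos = int(rng.integers(len(sel)))
        new = int(rng.integers(n_hh))
        new_counts = counts - ws.M[sel[pos]] + ws.M[new]
        new_tae = ws.tae(new_counts)
        delta = new_tae - cur_tae
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            sel[pos] = new
            counts = new_counts
            cur_tae = new_tae
            n_acc += 1
            # strict improvement resets the stall clock; plateau moves
            # (delta == 0) are neutral — they are the exploration mechanism —
            # and only accepted-worsening moves count against it
            if delta < 0:
                stall = 0
            elif delta > 0:
                stall += 1
            if cur_tae < best_tae:
                best_tae = cur_tae
                best_sel = list(sel)
        else:
            stall += 1
        if n % config.proposals_per_temperature == 0:
            temp *= config.cooling
        if n % 100 == 0:
            trace.append((n, best_tae))
    trace.append((n, best_tae))
    diag = FitDiagnostics(
        tract_id=ws.tract_id, initial_tae=initial_tae, best_tae=best_tae,
        relative_tae=best_tae / ws.target_total if ws.target_total else 0.0,
        person_target=ws.person_target, n_proposals=n, n_accepted=n_acc,
        initial_temperature=t0, final_temperature=temp,
        stop_reason=reason, tae_trace=trace,
    )
    return best_sel, diag


def anneal_tract(
    microdata: pd.DataFrame,
    tables: list[ConstraintTable],
    config: AnnealConfig,
) -> tuple[TractAssignment, FitDiagnostics]:
    """Optimize one tract's household multiset by simulated annealing.

    A proposal replaces one uniformly chosen selected household with one
    uniformly chosen pool household; acceptance follows the Metropolis rule
    at the current temperature, with geometric cooling every
    ``proposals_per_temperature`` proposals. With ``n_restarts > 1`` the
    schedule is run from independent derived substreams and the best restart
    kept. The best-so-far assignment ever visited is returned, so the
    reported TAE is non-increasing in the number of proposals. Fully
    reproducible from ``config.rng_seed``.
    """
    ws = _Workspace(microdata, tables, config.table_weights)
    if ws.person_target <= 0:
        logger.warning(
            "tract %s: person target is 0; empty assignment", ws.tract_id
        )
        zero_tae = ws.tae(np.zeros_like(ws.target))
        diag = FitDiagnostics(
            tract_id=ws.tract_id, initial_tae=zero_tae, best_tae=zero_tae,
            relative_tae=1.0 if ws.target_total else 0.0,
            person_target=0.0, n_proposals=0, n_accepted=0,
            initial_temperature=0.0, final_temperature=0.0,
            stop_reason="empty person target",
        )
        return TractAssignment(tract_id=ws.tract_id, selected=[]), diag
    best_sel = None
    best_diag = None
    total_proposals = 0
    for r in range(config.n_restarts):
        rng = np.random.default_rng(
            config.rng_seed if config.n_restarts == 1
            else derive_seed(config.rng_seed, "restart", r)
        )
        sel, diag = _anneal_once(ws, config, rng)
        total_proposals += diag.n_proposals
        if best_diag is None or diag.best_tae < best_diag.best_tae:
            best_sel, best_diag = sel, diag
        if best_diag.best_tae == 0.0:
            break
    best_diag.n_proposals = total_proposals
    assignment = TractAssignment(
        tract_id=ws.tract_id, selected=[ws.hh_ids[i] for i in best_sel]
    )
    return assignment, best_diag


def build_population(
    microdata: pd.DataFrame,
    all_tables: list[ConstraintTable],
    config: AnnealConfig,
) -> tuple[SyntheticPopulation, dict]:
    """Run the annealer independently for every tract.

    Per-tract seeds are derived from ``config.rng_seed`` and the tract id, so
    results do not depend on tract ordering. If any tract fails, no partial
    population is returned.
    """
    by_tract: dict = {}
    for t in all_tables:
        by_tract.setdefault(t.tract_id, []).append(t)
    if not by_tract:
        raise ConfigurationError("no constraint tables given")
    assignments = []
    report: dict = {"tracts": {}}
    failures = []
    for tract_id in sorted(by_tract, key=str):
        cfg = AnnealConfig(
            initial_temperature=config.initial_temperature,
            target_initial_acceptance=config.target_initial_acceptance,
            cooling=config.cooling,
            proposals_per_temperature=config.proposals_per_temperature,
            max_proposals=config.max_proposals,
            stall_limit=config.stall_limit,
            n_restarts=config.n_restarts,
            rng_seed=derive_seed(config.rng_seed, "anneal", tract_id),
            table_weights=config.table_weights,
        )
        try:
            assignment, diag = anneal_tract(microdata, by_tract[tract_id], cfg)
        except TractRiskError as exc:
            failures.append((tract_id, str(exc)))
            continue
        assignments.append(assignment)
        report["tracts"][str(tract_id)] = {
            "tae": diag.best_tae,
            "relative_tae": diag.relative_tae,
            "n_proposals": diag.n_proposals,
            "acceptance_rate": diag.acceptance_rate,
            "person_target": diag.person_target,
            "stop_reason": diag.stop_reason,
            "seed": cfg.rng_seed,
        }
    if failures:
        raise TractRiskError(f"annealing failed for tracts: {failures}")
    report["mean_relative_tae"] = float(
        np.mean([v["relative_tae"] for v in report["tracts"].values()])
    )
    return SyntheticPopulation(assignments=assignments), report


# ---------------------------------------------------------------------------
# long-format constraint CSV
# ---------------------------------------------------------------------------

def constraints_to_frame(tables: list[ConstraintTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for key, count in t.cells.items():
            rows.append({
                "tract_id": t.tract_id,
                "table_name": t.table_name,
                "level": t.level,
                "variables": "|".join(t.variables),
                "category_key": "|".join(map(str, key)),
                "count": count,
            })
    return pd.DataFrame(rows)


def constraints_from_frame(frame: pd.DataFrame) -> list[ConstraintTable]:
    tables = []
    for (tract, name), g in frame.groupby(["tract_id", "table_name"], sort=False):
        variables = tuple(g["variables"].iloc[0].split("|"))
        cells = {
            tuple(k.split("|")): float(c)
            for k, c in zip(g["category_key"], g["count"])
        }
        tables.append(ConstraintTable(
            tract_id=tract, table_name=name, level=g["level"].iloc[0],
            variables=variables, cells=cells,
        ))
    return tables
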