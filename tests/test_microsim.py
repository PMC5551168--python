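"""Annealer: fitness arithmetic, Metropolis rule, and optimization behavior."""

import math

import numpy as np
import pandas as pd
import pytest

from tractrisk.errors import ConfigurationError
from tractrisk.microsim import (
    AnnealConfig,
    ConstraintTable,
    TractAssignment,
    acceptance_probability,
    anneal_tract,
    build_population,
    initial_assignment,
    total_absolute_error,
)
from tractrisk.synthgen import sample_microdata, tabulate_constraints


def _sex_microdata(comps):
    """Households from strings like 'MF' (one row per member)."""
    rows = []
    for h, comp in enumerate(comps):
        for i, s in enumerate(comp):
            rows.append({"household_id": f"h{h}", "individual_id": f"h{h}p{i}",
                         "sex": "male" if s == "M" else "female",
                         "tenure": "own" if h % 2 else "rent"})
    return pd.DataFrame(rows)


def _sex_table(male, female, tract="t0"):
    return ConstraintTable(tract_id=tract, table_name="sex",
                           level="individual", variables=("sex",),
                           cells={("female",): float(female),
                                  ("male",): float(male)})


def _tenure_table(own, rent, tract="t0"):
    return ConstraintTable(tract_id=tract, table_name="tenure",
                           level="household", variables=("tenure",),
                           cells={("own",): float(own), ("rent",): float(rent)})


class TestTotalAbsoluteError:
    def test_exact_match_is_zero(self):
        micro = _sex_microdata(["M", "F"])
        a = TractAssignment("t0", ["h0", "h1"])
        assert total_absolute_error(a, micro, [_sex_table(1, 1)]) == 0.0

    def test_cellwise_arithmetic(self):
        micro = _sex_microdata(["M", "M", "M", "F"])
        a = TractAssignment("t0", ["h0", "h1", "h2", "h3"])
        # tabulated {M:3, F:1} vs target {M:2, F:2}
        assert total_absolute_error(a, micro, [_sex_table(2, 2)]) == 2.0

    def test_multi_table_sum_matches_cell_oracle(self):
        micro = _sex_microdata(["M", "F", "MF", "M"])
        a = TractAssignment("t0", ["h0", "h0", "h2"])
        tables = [_sex_table(3, 1), _tenure_table(1, 2)]
        # independent brute-force tabulation of the same selection
        chosen = micro[micro.household_id.isin([])]
        parts = [micro[micro.household_id == h] for h in a.selected]
        chosen = pd.concat(parts)
        males = (chosen.sex == "male").sum()
        females = (chosen.sex == "female").sum()
        owns = sum(p.tenure.iloc[0] == "own" for p in parts)
        rents = sum(p.tenure.iloc[0] == "rent" for p in parts)
        expect = (abs(males - 3) + abs(females - 1)
                  + abs(owns - 1) + abs(rents - 2))
        assert total_absolute_error(a, micro, tables) == expect

    def test_table_weights_scale_linearly(self):
        micro = _sex_microdata(["M", "M", "F"])
        a = TractAssignment("t0", ["h0", "h1", "h2"])
        base = total_absolute_error(a, micro, [_sex_table(0, 3)])
        doubled = total_absolute_error(a, micro, [_sex_table(0, 3)],
                                       table_weights={"sex": 2.0})
        assert doubled == 2 * base and base > 0


class TestAcceptanceProbability:
    def test_improving_move_always_accepted(self):
        assert acceptance_probability(-3.0, 0.01) == 1.0
        assert acceptance_probability(0.0, 5.0) == 1.0

    def test_matches_closed_form(self):
        assert acceptance_probability(2.0, 2.0) == pytest.approx(math.exp(-1))

    def test_cold_limit_vanishes(self):
        assert acceptance_probability(5.0, 0.001) < 1e-100

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ConfigurationError):
            acceptance_probability(1.0, 0.0)


class TestInitialAssignment:
    def test_zero_person_target_gives_empty_selection(self):
        micro = _sex_microdata(["M", "F"])
        a = initial_assignment(micro, [_sex_table(0, 0)], rng_seed=0)
        assert a.selected == []

    def test_unit_households_hit_target_exactly(self):
        micro = _sex_microdata(["M"] * 5)
        a = initial_assignment(micro, [_sex_table(30, 20)], rng_seed=1)
        assert len(a.selected) == 50

    def test_mixed_sizes_bounded_by_extremes(self):
        micro = _sex_microdata(["M", "MF", "MFF"])
        a = initial_assignment(micro, [_sex_table(60, 40)], rng_seed=2)
        assert 34 <= len(a.selected) <= 100


class TestAnnealTract:
    def test_same_seed_same_multiset(self):
        micro = _sex_microdata(["M", "F", "MF", "MM", "FF"])
        cfg = AnnealConfig(rng_seed=3, max_proposals=500)
        a1, _ = anneal_tract(micro, [_sex_table(4, 3)], cfg)
        a2, _ = anneal_tract(micro, [_sex_table(4, 3)], cfg)
        assert a1.selected == a2.selected

    def test_single_seed_attains_enumerated_minimum(self):
        import itertools

        comps = ["MM", "MF", "MF", "FF", "MM", "FF", "MF", "MM"]
        micro = _sex_microdata(comps)
        table = _sex_table(3, 2)

        def tae_of(sel):
            m = sum(comps[i].count("M") for i in sel)
            f = sum(comps[i].count("F") for i in sel)
            return abs(m - 3) + abs(f - 2)

        best = min(tae_of(s) for s in
                   itertools.combinations_with_replacement(range(8), 3))
        _, diag = anneal_tract(micro, [table],
                               AnnealConfig(rng_seed=0, max_proposals=2000))
        assert diag.best_tae == best

    def test_best_so_far_trace_is_monotone(self):
        micro = _sex_microdata(["M", "F", "MF", "MM", "FF", "MFF"])
        _, diag = anneal_tract(micro, [_sex_table(7, 5)],
                               AnnealConfig(rng_seed=4, max_proposals=3000))
        taes = [t for _, t in diag.tae_trace]
        assert all(a >= b for a, b in zip(taes, taes[1:]))

    def test_perfect_fit_reached_when_truth_pool_given(self, toy_city):
        tables = tabulate_constraints(toy_city)
        tract = toy_city.tract_ids[0]
        tabs = [t for t in tables if t.tract_id == tract]
        micro = sample_microdata(toy_city, 1.0, 1).to_frame()
        cfg = AnnealConfig(rng_seed=5, max_proposals=200_000,
                           stall_limit=20_000, n_restarts=6)
        assignment, diag = anneal_tract(micro, tabs, cfg)
        assert diag.best_tae == 0.0
        # zero TAE implies the materialized marginals equal the truth exactly
        assert total_absolute_error(assignment, micro, tabs) == 0.0


class TestBuildPopulation:
    def test_one_assignment_per_tract_and_determinism(self, toy_city):
        tables = tabulate_constraints(toy_city)
        micro = sample_microdata(toy_city, 1.0, 1).to_frame()
        cfg = AnnealConfig(rng_seed=6, max_proposals=3000, stall_limit=1000)
        synth1, report1 = build_population(micro, tables, cfg)
        synth2, _ = build_population(micro, tables, cfg)
        assert len(synth1.assignments) == 4
        assert [a.selected for a in synth1.assignments] == \
               [a.selected for a in synth2.assignments]
        assert set(report1["tracts"]) == set(toy_city.tract_ids)

    def test_materialized_counts_match_selection(self, toy_city):
        tables = tabulate_constraints(toy_city)
        micro = sample_microdata(toy_city, 1.0, 1).to_frame()
        cfg = AnnealConfig(rng_seed=6, max_proposals=2000, stall_limit=1000)
        synth, _ = build_population(micro, tables, cfg)
        mat = synth.materialize(micro)
        sizes = micro.groupby("household_id").size()
        for a in synth.assignments:
            expect = int(sum(sizes[h] for h in a.selected))
            assert (mat.tract_id == a.tract_id).sum() == expect

    def test_empty_tables_rejected(self):
        micro = _sex_microdata(["M"])
        with pytest.raises(ConfigurationError):
            build_population(micro, [], AnnealConfig())
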