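"""LP model behavior: the departure objective, the GHGE ladder and the
minimum-GHGE model, checked against brute-force and hand-solved oracles."""

import dataclasses
import itertools

import numpy as np
import pytest

from dietopt import (
    DietVector,
    FoodDatabase,
    LadderResult,
    build_model_constraints,
    evaluate_diet,
    minimize_departure,
    minimize_ghge,
    run_ladder,
    run_nutr,
)
from dietopt.constraints import ConstraintSet, LinearConstraint
from dietopt.optimizer import LadderError

from conftest import make_toy_db, make_toy_profile


def _energy_band(db, energy, rel=1e-3):
    coeffs = {it.item_id: it.nutrient_comp["energy_kcal"] for it in db.items}
    return [
        LinearConstraint("energy_min", coeffs, ">=", (1 - rel) * energy, "acceptability"),
        LinearConstraint("energy_max", coeffs, "<=", (1 + rel) * energy, "acceptability"),
    ]


def test_feasible_observed_diet_is_a_zero_departure_fixed_point():
    db = make_toy_db([{"item_id": "a", "energy": 1.0}, {"item_id": "b", "energy": 2.0}])
    profile = make_toy_profile(db, {"a": 100.0, "b": 50.0})
    cset = ConstraintSet(_energy_band(db, 200.0))
    sol = minimize_departure(db, profile, cset)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
    q = sol.quantities.to_array(db)
    assert q == pytest.approx(profile.observed.to_array(db), abs=1e-6)


def test_doubling_one_item_and_halving_another_costs_1_5():
    db = make_toy_db([{"item_id": "a"}, {"item_id": "b"}])
    profile = make_toy_profile(db, {"a": 100.0, "b": 100.0})
    cset = ConstraintSet([
        LinearConstraint("fix_a", {"a": 1.0}, "==", 200.0, "acceptability"),
        LinearConstraint("fix_b", {"b": 1.0}, "==", 50.0, "acceptability"),
    ])
    sol = minimize_departure(db, profile, cset)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(1.5, abs=1e-8)


def test_departure_equals_sum_of_relative_changes(default_db, women_ladder, women):
    profile, _ = women
    sol = women_ladder.nutr
    manual = sum(
        abs(sol.quantities.quantities[i] - q) / q
        for i, q in profile.observed.quantities.items() if q > 0
    )
    assert sol.departure == pytest.approx(manual, abs=1e-8)


def test_lp_matches_exhaustive_grid_search():
    """On a 4-item instance the LP optimum agrees with brute-force grid
    enumeration to within the grid resolution."""
    db = make_toy_db([
        {"item_id": "a", "energy": 1.0, "fiber": 0.030},
        {"item_id": "b", "energy": 2.0, "fiber": 0.000},
        {"item_id": "c", "energy": 1.5, "fiber": 0.010},
        {"item_id": "d", "energy": 0.5, "fiber": 0.005},
    ])
    obs = {"a": 100.0, "b": 100.0, "c": 100.0, "d": 100.0}
    profile = make_toy_profile(db, obs)
    cset = ConstraintSet(_energy_band(db, 500.0, rel=0.01))
    cset.add(LinearConstraint(
        "fiber_min", {"a": 0.030, "c": 0.010, "d": 0.005}, ">=", 6.0, "nutritional"))
    for iid in obs:
        cset.add(LinearConstraint(f"box:{iid}", {iid: 1.0}, "<=", 200.0, "acceptability"))

    sol = minimize_departure(db, profile, cset)
    assert sol.status == "optimal"

    step = 10.0
    grid = np.arange(0.0, 200.0 + step, step)
    Q = np.array(list(itertools.product(grid, repeat=4)))
    e = Q @ np.array([1.0, 2.0, 1.5, 0.5])
    fib = Q @ np.array([0.030, 0.0, 0.010, 0.005])
    feasible = (e >= 495.0) & (e <= 505.0) & (fib >= 6.0)
    assert feasible.any()
    f = np.abs(Q - 100.0).sum(axis=1) / 100.0
    grid_best = f[feasible].min()
    assert sol.objective_value <= grid_best + 1e-8
    # each item can be off-grid by at most step/2, costing step/(2*100) each
    assert grid_best - sol.objective_value <= 4 * step / 100.0


def _ladder_toy():
    """GHGE-minimal feasible diet sits at exactly 55% of observed GHGE:
    A (intensity 1) and B (intensity 0.1) are calorie-equivalent, energy is
    pinned at 100 kcal and B is capped at 50 g, so min GHGE = 50·1 + 50·0.1."""
    db = make_toy_db([
        {"item_id": "A", "energy": 1.0, "ghge": 1.0},
        {"item_id": "B", "energy": 1.0, "ghge": 0.1},
    ])
    profile = make_toy_profile(db, {"A": 100.0, "B": 0.0})
    cset = ConstraintSet(
        _energy_band(db, 100.0, rel=1e-6)
        + [LinearConstraint("box_B", {"B": 1.0}, "<=", 50.0, "acceptability")],
        metadata={"ghge_obs_gco2eq": 100.0},
    )
    return db, profile, cset


def test_ladder_on_known_ghge_floor():
    db, profile, cset = _ladder_toy()
    res = run_ladder(db, profile, base_cset=cset)
    feasible_rhos = [round(rho, 2) for rho, s in res.feasible_steps]
    assert feasible_rhos == [0.0, 0.1, 0.2, 0.3, 0.4]
    assert res.max_step == 4
    rho_last, last = res.steps[-1]
    assert rho_last == pytest.approx(0.5)
    assert last.status == "infeasible"
    assert res.mini.achieved.ghge_gco2eq == pytest.approx(55.0, rel=1e-4)
    assert res.max_reduction_fraction == pytest.approx(0.45, abs=1e-4)


def test_ladder_objective_nondecreasing_and_mini_is_floor(women_ladder):
    departures = [s.departure for _, s in women_ladder.feasible_steps]
    assert all(b >= a - 1e-7 for a, b in zip(departures, departures[1:]))
    ghges = [s.achieved.ghge_gco2eq for _, s in women_ladder.feasible_steps]
    assert all(women_ladder.mini.achieved.ghge_gco2eq <= g + 1e-6 for g in ghges)
    assert 0.0 <= women_ladder.max_reduction_fraction < 1.0
    # the mini optimum is at least as deep as the last feasible step
    assert women_ladder.max_reduction_fraction >= 0.1 * women_ladder.max_step - 1e-9


def test_ladder_step_validation(default_db, women):
    profile, _ = women
    with pytest.raises(ValueError):
        run_ladder(default_db, profile, step=0.0)


def test_infeasible_constraints_reported_not_raised():
    db = make_toy_db([{"item_id": "a"}])
    profile = make_toy_profile(db, {"a": 100.0})
    cset = ConstraintSet([
        LinearConstraint("lo", {"a": 1.0}, ">=", 10.0, "acceptability"),
        LinearConstraint("hi", {"a": 1.0}, "<=", 5.0, "acceptability"),
    ])
    sol = minimize_departure(db, profile, cset)
    assert sol.status == "infeasible"
    assert sol.quantities is None
    with pytest.raises(LadderError):
        run_ladder(db, profile, base_cset=ConstraintSet(
            list(cset), {"ghge_obs_gco2eq": 100.0}))


def test_nutritional_adequacy_can_increase_ghge():
    """When the only fiber source is GHGE-intense, meeting the fiber bound
    forces emissions above the observed level."""
    db = make_toy_db([
        {"item_id": "sugar", "energy": 1.0, "ghge": 0.1, "fiber": 0.0},
        {"item_id": "bran", "energy": 1.0, "ghge": 5.0, "fiber": 0.10},
    ])
    profile = make_toy_profile(db, {"sugar": 100.0, "bran": 0.0})
    cset = ConstraintSet(
        _energy_band(db, 100.0)
        + [LinearConstraint("fiber_min", {"bran": 0.10}, ">=", 5.0, "nutritional")]
    )
    sol = minimize_departure(db, profile, cset, model_label="NUTR")
    assert sol.status == "optimal"
    ghge_obs = evaluate_diet(db, profile.observed).ghge_gco2eq
    assert sol.achieved.ghge_gco2eq > ghge_obs


def test_minimize_ghge_lexicographic_tiebreak(default_db, women):
    profile, _ = women
    off = minimize_ghge(default_db, profile, lexicographic=False)
    on = minimize_ghge(default_db, profile, lexicographic=True)
    assert on.achieved.ghge_gco2eq == pytest.approx(
        off.achieved.ghge_gco2eq, rel=1e-6)
    assert on.departure <= off.departure + 1e-6


def test_minimum_ghge_diet_matches_hand_computed_vertex():
    """3-item toy: energy pinned at 100, C capped at 20 g; the GHGE-optimal
    vertex fills C to its cap, then B, leaving A at zero."""
    db = make_toy_db([
        {"item_id": "A", "energy": 1.0, "ghge": 2.0},
        {"item_id": "B", "energy": 1.0, "ghge": 1.0},
        {"item_id": "C", "energy": 1.0, "ghge": 0.5},
    ])
    profile = make_toy_profile(db, {"A": 80.0, "B": 10.0, "C": 10.0})
    cset = ConstraintSet(
        _energy_band(db, 100.0, rel=1e-9)
        + [LinearConstraint("box_C", {"C": 1.0}, "<=", 20.0, "acceptability")]
    )
    sol = minimize_ghge(db, profile, cset=cset)
    assert sol.status == "optimal"
    # vertex: C = 20, B = 80, A = 0 -> GHGE = 20*0.5 + 80*1 = 90
    assert sol.objective_value == pytest.approx(90.0, rel=1e-6)
    q = sol.quantities.quantities
    assert q["C"] == pytest.approx(20.0, abs=1e-6)
    assert q["A"] == pytest.approx(0.0, abs=1e-6)


def test_ghge_scale_invariance(default_db, women):
    profile, _ = women
    scaled_items = [
        dataclasses.replace(it, ghge_intensity=3.0 * it.ghge_intensity)
        for it in default_db.items
    ]
    db3 = FoodDatabase(scaled_items)
    base = run_ladder(default_db, profile)
    scaled = run_ladder(db3, profile)
    assert scaled.nutr.objective_value == pytest.approx(
        base.nutr.objective_value, rel=1e-9)
    assert scaled.max_step == base.max_step
    for (_, a), (_, b) in zip(base.feasible_steps, scaled.feasible_steps):
        assert b.achieved.ghge_gco2eq == pytest.approx(
            3.0 * a.achieved.ghge_gco2eq, rel=1e-6)


def test_objective_deterministic_across_runs(default_db, women):
    profile, _ = women
    a = run_nutr(default_db, profile)
    b = run_nutr(default_db, profile)
    assert a.objective_value == b.objective_value
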