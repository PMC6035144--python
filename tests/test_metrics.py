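"""Change diagnostics: departure statistics, the within/between-group
substitution split, item-change classes and group contributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietopt import (
    DietVector,
    change_report,
    classify_items,
    evaluate_diet,
    group_contributions,
    mean_abs_quantity_variation,
    substitution_decomposition,
)

from conftest import make_toy_db


def _pair(obs, opt):
    return DietVector(obs), DietVector(opt)


def test_identical_diets_have_zero_variation():
    o, p = _pair({"a": 10.0, "b": 5.0}, {"a": 10.0, "b": 5.0})
    assert mean_abs_quantity_variation(o, p) == 0.0


def test_one_doubled_one_unchanged_is_50_percent():
    o, p = _pair({"a": 10.0, "b": 5.0}, {"a": 20.0, "b": 5.0})
    assert mean_abs_quantity_variation(o, p) == pytest.approx(50.0)


def test_variation_matches_direct_loop(rng):
    obs = {f"i{k}": float(v) for k, v in enumerate(rng.uniform(1, 100, 5))}
    opt = {k: float(v) for k, v in zip(obs, rng.uniform(0, 150, 5))}
    o, p = _pair(obs, opt)
    direct = 100.0 / 5 * sum(abs(opt[k] - obs[k]) / obs[k] for k in obs)
    assert mean_abs_quantity_variation(o, p) == pytest.approx(direct, abs=1e-12)


def test_all_zero_observed_is_an_error():
    o, p = _pair({"a": 0.0}, {"a": 5.0})
    with pytest.raises(ValueError):
        mean_abs_quantity_variation(o, p)


def test_swap_inside_group_is_pure_within():
    o, p = _pair({"a": 100.0, "b": 100.0}, {"a": 150.0, "b": 50.0})
    within, between = substitution_decomposition(o, p, {"a": "g", "b": "g"})
    assert within == pytest.approx(100.0)
    assert between == pytest.approx(0.0)


def test_shift_across_groups_is_pure_between():
    o, p = _pair({"a": 100.0, "b": 100.0}, {"a": 150.0, "b": 50.0})
    within, between = substitution_decomposition(o, p, {"a": "g1", "b": "g2"})
    assert within == pytest.approx(0.0)
    assert between == pytest.approx(100.0)


def test_missing_grouping_entry_is_an_error():
    o, p = _pair({"a": 1.0}, {"a": 2.0})
    with pytest.raises(KeyError):
        substitution_decomposition(o, p, {})


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    obs=st.lists(st.floats(0, 500), min_size=10, max_size=10),
    opt=st.lists(st.floats(0, 500), min_size=10, max_size=10),
    groups=st.lists(st.integers(0, 3), min_size=10, max_size=10),
)
def test_decomposition_identity(obs, opt, groups):
    ids = [f"i{k}" for k in range(10)]
    o, p = _pair(dict(zip(ids, obs)), dict(zip(ids, opt)))
    grouping = {i: f"g{g}" for i, g in zip(ids, groups)}
    within, between = substitution_decomposition(o, p, grouping)
    total = sum(abs(a - b) for a, b in zip(obs, opt))
    assert within + between == pytest.approx(total, rel=1e-12, abs=1e-9)
    assert within >= -1e-9 and between >= -1e-9
    # one big group: between collapses to the net total change
    w1, b1 = substitution_decomposition(o, p, {i: "all" for i in ids})
    assert b1 == pytest.approx(abs(sum(opt) - sum(obs)), rel=1e-12, abs=1e-9)
    assert w1 == pytest.approx(total - b1, rel=1e-12, abs=1e-9)


def test_metrics_permutation_invariant(rng):
    ids = [f"i{k}" for k in range(8)]
    obs = dict(zip(ids, rng.uniform(1, 100, 8)))
    opt = dict(zip(ids, rng.uniform(0, 150, 8)))
    grouping = {i: f"g{k % 3}" for k, i in enumerate(ids)}
    perm = list(reversed(ids))
    o1, p1 = _pair(obs, opt)
    o2, p2 = _pair({i: obs[i] for i in perm}, {i: opt[i] for i in perm})
    assert mean_abs_quantity_variation(o1, p1) == pytest.approx(
        mean_abs_quantity_variation(o2, p2))
    assert substitution_decomposition(o1, p1, grouping) == pytest.approx(
        substitution_decomposition(o2, p2, grouping))
    assert classify_items(o1, p1) == classify_items(o2, p2)


def test_classification_cases_and_partition():
    o, p = _pair(
        {"up": 10.0, "down": 10.0, "same": 10.0, "gone": 30.0, "never": 0.0},
        {"up": 15.0, "down": 5.0, "same": 10.0, "gone": 0.0, "never": 0.0},
    )
    counts = classify_items(o, p)
    assert counts == {"increased": 1, "decreased": 1, "unmodified": 2, "deleted": 1}
    assert sum(counts.values()) == 5


def test_identical_diets_all_unmodified():
    o, p = _pair({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
    assert classify_items(o, p) == {
        "increased": 0, "decreased": 0, "unmodified": 2, "deleted": 0}


def test_single_group_contribution_equals_totals():
    db = make_toy_db([
        {"item_id": "a", "energy": 2.0, "ghge": 1.5},
        {"item_id": "b", "energy": 1.0, "ghge": 0.5},
    ])
    o = DietVector({"a": 100.0, "b": 50.0})
    p = DietVector({"a": 80.0, "b": 70.0})
    gc = group_contributions(db, o, p)
    assert list(gc.energy_kcal) == ["toy_main"]
    to, tp = evaluate_diet(db, o), evaluate_diet(db, p)
    assert gc.energy_kcal["toy_main"] == pytest.approx((to.energy_kcal, tp.energy_kcal))
    assert gc.ghge_gco2eq["toy_main"] == pytest.approx((to.ghge_gco2eq, tp.ghge_gco2eq))


def test_display_floor_zero_is_identity_and_floor_blanks_small_values():
    db = make_toy_db([{"item_id": "a", "energy": 0.3, "ghge": 0.2}])
    o = DietVector({"a": 100.0})
    gc = group_contributions(db, o, o)
    assert gc.rendered(0.0, 0.0) == gc
    blanked = gc.rendered(50.0, 100.0)
    assert blanked.energy_kcal["toy_main"] == (30.0, 30.0) or \
        blanked.energy_kcal["toy_main"] == (0.0, 0.0)
    # 30 kcal < 50 kcal floor and 20 g < 100 g floor: both blanked
    assert blanked.energy_kcal["toy_main"] == (0.0, 0.0)
    assert blanked.ghge_gco2eq["toy_main"] == (0.0, 0.0)


def test_group_contributions_partition_diet_totals(default_db, women, women_ladder):
    profile, _ = women
    sol = women_ladder.nutr
    gc = group_contributions(default_db, profile.observed, sol.quantities)
    totals_obs = evaluate_diet(default_db, profile.observed)
    totals_opt = evaluate_diet(default_db, sol.quantities)
    assert sum(v[0] for v in gc.energy_kcal.values()) == pytest.approx(
        totals_obs.energy_kcal, rel=1e-9)
    assert sum(v[1] for v in gc.energy_kcal.values()) == pytest.approx(
        totals_opt.energy_kcal, rel=1e-9)
    assert sum(v[1] for v in gc.ghge_gco2eq.values()) == pytest.approx(
        totals_opt.ghge_gco2eq, rel=1e-9)


def test_change_report_consistency(default_db, women, women_ladder):
    profile, _ = women
    sol = women_ladder.mini
    rep = change_report(default_db, profile.observed, sol.quantities)
    assert rep.within_group_g + rep.between_group_g == pytest.approx(
        rep.total_abs_weight_change_g, rel=1e-12)
    assert sum(rep.item_classes.values()) == len(default_db)
    counted = (rep.item_classes["increased"] + rep.item_classes["decreased"]
               + rep.item_classes["deleted"])
    assert rep.pct_items_modified == pytest.approx(100.0 * counted / len(default_db))
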