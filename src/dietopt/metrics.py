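"""Diet-change diagnostics.

Given an observed and an optimized diet these functions compute the
departure statistics used to describe modeled diets: the mean absolute
per-item quantity variation (%), the split of total absolute weight change
into within- and between-group substitutions, counts of items whose
quantity increased, decreased, was deleted or left unmodified, and
food-group contributions to dietary energy and GHGE.

The within/between split is the gross-minus-net decomposition: per group g,
``gross_g = Σ_{i∈g} |ΔQᵢ|`` and ``net_g = |Σ_{i∈g} ΔQᵢ|``; within =
Σ (gross − net), between = Σ net.  This is the unique additive split in
which an exact 1-for-1 swap inside a group counts entirely as "within" and
a group's net weight shift counts entirely as "between"; it is an
interpretation — other decompositions of substitution exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .food_model import DietVector, FoodDatabase, evaluate_diet

__all__ = [
    "ChangeReport",
    "GroupContribution",
    "mean_abs_quantity_variation",
    "substitution_decomposition",
    "classify_items",
    "group_contributions",
    "change_report",
]

#: Default tolerances for deciding whether an item's quantity changed.
CLASSIFY_TOL_REL = 1e-6
CLASSIFY_TOL_ABS_G = 0.01

#: Default display floors for rendered group-contribution reports.
DISPLAY_FLOOR_ENERGY_KCAL = 50.0
DISPLAY_FLOOR_GHGE_G = 100.0


@dataclass
class ChangeReport:
    """Summary of how an optimized diet departs from the observed one."""

    mean_abs_quantity_variation_pct: float
    total_abs_weight_change_g: float
    within_group_g: float
    between_group_g: float
    item_classes: dict[str, int]  # increased / decreased / unmodified / deleted
    pct_items_modified: float


@dataclass
class GroupContribution:
    """Main-group contributions to energy and GHGE, observed vs modeled.

    ``energy_kcal`` and ``ghge_gco2eq`` map group -> (observed, modeled).
    Stored values are exact sums; display floors are applied only when
    rendering.
    """

    energy_kcal: dict[str, tuple[float, float]]
    ghge_gco2eq: dict[str, tuple[float, float]]

    def rendered(
        self,
        floor_energy: float = DISPLAY_FLOOR_ENERGY_KCAL,
        floor_ghge: float = DISPLAY_FLOOR_GHGE_G,
    ) -> "GroupContribution":
        """Copy with values below the display floors blanked to 0."""

        def cut(d, floor):
            return {
                g: tuple(v if v >= floor else 0.0 for v in pair)
                for g, pair in d.items()
            }

        return GroupContribution(
            energy_kcal=cut(self.energy_kcal, floor_energy),
            ghge_gco2eq=cut(self.ghge_gco2eq, floor_ghge),
        )


def _deltas(observed: DietVector, optimized: DietVector) -> dict[str, float]:
    if set(observed.quantities) != set(optimized.quantities):
        raise KeyError("observed and optimized diets cover different item sets")
    return {
        iid: optimized.quantities[iid] - observed.quantities[iid]
        for iid in observed.quantities
    }


def mean_abs_quantity_variation(observed: DietVector, optimized: DietVector) -> float:
    """Mean absolute per-item quantity variation, in percent.

    ``(1/n) Σᵢ |ΔQᵢ|/Qᵢ_obs × 100`` over the n items observed at a
    positive quantity (zero-observed items have no defined relative
    change and are excluded, consistently with the optimizer's objective).
    """
    deltas = _deltas(observed, optimized)
    terms = [
        abs(d) / observed.quantities[iid]
        for iid, d in deltas.items()
        if observed.quantities[iid] > 0
    ]
    if not terms:
        raise ValueError("no item with positive observed quantity")
    return 100.0 * float(np.mean(terms))


def substitution_decomposition(
    observed: DietVector,
    optimized: DietVector,
    grouping: dict[str, str],
) -> tuple[float, float]:
    """Split total absolute weight change into (within_g, between_g).

    ``grouping`` maps every item id to its group (L1 groups by default in
    the pipeline).  The two parts always sum exactly to Σᵢ |ΔQᵢ|.
    """
    deltas = _deltas(observed, optimized)
    missing = [iid for iid in deltas if iid not in grouping]
    if missing:
        raise KeyError(f"items missing from grouping: {missing[:5]}")
    gross: dict[str, float] = {}
    net: dict[str, float] = {}
    for iid, d in deltas.items():
        g = grouping[iid]
        gross[g] = gross.get(g, 0.0) + abs(d)
        net[g] = net.get(g, 0.0) + d
    within = sum(gross[g] - abs(net[g]) for g in gross)
    between = sum(abs(v) for v in net.values())
    return float(within), float(between)


def classify_items(
    observed: DietVector,
    optimized: DietVector,
    tol_rel: float = CLASSIFY_TOL_REL,
    tol_abs: float = CLASSIFY_TOL_ABS_G,
) -> dict[str, int]:
    """Count items whose quantity increased, decreased, was deleted or
    stayed unmodified.

    "Deleted" means observed at a positive quantity but optimized to
    (numerically) zero; in/decreases must exceed a mixed tolerance
    ``tol_abs + tol_rel × Q_obs``.
    """
    counts = {"increased": 0, "decreased": 0, "unmodified": 0, "deleted": 0}
    for iid, d in _deltas(observed, optimized).items():
        q_obs = observed.quantities[iid]
        q_opt = optimized.quantities[iid]
        tol = tol_abs + tol_rel * q_obs
        if q_obs > tol_abs and q_opt <= tol_abs:
            counts["deleted"] += 1
        elif d > tol:
            counts["increased"] += 1
        elif d < -tol:
            counts["decreased"] += 1
        else:
            counts["unmodified"] += 1
    return counts


def pct_items_modified(counts: dict[str, int]) -> float:
    n = sum(counts.values())
    return 100.0 * (counts["increased"] + counts["decreased"] + counts["deleted"]) / n


def group_contributions(
    db: FoodDatabase,
    observed: DietVector,
    optimized: DietVector,
) -> GroupContribution:
    """Main-group contributions to energy (kcal/day) and GHGE (g CO₂eq/day)
    in the observed and the optimized diet.  Exact partition: group values
    sum to the diet totals."""
    energy = db.composition("energy_kcal")
    ghge = db.ghge
    q_obs = observed.to_array(db)
    q_opt = optimized.to_array(db)
    e_out: dict[str, tuple[float, float]] = {}
    g_out: dict[str, tuple[float, float]] = {}
    for grp in db.main_groups:
        m = db.main_mask(grp)
        e_out[grp] = (float(q_obs[m] @ energy[m]), float(q_opt[m] @ energy[m]))
        g_out[grp] = (float(q_obs[m] @ ghge[m]), float(q_opt[m] @ ghge[m]))
    return GroupContribution(energy_kcal=e_out, ghge_gco2eq=g_out)


def change_report(
    db: FoodDatabase,
    observed: DietVector,
    optimized: DietVector,
    level: str = "l1",
) -> ChangeReport:
    """Full change summary for one model solution.

    ``level`` selects the grouping of the substitution split: "l1" (the 27
    L1 groups, the default) or "main" (the 10 main groups).
    """
    if level == "l1":
        grouping = {it.item_id: it.l1_group for it in db.items}
    elif level == "main":
        grouping = {it.item_id: it.main_group for it in db.items}
    else:
        raise ValueError(f"level must be 'l1' or 'main', got {level!r}")
    within, between = substitution_decomposition(observed, optimized, grouping)
    counts = classify_items(observed, optimized)
    return ChangeReport(
        mean_abs_quantity_variation_pct=mean_abs_quantity_variation(observed, optimized),
        total_abs_weight_change_g=within + between,
        within_group_g=within,
        between_group_g=between,
        item_classes=counts,
        pct_items_modified=pct_items_modified(counts),
    )
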