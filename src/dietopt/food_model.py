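"""Domain types for the diet-optimization pipeline.

The model of the food nomenclature and of diets: individual food items with
group memberships, nutrient compositions and greenhouse-gas-emission (GHGE)
intensities; a food database (the nomenclature); diet vectors (grams per day
of each item); population profiles carrying the observed mean diet and its
acceptability envelope; and nutrient totals of a diet.

Units
-----
Nutrient compositions are stored **per gram of food**, in the unit of the
corresponding daily recommendation (g, mg or µg per gram of food; energy in
kcal per gram).  File readers convert from per-100 g input columns at read
time, so constraint coefficients are used directly without further scaling.
GHGE intensity is in grams of CO₂ equivalents per gram of food.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NUTRIENT_CODES",
    "ENERGY_CODE",
    "SPECIAL_FLAGS",
    "FoodItem",
    "FoodDatabase",
    "DietVector",
    "PopulationProfile",
    "NutrientTotals",
    "evaluate_diet",
]

#: Canonical nutrient codes (the 22 constrained nutrients), in a fixed order.
#: Units of the *daily totals*: proteins/carbohydrates/fats/SFA/free sugars/
#: fiber in g; sodium, calcium, magnesium, phosphorus, iron, potassium, zinc,
#: thiamin, riboflavin, vitamin B6, vitamin C, vitamin E in mg; vitamin A
#: (µg RE), vitamin B12, folate, vitamin D in µg.
NUTRIENT_CODES: tuple[str, ...] = (
    "protein",
    "carbohydrates",
    "fats",
    "sfa",
    "free_sugars",
    "sodium",
    "fiber",
    "calcium",
    "magnesium",
    "phosphorus",
    "iron",
    "potassium",
    "zinc",
    "vitamin_a",
    "thiamin",
    "riboflavin",
    "vitamin_b6",
    "vitamin_b12",
    "folate",
    "vitamin_c",
    "vitamin_d",
    "vitamin_e",
)

#: Energy is carried as an explicit composition column (kcal per gram of
#: food), never recomputed from macronutrients, so that data generators and
#: input files control it independently.
ENERGY_CODE = "energy_kcal"

#: Special food categories whose modeled amounts are capped at observed
#: levels (acceptability constraints).
SPECIAL_FLAGS: frozenset[str] = frozenset({"alcoholic_beverage", "fish_oil", "offal"})


@dataclass(frozen=True)
class FoodItem:
    """One food of the nomenclature.

    Parameters
    ----------
    item_id : str
        Opaque unique identifier.
    name : str
        Human-readable name.
    l1_group : str
        Level-1 food group (27 in the default nomenclature).
    main_group : str
        Main food group (10 in the default nomenclature); each L1 group
        belongs to exactly one main group.
    nutrient_comp : dict
        Nutrient code -> amount per gram of food, plus the ``energy_kcal``
        column (kcal/g).
    ghge_intensity : float
        g CO₂eq emitted per gram of food.
    is_liquid : bool
        Whether the item counts as liquid in the solid/liquid weight ratio
        (liquid milk and ready-to-eat soups count as liquid).
    special_flags : frozenset
        Subset of :data:`SPECIAL_FLAGS`.
    """

    item_id: str
    name: str
    l1_group: str
    main_group: str
    nutrient_comp: dict[str, float]
    ghge_intensity: float
    is_liquid: bool = False
    special_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ghge_intensity < 0:
            raise ValueError(
                f"item {self.item_id!r}: ghge_intensity must be >= 0, "
                f"got {self.ghge_intensity}"
            )
        for code, amount in self.nutrient_comp.items():
            if amount < 0:
                raise ValueError(
                    f"item {self.item_id!r}: nutrient {code!r} amount must be "
                    f">= 0, got {amount}"
                )
        unknown = set(self.special_flags) - SPECIAL_FLAGS
        if unknown:
            raise ValueError(
                f"item {self.item_id!r}: unknown special flags {sorted(unknown)}"
            )


class FoodDatabase:
    """The nomenclature: an ordered collection of food items.

    Exposes lookup maps (item_id -> index, L1 group -> main group) and
    vectorized views of composition columns for constraint building.
    """

    def __init__(self, items: list[FoodItem], nutrient_codes: tuple[str, ...] | None = None):
        if nutrient_codes is None:
            nutrient_codes = NUTRIENT_CODES + (ENERGY_CODE,)
        self.items: list[FoodItem] = list(items)
        self.nutrient_codes: tuple[str, ...] = tuple(nutrient_codes)

        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_ids: {dupes}")
        self.item_ids: list[str] = ids
        self.index: dict[str, int] = {iid: k for k, iid in enumerate(ids)}

        # grouping must be a tree: each L1 group under exactly one main group
        l1_to_main: dict[str, str] = {}
        for it in self.items:
            prev = l1_to_main.setdefault(it.l1_group, it.main_group)
            if prev != it.main_group:
                raise ValueError(
                    f"L1 group {it.l1_group!r} mapped to both {prev!r} and "
                    f"{it.main_group!r}; grouping must be a tree"
                )
        self.l1_to_main: dict[str, str] = l1_to_main

    # -- vector views -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.items)

    @property
    def l1_groups(self) -> list[str]:
        """Distinct L1 groups in first-appearance order."""
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.l1_group, None)
        return list(seen)

    @property
    def main_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.main_group, None)
        return list(seen)

    def composition(self, code: str) -> np.ndarray:
        """Per-gram amounts of one nutrient across all items (dense vector)."""
        if code not in self.nutrient_codes:
            raise KeyError(f"unknown nutrient code {code!r}")
        return np.array([it.nutrient_comp.get(code, 0.0) for it in self.items])

    @property
    def ghge(self) -> np.ndarray:
        return np.array([it.ghge_intensity for it in self.items])

    @property
    def liquid_mask(self) -> np.ndarray:
        return np.array([it.is_liquid for it in self.items], dtype=bool)

    def flag_mask(self, flag: str) -> np.ndarray:
        if flag not in SPECIAL_FLAGS:
            raise KeyError(f"unknown special flag {flag!r}")
        return np.array([flag in it.special_flags for it in self.items], dtype=bool)

    def l1_mask(self, l1_group: str) -> np.ndarray:
        return np.array([it.l1_group == l1_group for it in self.items], dtype=bool)

    def main_mask(self, main_group: str) -> np.ndarray:
        return np.array([it.main_group == main_group for it in self.items], dtype=bool)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodDatabase):
            return NotImplemented
        return self.items == other.items and self.nutrient_codes == other.nutrient_codes


@dataclass
class DietVector:
    """Quantities of each item, in grams per day.

    The domain must equal the database's item set; observed versus optimized
    diets are distinguished by role, not by type.
    """

    quantities: dict[str, float]

    def __post_init__(self) -> None:
        for iid, q in self.quantities.items():
            if q < 0:
                raise ValueError(f"negative quantity {q} for item {iid!r}")

    @classmethod
    def from_array(cls, db: FoodDatabase, values: np.ndarray) -> "DietVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(db),):
            raise ValueError(f"expected {len(db)} quantities, got {values.shape}")
        # clip tiny solver negatives
        values = np.where((values < 0) & (values > -1e-9), 0.0, values)
        return cls({iid: float(v) for iid, v in zip(db.item_ids, values)})

    def to_array(self, db: FoodDatabase) -> np.ndarray:
        missing = [iid for iid in db.item_ids if iid not in self.quantities]
        extra = [iid for iid in self.quantities if iid not in db.index]
        if missing or extra:
            raise KeyError(
                f"diet domain mismatch: missing items {missing[:5]}, "
                f"unknown items {extra[:5]}"
            )
        return np.array([self.quantities[iid] for iid in db.item_ids])

    def total_weight(self) -> float:
        return float(sum(self.quantities.values()))


@dataclass
class NutrientTotals:
    """Daily totals of a diet: each nutrient, energy, weight and GHGE.

    Every total is the dot product of item quantities with the matching
    composition column (linear aggregation), so totals are additive in diets.
    """

    nutrients: dict[str, float]
    energy_kcal: float
    weight_g: float
    ghge_gco2eq: float

    def __getitem__(self, code: str) -> float:
        if code == ENERGY_CODE:
            return self.energy_kcal
        return self.nutrients[code]


@dataclass
class PopulationProfile:
    """A (population × gender) stratum: observed diet and its envelope.

    ``item_lower`` holds the 10th percentile observed over the whole
    population (non-consumers included, hence frequently zero);
    ``item_upper`` the 90th percentile among consumers.  L1-group bounds use
    the same convention at group level.
    """

    label: str
    gender: str  # "women" | "men"
    body_weight_kg: float
    observed: DietVector
    item_lower: dict[str, float]
    item_upper: dict[str, float]
    l1_lower: dict[str, float]
    l1_upper: dict[str, float]
    energy_obs_kcal: float
    solid_liquid_ratio_obs: float
    special_caps: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in ("women", "men"):
            raise ValueError(f"gender must be 'women' or 'men', got {self.gender!r}")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be positive")
        for iid in self.item_lower:
            lo, hi = self.item_lower[iid], self.item_upper.get(iid, np.inf)
            if lo < 0 or hi < 0:
                raise ValueError(f"negative bound for item {iid!r}")
            if lo > hi:
                raise ValueError(f"item {iid!r}: lower bound {lo} > upper bound {hi}")
        for g in self.l1_lower:
            lo, hi = self.l1_lower[g], self.l1_upper.get(g, np.inf)
            if lo < 0 or hi < 0 or lo > hi:
                raise ValueError(f"L1 group {g!r}: invalid bounds [{lo}, {hi}]")


def evaluate_diet(db: FoodDatabase, diet: DietVector) -> NutrientTotals:
    """Aggregate a diet into daily nutrient totals, energy, weight and GHGE.

    Raises
    ------
    KeyError
        If the diet's domain does not match the database's item set; the
        offending item ids are named.
    """
    q = diet.to_array(db)
    nutrients = {
        code: float(q @ db.composition(code))
        for code in db.nutrient_codes
        if code != ENERGY_CODE
    }
    return NutrientTotals(
        nutrients=nutrients,
        energy_kcal=float(q @ db.composition(ENERGY_CODE)),
        weight_g=float(q.sum()),
        ghge_gco2eq=float(q @ db.ghge),
    )
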