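"""Seeded synthetic food-survey generator.

National dietary-survey summaries are rarely redistributable, so this
module fabricates inputs with the statistical structure the optimization
pipeline assumes: a food nomenclature of 151 items partitioned into 27 L1
groups nested in 10 main groups, per-gram nutrient compositions drawn from
group-typical ranges, GHGE intensities with animal-derived items
systematically above plant-derived ones, and gender-specific population
profiles whose observed mean diet under-supplies chosen nutrients (fiber;
iron for women) and over-supplies others (free sugars, saturated fat) —
the typical Western-diet pattern the optimizer is meant to correct.

Feasibility is guaranteed **by construction**: before emitting a profile
the generator solves for a hidden reference diet that satisfies every
nutritional bound (with a small margin) together with tightened versions
of the acceptability constraints, then places all percentile envelopes so
they contain both the reference and the observed diet.  The reference diet
is a certificate that the NUTR model is feasible for the emitted instance;
if it cannot be constructed after a few jittered retries the generator
raises rather than silently emitting an infeasible instance.

All randomness flows from labeled substreams of a single master seed
(database and each population draw from independent streams), so adding a
population never perturbs the database and a fixed seed reproduces every
byte of output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constraints import (
    ConstraintSet,
    LinearConstraint,
    build_model_constraints,
    build_nutritional,
    check_feasibility,
)
from .food_model import (
    ENERGY_CODE,
    NUTRIENT_CODES,
    DietVector,
    FoodDatabase,
    FoodItem,
    PopulationProfile,
)

__all__ = [
    "GeneratorConfig",
    "GeneratorError",
    "generate_database",
    "generate_population",
    "generate_population_with_certificate",
]


class GeneratorError(RuntimeError):
    """Raised when no feasible instance could be constructed; use a
    different seed."""


# --------------------------------------------------------------------------
# Nomenclature template
# --------------------------------------------------------------------------

#: Main groups and their L1 groups, in emission order.  The first L1 of
#: each main group is kept when the nomenclature is shrunk, so every main
#: group stays populated.
MAIN_GROUP_TREE: list[tuple[str, list[str]]] = [
    ("fruit_and_vegetables", ["vegetables", "fruits", "legumes", "fruit_juices"]),
    ("starches", ["bread", "pasta_rice_grains", "potatoes", "breakfast_cereals"]),
    ("meat", ["red_meat", "poultry", "processed_meat", "offal"]),
    ("fish", ["fish", "shellfish"]),
    ("dairy", ["liquid_milk", "cheese", "fermented_milk"]),
    ("eggs", ["eggs"]),
    ("sugar_fat_alcohol", ["sweets", "added_fats", "alcoholic_beverages"]),
    ("beverages", ["soft_drinks", "hot_beverages", "water"]),
    ("composite_dishes", ["mixed_dishes", "soups"]),
    ("nuts_and_seeds", ["nuts_seeds"]),
]

#: L1 groups counted as liquid in the solid/liquid weight ratio (liquid
#: milk and ready-to-eat soups included).
LIQUID_L1 = {
    "fruit_juices", "liquid_milk", "alcoholic_beverages",
    "soft_drinks", "hot_beverages", "water", "soups",
}

#: L1 groups of animal origin (systematically GHGE-intense).
ANIMAL_L1 = {
    "red_meat", "poultry", "processed_meat", "offal", "fish", "shellfish",
    "liquid_milk", "cheese", "fermented_milk", "eggs",
}

#: Special-category flag carried by every item of an L1 group.
L1_FLAGS = {"alcoholic_beverages": "alcoholic_beverage", "offal": "offal"}

#: Default item count per L1 group (sums to 151) — also the weights used
#: when the nomenclature is scaled to a different size.
L1_ITEM_WEIGHTS: dict[str, int] = {
    "vegetables": 14, "fruits": 12, "legumes": 4, "fruit_juices": 3,
    "bread": 7, "pasta_rice_grains": 7, "potatoes": 4, "breakfast_cereals": 4,
    "red_meat": 7, "poultry": 5, "processed_meat": 7, "offal": 2,
    "fish": 9, "shellfish": 3,
    "liquid_milk": 4, "cheese": 8, "fermented_milk": 4,
    "eggs": 2,
    "sweets": 10, "added_fats": 7, "alcoholic_beverages": 5,
    "soft_drinks": 4, "hot_beverages": 3, "water": 2,
    "mixed_dishes": 8, "soups": 3,
    "nuts_seeds": 3,
}

#: Typical daily grams per L1 group in the habit (pre-scaling) diet.
L1_HABIT_G: dict[str, float] = {
    "vegetables": 180, "fruits": 150, "legumes": 20, "fruit_juices": 80,
    "bread": 120, "pasta_rice_grains": 100, "potatoes": 80, "breakfast_cereals": 25,
    "red_meat": 60, "poultry": 40, "processed_meat": 40, "offal": 5,
    "fish": 30, "shellfish": 8,
    "liquid_milk": 200, "cheese": 35, "fermented_milk": 80,
    "eggs": 25,
    "sweets": 80, "added_fats": 40, "alcoholic_beverages": 150,
    "soft_drinks": 150, "hot_beverages": 300, "water": 500,
    "mixed_dishes": 150, "soups": 80,
    "nuts_seeds": 10,
}

#: Pre-multiplier GHGE intensity scale per L1 group (g CO₂eq per g food).
#: Animal groups carry relative structure only — their absolute level is
#: pinned to ``animal_ghge_multiplier × median plant intensity``.
L1_GHGE_BASE: dict[str, float] = {
    "vegetables": 0.50, "fruits": 0.45, "legumes": 0.70, "fruit_juices": 0.60,
    "bread": 0.80, "pasta_rice_grains": 0.90, "potatoes": 0.35, "breakfast_cereals": 1.00,
    "red_meat": 6.0, "poultry": 1.5, "processed_meat": 4.0, "offal": 2.5,
    "fish": 1.2, "shellfish": 2.0,
    "liquid_milk": 0.30, "cheese": 2.5, "fermented_milk": 0.40,
    "eggs": 0.50,
    "sweets": 1.50, "added_fats": 2.00, "alcoholic_beverages": 1.10,
    "soft_drinks": 0.35, "hot_beverages": 0.20, "water": 0.05,
    "mixed_dishes": 1.20, "soups": 0.50,
    "nuts_seeds": 1.30,
}


def _p100(
    energy=0.0, protein=0.0, carbohydrates=0.0, fats=0.0, sfa=0.0,
    free_sugars=0.0, sodium=0.0, fiber=0.0, calcium=0.0, magnesium=0.0,
    phosphorus=0.0, iron=0.0, potassium=0.0, zinc=0.0, vitamin_a=0.0,
    thiamin=0.0, riboflavin=0.0, vitamin_b6=0.0, vitamin_b12=0.0,
    folate=0.0, vitamin_c=0.0, vitamin_d=0.0, vitamin_e=0.0,
) -> dict[str, float]:
    d = dict(
        protein=protein, carbohydrates=carbohydrates, fats=fats, sfa=sfa,
        free_sugars=free_sugars, sodium=sodium, fiber=fiber, calcium=calcium,
        magnesium=magnesium, phosphorus=phosphorus, iron=iron,
        potassium=potassium, zinc=zinc, vitamin_a=vitamin_a, thiamin=thiamin,
        riboflavin=riboflavin, vitamin_b6=vitamin_b6, vitamin_b12=vitamin_b12,
        folate=folate, vitamin_c=vitamin_c, vitamin_d=vitamin_d,
        vitamin_e=vitamin_e,
    )
    d[ENERGY_CODE] = energy
    return d


#: Typical composition per 100 g of food, per L1 group.  Values are
#: group-level caricatures of European composition tables (units as in
#: :data:`dietopt.food_model.NUTRIENT_CODES`): plant groups rich in fiber,
#: vitamin C and folate; dairy in calcium; meat/fish in iron, zinc and
#: B12; breakfast cereals fortified; sugar/fat/alcohol energy-dense and
#: micronutrient-poor.  Per-item values are these multiplied by a
#: lognormal jitter.
L1_PROFILE_P100: dict[str, dict[str, float]] = {
    "vegetables": _p100(energy=35, protein=1.8, carbohydrates=5, fats=0.3, sfa=0.05,
                        free_sugars=2.5, sodium=20, fiber=2.8, calcium=40, magnesium=18,
                        phosphorus=40, iron=0.8, potassium=280, zinc=0.4, vitamin_a=220,
                        thiamin=0.07, riboflavin=0.06, vitamin_b6=0.12, folate=55,
                        vitamin_c=30, vitamin_e=0.8),
    "fruits": _p100(energy=55, protein=0.7, carbohydrates=12, fats=0.3, sfa=0.05,
                    free_sugars=9, sodium=3, fiber=2.2, calcium=15, magnesium=12,
                    phosphorus=20, iron=0.4, potassium=220, zinc=0.15, vitamin_a=30,
                    thiamin=0.03, riboflavin=0.03, vitamin_b6=0.08, folate=20,
                    vitamin_c=35, vitamin_e=0.5),
    "legumes": _p100(energy=110, protein=8, carbohydrates=15, fats=0.8, sfa=0.1,
                     free_sugars=0.5, sodium=10, fiber=6.5, calcium=50, magnesium=45,
                     phosphorus=130, iron=2.8, potassium=350, zinc=1.2, vitamin_a=10,
                     thiamin=0.2, riboflavin=0.08, vitamin_b6=0.15, folate=90,
                     vitamin_c=2, vitamin_e=0.5),
    "fruit_juices": _p100(energy=45, protein=0.3, carbohydrates=10.5, free_sugars=9.5,
                          sodium=5, fiber=0.2, calcium=10, magnesium=10, phosphorus=15,
                          iron=0.2, potassium=160, folate=15, vitamin_c=30),
    "bread": _p100(energy=260, protein=8.5, carbohydrates=50, fats=1.8, sfa=0.3,
                   free_sugars=2, sodium=500, fiber=4.5, calcium=30, magnesium=35,
                   phosphorus=100, iron=1.3, potassium=160, zinc=1.0, thiamin=0.12,
                   riboflavin=0.06, vitamin_b6=0.1, folate=30, vitamin_e=0.4),
    "pasta_rice_grains": _p100(energy=140, protein=4.5, carbohydrates=28, fats=0.8,
                               sfa=0.15, free_sugars=0.3, sodium=40, fiber=1.8,
                               calcium=10, magnesium=25, phosphorus=70, iron=0.8,
                               potassium=70, zinc=0.8, thiamin=0.06, riboflavin=0.02,
                               vitamin_b6=0.06, folate=10, vitamin_e=0.2),
    "potatoes": _p100(energy=80, protein=2, carbohydrates=17, fats=0.2, free_sugars=0.8,
                      sodium=10, fiber=1.8, calcium=10, magnesium=22, phosphorus=50,
                      iron=0.6, potassium=420, zinc=0.35, thiamin=0.08, riboflavin=0.03,
                      vitamin_b6=0.25, folate=20, vitamin_c=12, vitamin_e=0.05),
    "breakfast_cereals": _p100(energy=380, protein=9, carbohydrates=70, fats=4, sfa=1,
                               free_sugars=15, sodium=400, fiber=8, calcium=40,
                               magnesium=80, phosphorus=200, iron=12, potassium=250,
                               zinc=3.5, vitamin_a=400, thiamin=1.0, riboflavin=1.2,
                               vitamin_b6=1.4, vitamin_b12=1.5, folate=250,
                               vitamin_d=3.5, vitamin_e=3),
    "red_meat": _p100(energy=220, protein=20, carbohydrates=0.3, fats=15, sfa=6,
                      sodium=350, calcium=12, magnesium=20, phosphorus=180, iron=2.2,
                      potassium=300, zinc=4.5, vitamin_a=10, thiamin=0.08,
                      riboflavin=0.2, vitamin_b6=0.35, vitamin_b12=2, folate=8,
                      vitamin_d=0.4, vitamin_e=0.3),
    "poultry": _p100(energy=150, protein=21, fats=7, sfa=2, sodium=320, calcium=12,
                     magnesium=24, phosphorus=200, iron=0.8, potassium=280, zinc=1.4,
                     vitamin_a=15, thiamin=0.07, riboflavin=0.15, vitamin_b6=0.45,
                     vitamin_b12=0.4, folate=8, vitamin_d=0.2, vitamin_e=0.2),
    "processed_meat": _p100(energy=300, protein=14, carbohydrates=2, fats=26, sfa=9.5,
                            sodium=900, calcium=15, magnesium=15, phosphorus=160,
                            iron=1.3, potassium=220, zinc=2.2, vitamin_a=5, thiamin=0.3,
                            riboflavin=0.15, vitamin_b6=0.2, vitamin_b12=1, folate=3,
                            vitamin_d=0.5, vitamin_e=0.2),
    "offal": _p100(energy=140, protein=18, carbohydrates=2, fats=6, sfa=2, sodium=250,
                   calcium=10, magnesium=18, phosphorus=300, iron=8, potassium=280,
                   zinc=4, vitamin_a=8000, thiamin=0.25, riboflavin=2.5, vitamin_b6=0.6,
                   vitamin_b12=30, folate=250, vitamin_c=10, vitamin_d=1, vitamin_e=0.4),
    "fish": _p100(energy=140, protein=19, fats=6.5, sfa=1.3, sodium=380, calcium=25,
                  magnesium=28, phosphorus=230, iron=0.7, potassium=330, zinc=0.7,
                  vitamin_a=30, thiamin=0.08, riboflavin=0.12, vitamin_b6=0.4,
                  vitamin_b12=4.5, folate=12, vitamin_d=7, vitamin_e=1.2),
    "shellfish": _p100(energy=90, protein=17, carbohydrates=1, fats=1.5, sfa=0.3,
                       sodium=500, calcium=60, magnesium=40, phosphorus=200, iron=2.5,
                       potassium=250, zinc=3.5, vitamin_a=20, riboflavin=0.1,
                       vitamin_b6=0.1, vitamin_b12=8, folate=20, vitamin_d=2,
                       vitamin_e=1),
    "liquid_milk": _p100(energy=50, protein=3.4, carbohydrates=4.8, fats=1.8, sfa=1.1,
                         sodium=45, calcium=120, magnesium=11, phosphorus=95, iron=0.05,
                         potassium=155, zinc=0.4, vitamin_a=25, thiamin=0.04,
                         riboflavin=0.18, vitamin_b6=0.04, vitamin_b12=0.4, folate=5,
                         vitamin_c=0.5, vitamin_d=1, vitamin_e=0.05),
    "cheese": _p100(energy=350, protein=24, carbohydrates=2, fats=28, sfa=17,
                    sodium=700, calcium=750, magnesium=28, phosphorus=500, iron=0.3,
                    potassium=100, zinc=3.5, vitamin_a=250, thiamin=0.03,
                    riboflavin=0.4, vitamin_b6=0.08, vitamin_b12=1.5, folate=20,
                    vitamin_d=0.4, vitamin_e=0.5),
    "fermented_milk": _p100(energy=80, protein=4, carbohydrates=8, fats=3, sfa=1.9,
                            free_sugars=5, sodium=55, calcium=140, magnesium=13,
                            phosphorus=110, iron=0.1, potassium=190, zinc=0.5,
                            vitamin_a=30, thiamin=0.04, riboflavin=0.2, vitamin_b6=0.05,
                            vitamin_b12=0.3, folate=8, vitamin_c=0.8, vitamin_d=0.6,
                            vitamin_e=0.07),
    "eggs": _p100(energy=140, protein=12.5, carbohydrates=0.7, fats=10, sfa=3.1,
                  sodium=140, calcium=55, magnesium=12, phosphorus=190, iron=1.9,
                  potassium=130, zinc=1.3, vitamin_a=180, thiamin=0.07,
                  riboflavin=0.45, vitamin_b6=0.12, vitamin_b12=2, folate=45,
                  vitamin_d=1.8, vitamin_e=1.1),
    "sweets": _p100(energy=430, protein=4, carbohydrates=65, fats=17, sfa=9,
                    free_sugars=48, sodium=150, fiber=1.5, calcium=60, magnesium=30,
                    phosphorus=90, iron=1.2, potassium=180, zinc=0.6, vitamin_a=30,
                    riboflavin=0.1, folate=8, vitamin_e=1),
    "added_fats": _p100(energy=750, protein=0.3, carbohydrates=0.5, fats=83, sfa=25,
                        sodium=300, calcium=10, vitamin_a=300, vitamin_d=5,
                        vitamin_e=25),
    "alcoholic_beverages": _p100(energy=60, carbohydrates=3, free_sugars=1, sodium=8,
                                 magnesium=8, iron=0.3, potassium=60, folate=8),
    "soft_drinks": _p100(energy=40, carbohydrates=10, free_sugars=10, sodium=10,
                         potassium=10),
    "hot_beverages": _p100(energy=2, sodium=5, magnesium=5, potassium=40, folate=3),
    "water": _p100(energy=0, sodium=2, calcium=8, magnesium=3, potassium=1),
    "mixed_dishes": _p100(energy=160, protein=7, carbohydrates=15, fats=8, sfa=2.8,
                          free_sugars=1, sodium=450, fiber=1.5, calcium=40,
                          magnesium=22, phosphorus=110, iron=1.2, potassium=250,
                          zinc=1.2, vitamin_a=80, thiamin=0.1, riboflavin=0.1,
                          vitamin_b6=0.15, vitamin_b12=0.5, folate=25, vitamin_c=8,
                          vitamin_d=0.3, vitamin_e=1),
    "soups": _p100(energy=40, protein=1.5, carbohydrates=5, fats=1.5, sfa=0.4,
                   sodium=300, fiber=1, calcium=20, magnesium=10, phosphorus=30,
                   iron=0.4, potassium=150, zinc=0.3, vitamin_a=150, folate=15,
                   vitamin_c=5, vitamin_e=0.5),
    "nuts_seeds": _p100(energy=600, protein=20, carbohydrates=12, fats=52, sfa=6,
                        free_sugars=4, sodium=5, fiber=8, calcium=80, magnesium=250,
                        phosphorus=400, iron=3.5, potassium=650, zinc=3.2, vitamin_a=5,
                        thiamin=0.3, riboflavin=0.2, vitamin_b6=0.4, folate=70,
                        vitamin_e=15),
}

#: Composition of the fish-oil supplement item (one per nomenclature,
#: carried inside the fish L1 group; capped at observed amounts by the
#: acceptability constraints).
FISH_OIL_P100 = _p100(energy=900, fats=100, sfa=20, vitamin_d=250, vitamin_e=30)

#: Per-item lognormal jitter (sigma of log) on compositions and habits.
COMPOSITION_JITTER_SIGMA = 0.25
GHGE_JITTER_SIGMA = 0.30


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic survey.

    Defaults define the canonical study conditions: a 151/27/10
    nomenclature, women's observed diets deficient in fiber and iron and
    men's in fiber, both genders in free-sugar and saturated-fat excess,
    animal GHGE intensities four times the plant median, and realistic
    European adult body weights and energy intakes.
    """

    n_items: int = 151
    n_l1: int = 27
    n_main: int = 10
    seed: int = 42
    deficiency_targets: dict = field(
        default_factory=lambda: {"women": ("fiber", "iron"), "men": ("fiber",)}
    )
    excess_targets: tuple = ("free_sugars", "sfa")
    animal_ghge_multiplier: float = 4.0
    body_weight_kg: dict = field(default_factory=lambda: {"women": 66.0, "men": 80.0})
    energy_kcal: dict = field(default_factory=lambda: {"women": 1800.0, "men": 2300.0})
    #: fraction of items whose 10th-percentile lower bound is zero
    #: (non-consumers dominate the 10th percentile of many items)
    zero_p10_fraction: float = 0.30
    #: relative margin by which the observed diet violates each target
    violation_margin: float = 0.15
    #: percentile bounds computed per gender (default) or emulating a
    #: pooled-gender computation (wider envelopes)
    bounds_per_gender: bool = True
    max_retries: int = 5

    def __post_init__(self) -> None:
        if not (self.n_main <= self.n_l1 <= self.n_items):
            raise ValueError(
                f"need n_main <= n_l1 <= n_items, got "
                f"{self.n_main}/{self.n_l1}/{self.n_items}"
            )
        if self.n_main < 1 or self.n_main > len(MAIN_GROUP_TREE):
            raise ValueError(f"n_main must be in [1, {len(MAIN_GROUP_TREE)}]")
        if self.n_l1 > sum(len(l1s) for _, l1s in MAIN_GROUP_TREE[: self.n_main]):
            raise ValueError("n_l1 exceeds the L1 groups available under n_main")
        if self.animal_ghge_multiplier <= 0:
            raise ValueError("animal_ghge_multiplier must be positive")
        if not (0.0 <= self.zero_p10_fraction <= 1.0):
            raise ValueError("zero_p10_fraction must be in [0, 1]")


def _snap_per100(x: float) -> float:
    """Round a per-gram value to the nearest value exactly representable
    through the per-100 g interchange format (fixed point of x*100/100)."""
    y = float(x)
    while True:
        z = (y * 100.0) / 100.0
        if z == y:
            return y
        y = z


def _rng(seed: int, *labels: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *labels]))


# --------------------------------------------------------------------------
# Database generation
# --------------------------------------------------------------------------


def _select_nomenclature(cfg: GeneratorConfig) -> list[tuple[str, str, int]]:
    """(l1_group, main_group, item_count) triples for the configured size."""
    mains = MAIN_GROUP_TREE[: cfg.n_main]
    # one L1 per main group first, then the rest in template order
    chosen: list[tuple[str, str]] = [(l1s[0], main) for main, l1s in mains]
    for main, l1s in mains:
        for l1 in l1s[1:]:
            if len(chosen) < cfg.n_l1:
                chosen.append((l1, main))
    chosen = chosen[: cfg.n_l1]

    weights = np.array([L1_ITEM_WEIGHTS[l1] for l1, _ in chosen], dtype=float)
    shares = weights / weights.sum() * cfg.n_items
    counts = np.maximum(1, np.floor(shares).astype(int))
    # largest-remainder top-up / trim to hit n_items exactly
    while counts.sum() < cfg.n_items:
        counts[int(np.argmax(shares - counts))] += 1
    while counts.sum() > cfg.n_items:
        k = int(np.argmax(np.where(counts > 1, counts - shares, -np.inf)))
        counts[k] -= 1
    return [(l1, main, int(c)) for (l1, main), c in zip(chosen, counts)]


def generate_database(cfg: GeneratorConfig) -> FoodDatabase:
    """Generate the food nomenclature with compositions and GHGE intensities.

    Animal-group intensities are drawn from the same family as plant ones
    and then scaled so their median equals ``animal_ghge_multiplier ×``
    the plant median, with each animal item floored at that level; with a
    multiplier of 1 the two distributions coincide up to that floor.
    """
    rng = _rng(cfg.seed, 0)
    nomenclature = _select_nomenclature(cfg)

    items: list[FoodItem] = []
    serial = 0
    ghge_draw: list[float] = []
    animal_mask: list[bool] = []
    for l1, main, count in nomenclature:
        profile = L1_PROFILE_P100[l1]
        for k in range(count):
            serial += 1
            is_fish_oil = l1 == "fish" and k == count - 1 and count >= 2
            base = FISH_OIL_P100 if is_fish_oil else profile
            jitter = rng.lognormal(0.0, COMPOSITION_JITTER_SIGMA, size=len(base))
            # quantize to the per-100 g grid of the interchange format so
            # write/read round-trips reproduce the database exactly
            comp = {
                code: _snap_per100(val / 100.0 * j)
                for (code, val), j in zip(base.items(), jitter)
            }
            flags = set()
            if l1 in L1_FLAGS:
                flags.add(L1_FLAGS[l1])
            if is_fish_oil:
                flags.add("fish_oil")
            items.append(
                FoodItem(
                    item_id=f"F{serial:03d}",
                    name=f"{l1} {k + 1:02d}" if not is_fish_oil else "fish oil supplement",
                    l1_group=l1,
                    main_group=main,
                    nutrient_comp=comp,
                    ghge_intensity=0.0,  # filled below
                    is_liquid=l1 in LIQUID_L1,
                    special_flags=frozenset(flags),
                )
            )
            ghge_draw.append(L1_GHGE_BASE[l1] * rng.lognormal(0.0, GHGE_JITTER_SIGMA))
            animal_mask.append(l1 in ANIMAL_L1)

    g = np.array(ghge_draw)
    animal = np.array(animal_mask)
    if animal.any() and (~animal).any():
        plant_median = float(np.median(g[~animal]))
        m = cfg.animal_ghge_multiplier
        # pin the animal median at m × plant median, then floor each item there
        g[animal] *= m * plant_median / float(np.median(g[animal]))
        g[animal] = np.maximum(g[animal], m * plant_median)
    items = [replace(it, ghge_intensity=_snap_per100(gi)) for it, gi in zip(items, g)]
    return FoodDatabase(items)


# --------------------------------------------------------------------------
# Population generation
# --------------------------------------------------------------------------


def _habit_diet(db: FoodDatabase, cfg: GeneratorConfig, rng: np.random.Generator,
                energy_target: float) -> np.ndarray:
    """A plausible everyone-eats-everything diet scaled to the energy target."""
    h = np.zeros(len(db))
    for l1 in db.l1_groups:
        mask = db.l1_mask(l1)
        shares = rng.gamma(2.0, 1.0, size=int(mask.sum()))
        h[mask] = L1_HABIT_G[l1] * shares / shares.sum()
    e = db.composition(ENERGY_CODE)
    total_e = float(h @ e)
    if total_e <= 0:
        raise GeneratorError("habit diet has no energy; degenerate database")
    return h * (energy_target / total_e)


def _anchor_profile(db: FoodDatabase, gender: str, cfg: GeneratorConfig,
                    anchor: np.ndarray, energy: float) -> PopulationProfile:
    """Minimal profile carrying an anchor diet for departure LPs."""
    return PopulationProfile(
        label=f"synthetic-{gender}",
        gender=gender,
        body_weight_kg=cfg.body_weight_kg[gender],
        observed=DietVector.from_array(db, anchor),
        item_lower={}, item_upper={}, l1_lower={}, l1_upper={},
        energy_obs_kcal=energy,
        solid_liquid_ratio_obs=1.0,
    )


def _energy_band(db: FoodDatabase, energy: float, rel: float) -> list[LinearConstraint]:
    e = db.composition(ENERGY_CODE)
    coeffs = {iid: float(v) for iid, v in zip(db.item_ids, e) if v != 0.0}
    return [
        LinearConstraint("energy_min", coeffs, ">=", (1 - rel) * energy, "acceptability"),
        LinearConstraint("energy_max", coeffs, "<=", (1 + rel) * energy, "acceptability"),
    ]


def _observed_diet(db: FoodDatabase, gender: str, cfg: GeneratorConfig,
                   h: np.ndarray, energy: float) -> np.ndarray:
    """Observed mean diet: closest diet to the habits that violates every
    configured deficiency/excess target at the configured margin."""
    from .optimizer import minimize_departure  # deferred: avoids import cycle

    anchor = _anchor_profile(db, gender, cfg, h, energy)
    nutr = {c.label: c for c in build_nutritional(db, anchor)}
    margin = cfg.violation_margin

    cset = ConstraintSet(metadata={"purpose": "observed-diet construction"})
    cset.extend(_energy_band(db, energy, 1e-3))
    for code in cfg.deficiency_targets.get(gender, ()):
        ref = nutr[f"{code}_min"]
        cset.add(LinearConstraint(
            f"force_low:{code}", ref.coefficients, "<=", (1 - margin) * ref.rhs, "nutritional"
        ))
    for code in cfg.excess_targets:
        ref = nutr[f"{code}_max"]
        cset.add(LinearConstraint(
            f"force_high:{code}", ref.coefficients, ">=", (1 + margin) * ref.rhs, "nutritional"
        ))
    for iid, cap in zip(db.item_ids, 4.0 * h):
        cset.add(LinearConstraint(f"item_max:{iid}", {iid: 1.0}, "<=", float(cap), "acceptability"))
    # keep both phases of the solid/liquid ratio populated
    liq = db.liquid_mask
    for label, mask in (("liquid_floor", liq), ("solid_floor", ~liq)):
        members = {iid: 1.0 for iid, m in zip(db.item_ids, mask) if m}
        cset.add(LinearConstraint(label, members, ">=", 0.5 * float(h[mask].sum()), "acceptability"))

    sol = minimize_departure(db, anchor, cset, model_label="observed-construction")
    if not sol.is_optimal:
        raise GeneratorError(f"observed-diet LP {sol.status}: {sol.message}")
    return sol.quantities.to_array(db)


def _reference_diet(db: FoodDatabase, gender: str, cfg: GeneratorConfig,
                    o: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Hidden reference diet: satisfies every nutritional bound with a 2%
    margin and tightened acceptability envelopes around the observed diet
    (so it certifies NUTR feasibility once the real envelopes are set)."""
    from .optimizer import minimize_departure

    e = db.composition(ENERGY_CODE)
    energy_o = float(o @ e)
    anchor = _anchor_profile(db, gender, cfg, o, energy_o)

    cset = ConstraintSet(metadata={"purpose": "reference-diet construction"})
    for c in build_nutritional(db, anchor):
        rhs = c.rhs * (1.02 if c.sense == ">=" else 0.98)
        cset.add(LinearConstraint(c.label, c.coefficients, c.sense, rhs, c.provenance))
    cset.extend(_energy_band(db, energy_o, 5e-4))

    ones = {iid: 1.0 for iid in db.item_ids}
    w_o = float(o.sum())
    cset.add(LinearConstraint("total_weight_min", ones, ">=", 0.85 * w_o, "acceptability"))
    cset.add(LinearConstraint("total_weight_max", ones, "<=", 1.15 * w_o, "acceptability"))

    liq = db.liquid_mask
    w_liq, w_sol = float(o[liq].sum()), float(o[~liq].sum())
    if w_liq <= 0 or w_sol <= 0:
        raise GeneratorError("observed diet has a degenerate solid/liquid split")
    r_obs = w_sol / w_liq
    for label, band, sense in (("ratio_max", 1.005, "<="), ("ratio_min", 0.995, ">=")):
        coeffs = {
            iid: (1.0 if not l else -band * r_obs) for iid, l in zip(db.item_ids, liq)
        }
        cset.add(LinearConstraint(label, coeffs, sense, 0.0, "acceptability"))

    for flag in ("alcoholic_beverage", "fish_oil", "offal"):
        mask = db.flag_mask(flag)
        if mask.any():
            members = {iid: 1.0 for iid, m in zip(db.item_ids, mask) if m}
            cset.add(LinearConstraint(
                f"cap:{flag}", members, "<=", float(o[mask].sum()), "acceptability"
            ))

    for iid, cap in zip(db.item_ids, np.maximum(3.0 * h, 25.0)):
        cset.add(LinearConstraint(f"item_max:{iid}", {iid: 1.0}, "<=", float(cap), "acceptability"))

    sol = minimize_departure(db, anchor, cset, model_label="reference-construction")
    if not sol.is_optimal:
        raise GeneratorError(f"reference-diet LP {sol.status}: {sol.message}")
    return sol.quantities.to_array(db)


def generate_population_with_certificate(
    db: FoodDatabase, gender: str, cfg: GeneratorConfig
) -> tuple[PopulationProfile, DietVector]:
    """Generate one gender's profile and the reference diet certifying
    that the NUTR model on it is feasible.

    Raises :class:`GeneratorError` after ``cfg.max_retries`` jittered
    attempts rather than emitting an infeasible instance.
    """
    if gender not in ("women", "men"):
        raise ValueError(f"gender must be 'women' or 'men', got {gender!r}")
    gender_label = 1 if gender == "women" else 2
    energy = cfg.energy_kcal[gender]
    last_err: Exception | None = None

    for attempt in range(cfg.max_retries):
        rng = _rng(cfg.seed, gender_label, attempt)
        try:
            h = _habit_diet(db, cfg, rng, energy)
            o = _observed_diet(db, gender, cfg, h, energy)
            r = _reference_diet(db, gender, cfg, o, h)
            profile = _assemble_profile(db, gender, cfg, o, r, rng)
            certificate = DietVector.from_array(db, r)
            # audit the certificate against the real constraint set
            bad = check_feasibility(db, certificate, build_model_constraints(db, profile))
            if bad:
                raise GeneratorError(f"certificate violates {bad[:3]}")
            return profile, certificate
        except GeneratorError as err:
            last_err = err
    raise GeneratorError(
        f"could not construct a feasible {gender} instance after "
        f"{cfg.max_retries} attempts (last: {last_err}); try a different seed"
    )


def _assemble_profile(db: FoodDatabase, gender: str, cfg: GeneratorConfig,
                      o: np.ndarray, r: np.ndarray,
                      rng: np.random.Generator) -> PopulationProfile:
    n = len(db)
    widen = 1.0 if cfg.bounds_per_gender else 1.25
    zero_lo = rng.random(n) < cfg.zero_p10_fraction
    lo_f = rng.uniform(0.2, 0.6, size=n) / widen
    hi_f = rng.uniform(1.6, 2.4, size=n) * widen

    lower = np.where(zero_lo, 0.0, lo_f * np.minimum(o, r))
    upper = hi_f * np.maximum(o, r) + 10.0 * widen

    l1_lower: dict[str, float] = {}
    l1_upper: dict[str, float] = {}
    for l1 in db.l1_groups:
        mask = db.l1_mask(l1)
        g_o, g_r = float(o[mask].sum()), float(r[mask].sum())
        l1_lower[l1] = 0.5 / widen * min(g_o, g_r)
        l1_upper[l1] = 1.8 * widen * max(g_o, g_r) + 20.0 * widen

    e = db.composition(ENERGY_CODE)
    liq = db.liquid_mask
    special_caps = {
        flag: float(o[db.flag_mask(flag)].sum())
        for flag in ("alcoholic_beverage", "fish_oil", "offal")
        if db.flag_mask(flag).any()
    }
    return PopulationProfile(
        label=f"synthetic-{gender}",
        gender=gender,
        body_weight_kg=cfg.body_weight_kg[gender],
        observed=DietVector.from_array(db, o),
        item_lower={iid: float(v) for iid, v in zip(db.item_ids, lower)},
        item_upper={iid: float(v) for iid, v in zip(db.item_ids, upper)},
        l1_lower=l1_lower,
        l1_upper=l1_upper,
        energy_obs_kcal=float(o @ e),
        solid_liquid_ratio_obs=float(o[~liq].sum() / o[liq].sum()),
        special_caps=special_caps,
    )


def generate_population(db: FoodDatabase, gender: str, cfg: GeneratorConfig) -> PopulationProfile:
    """Generate one gender's population profile (observed diet, percentile
    envelopes, observed totals); NUTR feasibility is guaranteed by the
    internally constructed reference diet."""
    profile, _ = generate_population_with_certificate(db, gender, cfg)
    return profile
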