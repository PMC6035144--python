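import numpy as np
import pytest

from dietopt import (
    DietVector,
    FoodDatabase,
    FoodItem,
    GeneratorConfig,
    PopulationProfile,
    generate_database,
    generate_population_with_certificate,
    run_ladder,
)


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_db(default_cfg) -> FoodDatabase:
    return generate_database(default_cfg)


@pytest.fixture(scope="session")
def women(default_db, default_cfg):
    """(profile, certificate) for the default women population."""
    return generate_population_with_certificate(default_db, "women", default_cfg)


@pytest.fixture(scope="session")
def men(default_db, default_cfg):
    return generate_population_with_certificate(default_db, "men", default_cfg)


@pytest.fixture(scope="session")
def women_ladder(default_db, women):
    profile, _ = women
    return run_ladder(default_db, profile)


def make_toy_db(specs) -> FoodDatabase:
    """Small hand-built database.

    ``specs``: iterable of dicts with keys item_id, and optionally
    energy (kcal/g), ghge (g CO2eq/g), liquid, l1, main, plus any
    nutrient code mapped to its per-gram amount.
    """
    items = []
    for spec in specs:
        spec = dict(spec)
        iid = spec.pop("item_id")
        comp = {"energy_kcal": spec.pop("energy", 1.0)}
        ghge = spec.pop("ghge", 1.0)
        liquid = spec.pop("liquid", False)
        l1 = spec.pop("l1", "toy_l1")
        main = spec.pop("main", "toy_main")
        comp.update(spec)
        items.append(
            FoodItem(
                item_id=iid,
                name=iid,
                l1_group=l1,
                main_group=main,
                nutrient_comp=comp,
                ghge_intensity=ghge,
                is_liquid=liquid,
            )
        )
    return FoodDatabase(items)


def make_toy_profile(db: FoodDatabase, observed: dict[str, float],
                     gender: str = "women", body_weight_kg: float = 70.0,
                     **kwargs) -> PopulationProfile:
    energy = float(
        sum(q * db.items[db.index[i]].nutrient_comp["energy_kcal"]
            for i, q in observed.items())
    )
    defaults = dict(
        label="toy", gender=gender, body_weight_kg=body_weight_kg,
        observed=DietVector(observed),
        item_lower={}, item_upper={}, l1_lower={}, l1_upper={},
        energy_obs_kcal=energy, solid_liquid_ratio_obs=1.0,
    )
    defaults.update(kwargs)
    return PopulationProfile(**defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
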