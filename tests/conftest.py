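import numpy as np
import pytest

from dietopt import (
    NUTRIENT_PANEL,
    DietVector,
    FoodItem,
    FoodList,
    GeneratorConfig,
    generate_calibrated_database,
)

PANEL_IDS = [nid for nid, _ in NUTRIENT_PANEL]


def make_food(
    food_id: str,
    category: str = "other",
    energy: float = 100.0,
    carbon: float = 0.1,
    baseline: float = 100.0,
    popularity: float = 1.0,
    max_intake: float | None = None,
    lactose: float = 0.0,
    **nutrients: float,
) -> FoodItem:
    """Food with explicit per-100 g nutrient values, zeros elsewhere."""
    vec = np.zeros(len(PANEL_IDS))
    for nid, value in nutrients.items():
        vec[PANEL_IDS.index(nid)] = value
    return FoodItem(
        food_id=food_id,
        name=food_id,
        category=category,
        energy=energy,
        nutrients=vec,
        carbon=carbon,
        baseline_intake=baseline,
        popularity_weight=popularity,
        max_intake=max_intake,
        lactose=lactose,
    )


def make_foodlist(*items: FoodItem) -> FoodList:
    return FoodList(list(items))


def make_diet(amounts, foods: FoodList) -> DietVector:
    return DietVector(np.asarray(amounts, float), foods.food_ids)


@pytest.fixture(scope="session")
def calibrated_db():
    """Default-size calibrated synthetic database (250 foods, seed 1)."""
    return generate_calibrated_database(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_db():
    """Reduced database for cap-sweep tests (same structure, fewer foods)."""
    from dietopt import CategorySpec

    cats = (
        CategorySpec("fish", 4, (100, 250), (0.30, 0.60), 15, 12.0),
        CategorySpec("meat", 8, (150, 350), (0.80, 2.80), 110, 0.6),
        CategorySpec("dairy", 8, (40, 360), (0.10, 0.95), 350, 0.4),
        CategorySpec("eggs", 3, (130, 200), (0.20, 0.35), 15, 1.8),
        CategorySpec("vegetables", 10, (15, 80), (0.03, 0.15), 150, 0.05),
        CategorySpec("legumes", 4, (70, 130), (0.05, 0.12), 10, 0.01),
        CategorySpec("fruits", 6, (30, 90), (0.03, 0.12), 110, 0.005),
        CategorySpec("nuts_seeds", 4, (450, 650), (0.15, 0.35), 10, 0.005),
        CategorySpec("potatoes_tubers", 3, (70, 110), (0.03, 0.06), 100, 0.005),
        CategorySpec("bread_cereals", 10, (220, 380), (0.07, 0.15), 200, 0.8),
        CategorySpec("oils_fats", 6, (360, 900), (0.15, 0.55), 40, 3.0),
        CategorySpec("cakes", 5, (300, 500), (0.15, 0.35), 50, 0.1),
        CategorySpec("sugar_snacks", 6, (350, 550), (0.10, 0.45), 50, 0.02),
        CategorySpec("drinks", 7, (20, 60), (0.02, 0.12), 1200, 0.01),
        CategorySpec("other", 3, (50, 300), (0.05, 0.50), 30, 0.05),
    )
    return generate_calibrated_database(GeneratorConfig(categories=cats, seed=7))
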