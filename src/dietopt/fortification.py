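"""Vitamin-D-fortified food variants and the fortificant's carbon cost.

Fortification adds microgram quantities of vitamin D3 per 100 g of a
vehicle food (defaults: semi-skimmed milk 2, whole grain bread 6,
vegetable oil 15 ug/100 g).  The fortificant itself carries a footprint of
at most 200 kg CO2 eq per kg of pure vitamin D3; at these addition levels
that raises a food's footprint by about a part in 10^5 (~0.001 %), so
fortification is carbon-neutral at the level of a whole diet.  The
fortificant's mass and energy are negligible and left out of the
composition entirely; only the carbon increment is booked.

Staple vehicles consumed in fairly fixed amounts (bread, milk) are capped
at two servings per day so the optimizer cannot propose implausibly large
intakes of a single fortified item.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
import yaml

from .food_model import FoodItem, FoodList

__all__ = [
    "FORTIFICANT_FOOTPRINT_DEFAULT",
    "FortificationSpec",
    "make_fortified_variant",
    "relative_carbon_increment",
    "apply_serving_caps",
    "add_fortified_options",
    "read_fortification_specs",
]

#: kg CO2 eq per kg of pure vitamin D3 (upper estimate for the fortificant).
FORTIFICANT_FOOTPRINT_DEFAULT = 200.0

_UG_PER_KG = 1e9


@dataclass(frozen=True)
class FortificationSpec:
    """Fortify ``base_food_id`` with ``level`` ug of ``nutrient_id`` per 100 g.

    ``serving_size`` (g) times ``max_servings_per_day`` gives the intake cap
    of the fortified variant; ``max_servings_per_day=None`` leaves it
    uncapped (the default for oil).
    """

    base_food_id: str
    nutrient_id: str = "vitamin_d"
    level: float = 0.0  # ug per 100 g
    serving_size: float | None = None  # g
    max_servings_per_day: int | None = None
    fortificant_footprint: float = FORTIFICANT_FOOTPRINT_DEFAULT  # kg CO2e / kg

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("fortification level must be >= 0")
        if self.fortificant_footprint < 0:
            raise ValueError("fortificant footprint must be >= 0")
        if self.max_servings_per_day is not None:
            if self.serving_size is None or not self.serving_size > 0:
                raise ValueError("serving_size must be > 0 when max_servings is set")
            if self.max_servings_per_day < 0:
                raise ValueError("max_servings_per_day must be >= 0")

    @property
    def max_intake(self) -> float | None:
        if self.max_servings_per_day is None:
            return None
        return self.serving_size * self.max_servings_per_day

    @property
    def carbon_increment(self) -> float:
        """kg CO2 eq added per 100 g of food."""
        return (self.level / _UG_PER_KG) * self.fortificant_footprint

    @property
    def fortified_id(self) -> str:
        return f"{self.base_food_id}__fortified"


def make_fortified_variant(food: FoodItem, spec: FortificationSpec, foods: FoodList) -> FoodItem:
    """New food with the fortified nutrient raised by ``spec.level``.

    Energy and all other nutrients are untouched (the fortificant is added
    at the microgram scale); carbon rises by the fortificant increment.
    The variant starts outside the baseline diet (intake 0) and carries the
    serving cap when one is specified.
    """
    if spec.base_food_id != food.food_id:
        raise ValueError(
            f"spec targets {spec.base_food_id!r} but food is {food.food_id!r}"
        )
    k = foods.nutrient_index(spec.nutrient_id)
    unit = foods.nutrient_unit(spec.nutrient_id)
    if unit != "ug":
        raise ValueError(f"fortification levels are ug/100 g; {spec.nutrient_id} panel unit is {unit}")
    nutrients = food.nutrients.copy()
    nutrients[k] += spec.level
    return replace(
        food,
        food_id=spec.fortified_id,
        name=f"{food.name} (fortified)",
        nutrients=nutrients,
        carbon=food.carbon + spec.carbon_increment,
        baseline_intake=0.0,
        max_intake=spec.max_intake,
        is_fortified=True,
    )


def relative_carbon_increment(spec: FortificationSpec, base_carbon: float) -> float:
    """Fortificant carbon divided by the vehicle's own footprint.

    E.g. 15 ug/100 g on a 0.3 kg CO2e/100 g oil: (15e-9 kg * 200) / 0.3
    = 1e-5, i.e. ~0.001 %.
    """
    if not base_carbon > 0:
        raise ValueError("base carbon footprint must be positive")
    return spec.carbon_increment / base_carbon


def apply_serving_caps(foods: FoodList, specs: list[FortificationSpec]) -> FoodList:
    """Set max_intake = serving_size * max_servings on fortified variants.

    Specs without a serving cap leave their food unchanged.  Referencing a
    food absent from the list is an error.
    """
    by_id = {spec.fortified_id: spec for spec in specs}
    known = set(foods.food_ids)
    for fid in by_id:
        if fid not in known:
            raise ValueError(f"serving-cap spec references unknown food {fid!r}")
    items = []
    for f in foods.items:
        spec = by_id.get(f.food_id)
        if spec is not None and spec.max_servings_per_day is not None:
            f = replace(f, max_intake=spec.max_intake)
        items.append(f)
    return foods.with_items(items)


def add_fortified_options(foods: FoodList, specs: list[FortificationSpec]) -> FoodList:
    """Append fortified variants (with serving caps) to the food repertoire."""
    by_id = {f.food_id: f for f in foods.items}
    items = list(foods.items)
    for spec in specs:
        base = by_id.get(spec.base_food_id)
        if base is None:
            raise ValueError(f"fortification spec references unknown food {spec.base_food_id!r}")
        items.append(make_fortified_variant(base, spec, foods))
    return foods.with_items(items)


def read_fortification_specs(path) -> list[FortificationSpec]:
    """Load specs from YAML (list of mappings) or CSV.

    Columns/keys: base_food_id, nutrient, level_ug_100g, serving_g,
    max_servings, fortificant_kgco2e_per_kg.
    """
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or []
        rows = raw if isinstance(raw, list) else raw.get("fortified_options", [])
    else:
        rows = pd.read_csv(path).to_dict("records")
    specs = []
    for row in rows:
        max_servings = row.get("max_servings")
        if max_servings is not None and pd.isna(max_servings):
            max_servings = None
        serving = row.get("serving_g")
        if serving is not None and pd.isna(serving):
            serving = None
        specs.append(
            FortificationSpec(
                base_food_id=str(row["base_food_id"]),
                nutrient_id=str(row.get("nutrient", "vitamin_d")),
                level=float(row["level_ug_100g"]),
                serving_size=None if serving is None else float(serving),
                max_servings_per_day=None if max_servings is None else int(max_servings),
                fortificant_footprint=float(
                    row.get("fortificant_kgco2e_per_kg", FORTIFICANT_FOOTPRINT_DEFAULT)
                ),
            )
        )
    return specs
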