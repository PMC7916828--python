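"""Synthetic food-composition databases with a calibrated vitamin D gap.

National food-consumption and composition databases (food surveys, NEVO-
style composition tables, LCA footprints) are licensed and cannot ship
with the package.  This module generates databases with the statistical
structure the analysis assumes, so that every stage of the pipeline is
testable end to end:

* ~250 foods in 15 report categories, per-100 g nutrient contents drawn
  from right-skewed lognormals with category-specific abundance patterns
  (omega-3 in fish, calcium in dairy, fiber in plants, ...);
* a population-average baseline diet rescaled to 2243 kcal/day and a
  ~3.9 kg CO2 eq/day footprint, with animal-source categories more
  carbon-intensive than plant categories;
* a calibrated vitamin D gap: the 2000 kcal-standardized baseline supplies
  ~21 % of the adjusted adequate intake (13.4 ug/d), vitamin D is the
  first-limiting nutrient, baseline MAR sits near 86 %, and — verified by
  solving the maximization LP during calibration — the most vitamin D
  achievable within 2000 kcal *without* extra fortified foods stays
  strictly below the adequate intake.

Calibration proceeds in a fixed order (energy rescale, carbon rescale,
per-nutrient adequacy/excess rescale, vitamin D rescale + gap iteration);
the per-nutrient rescales are exact, so baseline adequacy ratios equal
their configured targets by construction and the generator never needs to
certify itself — the test suite re-derives every property through the
public metrics and optimizer operations.

Everything is driven by one integer seed through numpy's Generator;
identical seeds give identical databases, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .food_model import (
    NUTRIENT_PANEL,
    DietVector,
    FoodItem,
    FoodList,
    default_popularity,
    diet_totals,
)
from .metrics import density_report, standardize_to_energy
from .reference_model import ReferenceSet, default_reference_set, to_linear_bounds
from scipy import optimize

__all__ = [
    "CategorySpec",
    "GeneratorConfig",
    "CalibrationError",
    "default_categories",
    "generate_food_database",
    "calibrate_vitamin_d_gap",
    "generate_calibrated_database",
    "ANIMAL_CATEGORIES",
    "PLANT_CATEGORIES",
]

ANIMAL_CATEGORIES = ("fish", "meat", "dairy", "eggs")
PLANT_CATEGORIES = (
    "vegetables",
    "legumes",
    "fruits",
    "nuts_seeds",
    "potatoes_tubers",
    "bread_cereals",
)


class CalibrationError(RuntimeError):
    """Raised when the configured calibration targets cannot be met."""


@dataclass(frozen=True)
class CategorySpec:
    """One report category: food count, energy/carbon ranges, intake share.

    ``energy_range`` is kcal/100 g, ``carbon_range`` kg CO2 eq/100 g (both
    uniform draw ranges), ``intake_g`` the category's total baseline intake
    in g/day before the global energy rescale, ``vitamin_d_mean`` the
    pre-calibration mean vitamin D content in ug/100 g.
    """

    name: str
    n_foods: int
    energy_range: tuple[float, float]
    carbon_range: tuple[float, float]
    intake_g: float
    vitamin_d_mean: float

    def __post_init__(self) -> None:
        for lo, hi in (self.energy_range, self.carbon_range):
            if not (0 < lo <= hi):
                raise ValueError(f"{self.name}: ranges must be positive and ordered")
        if self.n_foods < 1 or self.intake_g < 0 or self.vitamin_d_mean < 0:
            raise ValueError(f"{self.name}: bad category spec")


def default_categories() -> list[CategorySpec]:
    """15 categories, 250 foods, Dutch-style intake pattern."""
    return [
        CategorySpec("fish", 12, (100, 250), (0.30, 0.60), 15, 12.0),
        CategorySpec("meat", 25, (150, 350), (0.80, 2.80), 110, 0.6),
        CategorySpec("dairy", 25, (40, 360), (0.10, 0.95), 350, 0.4),
        CategorySpec("eggs", 6, (130, 200), (0.20, 0.35), 15, 1.8),
        CategorySpec("vegetables", 30, (15, 80), (0.03, 0.15), 150, 0.05),
        CategorySpec("legumes", 10, (70, 130), (0.05, 0.12), 10, 0.01),
        CategorySpec("fruits", 20, (30, 90), (0.03, 0.12), 110, 0.005),
        CategorySpec("nuts_seeds", 10, (450, 650), (0.15, 0.35), 10, 0.005),
        CategorySpec("potatoes_tubers", 8, (70, 110), (0.03, 0.06), 100, 0.005),
        CategorySpec("bread_cereals", 30, (220, 380), (0.07, 0.15), 200, 0.8),
        CategorySpec("oils_fats", 15, (360, 900), (0.15, 0.55), 40, 3.0),
        CategorySpec("cakes", 15, (300, 500), (0.15, 0.35), 50, 0.1),
        CategorySpec("sugar_snacks", 20, (350, 550), (0.10, 0.45), 50, 0.02),
        CategorySpec("drinks", 18, (20, 60), (0.02, 0.12), 1200, 0.01),
        CategorySpec("other", 6, (50, 300), (0.05, 0.50), 30, 0.05),
    ]


# Baseline adequacy targets (% of the energy-adjusted RNI/AI supplied by the
# 2000 kcal-standardized baseline).  Fourteen nutrients sit below their
# reference, twelve above; the truncated mean is exactly the 86 % MAR
# target, with vitamin D lowest (first-limiting) at 21 %.
DEFAULT_ADEQUACY_TARGETS: dict[str, float] = {
    "vitamin_d": 21.0,
    "epa_dha": 40.0,
    "fiber": 62.0,
    "vitamin_a": 68.0,
    "folate": 70.0,
    "potassium": 72.0,
    "magnesium": 75.0,
    "iron": 78.0,
    "vitamin_e": 84.0,
    "selenium": 87.0,
    "zinc": 90.0,
    "copper": 92.0,
    "calcium": 98.0,
    "vitamin_c": 99.0,
    "protein": 115.0,
    "vitamin_k": 120.0,
    "thiamin": 105.0,
    "riboflavin": 110.0,
    "niacin": 130.0,
    "pantothenic_acid": 108.0,
    "vitamin_b6": 112.0,
    "vitamin_b12": 180.0,
    "biotin": 104.0,
    "phosphorus": 160.0,
    "iodine": 103.0,
    "manganese": 118.0,
}

# Baseline excess targets (% of MRV) averaging to a 120 % MER.
DEFAULT_EXCESS_TARGETS: dict[str, float] = {
    "total_fat": 110.0,
    "saturated_fat": 135.0,
    "trans_fat": 90.0,
    "cholesterol": 105.0,
    "added_sugars": 150.0,
    "sodium": 130.0,
}

# Per-nutrient base content (canonical unit per 100 g) and per-category
# relative abundance multipliers.  Absolute levels of calibrated nutrients
# only matter through their cross-category ratios — the calibration step
# rescales each column to its baseline target exactly.
_BASE_CONTENT: dict[str, float] = {
    "protein": 5.0, "fiber": 1.2, "epa_dha": 8.0, "vitamin_a": 60.0,
    "vitamin_e": 0.8, "vitamin_k": 8.0, "thiamin": 0.06, "riboflavin": 0.08,
    "niacin": 1.0, "pantothenic_acid": 0.4, "vitamin_b6": 0.12, "folate": 20.0,
    "vitamin_b12": 0.5, "vitamin_c": 5.0, "biotin": 3.0, "calcium": 40.0,
    "phosphorus": 80.0, "magnesium": 20.0, "iron": 0.8, "zinc": 0.7,
    "copper": 0.08, "selenium": 4.0, "iodine": 6.0, "potassium": 180.0,
    "manganese": 0.3, "total_fat": 3.0, "saturated_fat": 1.2, "trans_fat": 0.06,
    "cholesterol": 12.0, "sodium": 150.0, "mono_di_saccharides": 3.0,
    "carbohydrate": 8.0, "monounsaturated_fat": 1.2, "polyunsaturated_fat": 0.8,
    "alcohol": 0.0,
}

_CATEGORY_MULT: dict[str, dict[str, float]] = {
    "protein": {"meat": 4, "fish": 4, "eggs": 3, "dairy": 2, "legumes": 3,
                "nuts_seeds": 3, "bread_cereals": 1.8, "drinks": 0.05, "fruits": 0.1,
                "sugar_snacks": 0.3, "oils_fats": 0.1},
    "fiber": {"bread_cereals": 6, "legumes": 8, "vegetables": 4, "fruits": 3,
              "nuts_seeds": 5, "potatoes_tubers": 2.5, "meat": 0.02, "fish": 0.02,
              "dairy": 0.02, "eggs": 0.02, "oils_fats": 0.02, "drinks": 0.05},
    "epa_dha": {"fish": 200, "eggs": 2, "meat": 1, "vegetables": 0, "legumes": 0,
                "fruits": 0, "nuts_seeds": 0, "potatoes_tubers": 0,
                "bread_cereals": 0, "oils_fats": 0.5, "cakes": 0,
                "sugar_snacks": 0, "drinks": 0, "other": 0, "dairy": 0.3},
    "vitamin_a": {"vegetables": 5, "dairy": 2, "eggs": 3, "meat": 2, "oils_fats": 2,
                  "drinks": 0.1, "sugar_snacks": 0.1},
    "vitamin_e": {"oils_fats": 8, "nuts_seeds": 6, "vegetables": 1.2, "drinks": 0.05},
    "vitamin_k": {"vegetables": 10, "oils_fats": 2, "legumes": 1.5, "drinks": 0.05},
    "thiamin": {"meat": 2, "bread_cereals": 2, "legumes": 2, "potatoes_tubers": 1.5,
                "drinks": 0.1},
    "riboflavin": {"dairy": 3, "meat": 2, "eggs": 2, "bread_cereals": 1.5, "drinks": 0.1},
    "niacin": {"meat": 3, "fish": 3, "bread_cereals": 2, "drinks": 0.2},
    "pantothenic_acid": {"meat": 1.5, "eggs": 2, "dairy": 1.5, "drinks": 0.1},
    "vitamin_b6": {"meat": 2, "fish": 2, "potatoes_tubers": 2, "fruits": 1.5, "drinks": 0.1},
    "folate": {"vegetables": 6, "legumes": 5, "fruits": 2, "bread_cereals": 2,
               "eggs": 2, "drinks": 0.1},
    "vitamin_b12": {"fish": 8, "meat": 6, "dairy": 3, "eggs": 5, "vegetables": 0,
                    "legumes": 0, "fruits": 0, "nuts_seeds": 0, "potatoes_tubers": 0,
                    "bread_cereals": 0, "oils_fats": 0, "cakes": 0.2,
                    "sugar_snacks": 0, "drinks": 0, "other": 0.2},
    "vitamin_c": {"fruits": 8, "vegetables": 6, "potatoes_tubers": 3, "drinks": 2,
                  "meat": 0.05, "fish": 0.05, "bread_cereals": 0.05, "oils_fats": 0},
    "biotin": {"eggs": 2, "nuts_seeds": 2, "dairy": 1.5, "drinks": 0.1},
    "calcium": {"dairy": 10, "nuts_seeds": 2, "vegetables": 1.5, "legumes": 1.5,
                "drinks": 0.3, "oils_fats": 0.2},
    "phosphorus": {"dairy": 2.5, "meat": 2, "fish": 2, "bread_cereals": 1.5,
                   "drinks": 0.1, "oils_fats": 0.1},
    "magnesium": {"nuts_seeds": 4, "legumes": 3, "bread_cereals": 2.5,
                  "vegetables": 1.5, "drinks": 0.2},
    "iron": {"meat": 3, "legumes": 3, "bread_cereals": 2, "vegetables": 1.5,
             "eggs": 2, "drinks": 0.05, "dairy": 0.2},
    "zinc": {"meat": 4, "dairy": 2, "bread_cereals": 1.5, "nuts_seeds": 2,
             "legumes": 2, "drinks": 0.05},
    "copper": {"nuts_seeds": 3, "legumes": 2, "bread_cereals": 1.5, "drinks": 0.1},
    "selenium": {"fish": 6, "meat": 3, "eggs": 3, "bread_cereals": 2,
                 "nuts_seeds": 3, "drinks": 0.05},
    "iodine": {"fish": 10, "dairy": 3, "eggs": 2, "bread_cereals": 2, "drinks": 0.05},
    "potassium": {"potatoes_tubers": 4, "fruits": 3, "vegetables": 3, "legumes": 3,
                  "dairy": 1.5, "drinks": 0.5, "oils_fats": 0.1},
    "manganese": {"bread_cereals": 3, "nuts_seeds": 3, "legumes": 2,
                  "vegetables": 1.5, "drinks": 1.0},
    "total_fat": {"oils_fats": 10, "nuts_seeds": 8, "cakes": 4, "meat": 3,
                  "dairy": 1.5, "sugar_snacks": 3, "fish": 1.5, "eggs": 2,
                  "vegetables": 0.05, "fruits": 0.05, "potatoes_tubers": 0.05,
                  "drinks": 0.02, "legumes": 0.3},
    "saturated_fat": {"oils_fats": 6, "cakes": 4, "dairy": 2.5, "meat": 3,
                      "sugar_snacks": 2.5, "eggs": 2, "fish": 1,
                      "vegetables": 0.02, "fruits": 0.02, "potatoes_tubers": 0.02,
                      "drinks": 0.02, "legumes": 0.2, "nuts_seeds": 2},
    "trans_fat": {"cakes": 4, "dairy": 2, "meat": 2, "oils_fats": 2,
                  "sugar_snacks": 2, "vegetables": 0.01, "fruits": 0.01,
                  "legumes": 0.01, "nuts_seeds": 0.05, "potatoes_tubers": 0.01,
                  "bread_cereals": 0.2, "drinks": 0.01, "fish": 0.2, "eggs": 0.2},
    "cholesterol": {"eggs": 15, "meat": 4, "fish": 3, "dairy": 2, "cakes": 2,
                    "vegetables": 0, "legumes": 0, "fruits": 0, "nuts_seeds": 0,
                    "potatoes_tubers": 0, "bread_cereals": 0.02, "oils_fats": 0.5,
                    "sugar_snacks": 0.3, "drinks": 0},
    "sodium": {"bread_cereals": 3, "meat": 3, "sugar_snacks": 3, "fish": 2,
               "cakes": 1.5, "dairy": 1.2, "drinks": 0.05, "fruits": 0.02,
               "vegetables": 0.3},
    "mono_di_saccharides": {"sugar_snacks": 8, "cakes": 5, "drinks": 3, "fruits": 3,
                            "vegetables": 0.5, "meat": 0.05, "fish": 0.02,
                            "oils_fats": 0.05, "eggs": 0.05, "bread_cereals": 0.5},
    "carbohydrate": {"bread_cereals": 6, "potatoes_tubers": 3, "sugar_snacks": 8,
                     "cakes": 5, "drinks": 1.5, "fruits": 2, "legumes": 2,
                     "meat": 0.05, "fish": 0.02, "oils_fats": 0.02, "eggs": 0.05},
    "monounsaturated_fat": {"oils_fats": 10, "nuts_seeds": 8, "meat": 2,
                            "cakes": 3, "drinks": 0.02, "vegetables": 0.05},
    "polyunsaturated_fat": {"oils_fats": 10, "nuts_seeds": 8, "fish": 3,
                            "cakes": 2, "drinks": 0.02, "vegetables": 0.05},
    "alcohol": {},
}

_LOGNORMAL_SIGMA = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic database.

    Defaults reproduce the study conditions: 250 foods in 15 categories,
    2243 kcal/day baseline energy, ~3.9 kg CO2 eq/day baseline footprint,
    86 % baseline MAR with vitamin D first-limiting at 21 % of its
    adjusted adequate intake.
    """

    categories: tuple[CategorySpec, ...] = field(
        default_factory=lambda: tuple(default_categories())
    )
    seed: int = 1
    baseline_energy_target: float = 2243.0
    baseline_co2_target: float = 3.9
    mar_target: float = 86.0
    mar_tolerance: float = 2.0
    vitamin_d_adequacy_target: float = 21.0  # percent of the adjusted AI
    adequacy_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADEQUACY_TARGETS)
    )
    excess_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCESS_TARGETS)
    )
    # the vitamin D maximum achievable within the energy cap (no extra
    # fortified foods) must end up at or below this fraction of the AI
    gap_max_fraction: float = 0.95
    max_calibration_iterations: int = 50

    @property
    def n_foods(self) -> int:
        return sum(c.n_foods for c in self.categories)

    def validate(self) -> None:
        if not self.categories:
            raise ValueError("at least one category required")
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("duplicate category names")
        if not 0 < self.vitamin_d_adequacy_target:
            raise ValueError("vitamin_d_adequacy_target must be positive")
        if self.vitamin_d_adequacy_target < 100 and not self.gap_max_fraction < 1.0:
            raise ValueError("gap_max_fraction must be < 1 when a gap is requested")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_food_database(config: GeneratorConfig | None = None) -> tuple[FoodList, DietVector]:
    """Draw the food database and baseline diet (pre-gap-calibration).

    Per-category nutrient contents are lognormal draws around
    category-specific means; baseline intakes are drawn per category and
    rescaled so total energy equals the target exactly; carbon intensities
    are rescaled so the baseline footprint equals its target exactly.
    Deterministic for a fixed seed.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    items: list[FoodItem] = []
    intakes: list[float] = []
    for cat in config.categories:
        n = cat.n_foods
        energy = rng.uniform(*cat.energy_range, size=n)
        carbon = rng.uniform(*cat.carbon_range, size=n)
        noise = rng.lognormal(0.0, _LOGNORMAL_SIGMA, size=(n, len(NUTRIENT_PANEL)))
        lactose = (
            rng.uniform(3.5, 5.0, size=n) if cat.name == "dairy" else np.zeros(n)
        )
        monodi_dairy = lactose * rng.uniform(1.0, 1.4, size=n)
        shares = rng.lognormal(0.0, 1.0, size=n)
        shares = shares / shares.sum() * cat.intake_g
        for j in range(n):
            nut = np.empty(len(NUTRIENT_PANEL))
            for k, (nid, _) in enumerate(NUTRIENT_PANEL):
                if nid == "vitamin_d":
                    nut[k] = cat.vitamin_d_mean * noise[j, k]
                elif nid == "mono_di_saccharides" and cat.name == "dairy":
                    nut[k] = monodi_dairy[j]
                else:
                    mult = _CATEGORY_MULT.get(nid, {}).get(cat.name, 1.0)
                    nut[k] = _BASE_CONTENT[nid] * mult * noise[j, k]
            items.append(
                FoodItem(
                    food_id=f"{cat.name}_{j:03d}",
                    name=f"{cat.name} item {j}",
                    category=cat.name,
                    energy=float(energy[j]),
                    nutrients=nut,
                    carbon=float(carbon[j]),
                    baseline_intake=float(shares[j]),
                    popularity_weight=1.0,
                    lactose=float(lactose[j]),
                )
            )
            intakes.append(float(shares[j]))

    foods = FoodList(items)
    baseline = DietVector(np.array(intakes), foods.food_ids)

    # energy rescale: intakes scaled so the baseline hits the kcal target
    totals = diet_totals(baseline, foods)
    if not totals.energy > 0:
        raise CalibrationError("generated baseline has zero energy")
    baseline = baseline.scaled(config.baseline_energy_target / totals.energy)

    # carbon rescale: intensities scaled so the baseline footprint hits its
    # target (preserves the animal > plant intensity ordering)
    totals = diet_totals(baseline, foods)
    if not totals.carbon > 0:
        raise CalibrationError("generated baseline has zero carbon footprint")
    cfac = config.baseline_co2_target / totals.carbon
    foods = foods.with_items([replace(f, carbon=f.carbon * cfac) for f in foods.items])

    # popularity: intake-frequency proxy, mean 1 over consumed foods
    pop = default_popularity(baseline.amounts)
    foods = foods.with_items(
        [replace(f, popularity_weight=float(w), baseline_intake=float(b))
         for f, w, b in zip(foods.items, pop, baseline.amounts)]
    )
    return foods, baseline


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def _max_vitamin_d_lp(
    foods: FoodList, refs_adjusted: ReferenceSet, energy_cap: float
) -> tuple[float, np.ndarray]:
    """Stage-1 LP of the no-new-fortification analogue: max vitamin D
    subject to all references except the vitamin D lower bound, within the
    energy cap.  Returns (max ug/day, argmax diet)."""
    cons = to_linear_bounds(refs_adjusted, foods)
    cons = cons.drop(lambda r: r.label == "vitamin_d:lower")
    cons.add(foods.energy_per_gram(), "<=", energy_cap, "energy:upper")
    n = len(foods)
    c = foods.nutrient_per_gram("vitamin_d")
    a_ub, b_ub, a_eq, b_eq, bounds = cons.as_linprog(n)
    res = optimize.linprog(
        -c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    if res.status == 3:
        raise CalibrationError("vitamin D maximization unbounded (no effective cap)")
    if res.status != 0:
        raise CalibrationError(
            f"reference constraints infeasible within {energy_cap} kcal: {res.message}"
        )
    return float(-res.fun), res.x


def calibrate_vitamin_d_gap(
    foods: FoodList,
    baseline: DietVector,
    refs: ReferenceSet | None = None,
    config: GeneratorConfig | None = None,
) -> FoodList:
    """Rescale nutrient contents so the baseline matches its adequacy and
    excess targets and the vitamin D gap has the intended structure.

    Steps (exact column rescales computed on the 2000 kcal-standardized
    baseline):

    1. every qualifying nutrient except vitamin D → its adequacy target;
    2. every nutrient-to-limit → its excess target (added sugars via the
       mono+di-saccharide contents of the non-dairy added-sugar categories);
    3. vitamin D → its adequacy target (21 % of the adjusted AI);
    4. gap iteration: while the maximum vitamin D achievable within the
       energy cap (solved as an LP) exceeds ``gap_max_fraction`` of the AI,
       shrink the vitamin D content of the category carrying most of the
       LP optimum and re-normalize the baseline back to its target.

    Raises :class:`CalibrationError` when targets cannot be met within the
    iteration budget or the constraint system is infeasible.
    """
    config = config or GeneratorConfig()
    refs = refs or default_reference_set()
    adj = refs.adjusted()
    target_energy = adj.target_energy

    std = standardize_to_energy(baseline, foods, target_energy)

    def std_totals():
        return diet_totals(std, foods)

    # --- qualifying nutrients (vitamin D handled last) -------------------
    for ref in adj.qualifying:
        nid = ref.nutrient_id
        if nid == "vitamin_d":
            continue
        target_pct = config.adequacy_targets.get(nid)
        if target_pct is None:
            continue
        current = std_totals()[nid]
        if not current > 0:
            raise CalibrationError(f"{nid}: baseline supplies none; cannot rescale")
        foods = foods.scale_nutrient(nid, target_pct / 100.0 * ref.lower / current)

    # --- nutrients to limit ---------------------------------------------
    for ref in adj.disqualifying:
        nid = ref.nutrient_id
        target_pct = config.excess_targets.get(nid)
        if target_pct is None:
            continue
        if ref.basis == "absolute":
            allowed = ref.upper
        else:
            allowed = (ref.upper / 100.0) * target_energy / ref.energy_factor
        target_amount = target_pct / 100.0 * allowed
        if nid == "added_sugars":
            from .food_model import ADDED_SUGAR_CATEGORIES, added_sugar_coefficients

            coeffs = added_sugar_coefficients(foods)
            cats = np.array(foods.categories)
            in_cat = np.isin(cats, list(ADDED_SUGAR_CATEGORIES))
            fixed = float(coeffs[~in_cat] @ std.amounts[~in_cat])  # dairy excess
            scalable = float(coeffs[in_cat] @ std.amounts[in_cat])
            if not scalable > 0:
                raise CalibrationError("no scalable added-sugar foods in database")
            fac = max(0.0, target_amount - fixed) / scalable
            factors = np.where(in_cat, fac, 1.0)
            foods = foods.scale_nutrient("mono_di_saccharides", factors)
        else:
            current = std_totals()[nid]
            if not current > 0:
                raise CalibrationError(f"{nid}: baseline supplies none; cannot rescale")
            foods = foods.scale_nutrient(nid, target_amount / current)

    # --- vitamin D level and gap ----------------------------------------
    vitd_ref = adj["vitamin_d"]
    vitd_target = config.vitamin_d_adequacy_target / 100.0 * vitd_ref.lower

    def normalize_vitd(fl: FoodList) -> FoodList:
        current = diet_totals(std, fl)["vitamin_d"]
        if not current > 0:
            raise CalibrationError("baseline supplies no vitamin D; cannot rescale")
        return fl.scale_nutrient("vitamin_d", vitd_target / current)

    foods = normalize_vitd(foods)
    cap = config.gap_max_fraction * vitd_ref.lower
    cats = np.array(foods.categories)
    achieved = None
    for _ in range(config.max_calibration_iterations):
        max_vitd, x_opt = _max_vitamin_d_lp(foods, adj, target_energy)
        achieved = max_vitd
        if config.vitamin_d_adequacy_target >= 100 or max_vitd <= cap:
            break
        # shrink the dominant carrier category of the LP optimum
        per_gram = foods.nutrient_per_gram("vitamin_d")
        contrib = {
            cat: float(per_gram[cats == cat] @ x_opt[cats == cat])
            for cat in set(foods.categories)
        }
        top = max(contrib, key=contrib.get)
        factors = np.where(cats == top, 0.7, 1.0)
        foods = normalize_vitd(foods.scale_nutrient("vitamin_d", factors))
    else:
        raise CalibrationError(
            f"vitamin D gap not achieved in {config.max_calibration_iterations} "
            f"iterations (max within cap: {achieved:.2f} ug/d vs "
            f"allowed {cap:.2f})"
        )

    # --- final checks via the public metrics -----------------------------
    report = density_report(standardize_to_energy(baseline, foods, target_energy), foods, adj)
    if abs(report.mar - config.mar_target) > config.mar_tolerance:
        raise CalibrationError(
            f"baseline MAR {report.mar:.2f} outside "
            f"{config.mar_target} +/- {config.mar_tolerance}"
        )
    if config.vitamin_d_adequacy_target < 100 and report.first_limiting != ("vitamin_d",):
        raise CalibrationError(
            f"first-limiting nutrient is {report.first_limiting}, expected vitamin_d"
        )
    return foods


def generate_calibrated_database(
    config: GeneratorConfig | None = None,
    refs: ReferenceSet | None = None,
) -> tuple[FoodList, DietVector, ReferenceSet]:
    """Generate + calibrate in one call; returns (foods, baseline, refs)."""
    config = config or GeneratorConfig()
    refs = refs or default_reference_set()
    foods, baseline = generate_food_database(config)
    foods = calibrate_vitamin_d_gap(foods, baseline, refs, config)
    return foods, baseline, refs
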