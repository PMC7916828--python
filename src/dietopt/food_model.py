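"""Food-composition data model and I/O.

A :class:`FoodList` holds one row per food item with a per-100 g nutrient
panel (the convention of national food-composition tables such as NEVO),
an energy density, a cradle-to-fork carbon footprint, a baseline intake in
g/day and a popularity weight.  A :class:`DietVector` is the optimizer's
decision variable: grams per day of every food, aligned to a FoodList.

All per-day quantities are obtained from the per-100 g values through a
single ``amount / 100`` conversion in :func:`diet_totals`; nothing else in
the package rescales food composition data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NUTRIENT_PANEL",
    "QUALIFYING_NUTRIENTS",
    "DISQUALIFYING_NUTRIENTS",
    "ADDED_SUGAR_CATEGORIES",
    "DAIRY_CATEGORY",
    "FoodItem",
    "FoodList",
    "DietVector",
    "DietTotals",
    "read_food_csv",
    "write_food_csv",
    "read_diet_csv",
    "write_diet_csv",
    "diet_totals",
    "added_sugar_coefficients",
    "default_popularity",
]

# ---------------------------------------------------------------------------
# Nutrient panel
# ---------------------------------------------------------------------------

#: Canonical nutrient panel: 36 nutrients, each with its canonical unit
#: (amount per 100 g of food).  The first 26 are the "qualifying" nutrients
#: whose adequacy enters the mean adequacy ratio; the remainder carry the
#: nutrients-to-limit and the macronutrient bookkeeping columns.
NUTRIENT_PANEL: tuple[tuple[str, str], ...] = (
    # qualifying (desired) nutrients
    ("protein", "g"),
    ("fiber", "g"),
    ("epa_dha", "mg"),
    ("vitamin_a", "ug"),
    ("vitamin_d", "ug"),
    ("vitamin_e", "mg"),
    ("vitamin_k", "ug"),
    ("thiamin", "mg"),
    ("riboflavin", "mg"),
    ("niacin", "mg"),
    ("pantothenic_acid", "mg"),
    ("vitamin_b6", "mg"),
    ("folate", "ug"),
    ("vitamin_b12", "ug"),
    ("vitamin_c", "mg"),
    ("biotin", "ug"),
    ("calcium", "mg"),
    ("phosphorus", "mg"),
    ("magnesium", "mg"),
    ("iron", "mg"),
    ("zinc", "mg"),
    ("copper", "mg"),
    ("selenium", "ug"),
    ("iodine", "ug"),
    ("potassium", "mg"),
    ("manganese", "mg"),
    # nutrients to limit and macronutrient bookkeeping
    ("total_fat", "g"),
    ("saturated_fat", "g"),
    ("trans_fat", "g"),
    ("cholesterol", "mg"),
    ("sodium", "mg"),
    ("mono_di_saccharides", "g"),
    ("carbohydrate", "g"),
    ("monounsaturated_fat", "g"),
    ("polyunsaturated_fat", "g"),
    ("alcohol", "g"),
)

#: The 26 nutrients whose percent-of-reference (truncated at 100 %) is
#: averaged into the mean adequacy ratio.
QUALIFYING_NUTRIENTS: tuple[str, ...] = tuple(n for n, _ in NUTRIENT_PANEL[:26])

#: The 6 nutrients-to-limit averaged into the mean excess ratio.  Added
#: sugars are a derived quantity (see :func:`added_sugar_coefficients`),
#: not a raw panel column.
DISQUALIFYING_NUTRIENTS: tuple[str, ...] = (
    "total_fat",
    "saturated_fat",
    "trans_fat",
    "cholesterol",
    "added_sugars",
    "sodium",
)

#: Report categories in which mono- and di-saccharides are treated as
#: almost exclusively added sugars.  Shipped as an editable default; the
#: identification of these categories is a documented reconstruction.
ADDED_SUGAR_CATEGORIES: frozenset[str] = frozenset({"sugar_snacks", "cakes", "drinks"})

#: Category whose mono+di-saccharides are corrected for intrinsic lactose.
DAIRY_CATEGORY = "dairy"

# unit conversion factors to grams
_UNIT_TO_G = {"g": 1.0, "mg": 1e-3, "ug": 1e-6}


def _convert_unit(value: float, unit: str, target: str) -> float:
    try:
        factor = _UNIT_TO_G[unit] / _UNIT_TO_G[target]
    except KeyError as exc:
        raise ValueError(f"unknown unit {exc.args[0]!r}; expected one of g, mg, ug") from None
    return value if factor == 1.0 else value * factor


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoodItem:
    """One food: per-100 g composition plus intake metadata.

    ``nutrients`` is a vector aligned to the panel of the owning
    :class:`FoodList`, in the panel's canonical units per 100 g.
    ``max_intake`` is a hard consumption cap in g/day (``None`` = uncapped),
    used for fortified variants with serving limits.
    """

    food_id: str
    name: str
    category: str
    energy: float  # kcal per 100 g
    nutrients: np.ndarray  # per 100 g, canonical units
    carbon: float  # kg CO2 eq per 100 g
    baseline_intake: float  # g/day
    popularity_weight: float  # dimensionless, >= 0
    max_intake: float | None = None  # g/day
    is_fortified: bool = False
    lactose: float = 0.0  # g per 100 g (dairy)

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise ValueError(f"{self.food_id}: energy must be >= 0")
        if self.carbon < 0:
            raise ValueError(f"{self.food_id}: carbon must be >= 0")
        if self.baseline_intake < 0:
            raise ValueError(f"{self.food_id}: baseline_intake must be >= 0")
        if self.popularity_weight < 0:
            raise ValueError(f"{self.food_id}: popularity_weight must be >= 0")
        if self.max_intake is not None and self.max_intake < 0:
            raise ValueError(f"{self.food_id}: max_intake must be >= 0 when set")
        nut = np.asarray(self.nutrients, dtype=float)
        if np.any(nut < 0):
            raise ValueError(f"{self.food_id}: nutrient amounts must be >= 0")
        object.__setattr__(self, "nutrients", nut)


@dataclass
class FoodList:
    """Ordered collection of foods sharing one nutrient panel."""

    items: list[FoodItem]
    nutrient_panel: tuple[tuple[str, str], ...] = NUTRIENT_PANEL

    def __post_init__(self) -> None:
        ids = [f.food_id for f in self.items]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate food_id: {dup!r}")
        n = len(self.nutrient_panel)
        for f in self.items:
            if f.nutrients.shape != (n,):
                raise ValueError(
                    f"{f.food_id}: nutrient vector length {f.nutrients.shape} "
                    f"does not match panel of {n}"
                )
        self._index = {nid: k for k, (nid, _) in enumerate(self.nutrient_panel)}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def food_ids(self) -> list[str]:
        return [f.food_id for f in self.items]

    @property
    def categories(self) -> list[str]:
        return [f.category for f in self.items]

    def nutrient_index(self, nutrient_id: str) -> int:
        try:
            return self._index[nutrient_id]
        except KeyError:
            raise KeyError(f"nutrient {nutrient_id!r} not in food panel") from None

    def nutrient_unit(self, nutrient_id: str) -> str:
        return self.nutrient_panel[self.nutrient_index(nutrient_id)][1]

    def nutrient_matrix(self) -> np.ndarray:
        """(n_foods, n_nutrients) matrix of per-100 g contents."""
        return np.vstack([f.nutrients for f in self.items]) if self.items else np.empty((0, len(self.nutrient_panel)))

    def nutrient_per_gram(self, nutrient_id: str) -> np.ndarray:
        """Per-gram content of one nutrient over all foods."""
        k = self.nutrient_index(nutrient_id)
        return np.array([f.nutrients[k] for f in self.items]) / 100.0

    def energy_per_gram(self) -> np.ndarray:
        return np.array([f.energy for f in self.items]) / 100.0

    def carbon_per_gram(self) -> np.ndarray:
        return np.array([f.carbon for f in self.items]) / 100.0

    def baseline_vector(self) -> "DietVector":
        return DietVector(np.array([f.baseline_intake for f in self.items]), self.food_ids)

    def popularity_vector(self) -> np.ndarray:
        return np.array([f.popularity_weight for f in self.items])

    def max_intake_vector(self) -> np.ndarray:
        """Upper intake bounds in g/day; +inf where uncapped."""
        return np.array(
            [np.inf if f.max_intake is None else f.max_intake for f in self.items]
        )

    def with_items(self, items: list[FoodItem]) -> "FoodList":
        return FoodList(items, self.nutrient_panel)

    def scale_nutrient(self, nutrient_id: str, factors) -> "FoodList":
        """Return a copy with one nutrient column multiplied per food.

        ``factors`` is a scalar or a per-food array; used by the synthetic
        calibration loop.
        """
        k = self.nutrient_index(nutrient_id)
        fac = np.broadcast_to(np.asarray(factors, dtype=float), (len(self.items),))
        out = []
        for f, a in zip(self.items, fac):
            nut = f.nutrients.copy()
            nut[k] *= a
            out.append(replace(f, nutrients=nut))
        return self.with_items(out)


@dataclass(frozen=True)
class DietVector:
    """g/day per food, aligned to a FoodList."""

    amounts: np.ndarray
    food_ids: Sequence[str] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.amounts, dtype=float)
        if np.any(a < -1e-9):
            raise ValueError("diet amounts must be >= 0")
        object.__setattr__(self, "amounts", np.maximum(a, 0.0))

    def __len__(self) -> int:
        return len(self.amounts)

    def check_aligned(self, foods: FoodList) -> None:
        if len(self.amounts) != len(foods):
            raise ValueError(
                f"diet vector of length {len(self.amounts)} not aligned to "
                f"food list of length {len(foods)}"
            )
        if self.food_ids and list(self.food_ids) != foods.food_ids:
            raise ValueError("diet vector food_ids do not match the food list")

    def scaled(self, factor: float) -> "DietVector":
        return DietVector(self.amounts * factor, self.food_ids)


@dataclass(frozen=True)
class DietTotals:
    """Per-day totals of a diet: energy, carbon, and every panel nutrient."""

    energy: float  # kcal/day
    carbon: float  # kg CO2 eq/day
    nutrients: dict[str, float]  # canonical unit per day

    def __getitem__(self, nutrient_id: str) -> float:
        return self.nutrients[nutrient_id]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def diet_totals(diet: DietVector, foods: FoodList) -> DietTotals:
    """Exact linear accumulation of per-day totals.

    Each total is sum_i amount_i/100 * per-100 g value_i.  This is the one
    place where per-100 g data meet g/day amounts.
    """
    diet.check_aligned(foods)
    g = diet.amounts / 100.0
    energy = float(g @ np.array([f.energy for f in foods.items])) if len(foods) else 0.0
    carbon = float(g @ np.array([f.carbon for f in foods.items])) if len(foods) else 0.0
    mat = foods.nutrient_matrix()
    per_day = g @ mat if len(foods) else np.zeros(len(foods.nutrient_panel))
    nutrients = {nid: float(v) for (nid, _), v in zip(foods.nutrient_panel, per_day)}
    return DietTotals(energy=energy, carbon=carbon, nutrients=nutrients)


def added_sugar_coefficients(
    foods: FoodList,
    added_sugar_categories: Iterable[str] = ADDED_SUGAR_CATEGORIES,
    dairy_category: str = DAIRY_CATEGORY,
) -> np.ndarray:
    """Per-gram added-sugar content of every food.

    Foods in the configured added-sugar categories contribute their whole
    mono+di-saccharide content; dairy foods contribute their mono+di content
    in excess of intrinsic lactose (floored at zero); all other foods
    contribute nothing.  Because the per-food coefficient is constant, total
    added sugars are linear in the diet and usable as an optimizer row.
    """
    cats = set(added_sugar_categories)
    monodi = foods.nutrient_per_gram("mono_di_saccharides")
    coeffs = np.zeros(len(foods))
    for i, f in enumerate(foods.items):
        if f.category in cats:
            coeffs[i] = monodi[i]
        elif f.category == dairy_category:
            coeffs[i] = max(0.0, monodi[i] - f.lactose / 100.0)
    return coeffs


def default_popularity(
    baseline: np.ndarray, zero_weight: float | None = None
) -> np.ndarray:
    """Intake-frequency proxy: baseline intake rescaled to mean 1 over
    consumed foods.  Foods with zero baseline intake receive ``zero_weight``
    (default: the median weight of consumed foods)."""
    b = np.asarray(baseline, dtype=float)
    consumed = b > 0
    w = np.zeros_like(b)
    if consumed.any():
        w[consumed] = b[consumed] / b[consumed].mean()
        fill = float(np.median(w[consumed])) if zero_weight is None else zero_weight
    else:
        fill = 1.0 if zero_weight is None else zero_weight
    w[~consumed] = fill
    return w


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "food_id",
    "name",
    "category",
    "energy_kcal_100g",
    "carbon_kgco2e_100g",
    "baseline_g_d",
    "popularity",
    "max_g_d",
    "is_fortified",
    "lactose_g_100g",
]


def _nutrient_column(nutrient_id: str, unit: str) -> str:
    return f"{nutrient_id}_{unit}_100g"


def _parse_nutrient_column(col: str) -> tuple[str, str] | None:
    if not col.endswith("_100g"):
        return None
    stem = col[: -len("_100g")]
    nid, _, unit = stem.rpartition("_")
    if not nid or unit not in _UNIT_TO_G:
        return None
    return nid, unit


def read_food_csv(path) -> FoodList:
    """Read a food-composition table in the documented CSV dialect.

    Columns: the ten metadata columns, then one ``<nutrient>_<unit>_100g``
    column per panel nutrient.  Unit strings are normalized to the panel's
    canonical units; row order is preserved.
    """
    df = pd.read_csv(path, dtype={"food_id": str}, float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    nutrient_cols: dict[str, tuple[str, str]] = {}
    for col in df.columns:
        parsed = _parse_nutrient_column(col)
        if parsed and col not in _META_COLUMNS:
            nid, unit = parsed
            nutrient_cols[nid] = (col, unit)

    panel_ids = [nid for nid, _ in NUTRIENT_PANEL]
    absent = [nid for nid in panel_ids if nid not in nutrient_cols]
    if absent:
        raise ValueError(f"missing nutrient column(s): {', '.join(absent)}")

    dup = df["food_id"][df["food_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate food_id: {dup.iloc[0]!r}")

    items = []
    for _, row in df.iterrows():
        nut = np.empty(len(NUTRIENT_PANEL))
        for k, (nid, canon) in enumerate(NUTRIENT_PANEL):
            col, unit = nutrient_cols[nid]
            nut[k] = _convert_unit(float(row[col]), unit, canon)
        max_intake = row["max_g_d"]
        max_intake = None if pd.isna(max_intake) else float(max_intake)
        items.append(
            FoodItem(
                food_id=str(row["food_id"]),
                name=str(row["name"]),
                category=str(row["category"]),
                energy=float(row["energy_kcal_100g"]),
                nutrients=nut,
                carbon=float(row["carbon_kgco2e_100g"]),
                baseline_intake=float(row["baseline_g_d"]),
                popularity_weight=float(row["popularity"]),
                max_intake=max_intake,
                is_fortified=bool(row["is_fortified"]),
                lactose=float(row["lactose_g_100g"]),
            )
        )
    return FoodList(items)


def write_food_csv(foods: FoodList, path) -> None:
    """Write a FoodList in the canonical dialect (read/write round-trip
    stable for canonical files)."""
    records = []
    for f in foods.items:
        rec: dict[str, object] = {
            "food_id": f.food_id,
            "name": f.name,
            "category": f.category,
            "energy_kcal_100g": repr(float(f.energy)),
            "carbon_kgco2e_100g": repr(float(f.carbon)),
            "baseline_g_d": repr(float(f.baseline_intake)),
            "popularity": repr(float(f.popularity_weight)),
            "max_g_d": "" if f.max_intake is None else repr(float(f.max_intake)),
            "is_fortified": f.is_fortified,
            "lactose_g_100g": repr(float(f.lactose)),
        }
        for k, (nid, unit) in enumerate(foods.nutrient_panel):
            rec[_nutrient_column(nid, unit)] = repr(float(f.nutrients[k]))
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_diet_csv(path, foods: FoodList) -> DietVector:
    """Read a diet (columns food_id, amount_g_d) aligned to ``foods``."""
    df = pd.read_csv(path, dtype={"food_id": str}, float_precision="round_trip")
    for col in ("food_id", "amount_g_d"):
        if col not in df.columns:
            raise ValueError(f"missing required column(s): {col}")
    amounts = dict(zip(df["food_id"], df["amount_g_d"].astype(float)))
    unknown = set(amounts) - set(foods.food_ids)
    if unknown:
        raise ValueError(f"diet references unknown food_id(s): {sorted(unknown)}")
    vec = np.array([amounts.get(fid, 0.0) for fid in foods.food_ids])
    return DietVector(vec, foods.food_ids)


def write_diet_csv(diet: DietVector, foods: FoodList, path) -> None:
    diet.check_aligned(foods)
    pd.DataFrame(
        {"food_id": foods.food_ids, "amount_g_d": [repr(float(a)) for a in diet.amounts]}
    ).to_csv(path, index=False)
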