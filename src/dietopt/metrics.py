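"""Nutrient-density metrics and category contribution reports.

Diet quality is compared across scenarios on a common 2000 kcal basis:

* **MAR** (mean adequacy ratio) — percent of the RNI/AI supplied for each
  qualifying nutrient, truncated at 100 %, averaged over the 26 qualifying
  nutrients.  100 % means every desired nutrient meets its reference.
* **MER** (mean excess ratio) — percent of the MRV for each of the 6
  nutrients to limit, averaged *untruncated* (a diet can sit well above
  100 %).  Component ratios are not floored either: a nutrient below its
  MRV contributes its actual percent.

Added sugars are not a food-table column; they are estimated as the
mono- and di-saccharides of the categories where those are almost
exclusively added (sugar/snacks, cakes, soft drinks) plus the mono+di of
dairy foods in excess of intrinsic lactose.

Category contribution reports carry, per report category, the daily
vitamin D, carbon and energy delivered by a diet and the fold change
versus baseline — the content of the scenario figures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .food_model import (
    ADDED_SUGAR_CATEGORIES,
    DAIRY_CATEGORY,
    DietVector,
    FoodList,
    added_sugar_coefficients,
    diet_totals,
)
from .reference_model import ReferenceSet

__all__ = [
    "DensityReport",
    "ContributionReport",
    "standardize_to_energy",
    "mean_adequacy_ratio",
    "mean_excess_ratio",
    "adequacy_ratios",
    "excess_ratios",
    "estimate_added_sugars",
    "category_contributions",
    "density_report",
]


@dataclass(frozen=True)
class DensityReport:
    mar: float  # percent, in [0, 100]
    mer: float  # percent, >= 0, untruncated
    per_nutrient_adequacy: dict[str, float]  # untruncated percent of RNI/AI
    per_nutrient_excess: dict[str, float]  # percent of MRV
    first_limiting: tuple[str, ...]  # argmin of adequacy; >1 entry on ties

    def to_json(self, **extra) -> str:
        payload = {
            "mar_pct": self.mar,
            "mer_pct": self.mer,
            "first_limiting": list(self.first_limiting),
            "per_nutrient_adequacy_pct": self.per_nutrient_adequacy,
            "per_nutrient_excess_pct": self.per_nutrient_excess,
        }
        payload.update(extra)
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass(frozen=True)
class ContributionReport:
    """Per-category vitamin D / carbon / energy with fold changes."""

    table: pd.DataFrame  # rows: categories + "total"; see category_contributions

    def fold_change(self, category: str, quantity: str) -> float:
        return float(self.table.loc[category, f"{quantity}_fold"])

    def to_csv(self, path) -> None:
        tidy = self.table.reset_index().melt(
            id_vars="category", var_name="measure", value_name="value"
        )
        tidy.to_csv(path, index=False)


# ---------------------------------------------------------------------------


def standardize_to_energy(diet: DietVector, foods: FoodList, target: float = 2000.0) -> DietVector:
    """Scale all amounts so total energy equals ``target`` kcal/day."""
    energy = diet_totals(diet, foods).energy
    if not energy > 0:
        raise ValueError("cannot standardize a zero-energy diet")
    return diet.scaled(target / energy)


def _bound_in_grams(ref, energy_kcal: float, lower: bool) -> float:
    """Per-day allowance of a reference, resolving percent-of-energy bounds
    against the diet's realized energy."""
    value = ref.lower if lower else ref.upper
    if value is None:
        raise ValueError(f"{ref.nutrient_id}: missing {'lower' if lower else 'upper'} bound")
    if ref.basis == "absolute":
        return value
    return (value / 100.0) * energy_kcal / ref.energy_factor


def adequacy_ratios(diet: DietVector, foods: FoodList, refs: ReferenceSet) -> dict[str, float]:
    """Untruncated percent of RNI/AI per qualifying nutrient."""
    totals = diet_totals(diet, foods)
    out = {}
    for ref in refs.qualifying:
        bound = _bound_in_grams(ref, totals.energy, lower=True)
        out[ref.nutrient_id] = 100.0 * totals[ref.nutrient_id] / bound
    return out


def excess_ratios(diet: DietVector, foods: FoodList, refs: ReferenceSet) -> dict[str, float]:
    """Percent of MRV per disqualifying nutrient (added sugars derived)."""
    totals = diet_totals(diet, foods)
    out = {}
    for ref in refs.disqualifying:
        intake = (
            estimate_added_sugars(diet, foods)
            if ref.nutrient_id == "added_sugars"
            else totals[ref.nutrient_id]
        )
        bound = _bound_in_grams(ref, totals.energy, lower=False)
        out[ref.nutrient_id] = 100.0 * intake / bound
    return out


def mean_adequacy_ratio(diet_2000: DietVector, foods: FoodList, refs: ReferenceSet) -> float:
    """MAR: mean over qualifying nutrients of min(100, percent of RNI/AI).

    Expects a diet already standardized to the reference energy basis.
    """
    ratios = adequacy_ratios(diet_2000, foods, refs)
    if not ratios:
        raise ValueError("reference set has no qualifying nutrients")
    return float(np.mean([min(100.0, r) for r in ratios.values()]))


def mean_excess_ratio(diet_2000: DietVector, foods: FoodList, refs: ReferenceSet) -> float:
    """MER: mean percent of MRV over the disqualifying nutrients, untruncated."""
    ratios = excess_ratios(diet_2000, foods, refs)
    if not ratios:
        raise ValueError("reference set has no disqualifying nutrients")
    return float(np.mean(list(ratios.values())))


def estimate_added_sugars(
    diet: DietVector,
    foods: FoodList,
    added_sugar_categories=ADDED_SUGAR_CATEGORIES,
    dairy_category: str = DAIRY_CATEGORY,
) -> float:
    """g/day of added sugars (category sum plus dairy lactose correction)."""
    diet.check_aligned(foods)
    coeffs = added_sugar_coefficients(foods, added_sugar_categories, dairy_category)
    return float(coeffs @ diet.amounts)


def density_report(diet_2000: DietVector, foods: FoodList, refs: ReferenceSet) -> DensityReport:
    adequacy = adequacy_ratios(diet_2000, foods, refs)
    excess = excess_ratios(diet_2000, foods, refs)
    low = min(adequacy.values())
    # argmin with alphabetical tie-break; ties reported together
    limiting = tuple(sorted(n for n, r in adequacy.items() if np.isclose(r, low, rtol=1e-12, atol=1e-9)))
    return DensityReport(
        mar=float(np.mean([min(100.0, r) for r in adequacy.values()])),
        mer=float(np.mean(list(excess.values()))),
        per_nutrient_adequacy=adequacy,
        per_nutrient_excess=excess,
        first_limiting=limiting,
    )


def category_contributions(
    diet: DietVector, baseline: DietVector, foods: FoodList
) -> ContributionReport:
    """Per-category vitamin D (ug/d), carbon (kg CO2e/d) and energy (kcal/d)
    of ``diet``, with fold changes versus ``baseline``.

    Category rows sum exactly to the whole-diet totals (conservation); a
    fold change over a zero baseline category is reported as +inf.
    """
    diet.check_aligned(foods)
    baseline.check_aligned(foods)
    vitd = foods.nutrient_per_gram("vitamin_d")
    carbon = foods.carbon_per_gram()
    energy = foods.energy_per_gram()
    cats = np.array(foods.categories)
    rows = []
    for cat in sorted(set(foods.categories)):
        mask = cats == cat
        row = {"category": cat}
        for q, coeff in (("vitamin_d", vitd), ("carbon", carbon), ("energy", energy)):
            new = float(coeff[mask] @ diet.amounts[mask])
            old = float(coeff[mask] @ baseline.amounts[mask])
            row[q] = new
            row[f"{q}_baseline"] = old
            row[f"{q}_fold"] = new / old if old > 0 else (np.inf if new > 0 else 1.0)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("category")
    total = {}
    for q, coeff in (("vitamin_d", vitd), ("carbon", carbon), ("energy", energy)):
        new = float(coeff @ diet.amounts)
        old = float(coeff @ baseline.amounts)
        total[q] = new
        total[f"{q}_baseline"] = old
        total[f"{q}_fold"] = new / old if old > 0 else (np.inf if new > 0 else 1.0)
    df.loc["total"] = pd.Series(total)
    return ContributionReport(table=df)
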