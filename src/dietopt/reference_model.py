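"""Nutrient reference values and their translation into linear bounds.

Lower bounds are recommended nutrient intakes (RNI) or adequate intakes
(AI); upper bounds are tolerable upper intake levels (UL) or maximum
reference values (MRV) for nutrients to limit.  References for adults are
averaged over the sexes and energy-adjusted from the population's mean
consumption (2243 kcal/d) to a 2000 kcal/d basis, e.g. the vitamin D AI of
15 ug/d becomes 13.4 ug/d per 2000 kcal.

Two bound bases exist:

* ``absolute`` — an amount per day (ug, mg or g); scaled linearly under
  energy adjustment.
* ``percent_of_energy`` — a percent of total energy (e.g. saturated fat
  < 10 %E); linearized against the diet's realized energy and invariant
  under energy adjustment.

The default reference set ships as an editable CSV
(``data/default_references.csv``).  The split into 26 qualifying and 6
disqualifying nutrients follows the convention behind the mean adequacy
and mean excess ratios; the identity of the 26 qualifying nutrients is a
reconstruction of common European reference panels and is meant to be
edited per application.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal

import pandas as pd

from .diet_optimizer import LinearConstraintSet
from .food_model import FoodList, added_sugar_coefficients

__all__ = [
    "NutrientReference",
    "ReferenceSet",
    "average_sex_references",
    "energy_adjust",
    "to_linear_bounds",
    "default_reference_set",
    "read_reference_csv",
    "write_reference_csv",
    "display_round",
]

Basis = Literal["absolute", "percent_of_energy"]

_VALID_TAGS = {"RNI", "AI", "UL", "MRV"}


@dataclass(frozen=True)
class NutrientReference:
    """One nutrient's lower (RNI/AI) and upper (UL/MRV) bound.

    ``unit`` is the canonical per-day unit for absolute bounds; for
    percent_of_energy bounds the values are percents of energy and
    ``energy_factor`` is the kcal per gram of the nutrient (9 for fats,
    4 for sugars, 7 for alcohol).
    """

    nutrient_id: str
    lower: float | None
    upper: float | None
    basis: Basis = "absolute"
    unit: str = "g"
    energy_factor: float = 0.0
    source_tag: str = ""
    qualifying: bool = False
    disqualifying: bool = False

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"{self.nutrient_id}: lower bound exceeds upper bound")
        if self.basis == "percent_of_energy" and not self.energy_factor > 0:
            raise ValueError(f"{self.nutrient_id}: percent_of_energy needs energy_factor > 0")
        for tag in filter(None, self.source_tag.split("+")):
            if tag not in _VALID_TAGS:
                raise ValueError(f"{self.nutrient_id}: unknown source tag {tag!r}")


@dataclass
class ReferenceSet:
    """References keyed by nutrient, with their energy basis.

    ``reference_energy`` is the mean daily energy intake the absolute
    bounds were established for; ``target_energy`` the basis they are
    adjusted to before optimization (both kcal/day).
    """

    references: dict[str, NutrientReference]
    reference_energy: float = 2243.0
    target_energy: float = 2000.0

    def __post_init__(self) -> None:
        if not self.reference_energy > 0 or not self.target_energy > 0:
            raise ValueError("energies must be positive")
        for nid, ref in self.references.items():
            if nid != ref.nutrient_id:
                raise ValueError(f"key {nid!r} does not match reference {ref.nutrient_id!r}")

    def __getitem__(self, nutrient_id: str) -> NutrientReference:
        return self.references[nutrient_id]

    def __iter__(self):
        return iter(self.references.values())

    def __len__(self) -> int:
        return len(self.references)

    @property
    def qualifying(self) -> list[NutrientReference]:
        return [r for r in self if r.qualifying]

    @property
    def disqualifying(self) -> list[NutrientReference]:
        return [r for r in self if r.disqualifying]

    def adjusted(self) -> "ReferenceSet":
        """Energy-adjust every absolute reference to ``target_energy``."""
        refs = {
            nid: energy_adjust(ref, self.reference_energy, self.target_energy)
            for nid, ref in self.references.items()
        }
        return ReferenceSet(refs, self.target_energy, self.target_energy)

    def replace_reference(self, ref: NutrientReference) -> "ReferenceSet":
        refs = dict(self.references)
        refs[ref.nutrient_id] = ref
        return ReferenceSet(refs, self.reference_energy, self.target_energy)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def average_sex_references(male: ReferenceSet, female: ReferenceSet) -> ReferenceSet:
    """Arithmetic mean of per-sex references, bound by bound.

    Both sets must cover the same nutrients with the same basis; a bound
    present in one sex but missing in the other is an error (a silent
    one-sided average would not be a population reference).
    """
    if set(male.references) != set(female.references):
        only_m = sorted(set(male.references) - set(female.references))
        only_f = sorted(set(female.references) - set(male.references))
        raise ValueError(f"mismatched nutrient lists (male-only {only_m}, female-only {only_f})")
    out: dict[str, NutrientReference] = {}
    for nid, m in male.references.items():
        f = female.references[nid]
        if m.basis != f.basis:
            raise ValueError(f"{nid}: basis differs between sexes")

        def mean(a: float | None, b: float | None, side: str) -> float | None:
            if a is None and b is None:
                return None
            if a is None or b is None:
                raise ValueError(f"{nid}: {side} bound set for one sex only")
            return (a + b) / 2.0

        out[nid] = replace(m, lower=mean(m.lower, f.lower, "lower"), upper=mean(m.upper, f.upper, "upper"))
    if (male.reference_energy, male.target_energy) != (female.reference_energy, female.target_energy):
        ref_e = (male.reference_energy + female.reference_energy) / 2.0
        tgt_e = (male.target_energy + female.target_energy) / 2.0
    else:
        ref_e, tgt_e = male.reference_energy, male.target_energy
    return ReferenceSet(out, ref_e, tgt_e)


def energy_adjust(
    ref: NutrientReference, reference_energy: float, target_energy: float
) -> NutrientReference:
    """Scale absolute bounds by target/reference energy.

    Full precision is kept internally (15 ug/d at 2243 kcal adjusts to
    13.375... ug/d, displayed as 13.4); percent_of_energy references are
    returned unchanged because they already scale with the diet's energy.
    """
    if not reference_energy > 0 or not target_energy > 0:
        raise ValueError("energies must be positive")
    if ref.basis == "percent_of_energy":
        return ref
    k = target_energy / reference_energy
    return replace(
        ref,
        lower=None if ref.lower is None else ref.lower * k,
        upper=None if ref.upper is None else ref.upper * k,
    )


def display_round(value: float, sig: int = 3) -> float:
    """Display rounding policy: 3 significant figures."""
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, sig - 1 - int(math.floor(math.log10(abs(value)))))


def to_linear_bounds(refs: ReferenceSet, foods: FoodList) -> LinearConstraintSet:
    """Translate references into optimizer rows over a food list.

    Absolute bounds become ``a . x >= L`` / ``a . x <= U`` with ``a_i`` the
    nutrient content per gram of food ``i``.  A percent-of-energy bound of
    p %E linearizes to ``factor * (n . x) - (p/100) * (e . x) <= 0`` (and
    ``>=`` for lower bounds), with ``e`` the energy density in kcal/g.

    The derived nutrient ``added_sugars`` draws its per-food coefficients
    from :func:`dietopt.food_model.added_sugar_coefficients`.
    """
    cons = LinearConstraintSet(upper=foods.max_intake_vector())
    if len(refs) == 0:
        return cons
    e = foods.energy_per_gram()
    for ref in refs:
        if ref.nutrient_id == "added_sugars":
            a = added_sugar_coefficients(foods)
        else:
            a = foods.nutrient_per_gram(ref.nutrient_id)  # KeyError if absent
        if ref.basis == "absolute":
            if ref.lower is not None:
                cons.add(a, ">=", ref.lower, f"{ref.nutrient_id}:lower")
            if ref.upper is not None:
                cons.add(a, "<=", ref.upper, f"{ref.nutrient_id}:upper")
        else:
            if ref.lower is not None:
                cons.add(
                    ref.energy_factor * a - (ref.lower / 100.0) * e,
                    ">=",
                    0.0,
                    f"{ref.nutrient_id}:lower",
                )
            if ref.upper is not None:
                cons.add(
                    ref.energy_factor * a - (ref.upper / 100.0) * e,
                    "<=",
                    0.0,
                    f"{ref.nutrient_id}:upper",
                )
    return cons


# ---------------------------------------------------------------------------
# CSV I/O and the default set
# ---------------------------------------------------------------------------

_REF_COLUMNS = [
    "nutrient_id",
    "lower",
    "upper",
    "unit",
    "basis",
    "energy_factor",
    "qualifying",
    "disqualifying",
    "source_tag",
]


def read_reference_csv(path, reference_energy: float = 2243.0, target_energy: float = 2000.0) -> ReferenceSet:
    df = pd.read_csv(path)
    missing = [c for c in _REF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    refs: dict[str, NutrientReference] = {}
    for _, row in df.iterrows():
        nid = str(row["nutrient_id"])
        if nid in refs:
            raise ValueError(f"duplicate nutrient_id: {nid!r}")
        refs[nid] = NutrientReference(
            nutrient_id=nid,
            lower=None if pd.isna(row["lower"]) else float(row["lower"]),
            upper=None if pd.isna(row["upper"]) else float(row["upper"]),
            basis=str(row["basis"]),
            unit=str(row["unit"]),
            energy_factor=0.0 if pd.isna(row["energy_factor"]) else float(row["energy_factor"]),
            source_tag=str(row["source_tag"]),
            qualifying=bool(row["qualifying"]),
            disqualifying=bool(row["disqualifying"]),
        )
    return ReferenceSet(refs, reference_energy, target_energy)


def write_reference_csv(refs: ReferenceSet, path) -> None:
    records = []
    for r in refs:
        records.append(
            {
                "nutrient_id": r.nutrient_id,
                "lower": "" if r.lower is None else r.lower,
                "upper": "" if r.upper is None else r.upper,
                "unit": r.unit,
                "basis": r.basis,
                "energy_factor": r.energy_factor if r.basis == "percent_of_energy" else "",
                "qualifying": r.qualifying,
                "disqualifying": r.disqualifying,
                "source_tag": r.source_tag,
            }
        )
    pd.DataFrame.from_records(records, columns=_REF_COLUMNS).to_csv(path, index=False)


def default_reference_set() -> ReferenceSet:
    """The packaged adult reference set (sex-averaged, 2243 kcal basis).

    Exactly 26 qualifying and 6 disqualifying nutrients.  Call
    ``.adjusted()`` to move absolute bounds onto the 2000 kcal basis used
    throughout the scenarios.
    """
    path = resources.files("dietopt").joinpath("data/default_references.csv")
    with resources.as_file(path) as p:
        refs = read_reference_csv(p)
    nq, nd = len(refs.qualifying), len(refs.disqualifying)
    if (nq, nd) != (26, 6):
        raise RuntimeError(f"default reference set corrupt: {nq} qualifying / {nd} disqualifying")
    return refs
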