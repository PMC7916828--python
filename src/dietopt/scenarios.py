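"""The four scenario pipelines.

* **S1** — reach the adequate vitamin D intake (13.4 ug/d) fulfilling all
  nutrient references, with the energy cap removed.
* **S2** — maximize vitamin D within a 2000 kcal cap (the adequate intake
  is unreachable there without new fortified foods; the scenario reports
  the achieved maximum).
* **S3** — add vitamin D-fortified bread, milk and oil to the repertoire
  and reach 13.4 ug/d within 2000 kcal.
* **S4a / S4b** — S3 plus a carbon cap (3.9 kg CO2 eq/d, or the 10 %
  reduced 3.5 kg CO2 eq/d); S4b additionally flattens the popularity
  weighting ("compromising on popularity").

Every scenario builds one linear constraint system (nutrient references,
energy cap, CO2 cap, vitamin D goal), dispatches to the deviation QP or
the lexicographic maximizer, and assembles density and contribution
reports.  Runs are deterministic: identical config + data give identical
results, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

from .diet_optimizer import (
    FEASIBILITY_TOL,
    LinearConstraintSet,
    OptimizationResult,
    maximize_nutrient,
    minimize_deviation,
)
from .food_model import DietVector, FoodList, diet_totals
from .fortification import FortificationSpec, add_fortified_options
from .metrics import (
    ContributionReport,
    DensityReport,
    category_contributions,
    density_report,
    standardize_to_energy,
)
from .reference_model import ReferenceSet, default_reference_set, to_linear_bounds

__all__ = [
    "VITAMIN_D_GOAL",
    "ScenarioConfig",
    "ScenarioResult",
    "builtin_scenario",
    "default_fortification_specs",
    "run_scenario",
    "fortified_option_ablation",
    "scenario_from_yaml",
]

#: Adequate vitamin D intake per 2000 kcal (ug/day), the scenario goal.
VITAMIN_D_GOAL = 13.4

_KNOWN_IDS = ("S1", "S2", "S3", "S4a", "S4b")


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: caps, vitamin D goal, fortified options, popularity.

    ``vitamin_d_goal`` is a ug/day target or the string ``"maximize"``.
    ``popularity_factor`` flattens the popularity weighting: weights enter
    the deviation objective as ``w ** popularity_factor``, so 1 keeps the
    full popularity structure and 0 treats all foods alike (the
    "compromising on popularity" regime).  ``drop_lower_bounds`` removes
    the nutrient lower bounds (an exploratory variant; off by default).
    """

    id: str
    vitamin_d_goal: float | str = VITAMIN_D_GOAL
    energy_cap: float | None = 2000.0
    co2_cap: float | None = None
    fortified_options: tuple[FortificationSpec, ...] = ()
    popularity_factor: float = 1.0
    drop_lower_bounds: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.vitamin_d_goal, str):
            if self.vitamin_d_goal != "maximize":
                raise ValueError(
                    f"vitamin_d_goal must be a number or 'maximize', got {self.vitamin_d_goal!r}"
                )
        elif not self.vitamin_d_goal >= 0:
            raise ValueError("numeric vitamin_d_goal must be >= 0")
        if not 0.0 <= self.popularity_factor <= 1.0:
            raise ValueError("popularity_factor must be in [0, 1]")
        for cap in (self.energy_cap, self.co2_cap):
            if cap is not None and not cap > 0:
                raise ValueError("caps must be positive when set")

    @property
    def maximizing(self) -> bool:
        return self.vitamin_d_goal == "maximize"


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    optimization: OptimizationResult
    density: DensityReport | None
    contributions: ContributionReport | None
    achieved_vitamin_d: float
    total_co2: float
    total_energy: float
    foods: FoodList  # repertoire actually optimized (incl. fortified options)
    baseline: DietVector  # aligned to ``foods``

    @property
    def status(self) -> str:
        return self.optimization.status


def default_fortification_specs(foods: FoodList) -> list[FortificationSpec]:
    """Fortified bread/milk/oil options on the most-consumed vehicle of
    each category: 6 / 2 / 15 ug per 100 g, bread and milk capped at two
    servings (35 g slices, 150 g glasses), oil uncapped."""
    specs = []
    for category, level, serving, max_srv in (
        ("bread_cereals", 6.0, 35.0, 2),
        ("dairy", 2.0, 150.0, 2),
        ("oils_fats", 15.0, None, None),
    ):
        candidates = [f for f in foods.items if f.category == category and not f.is_fortified]
        if not candidates:
            raise ValueError(f"no vehicle available in category {category!r}")
        vehicle = max(candidates, key=lambda f: f.baseline_intake)
        specs.append(
            FortificationSpec(
                base_food_id=vehicle.food_id,
                level=level,
                serving_size=serving,
                max_servings_per_day=max_srv,
            )
        )
    return specs


def builtin_scenario(scenario_id: str, foods: FoodList | None = None) -> ScenarioConfig:
    """Canonical configs for S1, S2, S3, S4a, S4b.

    S3/S4 need ``foods`` to pick fortification vehicles.
    """
    if scenario_id not in _KNOWN_IDS:
        raise ValueError(f"unknown scenario {scenario_id!r}; expected one of {_KNOWN_IDS}")
    if scenario_id == "S1":
        return ScenarioConfig(id="S1", vitamin_d_goal=VITAMIN_D_GOAL, energy_cap=None)
    if scenario_id == "S2":
        return ScenarioConfig(id="S2", vitamin_d_goal="maximize", energy_cap=2000.0)
    if foods is None:
        raise ValueError(f"{scenario_id} needs a food list to choose fortification vehicles")
    options = tuple(default_fortification_specs(foods))
    if scenario_id == "S3":
        return ScenarioConfig(id="S3", energy_cap=2000.0, fortified_options=options)
    if scenario_id == "S4a":
        return ScenarioConfig(id="S4a", energy_cap=2000.0, co2_cap=3.9, fortified_options=options)
    return ScenarioConfig(
        id="S4b", energy_cap=2000.0, co2_cap=3.5, fortified_options=options,
        popularity_factor=0.0,
    )


def _materialize(
    config: ScenarioConfig, foods: FoodList, baseline: DietVector
) -> tuple[FoodList, DietVector]:
    """Append fortified options not yet present; extend baseline with zeros."""
    baseline.check_aligned(foods)
    missing = [s for s in config.fortified_options if s.fortified_id not in foods.food_ids]
    if not missing:
        return foods, baseline
    foods2 = add_fortified_options(foods, missing)
    amounts = np.concatenate([baseline.amounts, np.zeros(len(missing))])
    return foods2, DietVector(amounts, foods2.food_ids)


def build_constraints(
    config: ScenarioConfig, foods: FoodList, refs: ReferenceSet
) -> LinearConstraintSet:
    """Assemble the scenario's linear constraint system.

    Nutrient references (energy-adjusted), then the energy cap, CO2 cap
    and — for a numeric goal — a vitamin D goal row replacing the plain
    vitamin D lower bound.
    """
    adj = refs.adjusted()
    cons = to_linear_bounds(adj, foods)
    if config.drop_lower_bounds:
        cons = cons.drop(lambda r: r.label.endswith(":lower"))
    # a numeric goal supersedes the plain vitamin D lower bound;
    # maximization removes it (the reference may be unreachable there)
    cons = cons.drop(lambda r: r.label == "vitamin_d:lower")
    if not config.maximizing:
        cons.add(
            foods.nutrient_per_gram("vitamin_d"), ">=", float(config.vitamin_d_goal),
            "vitamin_d:goal",
        )
    if config.energy_cap is not None:
        cons.add(foods.energy_per_gram(), "<=", config.energy_cap, "energy:upper")
    if config.co2_cap is not None:
        cons.add(foods.carbon_per_gram(), "<=", config.co2_cap, "carbon:upper")
    return cons


def run_scenario(
    config: ScenarioConfig,
    foods: FoodList,
    baseline: DietVector,
    refs: ReferenceSet | None = None,
) -> ScenarioResult:
    """Execute one scenario end to end.

    Returns density/contribution reports for optimal runs; an infeasible
    system yields status ``infeasible`` with the offending constraint
    labels in ``optimization.solver_report["hint"]`` (e.g. a vitamin D
    goal unreachable under the energy cap).
    """
    refs = refs or default_reference_set()
    foods, baseline = _materialize(config, foods, baseline)
    cons = build_constraints(config, foods, refs)
    weights = foods.popularity_vector() ** config.popularity_factor

    if config.maximizing:
        max_level, result = maximize_nutrient(
            baseline, foods, cons, "vitamin_d", weights=weights
        )
        achieved = max_level if result.status == "optimal" else np.nan
    else:
        result = minimize_deviation(baseline, foods, cons, weights=weights)
        achieved = np.nan

    if result.status != "optimal":
        return ScenarioResult(
            config=config, optimization=result, density=None, contributions=None,
            achieved_vitamin_d=achieved, total_co2=np.nan, total_energy=np.nan,
            foods=foods, baseline=baseline,
        )

    totals = diet_totals(result.diet, foods)
    adj = refs.adjusted()
    # Density basis: standardize to the reference energy when that cannot
    # lower adequacy (scaling a compliant sub-2000 kcal diet up preserves
    # every ratio >= 100 %).  A diet above the reference energy (energy cap
    # removed) is scored as optimized — scaling it down would misreport a
    # constraint-satisfying diet as inadequate.
    if totals.energy <= adj.target_energy:
        std = standardize_to_energy(result.diet, foods, adj.target_energy)
    else:
        std = result.diet
    return ScenarioResult(
        config=config,
        optimization=result,
        density=density_report(std, foods, adj),
        contributions=category_contributions(result.diet, baseline, foods),
        achieved_vitamin_d=totals["vitamin_d"],
        total_co2=totals.carbon,
        total_energy=totals.energy,
        foods=foods,
        baseline=baseline,
    )


def fortified_option_ablation(
    base_config: ScenarioConfig,
    foods: FoodList,
    baseline: DietVector,
    options_subsets: Sequence[Iterable[FortificationSpec]],
    refs: ReferenceSet | None = None,
) -> list[dict]:
    """Re-run a goal scenario for each subset of fortified options.

    For every subset, reports the scenario result and which fortified
    option carries the largest vitamin D share of the optimized diet
    (``carrier`` is ``None`` when the run is infeasible or no fortified
    food is consumed).  An empty subset degenerates to the
    no-new-fortification scenario.  Results are ordered by ascending
    deviation objective (feasible runs first).
    """
    subsets = [tuple(s) for s in options_subsets]
    if not subsets:
        raise ValueError("options_subsets must contain at least one subset")
    out = []
    for subset in subsets:
        config = replace(base_config, fortified_options=subset)
        result = run_scenario(config, foods, baseline, refs)
        carrier = None
        shares: dict[str, float] = {}
        if result.status == "optimal" and subset:
            vitd = result.foods.nutrient_per_gram("vitamin_d")
            ids = result.foods.food_ids
            x = result.optimization.diet.amounts
            for spec in subset:
                i = ids.index(spec.fortified_id)
                shares[spec.fortified_id] = float(vitd[i] * x[i])
            if any(v > FEASIBILITY_TOL for v in shares.values()):
                carrier = max(shares, key=shares.get)
        out.append(
            {
                "options": tuple(s.fortified_id for s in subset),
                "result": result,
                "carrier": carrier,
                "vitamin_d_shares": shares,
            }
        )
    out.sort(
        key=lambda r: (
            r["result"].status != "optimal",
            r["result"].optimization.objective if r["result"].status == "optimal" else np.inf,
        )
    )
    return out


def scenario_from_yaml(path) -> ScenarioConfig:
    """Load a scenario config from YAML.

    Keys: id, vitamin_d_goal (number or "maximize"), energy_cap, co2_cap,
    popularity_factor, drop_lower_bounds, fortified_options (list of
    fortification-spec mappings as in
    :func:`dietopt.fortification.read_fortification_specs`).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    options = []
    for row in raw.get("fortified_options", []) or []:
        options.append(
            FortificationSpec(
                base_food_id=str(row["base_food_id"]),
                nutrient_id=str(row.get("nutrient", "vitamin_d")),
                level=float(row["level_ug_100g"]),
                serving_size=None if row.get("serving_g") is None else float(row["serving_g"]),
                max_servings_per_day=(
                    None if row.get("max_servings") is None else int(row["max_servings"])
                ),
                fortificant_footprint=float(row.get("fortificant_kgco2e_per_kg", 200.0)),
            )
        )
    goal = raw.get("vitamin_d_goal", VITAMIN_D_GOAL)
    return ScenarioConfig(
        id=str(raw.get("id", "custom")),
        vitamin_d_goal=goal if goal == "maximize" else float(goal),
        energy_cap=None if raw.get("energy_cap") is None else float(raw["energy_cap"]),
        co2_cap=None if raw.get("co2_cap") is None else float(raw["co2_cap"]),
        fortified_options=tuple(options),
        popularity_factor=float(raw.get("popularity_factor", 1.0)),
        drop_lower_bounds=bool(raw.get("drop_lower_bounds", False)),
    )
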