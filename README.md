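# dietopt

Diet optimization under nutrient, energy and carbon-footprint constraints,
with vitamin D fortification scenarios and nutrient-density metrics.

`dietopt` is for nutrition modellers and sustainability researchers who ask
questions of the form: *starting from what a population actually eats, what
is the smallest realistic dietary shift that meets every nutrient reference —
and what does it cost in calories and CO₂?*  The motivating application is
vitamin D: few foods contain it naturally (oily fish, eggs, meat, dairy and
some voluntarily fortified products), so a typical Western diet supplies only
about a fifth of the adequate intake, and closing that gap by eating more
animal-source food collides with both calorie and carbon budgets.  The
package models fortifying staples (bread, milk, vegetable oil) as a way out.

## The model

Foods are rows of a composition table (per-100 g energy, 36 nutrients,
kg CO₂ eq footprint, baseline intake g/day, popularity weight).  A diet is a
vector *x* of g/day amounts.  The core solver finds the diet closest to the
observed baseline *b* that satisfies all constraints:

```
minimize   D(x) = Σᵢ wᵢ ((xᵢ − bᵢ) / sᵢ)²         sᵢ = max(bᵢ, s_min)
subject to a·x ≥ RNI/AI       for each qualifying nutrient (lower bounds)
           a·x ≤ UL / MRV     for each nutrient to limit (upper bounds)
           e·x ≤ energy cap,  c·x ≤ CO₂ cap,  0 ≤ xᵢ ≤ max_intakeᵢ
```

where *wᵢ* is the food's popularity (intake-frequency proxy) — deviating
from popular foods is penalized more.  This is a convex quadratic program
with a unique, deterministic solution.  "How much vitamin D is achievable at
all?" is answered lexicographically: a linear program maximizes vitamin D
first, then the deviation objective selects the most familiar diet among the
near-maximal ones.

Nutrient references (RNI/AI lower bounds, UL/MRV upper bounds, sex-averaged)
are energy-adjusted from the population mean intake of 2243 kcal/day to a
2000 kcal/day basis — e.g. the vitamin D adequate intake of 15 µg/d becomes
13.4 µg/d per 2000 kcal.  Diet quality is scored per 2000 kcal by

* **MAR** (mean adequacy ratio): mean over 26 qualifying nutrients of
  percent-of-reference, truncated at 100 %;
* **MER** (mean excess ratio): mean over 6 nutrients to limit (total fat,
  saturated fat, trans fat, cholesterol, added sugars, sodium) of
  percent-of-MRV, untruncated.

Fortification adds micrograms of vitamin D₃ per 100 g of a vehicle food
(milk 2, bread 6, oil 15 µg/100 g; bread and milk capped at two servings a
day).  The fortificant's own footprint (≤ 200 kg CO₂ eq per kg of pure
vitamin D₃) raises a food's footprint by about 0.001 % — carbon-neutral at
diet level.

Because the original survey/composition/LCA databases are licensed, the
package ships a synthetic-data generator that reproduces their statistical
structure (250 foods, 15 categories, right-skewed nutrient contents,
animal foods more carbon-intensive than plants) and calibrates a vitamin D
gap: the baseline supplies 21 % of the adequate intake, vitamin D is the
first-limiting nutrient at a MAR of 86 %, and — verified by solving the
maximization LP during calibration — the adequate intake is unreachable
within 2000 kcal until fortified options are added.

## Worked example

```
$ dietopt generate --seed 1 --out gen
wrote 250 foods to gen

$ dietopt report --foods gen/foods.csv --baseline gen/baseline.csv
baseline: 2243 kcal/d  3.90 kg CO2e/d  vitamin D 3.15 ug/d
per 2000 kcal: MAR 86.0%  MER 120.0%  first-limiting vitamin_d

$ cat s3.yaml
id: S3
vitamin_d_goal: 13.4
energy_cap: 2000
fortified_options:
  - {base_food_id: bread_cereals_013, level_ug_100g: 6.0, serving_g: 35, max_servings: 2}
  - {base_food_id: dairy_010, level_ug_100g: 2.0, serving_g: 150, max_servings: 2}
  - {base_food_id: oils_fats_003, level_ug_100g: 15.0}

$ dietopt run --scenario s3.yaml --foods gen/foods.csv \
      --baseline gen/baseline.csv --out s3out
S3: optimal  vitamin D 13.40 ug/d  energy 2000 kcal/d  CO2 2.42 kg/d  MAR 100.0%  MER 90.1%
```

The baseline diet carries 2243 kcal and 3.9 kg CO₂ eq per day but only
3.15 µg/d of vitamin D (2.81 µg per 2000 kcal — 21 % of the adequate
intake), making vitamin D the first-limiting nutrient and holding the mean
adequacy ratio at 86 %.  Running the fortified-options scenario (`s3.yaml`: vitamin D goal
13.4 µg/d, 2000 kcal cap, fortified bread/milk/oil added to the repertoire)
finds a diet that reaches the adequate intake *within* the calorie budget,
lifts MAR to 100 % and brings the excess ratio below 100 % — while the same
goal without the fortified options exits with code 2 (infeasible).  Scenario
configs are YAML data files; `builtin_scenario()` produces the canonical
S1–S4b configurations programmatically, and exit codes (0 optimal,
1 goal-not-reached, 2 infeasible, 3 unbounded, 4 input error) let pipelines
branch on feasibility.

## Layout

| module | contents |
| --- | --- |
| `dietopt.food_model` | FoodItem/FoodList/DietVector, CSV dialect, diet totals |
| `dietopt.reference_model` | nutrient references, energy adjustment, linear bounds |
| `dietopt.fortification` | fortified variants, serving caps, fortificant carbon |
| `dietopt.diet_optimizer` | deviation QP, nutrient maximization LP, verification |
| `dietopt.metrics` | MAR/MER, added-sugar estimation, contribution reports |
| `dietopt.scenarios` | S1–S4b pipelines, ablation of fortified options |
| `dietopt.synthetic_data` | calibrated synthetic database generator |
| `dietopt.cli` | `dietopt generate / fortify / run / ablate / report` |

See `docs/methods.md` for modelling assumptions, calibration details and
known limitations.
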