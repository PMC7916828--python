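# Methods

This note records the modelling choices behind `dietopt`: the optimization
model and its assumptions, the reference-value handling, the nutrient-density
metrics, what the synthetic data generator does and does not emulate, and the
numerical details a maintainer would want before changing a tolerance.

## The deviation objective

The central question — "the smallest realistic dietary shift that satisfies
the constraints" — is posed as a convex quadratic program over g/day amounts
*x* with baseline *b*:

    D(x) = Σᵢ wᵢ ((xᵢ − bᵢ) / sᵢ)²,    sᵢ = max(bᵢ, s_min)

Choices and rationale:

* **Relative deviation.** Dividing by *sᵢ* makes a 10 % change of a staple
  (300 g of milk) comparable to a 10 % change of a condiment (10 g), rather
  than letting bulky foods dominate the objective.  Commercial diet-shift
  tools behave the same way qualitatively; since no published objective
  exists for them, ours is a documented reconstruction, and absolute
  objective values should never be compared across packages — only across
  scenarios run with the same weights.
* **`s_min` = 10 g/day** (configurable).  Foods absent from the baseline —
  above all the newly added fortified variants — would otherwise have scale
  0 and an infinite penalty.  With `s_min` = 10, consuming 70 g of fortified
  bread costs the same as a 70 g move of any food with a 10 g/day baseline:
  admissible but not free.  This is the single most consequential free
  choice in the model; it is exposed as a parameter of
  `minimize_deviation` and logged in solver reports.
* **Weights** are popularity (intake-frequency proxies, mean 1 over consumed
  foods; zero-baseline foods get the median weight of consumed foods).  A
  scenario's `popularity_factor` λ ∈ [0, 1] enters as `w**λ`: λ = 1 keeps the
  full popularity structure, λ = 0 makes all foods equal ("compromising on
  popularity").  A plain multiplicative rescaling of all weights would not
  change the minimizer at all — the objective is scale-invariant — which is
  why the exponent form is used.
* The QP is strictly convex whenever all weights are positive, so the
  optimizer is deterministic and its minimizer unique; no randomness exists
  anywhere in the solver path.

## Constraints

Nutrient references are stored sex-averaged at the population's mean energy
intake (2243 kcal/day) and energy-adjusted to the 2000 kcal/day analysis
basis by linear scaling of absolute bounds (15 µg/d vitamin D → 13.375…,
displayed as 13.4 at three significant figures; values keep full precision
internally).  Percent-of-energy bounds (total fat < 30 %E, saturated fat
< 10 %E, trans fat < 1 %E, free sugars < 10 %E) are invariant under energy
adjustment and are linearized against the diet's realized energy:
`factor·(n·x) − (p/100)·(e·x) ≤ 0`.  Cholesterol (300 mg/d) and sodium
(2 g/d) are absolute upper bounds and are energy-adjusted like the lower
bounds.

Added sugars are not a composition column.  They are estimated as the mono-
and di-saccharides of the categories where those sugars are almost
exclusively added (sugar/snacks, cakes, soft drinks) plus dairy mono+di in
excess of intrinsic lactose, floored at zero.  Because the per-food
coefficient is constant, the estimate is linear in the diet and doubles as
an optimizer row.

The packaged reference CSV (`data/default_references.csv`) has exactly 26
qualifying and 6 disqualifying nutrients.  The six nutrients to limit are
fixed by the MER definition; the identity of the 26 qualifying nutrients is
a **reconstruction** assembled from standard European adult reference
panels, shipped as an editable file rather than hard-coded, precisely so a
user with the authoritative list can swap it in.  Energy conversion factors
are 4 kcal/g for carbohydrate and protein, 9 for fat, 7 for alcohol.

## Scenarios

* **S1** — vitamin D goal 13.4 µg/d, references enforced, *no* energy cap.
* **S2** — maximize vitamin D within 2000 kcal (the vitamin D lower bound is
  removed; it is unreachable there by construction).  Solved
  lexicographically: LP maximum first, then the deviation QP restricted to
  diets within a relative ε = 10⁻⁶ of that maximum.
* **S3** — goal 13.4 µg/d within 2000 kcal after adding fortified bread
  (6 µg/100 g, ≤ 2 × 35 g servings), milk (2 µg/100 g, ≤ 2 × 150 g) and oil
  (15 µg/100 g, uncapped).  Serving sizes are household-measure defaults
  (35 g slice, 150 g glass) and configurable; only the product
  serving × count enters the model.  Oil is left uncapped deliberately:
  only bread and milk warrant intake caps as foods eaten in discrete
  servings.
* **S4a / S4b** — S3 plus a CO₂ cap of 3.9 or 3.5 kg CO₂ eq/day (absolute
  caps, not fractions of realized baseline; the generator targets a ~3.9
  baseline so "10 % reduced" is meaningful).  S4b uses λ = 0.  A
  `drop_lower_bounds` flag exposes the remove-the-recommendations variant;
  off by default.

Scenario density reports are computed on the diet standardized to 2000 kcal
*when the realized energy is at or below 2000 kcal* (scaling up cannot push
a satisfied lower bound below 100 %).  A diet above the basis — S1, where
the cap is removed — is scored as optimized: scaling a constraint-satisfying
4000 kcal diet down to 2000 kcal would mechanically report inadequacy the
optimizer was never asked to prevent.  This choice is what makes "every
lower bound enforced ⇒ MAR = 100 %" hold across all scenarios.

The fortificant's carbon is booked on the fortified food
(level × 200 kg CO₂ eq per kg of vitamin D₃ ≈ 10⁻⁶ kg per 100 g), its mass
and energy are not: at microgram scale they are below the resolution of any
composition table.

## Synthetic data and calibration

The generator emulates the *statistical structure* of a national
food-consumption + composition + LCA dataset, not any actual database:

* 250 foods in 15 report categories with category-specific uniform ranges
  for energy density and carbon intensity, and lognormal (right-skewed,
  non-negative) nutrient contents whose category multipliers encode the
  ecology that matters to the analysis — omega-3 only in fish, B12 only in
  animal foods, fiber/folate/potassium in plants, calcium in dairy,
  cholesterol in eggs, vitamin D concentrated in fish ≫ eggs > meat > dairy
  plus voluntarily fortified spreads and cereals, ~0 in plants.
* Baseline intakes are drawn per category (Dutch-style pattern: much milk,
  bread and soft drink, little fish) and rescaled so baseline energy is
  exactly 2243 kcal/day; carbon intensities are then rescaled so the
  baseline footprint is exactly 3.9 kg CO₂ eq/day (a global scaling, so the
  animal > plant intensity ordering is preserved).
* **Calibration** rescales each nutrient column so the 2000 kcal-standardized
  baseline hits a configured adequacy target exactly.  The targets (14
  nutrients below 100 %, 12 above) are chosen so the truncated mean is
  exactly the 86 % MAR of the study population with vitamin D lowest at
  21 % of its adjusted adequate intake; the six excess targets average to
  the 120 % MER.  Because the rescales are exact, these properties hold by
  construction — and the test suite still re-derives them through the public
  metrics, never through generator internals.
* **Gap iteration**: after levelling, the maximization LP (all references
  except the vitamin D lower bound, energy ≤ 2000 kcal) is solved.  While
  its optimum exceeds 95 % of the adequate intake, the vitamin D content of
  the category carrying most of the LP optimum is shrunk by 0.7 and the
  baseline re-normalized to 21 %; this converges in a few iterations (cap
  50) because the baseline total is pinned while the densest carrier is
  diluted.  On the default configuration the resulting 2000 kcal maximum is
  ~12 µg/d — below the 13.4 goal, mirroring the real-data structure where
  only ~9.6 µg/d was achievable.
* Calibration order is energy → carbon → nutrient levels → vitamin D gap;
  later steps only touch nutrient columns, so the earlier energy/carbon
  targets are not perturbed.

What the generator does **not** emulate: the covariance of nutrients within
a food (columns are calibrated independently, so e.g. saturated fat is not
constrained to be ≤ total fat within each item), person-level intake
variation (one population-average diet), seasonal and brand variation, and
any real database's actual values.  Passing tests therefore demonstrate that
the pipeline's logic and feasibility structure are correct on data with the
assumed shape — not that real-data headline numbers (fold changes, the 9.6
µg/d maximum, the 8 % footprint increase) are reproduced.  Those depend on
undeposited licensed inputs and a proprietary objective, and the synthetic
counterparts can differ: on the default synthetic database, for instance,
the optimized fortified diet *lowers* total CO₂, because the exchange of
fatty animal foods against the saturated-fat ceiling outweighs the extra
fish.

## Numerics

* The deviation QP is solved with `scipy.optimize.minimize`
  (`trust-constr`, exact gradient and diagonal Hessian) after an LP
  feasibility pre-check (`scipy.optimize.linprog`).  LP stages use the HiGHS
  method directly.  Both are deterministic for fixed inputs.
* Constraint rows are normalized to unit ∞-norm before solving, so the
  feasibility tolerance τ = 10⁻⁶ is comparable across nutrients with very
  different magnitudes.  `verify_solution` recomputes every row from raw
  food data and reports violations above τ.
* Infeasible systems are diagnosed with a deletion filter: a row is
  reported when removing it alone restores feasibility (phase-1 slack
  distributions are not unique, so slack location is not a reliable
  indicator).  A goal scenario that cannot be met within its energy cap
  thus names exactly the goal row and the cap.
* Interior-point solutions sit up to ~10⁻³ g inside active constraints;
  "binding" classification uses that slack, and hand-value tests assert
  amounts at 0.01 g precision — far below any dietary significance.
* Fold changes over a zero baseline category are reported as +∞ rather than
  an arbitrary large number; ties for the first-limiting nutrient are
  reported together, sorted alphabetically.
* Degenerate inputs: all-zero weights → explicit `unbounded` flag;
  zero-energy diets cannot be standardized (error); a nutrient the baseline
  does not supply at all cannot be calibrated (explicit calibration error).

## Problem sizes

Default runs use the full 250-food database; a single scenario (constraint
assembly + feasibility LP + QP) solves in ~2 s on one CPU, calibration in
well under a second.  The test-suite cap sweeps use a 87-food database with
the same category structure to keep repeated solves cheap; the solver
oracles run on 2–4 food instances where dense grid search and vertex
enumeration are exact.

## Known limitations

* The objective and popularity weighting are reconstructions; headline
  numbers from analyses built on other tools are not expected to match.
* Only carbon is modelled among environmental indicators; no land, water or
  biodiversity accounting.
* References are a single adult sex-average; no age/life-stage
  stratification, pregnancy or lactation.
* Amounts are continuous g/day; no discrete-serving optimization.
* Sun exposure and vitamin D status (serum 25(OH)D) are out of scope — the
  model speaks only about dietary intake relative to the adequate intake.
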