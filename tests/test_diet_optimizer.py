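"""Solver correctness against independent brute-force oracles.

The deviation QP is checked against a dense grid search (coarse pass over
the whole box, 0.01 g refinement around the best grid point); nutrient
maximization is checked against exact vertex enumeration of the LP
polytope.  Both oracles know nothing about the solver path.
"""

import itertools

import numpy as np
import pytest

from dietopt import (
    LinearConstraintSet,
    deviation_objective,
    maximize_nutrient,
    minimize_deviation,
    verify_solution,
)
from dietopt.food_model import DietVector

from conftest import make_diet, make_food, make_foodlist

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def grid_search_qp(b, w, rows, box_hi, s_min=10.0):
    """Dense grid-search minimizer of the deviation objective.

    Successively refined dense grids over [0, box_hi]^n (steps 2.5, 0.1,
    0.01 g); each stage searches a window around the previous stage's best
    feasible point.  Returns (x, objective) or (None, inf) when no grid
    point is feasible.
    """
    n = len(b)
    s = np.maximum(b, s_min)

    def best_on(axes):
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        ok = np.ones(len(pts), bool)
        for coeffs, relation, bound in rows:
            v = pts @ np.asarray(coeffs)
            ok &= (v <= bound + 1e-9) if relation == "<=" else (v >= bound - 1e-9)
        if not ok.any():
            return None, np.inf
        pts = pts[ok]
        d = (pts - b) / s
        obj = (w * d * d).sum(axis=1)
        i = int(np.argmin(obj))
        return pts[i], float(obj[i])

    x, obj = best_on([np.arange(0.0, hi + 2.5, 2.5) for hi in box_hi])
    if x is None:
        return None, np.inf
    for step, window in ((0.1, 2.6), (0.02, 0.6), (0.01, 0.1)):
        axes = [
            np.arange(max(0.0, x[i] - window), min(box_hi[i], x[i] + window) + step, step)
            for i in range(n)
        ]
        x, obj = best_on(axes)
    return x, obj


def vertex_enumeration_lp(c, rows, lo, hi):
    """Exact LP maximum of c.x by enumerating basic feasible points.

    All constraint rows plus the box faces are candidate active sets; every
    n-subset's linear system is solved and feasible solutions are scored.
    """
    n = len(c)
    planes = []
    for coeffs, relation, bound in rows:
        planes.append((np.asarray(coeffs, float), float(bound)))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        planes.append((e.copy(), float(lo[i])))
        if np.isfinite(hi[i]):
            planes.append((e.copy(), float(hi[i])))

    def feasible(x):
        if np.any(x < lo - 1e-8) or np.any(x > hi + 1e-8):
            return False
        for coeffs, relation, bound in rows:
            v = coeffs @ x
            if relation == "<=" and v > bound + 1e-8:
                return False
            if relation == ">=" and v < bound - 1e-8:
                return False
        return True

    best = -np.inf
    best_x = None
    for combo in itertools.combinations(planes, n):
        A = np.array([p[0] for p in combo])
        rhs = np.array([p[1] for p in combo])
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        x = np.linalg.solve(A, rhs)
        if feasible(x):
            v = float(c @ x)
            if v > best:
                best, best_x = v, x
    return best, best_x


# ---------------------------------------------------------------------------
# minimize_deviation
# ---------------------------------------------------------------------------


def _foods_with_upper(items, upper):
    foods = make_foodlist(*items)
    return foods, upper


class TestMinimizeDeviation:
    def test_feasible_baseline_returned_unchanged(self):
        foods = make_foodlist(make_food("a", vitamin_d=5.0), make_food("b"))
        cons = LinearConstraintSet()
        cons.add(foods.nutrient_per_gram("vitamin_d"), ">=", 1.0, "vitamin_d:lower")
        res = minimize_deviation(foods.baseline_vector(), foods, cons)
        assert res.status == "optimal"
        np.testing.assert_allclose(res.diet.amounts, [100.0, 100.0], atol=1e-3)
        assert res.objective == pytest.approx(0.0, abs=1e-10)

    def test_single_binding_constraint_kkt_solution(self):
        """Two foods at 100 g baseline, vitamin D only in food 1 at
        0.05 ug/g, requirement 10 ug/d: the optimum sits on the constraint
        boundary at x = (200, 100)."""
        foods = make_foodlist(make_food("a", vitamin_d=5.0), make_food("b"))
        cons = LinearConstraintSet()
        cons.add([0.05, 0.0], ">=", 10.0, "vitamin_d:lower")
        res = minimize_deviation(foods.baseline_vector(), foods, cons)
        assert res.status == "optimal"
        np.testing.assert_allclose(res.diet.amounts, [200.0, 100.0], atol=0.01)
        assert "vitamin_d:lower" in res.binding

    def test_infeasible_reports_hint(self):
        foods = make_foodlist(make_food("a"), make_food("b"))
        cons = LinearConstraintSet()
        cons.add([0.0, 0.0], ">=", 10.0, "vitamin_d:lower")
        res = minimize_deviation(foods.baseline_vector(), foods, cons)
        assert res.status == "infeasible"
        assert "vitamin_d:lower" in res.solver_report["hint"]

    def test_degenerate_all_zero_weights_flagged(self):
        foods = make_foodlist(make_food("a"))
        res = minimize_deviation(foods.baseline_vector(), foods, LinearConstraintSet(), weights=[0.0])
        assert res.status == "unbounded"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_matches_grid_search_oracle(self, seed):
        """Random 2-3 food, 1-3 constraint QPs agree with dense grid search
        within 0.5 g per food and 1e-3 on the objective."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 4))
        b = rng.uniform(40, 160, n).round(0)
        w = rng.uniform(0.5, 2.0, n).round(2)
        foods = make_foodlist(
            *[make_food(f"f{i}", baseline=b[i], popularity=w[i]) for i in range(n)]
        )
        box_hi = np.full(n, 320.0)
        m = int(rng.integers(1, 4))
        rows = []
        cons = LinearConstraintSet(upper=box_hi)
        for j in range(m):
            coeffs = rng.uniform(0.1, 1.0, n).round(2)
            relation = "<=" if rng.random() < 0.5 else ">="
            at_b = float(coeffs @ b)
            bound = round(at_b * (1.25 if relation == ">=" else 0.8), 1)
            rows.append((coeffs, relation, bound))
            cons.add(coeffs, relation, bound, f"row{j}")
        baseline = make_diet(b, foods)
        res = minimize_deviation(baseline, foods, cons, weights=w)
        x_grid, obj_grid = grid_search_qp(b, w, rows, box_hi)
        if x_grid is None:
            assert res.status == "infeasible"
            return
        assert res.status == "optimal"
        np.testing.assert_allclose(res.diet.amounts, x_grid, atol=0.5)
        assert res.objective == pytest.approx(obj_grid, abs=1e-3)

    def test_certificate_never_beaten_by_feasible_point(self):
        """The reported optimum is at least as good as any feasible diet."""
        foods = make_foodlist(
            make_food("a", vitamin_d=4.0, baseline=120),
            make_food("b", vitamin_d=0.5, baseline=250),
        )
        cons = LinearConstraintSet()
        cons.add(foods.nutrient_per_gram("vitamin_d"), ">=", 12.0, "vitamin_d:lower")
        res = minimize_deviation(foods.baseline_vector(), foods, cons)
        w = foods.popularity_vector()
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.uniform(0, 500, 2)
            if 0.04 * x[0] + 0.005 * x[1] >= 12.0:
                assert res.objective <= deviation_objective(
                    x, foods.baseline_vector().amounts, w
                ) + 1e-6


# ---------------------------------------------------------------------------
# maximize_nutrient
# ---------------------------------------------------------------------------


class TestMaximizeNutrient:
    def test_two_food_vertex_solution(self):
        """Foods A (2 kcal/g, 0.05 ug/g) and B (1 kcal/g, no vitamin D),
        energy <= 2000 and B >= 500 g: optimum is A = 750 g, 37.5 ug/d."""
        foods = make_foodlist(
            make_food("A", energy=200, vitamin_d=5.0),
            make_food("B", energy=100, vitamin_d=0.0),
        )
        cons = LinearConstraintSet()
        cons.add(foods.energy_per_gram(), "<=", 2000.0, "energy:upper")
        cons.add([0.0, 1.0], ">=", 500.0, "b:floor")
        max_level, res = maximize_nutrient(foods.baseline_vector(), foods, cons, "vitamin_d")
        assert max_level == pytest.approx(37.5)
        assert res.status == "optimal"
        assert res.diet.amounts[0] == pytest.approx(750.0, abs=1e-3)

    def test_single_food_closed_form(self):
        foods = make_foodlist(make_food("A", energy=200, vitamin_d=5.0))
        cons = LinearConstraintSet()
        cons.add(foods.energy_per_gram(), "<=", 1000.0, "energy:upper")
        max_level, _ = maximize_nutrient(foods.baseline_vector(), foods, cons, "vitamin_d")
        assert max_level == pytest.approx(1000.0 / 200 * 5.0)  # cap/density * content

    def test_unbounded_without_cap(self):
        foods = make_foodlist(make_food("A", energy=200, vitamin_d=5.0))
        max_level, res = maximize_nutrient(
            foods.baseline_vector(), foods, LinearConstraintSet(), "vitamin_d"
        )
        assert np.isinf(max_level)
        assert res.status == "unbounded"

    @pytest.mark.parametrize("seed", [10, 11, 12, 13, 14])
    def test_matches_vertex_enumeration(self, seed):
        """Stage-1 maxima agree exactly with brute-force vertex enumeration
        on <=4-variable LPs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        foods = make_foodlist(
            *[
                make_food(f"f{i}", energy=round(float(rng.uniform(50, 400)), 0),
                          vitamin_d=round(float(rng.uniform(0, 8)), 1))
                for i in range(n)
            ]
        )
        hi = rng.uniform(200, 600, n).round(0)
        cons = LinearConstraintSet(upper=hi)
        rows = [(foods.energy_per_gram(), "<=", 2000.0)]
        cons.add(foods.energy_per_gram(), "<=", 2000.0, "energy:upper")
        if rng.random() < 0.7:
            coeffs = rng.uniform(0.01, 0.5, n).round(2)
            rows.append((coeffs, ">=", 5.0))
            cons.add(coeffs, ">=", 5.0, "floor")
        max_level, res = maximize_nutrient(foods.baseline_vector(), foods, cons, "vitamin_d")
        c = foods.nutrient_per_gram("vitamin_d")
        best, _ = vertex_enumeration_lp(c, [(r[0] * 1.0, r[1], r[2]) for r in rows], np.zeros(n), hi)
        # rows are scaled inside the solver; compare the achieved level
        assert max_level == pytest.approx(best, rel=1e-7, abs=1e-7)
        if res.status == "optimal":
            assert float(c @ res.diet.amounts) == pytest.approx(max_level, rel=1e-5)


# ---------------------------------------------------------------------------
# verify_solution
# ---------------------------------------------------------------------------


class TestVerifySolution:
    def test_optimal_solution_verifies_clean(self):
        foods = make_foodlist(make_food("a", vitamin_d=5.0), make_food("b"))
        cons = LinearConstraintSet()
        cons.add([0.05, 0.0], ">=", 10.0, "vitamin_d:lower")
        res = minimize_deviation(foods.baseline_vector(), foods, cons)
        assert verify_solution(res, foods, cons) == []

    def test_perturbed_diet_reports_violation(self):
        foods = make_foodlist(make_food("a", vitamin_d=5.0), make_food("b"))
        cons = LinearConstraintSet()
        cons.add([0.05, 0.0], "=", 10.0, "vitamin_d:eq")
        res = minimize_deviation(foods.baseline_vector(), foods, cons)
        res.diet = DietVector(res.diet.amounts * np.array([1.1, 1.0]), foods.food_ids)
        report = verify_solution(res, foods, cons)
        assert report and report[0][0] == "vitamin_d:eq"

    def test_empty_constraints_empty_report(self):
        foods = make_foodlist(make_food("a"))
        res = minimize_deviation(foods.baseline_vector(), foods, LinearConstraintSet())
        assert verify_solution(res, foods, LinearConstraintSet()) == []
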