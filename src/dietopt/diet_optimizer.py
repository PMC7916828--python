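"""Core solvers: closest-diet quadratic program and nutrient maximization.

The central operation mirrors goal-programming diet models: find the diet
``x`` (g/day per food) that minimizes a popularity-weighted squared
relative deviation from the observed baseline diet ``b``,

    D(x) = sum_i w_i ((x_i - b_i) / s_i)^2,      s_i = max(b_i, s_min),

subject to linear nutrient/energy/carbon constraints and per-food intake
bounds.  ``s_min`` (default 10 g/day) gives foods absent from the baseline
(e.g. newly added fortified variants) a finite penalty scale so they remain
admissible.  The problem is a convex QP with a unique minimizer whenever
all weights are positive; no randomness enters anywhere, so results are
bit-reproducible for fixed inputs.

Nutrient maximization (e.g. "the most vitamin D achievable within
2000 kcal") is solved lexicographically: a linear program finds the
maximum, then the deviation QP picks the most baseline-like diet among
those within a relative tolerance of that maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .food_model import DietVector, FoodList

__all__ = [
    "S_MIN_DEFAULT",
    "FEASIBILITY_TOL",
    "LEXICO_EPS",
    "ConstraintRow",
    "LinearConstraintSet",
    "OptimizationResult",
    "InfeasibleError",
    "minimize_deviation",
    "maximize_nutrient",
    "verify_solution",
    "deviation_objective",
    "deviation_scales",
]

#: Penalty scale floor (g/day) for zero-baseline foods; configurable per call.
S_MIN_DEFAULT = 10.0
#: Feasibility tolerance in constraint units after rows are normalized to
#: unit infinity-norm.
FEASIBILITY_TOL = 1e-6
#: Relative tolerance for the lexicographic second stage.
LEXICO_EPS = 1e-6

Relation = Literal["<=", ">=", "="]


@dataclass(frozen=True)
class ConstraintRow:
    """One linear constraint: coeffs . x  <relation>  bound.

    Coefficients are per *gram* of each food, aligned to the FoodList.
    ``label`` records the originating quantity (nutrient id, "energy",
    "carbon", ...) and bound side for diagnostics.
    """

    coeffs: np.ndarray
    relation: Relation
    bound: float
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        if self.relation not in ("<=", ">=", "="):
            raise ValueError(f"bad relation {self.relation!r}")

    def residual(self, x: np.ndarray) -> float:
        """Signed violation: positive = violated by that amount."""
        v = float(self.coeffs @ x)
        if self.relation == "<=":
            return v - self.bound
        if self.relation == ">=":
            return self.bound - v
        return abs(v - self.bound)

    def scaled(self) -> "ConstraintRow":
        """Row normalized to unit infinity-norm (tolerances comparable)."""
        norm = float(np.max(np.abs(self.coeffs))) if self.coeffs.size else 0.0
        if norm == 0.0 or norm == 1.0:
            return self
        return replace(self, coeffs=self.coeffs / norm, bound=self.bound / norm)


@dataclass
class LinearConstraintSet:
    """Rows plus per-food variable bounds (lower 0, upper max_intake)."""

    rows: list[ConstraintRow] = field(default_factory=list)
    lower: np.ndarray | None = None  # per-food g/day, default 0
    upper: np.ndarray | None = None  # per-food g/day, default +inf

    def variable_bounds(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.zeros(n) if self.lower is None else np.asarray(self.lower, float)
        hi = np.full(n, np.inf) if self.upper is None else np.asarray(self.upper, float)
        return lo, hi

    def add(self, coeffs, relation: Relation, bound: float, label: str) -> None:
        self.rows.append(ConstraintRow(np.asarray(coeffs, float), relation, bound, label))

    def with_rows(self, rows: list[ConstraintRow]) -> "LinearConstraintSet":
        return LinearConstraintSet(rows=rows, lower=self.lower, upper=self.upper)

    def drop(self, predicate) -> "LinearConstraintSet":
        return self.with_rows([r for r in self.rows if not predicate(r)])

    def scaled_rows(self) -> list[ConstraintRow]:
        return [r.scaled() for r in self.rows]

    def as_linprog(self, n: int):
        """(A_ub, b_ub, A_eq, b_eq, bounds) for scipy.optimize.linprog."""
        a_ub, b_ub, a_eq, b_eq = [], [], [], []
        for r in self.scaled_rows():
            if r.relation == "<=":
                a_ub.append(r.coeffs)
                b_ub.append(r.bound)
            elif r.relation == ">=":
                a_ub.append(-r.coeffs)
                b_ub.append(-r.bound)
            else:
                a_eq.append(r.coeffs)
                b_eq.append(r.bound)
        lo, hi = self.variable_bounds(n)
        bounds = list(zip(lo, hi))
        return (
            np.array(a_ub) if a_ub else None,
            np.array(b_ub) if b_ub else None,
            np.array(a_eq) if a_eq else None,
            np.array(b_eq) if b_eq else None,
            bounds,
        )


@dataclass
class OptimizationResult:
    diet: DietVector
    status: Literal["optimal", "infeasible", "unbounded"]
    objective: float
    binding: list[str] = field(default_factory=list)
    solver_report: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class InfeasibleError(RuntimeError):
    """Raised internally when a constraint system has no feasible point."""


# ---------------------------------------------------------------------------
# Objective helpers
# ---------------------------------------------------------------------------


def deviation_scales(baseline: np.ndarray, s_min: float = S_MIN_DEFAULT) -> np.ndarray:
    return np.maximum(np.asarray(baseline, float), s_min)


def deviation_objective(
    x: np.ndarray,
    baseline: np.ndarray,
    weights: np.ndarray,
    s_min: float = S_MIN_DEFAULT,
) -> float:
    s = deviation_scales(baseline, s_min)
    d = (np.asarray(x, float) - baseline) / s
    return float(np.sum(weights * d * d))


# ---------------------------------------------------------------------------
# Feasibility (phase-1 LP)
# ---------------------------------------------------------------------------


def _feasible_point(
    constraints: LinearConstraintSet, n: int
) -> tuple[np.ndarray | None, list[str]]:
    """Phase-1 LP: minimize total constraint slack.

    Returns a feasible point (slack within tolerance) or ``None`` plus the
    labels of rows that still need slack — an irreducible-infeasibility
    hint for the caller's error message.
    """
    rows = constraints.scaled_rows()
    m = len(rows)
    lo, hi = constraints.variable_bounds(n)
    if m == 0:
        x0 = np.clip(np.zeros(n), lo, np.where(np.isfinite(hi), hi, 0.0))
        return x0, []
    # variables: x (n) then one slack per row
    c = np.concatenate([np.zeros(n), np.ones(m)])
    a_ub, b_ub, a_eq, b_eq = [], [], [], []
    for j, r in enumerate(rows):
        e = np.zeros(m)
        e[j] = 1.0
        if r.relation == "<=":
            a_ub.append(np.concatenate([r.coeffs, -e]))
            b_ub.append(r.bound)
        elif r.relation == ">=":
            a_ub.append(np.concatenate([-r.coeffs, -e]))
            b_ub.append(-r.bound)
        else:  # equality: two slack-relaxed inequalities sharing one slack
            a_ub.append(np.concatenate([r.coeffs, -e]))
            b_ub.append(r.bound)
            a_ub.append(np.concatenate([-r.coeffs, -e]))
            b_ub.append(-r.bound)
    bounds = list(zip(lo, hi)) + [(0, None)] * m
    res = optimize.linprog(
        c,
        A_ub=np.array(a_ub),
        b_ub=np.array(b_ub),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        return None, [r.label for r in rows]
    slacks = res.x[n:]
    if np.any(slacks > 10 * FEASIBILITY_TOL):
        return None, _critical_rows(constraints, n)
    return res.x[:n], []


def _critical_rows(constraints: LinearConstraintSet, n: int) -> list[str]:
    """Deletion filter: a row is critical when removing it (alone) makes
    the system feasible — it belongs to every irreducible infeasible
    subset.  The phase-1 slack distribution is not unique, so this is the
    reliable way to name the conflicting constraints."""
    critical = []
    for j, row in enumerate(constraints.rows):
        reduced = constraints.with_rows(
            [r for k, r in enumerate(constraints.rows) if k != j]
        )
        a_ub, b_ub, a_eq, b_eq, bounds = reduced.as_linprog(n)
        res = optimize.linprog(
            np.zeros(n), A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq,
            bounds=bounds, method="highs",
        )
        if res.status == 0:
            critical.append(row.label)
    return critical or [r.label for r in constraints.rows]


# ---------------------------------------------------------------------------
# Deviation QP
# ---------------------------------------------------------------------------


def minimize_deviation(
    baseline: DietVector,
    foods: FoodList,
    constraints: LinearConstraintSet,
    weights: Sequence[float] | np.ndarray | None = None,
    s_min: float = S_MIN_DEFAULT,
    tol: float = FEASIBILITY_TOL,
) -> OptimizationResult:
    """Find the feasible diet closest to baseline (convex QP).

    ``weights`` defaults to the foods' popularity weights.  Returns status
    ``infeasible`` (with offending row labels in ``solver_report["hint"]``)
    when the constraint system admits no diet.
    """
    baseline.check_aligned(foods)
    n = len(foods)
    b = baseline.amounts
    w = foods.popularity_vector() if weights is None else np.asarray(weights, float)
    if w.shape != (n,):
        raise ValueError("weights not aligned to foods")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if np.all(w == 0):
        return OptimizationResult(
            diet=baseline,
            status="unbounded",
            objective=np.nan,
            solver_report={"hint": "all deviation weights are zero (degenerate)"},
        )
    s = deviation_scales(b, s_min)
    q = w / (s * s)  # diagonal Hessian / 2

    x_feas, bad = _feasible_point(constraints, n)
    if x_feas is None:
        return OptimizationResult(
            diet=baseline,
            status="infeasible",
            objective=np.nan,
            solver_report={"hint": f"no diet satisfies: {', '.join(bad)}"},
        )

    rows = constraints.scaled_rows()
    lo, hi = constraints.variable_bounds(n)

    lin = []
    for r in rows:
        if r.relation == "<=":
            lin.append(optimize.LinearConstraint(r.coeffs, -np.inf, r.bound))
        elif r.relation == ">=":
            lin.append(optimize.LinearConstraint(r.coeffs, r.bound, np.inf))
        else:
            lin.append(optimize.LinearConstraint(r.coeffs, r.bound, r.bound))

    def fun(x):
        d = x - b
        return float(np.sum(q * d * d))

    def jac(x):
        return 2.0 * q * (x - b)

    hess_mat = np.diag(2.0 * q)

    x0 = np.clip(b, lo, np.minimum(hi, np.where(np.isfinite(hi), hi, b)))
    # start from a feasible point when the clipped baseline violates rows
    if any(r.residual(x0) > tol for r in rows):
        x0 = x_feas

    res = optimize.minimize(
        fun,
        x0,
        jac=jac,
        hess=lambda x: hess_mat,
        method="trust-constr",
        constraints=lin,
        bounds=optimize.Bounds(lo, hi),
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000, "verbose": 0},
    )
    x = np.clip(res.x, lo, hi)
    viol = max((r.residual(x) for r in rows), default=0.0)
    if viol > 10 * tol:
        # polish from the phase-1 feasible point
        res = optimize.minimize(
            fun,
            x_feas,
            jac=jac,
            hess=lambda x: hess_mat,
            method="trust-constr",
            constraints=lin,
            bounds=optimize.Bounds(lo, hi),
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000, "verbose": 0},
        )
        x = np.clip(res.x, lo, hi)
        viol = max((r.residual(x) for r in rows), default=0.0)

    # binding = active within the solver's attainable precision (rows are
    # unit-inf-norm scaled, so this is a per-gram-scale slack)
    binding_tol = max(1e-3, 100 * tol)
    binding = [
        r.label for r in rows if r.relation == "=" or abs(r.residual(x)) <= binding_tol
    ]
    diet = DietVector(np.maximum(x, 0.0), foods.food_ids)
    return OptimizationResult(
        diet=diet,
        status="optimal",
        objective=deviation_objective(diet.amounts, b, w, s_min),
        binding=binding,
        solver_report={
            "iterations": int(getattr(res, "niter", -1)),
            "max_violation": float(viol),
            "tol": tol,
        },
    )


# ---------------------------------------------------------------------------
# Nutrient maximization (lexicographic LP -> QP)
# ---------------------------------------------------------------------------


def maximize_nutrient(
    baseline: DietVector,
    foods: FoodList,
    constraints: LinearConstraintSet,
    nutrient_id: str,
    weights: Sequence[float] | np.ndarray | None = None,
    s_min: float = S_MIN_DEFAULT,
    eps: float = LEXICO_EPS,
) -> tuple[float, OptimizationResult]:
    """Maximum achievable daily amount of one nutrient, plus the most
    baseline-like diet achieving (1 - eps) of it.

    Stage 1 is a linear program (deterministic HiGHS solve); an explicit
    ``unbounded`` status is returned when no energy/intake cap limits the
    nutrient.
    """
    baseline.check_aligned(foods)
    n = len(foods)
    c = foods.nutrient_per_gram(nutrient_id)  # canonical unit per gram
    a_ub, b_ub, a_eq, b_eq, bounds = constraints.as_linprog(n)
    res = optimize.linprog(
        -c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    if res.status == 3:
        return np.inf, OptimizationResult(
            diet=baseline,
            status="unbounded",
            objective=np.nan,
            solver_report={"hint": f"no cap bounds {nutrient_id}; add an energy or intake limit"},
        )
    if res.status != 0:
        return np.nan, OptimizationResult(
            diet=baseline,
            status="infeasible",
            objective=np.nan,
            solver_report={"hint": res.message},
        )
    max_level = float(-res.fun)

    # stage 2: nearest-to-baseline diet among near-maximal ones
    stage2 = LinearConstraintSet(
        rows=list(constraints.rows), lower=constraints.lower, upper=constraints.upper
    )
    stage2.add(c, ">=", (1.0 - eps) * max_level, f"{nutrient_id}:lexicographic")
    result = minimize_deviation(baseline, foods, stage2, weights=weights, s_min=s_min)
    return max_level, result


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------


def verify_solution(
    result: OptimizationResult,
    foods: FoodList,
    constraints: LinearConstraintSet,
    tol: float = FEASIBILITY_TOL,
) -> list[tuple[str, float]]:
    """Recompute every (scaled) constraint row from raw food data; return
    ``(label, violation)`` pairs exceeding ``tol``.  Empty iff the solution
    satisfies all rows within tolerance."""
    if result.status != "optimal":
        raise ValueError("verify_solution requires an optimal result")
    x = result.diet.amounts
    report = []
    for r in constraints.scaled_rows():
        v = r.residual(x)
        if v > tol:
            report.append((r.label, float(v)))
    lo, hi = constraints.variable_bounds(len(foods))
    for i, (xi, l, h) in enumerate(zip(x, lo, hi)):
        if xi < l - tol or xi > h + tol:
            report.append((f"bound:{foods.food_ids[i]}", float(max(l - xi, xi - h))))
    return report
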