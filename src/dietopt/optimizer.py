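"""The three LP model families.

* **NUTR** — minimize departure from the observed diet subject to the
  nutritional and acceptability constraints (no GHGE constraint), to see
  what achieving nutritional adequacy alone does to emissions.
* **NUTR-GHGE-ρ** — the same, plus a cap forcing diet GHGE down to
  ``(1 − ρ) ×`` observed, applied on a ladder of 10% steps until the first
  infeasible step.
* **NUTR-GHGE-MINI** — minimize diet GHGE under the same nutritional (and,
  by default, acceptability) constraints; its optimum defines the maximal
  achievable GHGE reduction.

Departure is ``f = Σᵢ |Qᵢ − Qᵢ_obs| / Qᵢ_obs``, the sum of absolute
per-item relative quantity changes.  The absolute value is linearized
exactly with one auxiliary variable per item (dᵢ ≥ ±(qᵢ − Qᵢ_obs)/Qᵢ_obs),
so the LP optimum is the true optimum of f.  Items observed at zero have an
undefined relative change; by default they are excluded from the objective
but kept as decision variables inside their acceptability box
(``zero_obs_policy="exclude"``); the ``"epsilon"`` policy instead uses a
0.1 g denominator for them.

All LPs are solved with HiGHS via :func:`scipy.optimize.linprog`.  Among
alternative optima the solver's tie-break is accepted: downstream code and
tests should rely on objective values and constraint activity, not on the
exact quantity vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .constraints import (
    ConstraintSet,
    LinearConstraint,
    build_ghge_cap,
    build_model_constraints,
    check_feasibility,
)
from .food_model import (
    DietVector,
    FoodDatabase,
    NutrientTotals,
    PopulationProfile,
    evaluate_diet,
)

__all__ = [
    "Solution",
    "LadderResult",
    "LadderError",
    "minimize_departure",
    "minimize_ghge",
    "run_nutr",
    "run_ladder",
]

#: HiGHS feasibility/optimality tolerance.
SOLVER_TOL = 1e-7
#: Relative tolerance at which returned solutions are audited.
AUDIT_TOL = 1e-6
#: Relative slack threshold below which a constraint is reported active.
ACTIVE_TOL = 1e-7
#: Denominator for zero-observed items under the "epsilon" policy (grams).
ZERO_OBS_EPSILON_G = 0.1


class LadderError(RuntimeError):
    """The ladder cannot start (the unconstrained NUTR model is infeasible)."""


@dataclass
class Solution:
    """Result of one LP model.

    ``objective_value`` is the value of the model's own objective (the
    departure f for NUTR/NUTR-GHGE models, total GHGE in g CO₂eq for the
    minimum-GHGE model); ``departure`` always carries f so models can be
    compared.  ``status`` is "optimal", "infeasible" or "numeric_failure";
    quantities and totals are only present when optimal.
    """

    model_label: str
    status: str
    quantities: DietVector | None = None
    objective_value: float | None = None
    departure: float | None = None
    achieved: NutrientTotals | None = None
    active_constraints: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class LadderResult:
    """Outcome of the stepwise GHGE-reduction ladder.

    ``steps`` holds ``(ρ, Solution)`` pairs in increasing ρ, starting at
    ρ = 0 (the NUTR model) and ending with the first infeasible step, if
    one was reached before ρ = 1.  Feasible regions are nested, so
    feasibility is monotone in ρ and the scan stops at the first failure.
    """

    steps: list[tuple[float, Solution]]
    mini: Solution
    ghge_obs: float

    @property
    def nutr(self) -> Solution:
        return self.steps[0][1]

    @property
    def max_step(self) -> int:
        """Largest feasible step index k (ρ = step_size × k)."""
        return sum(1 for _, s in self.steps if s.is_optimal) - 1

    @property
    def feasible_steps(self) -> list[tuple[float, Solution]]:
        return [(rho, s) for rho, s in self.steps if s.is_optimal]

    @property
    def max_reduction_fraction(self) -> float:
        """1 − (minimum achievable GHGE / observed GHGE)."""
        if not self.mini.is_optimal:
            return float("nan")
        return 1.0 - self.mini.achieved.ghge_gco2eq / self.ghge_obs


# --------------------------------------------------------------------------
# Core solves
# --------------------------------------------------------------------------


def _objective_weights(obs: np.ndarray, zero_obs_policy: str) -> tuple[np.ndarray, np.ndarray]:
    """(mask of items entering the objective, their denominators)."""
    if zero_obs_policy == "exclude":
        mask = obs > 0
        return mask, obs[mask]
    if zero_obs_policy == "epsilon":
        mask = np.ones_like(obs, dtype=bool)
        return mask, np.maximum(obs, ZERO_OBS_EPSILON_G)
    raise ValueError(f"unknown zero_obs_policy {zero_obs_policy!r}")


def _finish(
    db: FoodDatabase,
    cset: ConstraintSet,
    model_label: str,
    res,
    n_items: int,
    obs: np.ndarray,
    obj_mask: np.ndarray,
    denom: np.ndarray,
    objective_value: float | None = None,
) -> Solution:
    if res.status == 2:
        return Solution(model_label, "infeasible", message=res.message)
    if res.status != 0:
        return Solution(model_label, "numeric_failure", message=res.message)
    q = np.clip(res.x[:n_items], 0.0, None)
    diet = DietVector.from_array(db, q)
    departure = float(np.abs(q[obj_mask] - obs[obj_mask]) @ (1.0 / denom))
    active = []
    for c in cset:
        lhs = c.lhs(db, q)
        if abs(lhs - c.rhs) <= max(1.0, abs(c.rhs)) * 1e-6:
            active.append(c.label)
    return Solution(
        model_label=model_label,
        status="optimal",
        quantities=diet,
        objective_value=departure if objective_value is None else objective_value,
        departure=departure,
        achieved=evaluate_diet(db, diet),
        active_constraints=active,
        message=res.message,
    )


def _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds):
    return linprog(
        c,
        A_ub=A_ub if A_ub is not None and len(A_ub) else None,
        b_ub=b_ub if b_ub is not None and len(b_ub) else None,
        A_eq=A_eq if A_eq is not None and len(A_eq) else None,
        b_eq=b_eq if b_eq is not None and len(b_eq) else None,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL, "dual_feasibility_tolerance": SOLVER_TOL},
    )


def minimize_departure(
    db: FoodDatabase,
    profile: PopulationProfile,
    cset: ConstraintSet,
    model_label: str = "NUTR",
    zero_obs_policy: str = "exclude",
) -> Solution:
    """Minimize the departure f subject to a prebuilt constraint set.

    Returns a :class:`Solution` whose status is "infeasible" (never an
    exception) when the constraint set admits no diet.
    """
    n = len(db)
    obs = profile.observed.to_array(db)
    obj_mask, denom = _objective_weights(obs, zero_obs_policy)
    m = int(obj_mask.sum())
    obj_idx = np.flatnonzero(obj_mask)

    A_ub, b_ub, _, A_eq, b_eq, _ = cset.to_matrices(db)
    # widen to [q, d] variable space
    A_ub = np.hstack([A_ub, np.zeros((A_ub.shape[0], m))])
    A_eq = np.hstack([A_eq, np.zeros((A_eq.shape[0], m))]) if len(A_eq) else None
    b_eq = b_eq if b_eq is not None and len(b_eq) else None

    # |q_i - obs_i|/w_i <= d_i   ->   ±(q_i - obs_i)/w_i - d_i <= 0
    rows = np.zeros((2 * m, n + m))
    rhs = np.zeros(2 * m)
    inv = 1.0 / denom
    for k, i in enumerate(obj_idx):
        rows[2 * k, i] = inv[k]
        rows[2 * k, n + k] = -1.0
        rhs[2 * k] = obs[i] * inv[k]
        rows[2 * k + 1, i] = -inv[k]
        rows[2 * k + 1, n + k] = -1.0
        rhs[2 * k + 1] = -obs[i] * inv[k]
    A_ub = np.vstack([A_ub, rows])
    b_ub = np.concatenate([b_ub, rhs])

    c = np.concatenate([np.zeros(n), np.ones(m)])
    res = _solve_lp(c, A_ub, b_ub, A_eq, b_eq, [(0, None)] * (n + m))
    return _finish(db, cset, model_label, res, n, obs, obj_mask, denom)


def minimize_ghge(
    db: FoodDatabase,
    profile: PopulationProfile,
    cset: ConstraintSet | None = None,
    lexicographic: bool = False,
    keep_acceptability: bool = True,
    zero_obs_policy: str = "exclude",
) -> Solution:
    """NUTR-GHGE-MINI: minimize total diet GHGE under the constraints.

    With ``lexicographic`` set, a second stage minimizes departure among
    GHGE-optimal diets (GHGE pinned at its optimum with 1e-9 relative
    slack).  The default is off: the minimum-GHGE diet is whatever vertex
    the solver returns, and its departure is typically enormous.
    ``keep_acceptability=False`` drops the acceptability family and keeps
    only the nutritional bounds.
    """
    if cset is None:
        cset = build_model_constraints(db, profile)
    if not keep_acceptability:
        kept = [c for c in cset if c.provenance != "acceptability"]
        cset = ConstraintSet(kept, cset.metadata)

    n = len(db)
    obs = profile.observed.to_array(db)
    obj_mask, denom = _objective_weights(obs, zero_obs_policy)
    A_ub, b_ub, _, A_eq, b_eq, _ = cset.to_matrices(db)
    g = db.ghge

    res = _solve_lp(g, A_ub, b_ub, A_eq if len(A_eq) else None, b_eq if len(b_eq) else None,
                    [(0, None)] * n)
    sol = _finish(db, cset, "NUTR-GHGE-MINI", res, n, obs, obj_mask, denom,
                  objective_value=float(res.fun) if res.status == 0 else None)
    if not sol.is_optimal or not lexicographic:
        return sol

    # stage 2: among GHGE-optimal diets, pick the one closest to observed
    ghge_opt = float(res.fun)
    pin = LinearConstraint(
        "ghge_pin_mini",
        {iid: float(gi) for iid, gi in zip(db.item_ids, g) if gi != 0.0},
        "<=",
        ghge_opt * (1 + 1e-9) + 1e-12,
        "environmental",
    )
    pinned = ConstraintSet(list(cset) + [pin], cset.metadata)
    sol2 = minimize_departure(db, profile, pinned, model_label="NUTR-GHGE-MINI",
                              zero_obs_policy=zero_obs_policy)
    if sol2.is_optimal:
        sol2.objective_value = sol2.achieved.ghge_gco2eq
        return sol2
    return sol


# --------------------------------------------------------------------------
# Model runners
# --------------------------------------------------------------------------


def run_nutr(
    db: FoodDatabase,
    profile: PopulationProfile,
    cset: ConstraintSet | None = None,
    zero_obs_policy: str = "exclude",
) -> Solution:
    """Solve the NUTR model (nutritional + acceptability, no GHGE cap)."""
    if cset is None:
        cset = build_model_constraints(db, profile)
    return minimize_departure(db, profile, cset, "NUTR", zero_obs_policy)


def run_ladder(
    db: FoodDatabase,
    profile: PopulationProfile,
    step: float = 0.10,
    base_cset: ConstraintSet | None = None,
    zero_obs_policy: str = "exclude",
    audit: bool = True,
) -> LadderResult:
    """Run NUTR, the stepwise GHGE-reduction ladder, and NUTR-GHGE-MINI.

    Steps ρ = step, 2·step, … are solved until the first infeasible one
    (feasible regions are nested in ρ, so no later step can be feasible);
    that infeasible step is kept in ``steps`` as its marker.  ``base_cset``
    overrides the default nutritional + acceptability set (used for
    engineered instances).
    """
    if not (0 < step < 1):
        raise ValueError(f"step must be in (0, 1), got {step}")
    if base_cset is None:
        base_cset = build_model_constraints(db, profile)
    ghge_obs = base_cset.metadata.get(
        "ghge_obs_gco2eq", evaluate_diet(db, profile.observed).ghge_gco2eq
    )
    if ghge_obs <= 0:
        raise ValueError("observed GHGE must be positive")

    nutr = minimize_departure(db, profile, base_cset, "NUTR", zero_obs_policy)
    if not nutr.is_optimal:
        raise LadderError(
            f"NUTR model is {nutr.status}; the GHGE ladder cannot start "
            f"({nutr.message})"
        )
    steps: list[tuple[float, Solution]] = [(0.0, nutr)]

    k = 1
    while step * k < 1.0 - 1e-12:
        rho = step * k
        cset_k = ConstraintSet(
            list(base_cset) + [build_ghge_cap(db, ghge_obs, rho)], base_cset.metadata
        )
        label = f"NUTR-GHGE-{round(rho * 100)}"
        sol = minimize_departure(db, profile, cset_k, label, zero_obs_policy)
        steps.append((rho, sol))
        if not sol.is_optimal:
            break
        k += 1

    mini = minimize_ghge(db, profile, cset=base_cset, zero_obs_policy=zero_obs_policy)

    if audit:
        for rho, sol in steps:
            if sol.is_optimal:
                cs = base_cset if rho == 0 else ConstraintSet(
                    list(base_cset) + [build_ghge_cap(db, ghge_obs, rho)], base_cset.metadata
                )
                bad = check_feasibility(db, sol.quantities, cs, AUDIT_TOL)
                if bad:  # pragma: no cover - solver contract
                    raise AssertionError(f"solution at rho={rho} violates {bad[:3]}")

    return LadderResult(steps=steps, mini=mini, ghge_obs=ghge_obs)
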