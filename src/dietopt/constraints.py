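"""Constraint construction and auditing.

Three families of linear bounds over item quantities are built here:

* **nutritional** — the 32 nutrient recommendations (per gender) derived
  from EFSA dietary reference values, completed by the Nordic bounds for
  sodium and saturated fat and the WHO cap on free sugars;
* **acceptability** — bounds keeping modeled diets culturally plausible:
  total diet weight within ±20% of observed, per-item and per-L1-group
  percentile envelopes, fixed solid/liquid weight ratio, caps on alcoholic
  beverages, fish oil and offal at observed amounts, and fixed energy;
* **environmental** — a cap on total diet GHGE at a fraction of the
  observed level.

Percent-of-energy recommendations (carbohydrates, fats, SFA, free sugars)
are linear because total energy is pinned to its observed value by an
acceptability constraint: the nutrient's energy, computed with fixed Atwater
factors, is bounded against ``(bound/100) × energy_obs``.

Exact equalities (energy, solid/liquid ratio) are emitted as two
inequalities with a small relative band — exact float equality makes LPs
needlessly infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .food_model import (
    ENERGY_CODE,
    SPECIAL_FLAGS,
    DietVector,
    FoodDatabase,
    PopulationProfile,
    evaluate_diet,
)

__all__ = [
    "LinearConstraint",
    "ConstraintSet",
    "Violation",
    "NUTRIENT_RECOMMENDATIONS",
    "ENERGY_FACTORS_KCAL_PER_G",
    "build_nutritional",
    "build_acceptability",
    "build_ghge_cap",
    "build_model_constraints",
    "check_feasibility",
]

# --------------------------------------------------------------------------
# Recommendation table
# --------------------------------------------------------------------------

#: Daily nutrient recommendations per gender: code -> (kind, (women_min,
#: women_max), (men_min, men_max)).  kind is one of:
#:   "per_kg_bw"  — bound is g per kg of body weight (protein);
#:   "pct_energy" — bound is % of total energy intake;
#:   "absolute"   — bound is a daily amount in the nutrient's own unit.
#: None means no bound on that side.  A row with both sides set yields two
#: linear constraints; in total each gender gets exactly 32 bounds.
NUTRIENT_RECOMMENDATIONS: list[tuple[str, str, tuple, tuple]] = [
    ("protein", "per_kg_bw", (0.83, None), (0.83, None)),
    ("carbohydrates", "pct_energy", (45.0, 60.0), (45.0, 60.0)),
    ("fats", "pct_energy", (20.0, 35.0), (20.0, 35.0)),
    ("sfa", "pct_energy", (None, 10.0), (None, 10.0)),
    ("free_sugars", "pct_energy", (None, 10.0), (None, 10.0)),
    ("sodium", "absolute", (575.0, 2400.0), (575.0, 2400.0)),
    ("fiber", "absolute", (25.0, None), (25.0, None)),
    ("calcium", "absolute", (950.0, 2500.0), (950.0, 2500.0)),
    ("magnesium", "absolute", (300.0, None), (350.0, None)),
    ("phosphorus", "absolute", (550.0, None), (550.0, None)),
    ("iron", "absolute", (16.0, None), (11.0, None)),
    ("potassium", "absolute", (3100.0, None), (3100.0, None)),
    ("zinc", "absolute", (10.1, 25.0), (12.85, 25.0)),
    ("vitamin_a", "absolute", (650.0, 3000.0), (750.0, 3000.0)),
    ("thiamin", "absolute", (0.9, None), (1.1, None)),
    ("riboflavin", "absolute", (1.3, None), (1.6, None)),
    ("vitamin_b6", "absolute", (1.1, 25.0), (1.5, 25.0)),
    ("vitamin_b12", "absolute", (4.0, None), (4.0, None)),
    ("folate", "absolute", (330.0, 1000.0), (330.0, 1000.0)),
    ("vitamin_c", "absolute", (95.0, None), (110.0, None)),
    ("vitamin_d", "absolute", (5.0, 100.0), (5.0, 100.0)),
    ("vitamin_e", "absolute", (11.0, 300.0), (13.0, 300.0)),
]

#: Atwater energy-conversion factors, kcal per gram of nutrient.
ENERGY_FACTORS_KCAL_PER_G: dict[str, float] = {
    "protein": 4.0,
    "carbohydrates": 4.0,
    "fats": 9.0,
    "sfa": 9.0,
    "free_sugars": 4.0,
    "alcohol": 7.0,
}

#: Relative half-width of the band replacing the energy equality.
ENERGY_BAND_REL = 1e-3
#: Relative half-width of the band replacing the solid/liquid ratio equality.
RATIO_BAND_REL = 1e-2
#: Total-diet-weight envelope around the observed weight.
WEIGHT_ENVELOPE_REL = 0.20


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearConstraint:
    """One linear bound  Σᵢ coefᵢ·qᵢ  (≤ | ≥ | =)  rhs  over item quantities.

    ``coefficients`` is sparse: item ids absent from the map have
    coefficient zero.  ``provenance`` records which constraint family the
    bound belongs to.
    """

    label: str
    coefficients: dict[str, float]
    sense: str  # "<=", ">=", "=="
    rhs: float
    provenance: str  # "nutritional" | "acceptability" | "environmental"

    def __post_init__(self) -> None:
        if self.sense not in ("<=", ">=", "=="):
            raise ValueError(f"{self.label}: bad sense {self.sense!r}")
        if not np.isfinite(self.rhs):
            raise ValueError(f"{self.label}: rhs must be finite")
        for iid, c in self.coefficients.items():
            if not np.isfinite(c):
                raise ValueError(f"{self.label}: non-finite coefficient for {iid!r}")

    def dense(self, db: FoodDatabase) -> np.ndarray:
        a = np.zeros(len(db))
        for iid, c in self.coefficients.items():
            a[db.index[iid]] = c
        return a

    def lhs(self, db: FoodDatabase, q: np.ndarray) -> float:
        return float(self.dense(db) @ q)


class ConstraintSet:
    """An ordered, label-unique collection of linear constraints."""

    def __init__(self, constraints: Iterable[LinearConstraint] = (), metadata: dict | None = None):
        self.constraints: list[LinearConstraint] = []
        self._labels: set[str] = set()
        self.metadata: dict = dict(metadata or {})
        for c in constraints:
            self.add(c)

    def add(self, constraint: LinearConstraint) -> None:
        if constraint.label in self._labels:
            raise ValueError(f"duplicate constraint label {constraint.label!r}")
        self._labels.add(constraint.label)
        self.constraints.append(constraint)

    def extend(self, constraints: Iterable[LinearConstraint]) -> None:
        for c in constraints:
            self.add(c)

    def __len__(self) -> int:
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    def __getitem__(self, label: str) -> LinearConstraint:
        for c in self.constraints:
            if c.label == label:
                return c
        raise KeyError(label)

    def by_provenance(self, provenance: str) -> list[LinearConstraint]:
        return [c for c in self.constraints if c.provenance == provenance]

    def replaced(self, metadata: dict | None = None) -> "ConstraintSet":
        return ConstraintSet(self.constraints, metadata or self.metadata)

    def to_matrices(self, db: FoodDatabase):
        """Matrix form for the solver.

        Returns ``(A_ub, b_ub, labels_ub, A_eq, b_eq, labels_eq)`` with all
        inequality rows oriented as ``A_ub q <= b_ub``.
        """
        rows_ub, b_ub, lab_ub = [], [], []
        rows_eq, b_eq, lab_eq = [], [], []
        for c in self.constraints:
            a = c.dense(db)
            if c.sense == "<=":
                rows_ub.append(a), b_ub.append(c.rhs), lab_ub.append(c.label)
            elif c.sense == ">=":
                rows_ub.append(-a), b_ub.append(-c.rhs), lab_ub.append(c.label)
            else:
                rows_eq.append(a), b_eq.append(c.rhs), lab_eq.append(c.label)
        n = len(db)
        A_ub = np.array(rows_ub) if rows_ub else np.zeros((0, n))
        A_eq = np.array(rows_eq) if rows_eq else np.zeros((0, n))
        return A_ub, np.array(b_ub), lab_ub, A_eq, np.array(b_eq), lab_eq

    def to_audit_rows(self) -> list[dict]:
        """Human-readable audit (one dict per constraint, TSV-friendly)."""
        return [
            {
                "label": c.label,
                "sense": c.sense,
                "rhs": c.rhs,
                "provenance": c.provenance,
                "n_items": len(c.coefficients),
            }
            for c in self.constraints
        ]


class Violation(NamedTuple):
    """A constraint violated by a diet: ``gap`` is the overshoot in the
    constraint's own units (always positive)."""

    label: str
    lhs: float
    rhs: float
    gap: float


# --------------------------------------------------------------------------
# Builders
# --------------------------------------------------------------------------


def _bound_pair(lo, hi, make, code: str) -> list[LinearConstraint]:
    out = []
    if lo is not None:
        out.append(make(f"{code}_min", ">=", lo))
    if hi is not None:
        out.append(make(f"{code}_max", "<=", hi))
    return out


def build_nutritional(db: FoodDatabase, profile: PopulationProfile) -> list[LinearConstraint]:
    """The 32 gender-specific nutrient bounds as linear constraints.

    Absolute rows bound the dot product of quantities with the nutrient's
    per-gram composition.  The protein row scales its bound by body weight
    (g per kg per day).  Percent-of-energy rows bound nutrient energy
    against ``(bound/100) × energy_obs_kcal``.
    """
    missing = [
        code for code, *_ in NUTRIENT_RECOMMENDATIONS if code not in db.nutrient_codes
    ]
    if missing:
        raise KeyError(f"food database lacks nutrient columns: {missing}")

    col = 0 if profile.gender == "women" else 1
    out: list[LinearConstraint] = []
    for code, kind, women, men in NUTRIENT_RECOMMENDATIONS:
        lo, hi = (women, men)[col]
        comp = db.composition(code)

        if kind == "absolute":
            coeffs = {iid: float(v) for iid, v in zip(db.item_ids, comp) if v != 0.0}

            def make(label, sense, b, coeffs=coeffs):
                return LinearConstraint(label, coeffs, sense, float(b), "nutritional")

            out += _bound_pair(lo, hi, make, code)

        elif kind == "per_kg_bw":
            coeffs = {iid: float(v) for iid, v in zip(db.item_ids, comp) if v != 0.0}

            def make(label, sense, b, coeffs=coeffs):
                return LinearConstraint(
                    label, coeffs, sense, float(b) * profile.body_weight_kg, "nutritional"
                )

            out += _bound_pair(lo, hi, make, code)

        elif kind == "pct_energy":
            factor = ENERGY_FACTORS_KCAL_PER_G[code]
            coeffs = {
                iid: float(v) * factor for iid, v in zip(db.item_ids, comp) if v != 0.0
            }

            def make(label, sense, b, coeffs=coeffs):
                rhs = float(b) / 100.0 * profile.energy_obs_kcal
                return LinearConstraint(label, coeffs, sense, rhs, "nutritional")

            out += _bound_pair(lo, hi, make, code)

        else:  # pragma: no cover - table is static
            raise ValueError(f"unknown recommendation kind {kind!r}")
    return out


def build_acceptability(db: FoodDatabase, profile: PopulationProfile) -> list[LinearConstraint]:
    """Cultural-plausibility bounds tied to the observed diet.

    Emits, in order: the ±20% total-weight envelope; per-item percentile
    boxes; per-L1-group weight boxes; the solid/liquid ratio band; caps on
    special categories (alcoholic beverages, fish oil, offal) at observed
    amounts; and the fixed-energy band.
    """
    obs = profile.observed.to_array(db)
    out: list[LinearConstraint] = []
    ones = {iid: 1.0 for iid in db.item_ids}

    # (a) total weight envelope
    w_obs = float(obs.sum())
    out.append(
        LinearConstraint(
            "total_weight_min", ones, ">=", (1 - WEIGHT_ENVELOPE_REL) * w_obs, "acceptability"
        )
    )
    out.append(
        LinearConstraint(
            "total_weight_max", ones, "<=", (1 + WEIGHT_ENVELOPE_REL) * w_obs, "acceptability"
        )
    )

    # (b) per-item percentile boxes
    for iid in db.item_ids:
        lo = profile.item_lower.get(iid, 0.0)
        hi = profile.item_upper.get(iid)
        if lo > 0:
            out.append(LinearConstraint(f"item_min:{iid}", {iid: 1.0}, ">=", lo, "acceptability"))
        if hi is not None:
            out.append(LinearConstraint(f"item_max:{iid}", {iid: 1.0}, "<=", hi, "acceptability"))

    # (c) per-L1-group weight boxes
    for grp in db.l1_groups:
        members = {iid: 1.0 for iid, it in zip(db.item_ids, db.items) if it.l1_group == grp}
        lo = profile.l1_lower.get(grp)
        hi = profile.l1_upper.get(grp)
        if lo is not None and lo > 0:
            out.append(LinearConstraint(f"l1_min:{grp}", members, ">=", lo, "acceptability"))
        if hi is not None:
            out.append(LinearConstraint(f"l1_max:{grp}", members, "<=", hi, "acceptability"))

    # (d) solid/liquid ratio band around the observed ratio
    liquid = db.liquid_mask
    w_liquid = float(obs[liquid].sum())
    w_solid = float(obs[~liquid].sum())
    if w_liquid <= 0 or w_solid <= 0:
        raise ValueError(
            "solid/liquid ratio undefined: observed diet has "
            f"solid weight {w_solid} g and liquid weight {w_liquid} g"
        )
    r_obs = w_solid / w_liquid
    hi_c = {
        iid: (1.0 if not liq else -(1 + RATIO_BAND_REL) * r_obs)
        for iid, liq in zip(db.item_ids, liquid)
    }
    lo_c = {
        iid: (1.0 if not liq else -(1 - RATIO_BAND_REL) * r_obs)
        for iid, liq in zip(db.item_ids, liquid)
    }
    out.append(LinearConstraint("solid_liquid_ratio_max", hi_c, "<=", 0.0, "acceptability"))
    out.append(LinearConstraint("solid_liquid_ratio_min", lo_c, ">=", 0.0, "acceptability"))

    # (e) special-category caps at observed amounts
    for flag in sorted(SPECIAL_FLAGS):
        mask = db.flag_mask(flag)
        if not mask.any():
            continue
        cap = profile.special_caps.get(flag, float(obs[mask].sum()))
        members = {iid: 1.0 for iid, m in zip(db.item_ids, mask) if m}
        out.append(LinearConstraint(f"cap:{flag}", members, "<=", cap, "acceptability"))

    # (f) fixed energy (narrow band around the observed value)
    e = db.composition(ENERGY_CODE)
    e_coeffs = {iid: float(v) for iid, v in zip(db.item_ids, e) if v != 0.0}
    E = profile.energy_obs_kcal
    out.append(
        LinearConstraint("energy_min", e_coeffs, ">=", (1 - ENERGY_BAND_REL) * E, "acceptability")
    )
    out.append(
        LinearConstraint("energy_max", e_coeffs, "<=", (1 + ENERGY_BAND_REL) * E, "acceptability")
    )
    return out


def build_ghge_cap(db: FoodDatabase, ghge_obs: float, reduction_fraction: float) -> LinearConstraint:
    """GHGE cap at ``(1 − ρ) × ghge_obs`` for reduction fraction ρ ∈ [0, 1)."""
    if not (0.0 <= reduction_fraction < 1.0):
        raise ValueError(f"reduction fraction must be in [0, 1), got {reduction_fraction}")
    if ghge_obs <= 0:
        raise ValueError("observed GHGE must be positive")
    coeffs = {iid: float(g) for iid, g in zip(db.item_ids, db.ghge) if g != 0.0}
    label = f"ghge_cap_{round(reduction_fraction * 100)}"
    return LinearConstraint(
        label, coeffs, "<=", (1.0 - reduction_fraction) * ghge_obs, "environmental"
    )


def build_model_constraints(
    db: FoodDatabase,
    profile: PopulationProfile,
    reduction_fraction: float | None = None,
) -> ConstraintSet:
    """Full constraint set for one model: nutritional + acceptability, plus
    an optional GHGE cap."""
    ghge_obs = evaluate_diet(db, profile.observed).ghge_gco2eq
    cset = ConstraintSet(
        metadata={
            "gender": profile.gender,
            "body_weight_kg": profile.body_weight_kg,
            "energy_obs_kcal": profile.energy_obs_kcal,
            "ghge_obs_gco2eq": ghge_obs,
            "label": profile.label,
        }
    )
    cset.extend(build_nutritional(db, profile))
    cset.extend(build_acceptability(db, profile))
    if reduction_fraction is not None:
        cset.add(build_ghge_cap(db, ghge_obs, reduction_fraction))
    return cset


# --------------------------------------------------------------------------
# Audit
# --------------------------------------------------------------------------


def check_feasibility(
    db: FoodDatabase,
    diet: DietVector,
    cset: ConstraintSet,
    tol: float = 1e-6,
) -> list[Violation]:
    """Audit a diet against a constraint set.

    Returns one :class:`Violation` per constraint broken beyond a relative
    tolerance (``tol × max(1, |rhs|)``); an empty list means the diet is
    feasible at that tolerance.  Gaps are reported in constraint units.
    """
    q = diet.to_array(db)
    violations: list[Violation] = []
    for c in cset:
        lhs = c.lhs(db, q)
        scale = max(1.0, abs(c.rhs))
        if c.sense == "<=":
            gap = lhs - c.rhs
        elif c.sense == ">=":
            gap = c.rhs - lhs
        else:
            gap = abs(lhs - c.rhs)
        if gap > tol * scale:
            violations.append(Violation(c.label, lhs, c.rhs, gap))
    return violations
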