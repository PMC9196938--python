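"""Mixed-integer linear formulation of the allocation model.

Once the network distances are fixed, each route's waiting cost
``lambda_k(e_m * D_hij)`` is a constant, so both objectives are linear in
the decision variables and the whole model is a MILP:

* G1 = sum_jk w_k * d_jk * plateau_k  +  sum w_k * (lambda_route - plateau_k) * y
  (a constant offset plus non-positive coefficients on deliveries),
* G2 = sum_i rent_i * z_i + sum D_hij * f_m * x_hijm.

The coverage restriction is enforced by fixing the upper bound of any
vehicle variable on a path longer than the radius to zero, which keeps the
relaxation tight without big-M rows.  The remaining constraint families are
emitted as <= rows tagged with their numeric ids (6)-(11); goal rows carry
tag 16.

The goal-programming transformation introduces deviation variables
``theta_n^+/-`` and equality rows ``G_n + theta_n^- - theta_n^+ = R_n``
against ideal levels ``R_n``; only positive deviations are penalised, with
preemptive priority of the loss objective over cost.  Complementarity of
the deviation pair is not imposed as a row (it would be nonlinear): with
both deviations non-negative in a single equality and only the positive one
penalised, an optimal basic solution never needs both strictly positive,
and the property is verified after solving instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp

from .model_core import AllocationPlan, Instance, route_unit_costs

__all__ = [
    "Variable",
    "Row",
    "MILPFormulation",
    "GoalSpec",
    "GoalFormulation",
    "build_formulation",
    "attach_goal",
    "extract_plan",
    "embed_plan",
]

Kind = Literal["binary", "integer", "continuous"]


@dataclass(frozen=True)
class Variable:
    """One column of the MILP: bounds, integrality and model identity."""

    name: str
    kind: Kind
    lb: float
    ub: float
    symbol: str          # z / x / y / theta+ / theta-
    indices: tuple = ()


@dataclass(frozen=True)
class Row:
    """One linear constraint, stored sparse as (column, coefficient) pairs."""

    coeffs: tuple  # of (int position, float coefficient)
    sense: Literal["<=", "=", ">="]
    rhs: float
    tag: int        # constraint-family id
    indices: tuple = ()

    def activity(self, vec: np.ndarray) -> float:
        return float(sum(c * vec[p] for p, c in self.coeffs))


@dataclass
class MILPFormulation:
    """Variable catalog, sparse constraint rows and both objective vectors."""

    instance: Instance
    variables: list[Variable]
    rows: list[Row]
    obj_g1: np.ndarray
    offset_g1: float
    obj_g2: np.ndarray
    offset_g2: float
    z_index: np.ndarray        # (I,)
    x_index: np.ndarray        # (H, I, J, M)
    y_index: np.ndarray        # (H, I, J, K, M)
    theta_index: dict = field(default_factory=dict)  # {"plus": [...], "minus": [...]}

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([v.lb for v in self.variables])
        ub = np.array([v.ub for v in self.variables])
        return lb, ub

    @property
    def integer_mask(self) -> np.ndarray:
        return np.array([v.kind in ("binary", "integer") for v in self.variables])

    def matrices(self):
        """(A_ub, b_ub, A_eq, b_eq) as scipy sparse / dense vectors."""
        data_ub, rows_ub, cols_ub, b_ub = [], [], [], []
        data_eq, rows_eq, cols_eq, b_eq = [], [], [], []
        for row in self.rows:
            if row.sense == "=":
                r = len(b_eq)
                for p, c in row.coeffs:
                    rows_eq.append(r)
                    cols_eq.append(p)
                    data_eq.append(c)
                b_eq.append(row.rhs)
            else:
                sign = 1.0 if row.sense == "<=" else -1.0
                r = len(b_ub)
                for p, c in row.coeffs:
                    rows_ub.append(r)
                    cols_ub.append(p)
                    data_ub.append(sign * c)
                b_ub.append(sign * row.rhs)
        n = self.n_vars
        A_ub = sp.csr_matrix((data_ub, (rows_ub, cols_ub)),
                             shape=(len(b_ub), n)) if b_ub else None
        A_eq = sp.csr_matrix((data_eq, (rows_eq, cols_eq)),
                             shape=(len(b_eq), n)) if b_eq else None
        return (A_ub, np.array(b_ub), A_eq, np.array(b_eq))

    # -- objective evaluation on raw vectors ---------------------------
    def g1_of(self, vec: np.ndarray) -> float:
        return float(self.obj_g1 @ vec + self.offset_g1)

    def g2_of(self, vec: np.ndarray) -> float:
        return float(self.obj_g2 @ vec + self.offset_g2)

    def to_lp_string(self, objective: np.ndarray | None = None,
                     offset: float = 0.0) -> str:
        """Render the program in LP-file syntax (fixed decimals), for debugging."""
        obj = self.obj_g1 if objective is None else objective
        lines = ["Minimize", " obj: " + _lincomb(obj, self.variables)]
        lines.append("Subject To")
        for r_id, row in enumerate(self.rows):
            expr = " ".join(
                f"{c:+.9f} {self.variables[p].name}" for p, c in row.coeffs
            )
            lines.append(f" c{r_id}: {expr} {row.sense} {row.rhs:.9f}")
        lines.append("Bounds")
        for v in self.variables:
            ub = "+inf" if np.isinf(v.ub) else f"{v.ub:.9f}"
            lines.append(f" {v.lb:.9f} <= {v.name} <= {ub}")
        ints = [v.name for v in self.variables if v.kind in ("binary", "integer")]
        if ints:
            lines.append("Generals")
            lines.append(" " + " ".join(ints))
        lines.append("End")
        return "\n".join(lines)


def _lincomb(coeffs: np.ndarray, variables: Sequence[Variable]) -> str:
    terms = [f"{c:+.9f} {variables[p].name}"
             for p, c in enumerate(coeffs) if c != 0.0]
    return " ".join(terms) if terms else "0 " + variables[0].name


def build_formulation(instance: Instance) -> MILPFormulation:
    """Translate an instance into variables, rows (6)-(11) and objectives.

    Variable bounds encode (5) and (12)-(14): vehicle counts are integers in
    ``[0, min(U_hm, P_im)]`` (zero when the path exceeds the coverage
    radius), DC openings are binary, deliveries are continuous in
    ``[0, min(d_jk, W_hk, Q_ik, V_m * x_ub)]``.
    """
    H, I, J, K, M = instance.shape()
    variables: list[Variable] = []

    z_index = np.empty(I, dtype=int)
    for i in range(I):
        z_index[i] = len(variables)
        variables.append(Variable(f"z_{instance.dc_ids[i]}", "binary", 0, 1, "z", (i,)))

    reachable = instance.distance <= instance.coverage
    x_index = np.empty((H, I, J, M), dtype=int)
    x_ub = np.empty((H, I, J, M))
    for h in range(H):
        for i in range(I):
            for j in range(J):
                for m in range(M):
                    ub = min(instance.vehicle_supply[h, m],
                             instance.dc_vehicle_cap[i, m])
                    ub = np.floor(ub) if reachable[h, i, j] else 0.0
                    x_ub[h, i, j, m] = ub
                    x_index[h, i, j, m] = len(variables)
                    variables.append(Variable(
                        f"x_{h}_{i}_{j}_{m}", "integer", 0, ub, "x", (h, i, j, m)))

    y_index = np.empty((H, I, J, K, M), dtype=int)
    for h in range(H):
        for i in range(I):
            for j in range(J):
                for k in range(K):
                    for m in range(M):
                        ub = min(instance.demand[j, k],
                                 instance.ppe_supply[h, k],
                                 instance.dc_ppe_cap[i, k],
                                 instance.vehicle_capacity[m] * x_ub[h, i, j, m])
                        y_index[h, i, j, k, m] = len(variables)
                        variables.append(Variable(
                            f"y_{h}_{i}_{j}_{k}_{m}", "continuous", 0, ub,
                            "y", (h, i, j, k, m)))

    n = len(variables)
    if not np.all(np.isfinite(instance.distance)):
        raise ValueError("distance contains non-finite entries")

    # objectives
    lam = route_unit_costs(instance)  # (H, I, J, K, M)
    plateaus = instance.plateaus
    obj_g1 = np.zeros(n)
    w = instance.ppe_weight
    coef = w[None, None, None, :, None] * (lam - plateaus[None, None, None, :, None])
    obj_g1[y_index.ravel()] = coef.ravel()
    offset_g1 = float((instance.demand * plateaus[None, :] * w[None, :]).sum())

    obj_g2 = np.zeros(n)
    obj_g2[z_index] = instance.rent
    obj_g2[x_index.ravel()] = (
        instance.distance[..., None] * instance.unit_cost[None, None, None, :]
    ).ravel()
    offset_g2 = 0.0

    rows: list[Row] = []
    # (6) vehicles leaving each reserve bounded by supply
    for h in range(H):
        for m in range(M):
            coeffs = tuple((int(x_index[h, i, j, m]), 1.0)
                           for i in range(I) for j in range(J))
            rows.append(Row(coeffs, "<=", float(instance.vehicle_supply[h, m]),
                            6, (h, m)))
    # (7) PPE leaving each reserve bounded by stock
    for h in range(H):
        for k in range(K):
            coeffs = tuple((int(y_index[h, i, j, k, m]), 1.0)
                           for i in range(I) for j in range(J) for m in range(M))
            rows.append(Row(coeffs, "<=", float(instance.ppe_supply[h, k]),
                            7, (h, k)))
    # (8) vehicles through a DC bounded by its (gated) capacity
    for i in range(I):
        for m in range(M):
            coeffs = tuple((int(x_index[h, i, j, m]), 1.0)
                           for h in range(H) for j in range(J))
            coeffs += ((int(z_index[i]), -float(instance.dc_vehicle_cap[i, m])),)
            rows.append(Row(coeffs, "<=", 0.0, 8, (i, m)))
    # (9) PPE through a DC bounded by its (gated) capacity
    for i in range(I):
        for k in range(K):
            coeffs = tuple((int(y_index[h, i, j, k, m]), 1.0)
                           for h in range(H) for j in range(J) for m in range(M))
            coeffs += ((int(z_index[i]), -float(instance.dc_ppe_cap[i, k])),)
            rows.append(Row(coeffs, "<=", 0.0, 9, (i, k)))
    # (10) load on each path bounded by vehicle capacity
    for h in range(H):
        for i in range(I):
            for j in range(J):
                for m in range(M):
                    coeffs = tuple((int(y_index[h, i, j, k, m]), 1.0)
                                   for k in range(K))
                    coeffs += ((int(x_index[h, i, j, m]),
                                -float(instance.vehicle_capacity[m])),)
                    rows.append(Row(coeffs, "<=", 0.0, 10, (h, i, j, m)))
    # (11) deliveries never exceed demand
    for j in range(J):
        for k in range(K):
            coeffs = tuple((int(y_index[h, i, j, k, m]), 1.0)
                           for h in range(H) for i in range(I) for m in range(M))
            rows.append(Row(coeffs, "<=", float(instance.demand[j, k]), 11, (j, k)))

    return MILPFormulation(
        instance=instance, variables=variables, rows=rows,
        obj_g1=obj_g1, offset_g1=offset_g1,
        obj_g2=obj_g2, offset_g2=offset_g2,
        z_index=z_index, x_index=x_index, y_index=y_index,
    )


# ---------------------------------------------------------------------------
# goal programming
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoalSpec:
    """Ideal levels and priorities for the two-goal transformation.

    ``ideals = (R1, R2)`` are the target levels of the loss and cost
    objectives.  The loss goal has preemptive priority; lexicographic mode
    realises this exactly by staged optimisation, weighted mode
    approximates it with a large priority ratio.
    """

    ideals: tuple[float, float]
    mode: Literal["lexicographic", "weighted"] = "lexicographic"
    priorities: tuple[float, float] = (1e6, 1.0)
    min_priority_ratio: float = 1e3

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.ideals)):
            raise ValueError("ideal levels must be finite")
        if self.mode not in ("lexicographic", "weighted"):
            raise ValueError(f"unknown goal mode: {self.mode!r}")
        if self.mode == "weighted":
            ratio = self.priorities[0] / self.priorities[1]
            if ratio < self.min_priority_ratio:
                raise ValueError(
                    "weighted mode requires a preemptive priority ratio "
                    f">= {self.min_priority_ratio:g}, got {ratio:g}")


@dataclass
class GoalFormulation:
    """Base MILP extended with deviation variables and goal equality rows.

    ``milp`` holds the extended catalog; the deviation variable positions
    are exposed through ``milp.theta_index``.  ``objective`` is the
    weighted goal objective (used directly in weighted mode; lexicographic
    mode optimises the positive deviations in stages instead).
    """

    milp: MILPFormulation
    spec: GoalSpec
    objective: np.ndarray

    @property
    def theta_plus(self) -> list[int]:
        return self.milp.theta_index["plus"]

    @property
    def theta_minus(self) -> list[int]:
        return self.milp.theta_index["minus"]


def attach_goal(base: MILPFormulation, spec: GoalSpec) -> GoalFormulation:
    """Apply the goal transformation to a base formulation.

    Adds ``theta_n^+/- >= 0`` and rows ``G_n + theta_n^- - theta_n^+ = R_n``
    for both objectives, plus the goal objective penalising positive
    deviations by priority.
    """
    n0 = base.n_vars
    variables = list(base.variables)
    theta_plus, theta_minus = [], []
    for nm in (1, 2):
        theta_plus.append(len(variables))
        variables.append(Variable(f"theta{nm}_plus", "continuous", 0, np.inf,
                                  "theta+", (nm,)))
        theta_minus.append(len(variables))
        variables.append(Variable(f"theta{nm}_minus", "continuous", 0, np.inf,
                                  "theta-", (nm,)))
    n = len(variables)

    def extend(vec: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        out[:n0] = vec
        return out

    obj_vecs = [(base.obj_g1, base.offset_g1), (base.obj_g2, base.offset_g2)]
    rows = list(base.rows)
    for nm, (vec, offset) in enumerate(obj_vecs):
        coeffs = tuple((int(p), float(c)) for p, c in enumerate(vec) if c != 0.0)
        coeffs += ((theta_minus[nm], 1.0), (theta_plus[nm], -1.0))
        rows.append(Row(coeffs, "=", float(spec.ideals[nm] - offset), 16, (nm + 1,)))

    objective = np.zeros(n)
    objective[theta_plus[0]] = spec.priorities[0]
    objective[theta_plus[1]] = spec.priorities[1]

    milp = MILPFormulation(
        instance=base.instance, variables=variables, rows=rows,
        obj_g1=extend(base.obj_g1), offset_g1=base.offset_g1,
        obj_g2=extend(base.obj_g2), offset_g2=base.offset_g2,
        z_index=base.z_index, x_index=base.x_index, y_index=base.y_index,
        theta_index={"plus": theta_plus, "minus": theta_minus},
    )
    return GoalFormulation(milp=milp, spec=spec, objective=objective)


# ---------------------------------------------------------------------------
# vector <-> plan plumbing
# ---------------------------------------------------------------------------

def extract_plan(formulation: MILPFormulation, vec: np.ndarray,
                 *, tol: float = 1e-6) -> AllocationPlan:
    """Read an allocation plan out of a solution vector.

    Integer variables are rounded within ``tol``; a fractional value beyond
    the tolerance is an error (the vector is not an integer solution).
    """
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (formulation.n_vars,):
        raise ValueError(
            f"solution vector has length {vec.size}, catalog has {formulation.n_vars}")
    z = vec[formulation.z_index]
    x = vec[formulation.x_index]
    for label, arr in (("z", z), ("x", x)):
        frac = np.abs(arr - np.round(arr))
        if np.any(frac > tol):
            worst = float(frac.max())
            raise ValueError(
                f"{label} variable fractional by {worst:g} (> tol {tol:g}); "
                "not an integer solution")
    y = np.maximum(vec[formulation.y_index], 0.0)
    return AllocationPlan(open_dc=np.round(z), vehicles=np.round(x), shipped=y)


def embed_plan(formulation: MILPFormulation, plan: AllocationPlan) -> np.ndarray:
    """Write a plan into a solution vector over the catalog (inverse of extract)."""
    vec = np.zeros(formulation.n_vars)
    vec[formulation.z_index] = plan.open_dc
    vec[formulation.x_index] = plan.vehicles
    vec[formulation.y_index] = plan.shipped
    return vec
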