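"""Core domain model for emergency PPE location-allocation planning.

The planning network has three layers: reserve centers (stocks of PPE and
vehicles), candidate distribution centers (DCs, to be opened or not), and
affected areas (demand points).  A plan decides which DCs to open (``z``),
how many vehicles of each type travel each reserve -> DC -> area path
(``x``), and how many kilograms of each PPE type those vehicles carry
(``y``).

Two objectives are evaluated on a plan:

* ``G1`` — the total weighted loss borne by victims waiting for PPE.  Each
  kilogram of unmet demand accrues the plateau (worst-case) unit waiting
  cost; each delivered kilogram accrues the unit waiting cost evaluated at
  its route's travel time.  This single function trades off fairness
  (unmet demand) against efficiency (delivery delay).
* ``G2`` — the total logistics cost: DC renting plus distance-proportional
  transportation.

Everything in this module is expressed in canonical units: kilograms,
meters, seconds, yuan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "WaitingCostCurve",
    "Instance",
    "AllocationPlan",
    "ObjectiveValues",
    "Violation",
    "OverDeliveryError",
    "CONSTRAINT_NAMES",
    "waiting_cost",
    "route_time",
    "route_times",
    "route_unit_costs",
    "area_loss",
    "total_loss",
    "logistics_cost",
    "evaluate",
    "check_feasibility",
]

#: Human-readable names for the model's constraint families, keyed by the
#: stable numeric ids used in violation reports.
CONSTRAINT_NAMES = {
    5: "vehicle coverage radius",
    6: "reserve vehicle supply",
    7: "reserve PPE supply",
    8: "DC vehicle capacity (only open DCs route vehicles)",
    9: "DC PPE capacity (only open DCs handle PPE)",
    10: "vehicle load capacity",
    11: "no over-delivery beyond demand",
    12: "DC-opening variables binary",
    13: "vehicle counts non-negative integers",
    14: "shipped quantities non-negative",
}


class OverDeliveryError(ValueError):
    """Raised when a plan ships more of a PPE type than an area demands."""


@dataclass(frozen=True)
class WaitingCostCurve:
    """Unit waiting cost lambda(t) of victims waiting ``t`` seconds for PPE.

    The curve grows quadratically — victims' bearing capacity erodes at an
    accelerating rate — until ``breakpoint`` seconds, after which the loss
    saturates at ``plateau`` (the cost of never receiving the item).

    Parameters
    ----------
    quad_coeff:
        Quadratic growth coefficient, yuan / (kg * s^2).
    breakpoint:
        Time at which the curve saturates, seconds.
    plateau:
        Saturated unit cost, yuan / kg.
    """

    quad_coeff: float
    breakpoint: float
    plateau: float

    #: relative tolerance for continuity at the breakpoint
    _CONTINUITY_RTOL = 1e-4

    def __post_init__(self) -> None:
        if not (self.quad_coeff > 0 and self.breakpoint > 0 and self.plateau > 0):
            raise ValueError("quad_coeff, breakpoint and plateau must all be positive")
        jump = abs(self.quad_coeff * self.breakpoint**2 - self.plateau)
        if jump / self.plateau > self._CONTINUITY_RTOL:
            raise ValueError(
                "curve is discontinuous at its breakpoint: "
                f"quad_coeff*breakpoint^2 = {self.quad_coeff * self.breakpoint**2:g} "
                f"vs plateau = {self.plateau:g}"
            )

    def __call__(self, t):
        """Evaluate the curve at waiting time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("waiting time must be non-negative")
        out = np.where(t <= self.breakpoint, self.quad_coeff * t**2, self.plateau)
        # the quadratic branch may slightly overshoot the plateau just
        # before the breakpoint (continuity holds only to a tolerance)
        out = np.minimum(out, self.plateau)
        return float(out) if out.ndim == 0 else out


def waiting_cost(curve: WaitingCostCurve, t) -> float:
    """Unit waiting cost (yuan/kg) after waiting ``t`` seconds."""
    return curve(t)


@dataclass
class Instance:
    """A complete problem instance of the three-layer allocation network.

    Index sets are identified by string ids; all numeric parameters are
    dense numpy arrays in canonical units (kg, m, s, yuan).

    Array shapes (H = reserves, I = DCs, J = areas, K = PPE types,
    M = vehicle types):

    ======================  ===========  =============================
    field                   shape        meaning
    ======================  ===========  =============================
    distance                (H, I, J)    reserve->DC->area path length, m
    ppe_weight              (K,)         importance weight of each PPE
    vehicle_capacity        (M,)         load capacity, kg/vehicle
    vehicle_supply          (H, M)       vehicles stocked per reserve
    ppe_supply              (H, K)       PPE stocked per reserve, kg
    dc_vehicle_cap          (I, M)       vehicle throughput cap per DC
    dc_ppe_cap              (I, K)       PPE throughput cap per DC, kg
    demand                  (J, K)       demand per area, kg
    unit_cost               (M,)         transport cost, yuan/m
    unit_time               (M,)         travel time, s/m
    rent                    (I,)         DC renting cost, yuan
    ======================  ===========  =============================
    """

    reserve_ids: Sequence[str]
    dc_ids: Sequence[str]
    area_ids: Sequence[str]
    ppe_ids: Sequence[str]
    vehicle_ids: Sequence[str]
    distance: np.ndarray
    coverage: float
    ppe_weight: np.ndarray
    vehicle_capacity: np.ndarray
    vehicle_supply: np.ndarray
    ppe_supply: np.ndarray
    dc_vehicle_cap: np.ndarray
    dc_ppe_cap: np.ndarray
    demand: np.ndarray
    unit_cost: np.ndarray
    unit_time: np.ndarray
    rent: np.ndarray
    curves: Sequence[WaitingCostCurve]
    name: str = "instance"

    def __post_init__(self) -> None:
        for fld in (
            "distance", "ppe_weight", "vehicle_capacity", "vehicle_supply",
            "ppe_supply", "dc_vehicle_cap", "dc_ppe_cap", "demand",
            "unit_cost", "unit_time", "rent",
        ):
            setattr(self, fld, np.asarray(getattr(self, fld), dtype=float))
        self.validate()

    # -- sizes ---------------------------------------------------------
    @property
    def n_reserves(self) -> int:
        return len(self.reserve_ids)

    @property
    def n_dcs(self) -> int:
        return len(self.dc_ids)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_ppes(self) -> int:
        return len(self.ppe_ids)

    @property
    def n_vehicles(self) -> int:
        return len(self.vehicle_ids)

    def shape(self) -> tuple[int, int, int, int, int]:
        return (self.n_reserves, self.n_dcs, self.n_areas,
                self.n_ppes, self.n_vehicles)

    def validate(self) -> None:
        H, I, J, K, M = self.shape()
        if min(H, I, J, K, M) < 1:
            raise ValueError("all index sets must be non-empty")
        expected = {
            "distance": (H, I, J),
            "ppe_weight": (K,),
            "vehicle_capacity": (M,),
            "vehicle_supply": (H, M),
            "ppe_supply": (H, K),
            "dc_vehicle_cap": (I, M),
            "dc_ppe_cap": (I, K),
            "demand": (J, K),
            "unit_cost": (M,),
            "unit_time": (M,),
            "rent": (I,),
        }
        for fld, shp in expected.items():
            arr = getattr(self, fld)
            if arr.shape != shp:
                raise ValueError(f"{fld} has shape {arr.shape}, expected {shp}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{fld} contains non-finite entries")
            if np.any(arr < 0):
                raise ValueError(f"{fld} contains negative entries")
        if not (np.isfinite(self.coverage) and self.coverage > 0):
            raise ValueError("coverage must be a positive finite distance")
        if len(self.curves) != K:
            raise ValueError(f"expected {K} waiting-cost curves, got {len(self.curves)}")

    def with_distance(self, distance: np.ndarray) -> "Instance":
        """Copy of this instance with a replacement distance matrix."""
        return replace(self, distance=np.asarray(distance, dtype=float))

    @property
    def plateaus(self) -> np.ndarray:
        """Plateau unit costs per PPE type, shape (K,)."""
        return np.array([c.plateau for c in self.curves])


@dataclass
class AllocationPlan:
    """A candidate decision: DC openings, vehicle routing, PPE allocation.

    ``open_dc[i]`` is 0/1; ``vehicles[h, i, j, m]`` counts vehicles of type
    m on the path reserve h -> DC i -> area j; ``shipped[h, i, j, k, m]``
    is the kg of PPE k carried on that path by that vehicle type.
    """

    open_dc: np.ndarray
    vehicles: np.ndarray
    shipped: np.ndarray

    def __post_init__(self) -> None:
        self.open_dc = np.asarray(self.open_dc, dtype=float)
        self.vehicles = np.asarray(self.vehicles, dtype=float)
        self.shipped = np.asarray(self.shipped, dtype=float)

    @classmethod
    def zero(cls, instance: Instance) -> "AllocationPlan":
        """The do-nothing plan: no DCs opened, nothing routed or shipped."""
        H, I, J, K, M = instance.shape()
        return cls(
            open_dc=np.zeros(I),
            vehicles=np.zeros((H, I, J, M)),
            shipped=np.zeros((H, I, J, K, M)),
        )


@dataclass(frozen=True)
class ObjectiveValues:
    """Both objective values of a plan, in yuan."""

    total_loss: float
    logistics_cost: float

    def __post_init__(self) -> None:
        if self.total_loss < 0 or self.logistics_cost < 0:
            raise ValueError("objective values must be non-negative")


@dataclass(frozen=True)
class Violation:
    """One violated constraint: numeric id, offending indices, slack.

    ``slack`` is the amount by which the constraint is exceeded (positive).
    """

    constraint: int
    indices: tuple
    slack: float

    @property
    def name(self) -> str:
        return CONSTRAINT_NAMES[self.constraint]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"constraint ({self.constraint}) {self.name} violated at "
                f"{self.indices}: excess {self.slack:g}")


# ---------------------------------------------------------------------------
# objective evaluation
# ---------------------------------------------------------------------------

def route_time(instance: Instance, h: int, i: int, j: int, m: int) -> float:
    """Travel time (s) of vehicle type ``m`` along path h -> i -> j."""
    return float(instance.unit_time[m] * instance.distance[h, i, j])


def route_times(instance: Instance) -> np.ndarray:
    """All route travel times, shape (H, I, J, M)."""
    return instance.unit_time[None, None, None, :] * instance.distance[..., None]


def route_unit_costs(instance: Instance) -> np.ndarray:
    """Unit waiting cost lambda_k(t_route) per (h, i, j, k, m), yuan/kg."""
    t = route_times(instance)  # (H, I, J, M)
    H, I, J, K, M = instance.shape()
    lam = np.empty((H, I, J, K, M))
    for k, curve in enumerate(instance.curves):
        lam[:, :, :, k, :] = curve(t)
    return lam


def area_loss(instance: Instance, plan: AllocationPlan, j: int, k: int,
              *, tol: float = 1e-9) -> float:
    """Victims' waiting loss (yuan) for PPE ``k`` in area ``j``.

    Unmet demand is charged the plateau unit cost (infinite delay);
    delivered quantities are charged the unit cost at their route time.
    """
    d = instance.demand[j, k]
    y = plan.shipped[:, :, j, k, :]  # (H, I, M)
    delivered = float(y.sum())
    if delivered > d * (1 + tol) + tol:
        raise OverDeliveryError(
            f"area {j} PPE {k}: delivered {delivered:g} kg exceeds demand {d:g} kg"
        )
    curve = instance.curves[k]
    t = route_times(instance)[:, :, j, :]  # (H, I, M)
    return float((d - delivered) * curve.plateau + (y * curve(t)).sum())


def total_loss(instance: Instance, plan: AllocationPlan) -> float:
    """Objective G1: importance-weighted sum of area losses, yuan."""
    lam = route_unit_costs(instance)  # (H, I, J, K, M)
    delivered = plan.shipped.sum(axis=(0, 1, 4))  # (J, K)
    over = delivered - instance.demand
    bad = over > 1e-9 * np.maximum(1.0, instance.demand) + 1e-9
    if np.any(bad):
        j, k = map(int, np.argwhere(bad)[0])
        raise OverDeliveryError(
            f"area {j} PPE {k}: delivered {delivered[j, k]:g} kg "
            f"exceeds demand {instance.demand[j, k]:g} kg"
        )
    plateaus = instance.plateaus
    unmet_term = ((instance.demand - delivered) * plateaus[None, :])
    delay_term = np.einsum("hijkm,hijkm->jk", plan.shipped, lam)
    return float(((unmet_term + delay_term) * instance.ppe_weight[None, :]).sum())


def logistics_cost(instance: Instance, plan: AllocationPlan) -> float:
    """Objective G2: DC renting plus transportation cost, yuan."""
    rent = float(instance.rent @ plan.open_dc)
    transport = float(np.einsum(
        "hij,m,hijm->", instance.distance, instance.unit_cost, plan.vehicles
    ))
    return rent + transport


def evaluate(instance: Instance, plan: AllocationPlan) -> ObjectiveValues:
    """Both objectives of a plan."""
    return ObjectiveValues(total_loss(instance, plan),
                           logistics_cost(instance, plan))


# ---------------------------------------------------------------------------
# feasibility checking
# ---------------------------------------------------------------------------

def check_feasibility(instance: Instance, plan: AllocationPlan,
                      *, tol: float = 1e-6) -> list[Violation]:
    """List every violated constraint of a plan (empty list == feasible).

    Tolerances are absolute on counts/binaries and relative on kg/capacity
    quantities, so LP round-off never produces spurious violations.
    """
    H, I, J, K, M = instance.shape()
    z, x, y = plan.open_dc, plan.vehicles, plan.shipped
    out: list[Violation] = []

    def scaled_tol(ref) -> float:
        return tol * max(1.0, float(np.max(ref)) if np.size(ref) else 1.0)

    # (5) coverage: no vehicles on paths longer than the radius
    too_far = instance.distance > instance.coverage
    for h, i, j, m in zip(*np.nonzero(x > tol)):
        if too_far[h, i, j]:
            out.append(Violation(5, (int(h), int(i), int(j), int(m)),
                                 float(x[h, i, j, m])))

    # (6) reserve vehicle supply
    used = x.sum(axis=(1, 2))  # (H, M)
    for h, m in zip(*np.nonzero(used > instance.vehicle_supply + tol)):
        out.append(Violation(6, (int(h), int(m)),
                             float(used[h, m] - instance.vehicle_supply[h, m])))

    # (7) reserve PPE supply
    shipped_hk = y.sum(axis=(1, 2, 4))  # (H, K)
    t7 = scaled_tol(instance.ppe_supply)
    for h, k in zip(*np.nonzero(shipped_hk > instance.ppe_supply + t7)):
        out.append(Violation(7, (int(h), int(k)),
                             float(shipped_hk[h, k] - instance.ppe_supply[h, k])))

    # (8) DC vehicle capacity gated by opening
    through = x.sum(axis=(0, 2))  # (I, M)
    cap8 = instance.dc_vehicle_cap * z[:, None]
    for i, m in zip(*np.nonzero(through > cap8 + tol)):
        out.append(Violation(8, (int(i), int(m)), float(through[i, m] - cap8[i, m])))

    # (9) DC PPE capacity gated by opening
    through_ik = y.sum(axis=(0, 2, 4))  # (I, K)
    cap9 = instance.dc_ppe_cap * z[:, None]
    t9 = scaled_tol(instance.dc_ppe_cap)
    for i, k in zip(*np.nonzero(through_ik > cap9 + t9)):
        out.append(Violation(9, (int(i), int(k)), float(through_ik[i, k] - cap9[i, k])))

    # (10) vehicle load capacity per path
    load = y.sum(axis=3)  # (H, I, J, M)
    cap10 = instance.vehicle_capacity[None, None, None, :] * x
    t10 = scaled_tol(instance.vehicle_capacity)
    for h, i, j, m in zip(*np.nonzero(load > cap10 + t10)):
        out.append(Violation(10, (int(h), int(i), int(j), int(m)),
                             float(load[h, i, j, m] - cap10[h, i, j, m])))

    # (11) no over-delivery
    delivered = y.sum(axis=(0, 1, 4))  # (J, K)
    t11 = scaled_tol(instance.demand)
    for j, k in zip(*np.nonzero(delivered > instance.demand + t11)):
        out.append(Violation(11, (int(j), int(k)),
                             float(delivered[j, k] - instance.demand[j, k])))

    # (12)-(14) variable domains
    for i in range(I):
        if min(abs(z[i]), abs(z[i] - 1)) > tol:
            out.append(Violation(12, (i,), float(min(abs(z[i]), abs(z[i] - 1)))))
    frac = np.abs(x - np.round(x))
    for h, i, j, m in zip(*np.nonzero((frac > tol) | (x < -tol))):
        out.append(Violation(13, (int(h), int(i), int(j), int(m)),
                             float(max(frac[h, i, j, m], -x[h, i, j, m]))))
    for idx in zip(*np.nonzero(y < -scaled_tol(instance.demand))):
        out.append(Violation(14, tuple(int(v) for v in idx), float(-y[idx])))

    return out
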