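"""Instance serialization, the Wenzhou case fixture and synthetic instances.

Instances travel as a single YAML document with an explicit ``units`` block.
Canonical internal units are kilograms, meters, seconds and yuan; the
loader converts declared table units (e.g. masses recorded in thousands of
kilograms, as supply/demand tables commonly are) on input, and the saver
always writes canonical units.

The Wenzhou case — five affected areas in the south of the city, three
reserve centers, two candidate DCs, masks and protective clothing moved by
light/medium/heavy vehicles — ships as a programmatic fixture.  Its
reserve-to-DC-to-area distance matrix is not part of the published data,
so admissible matrices are produced by the seeded synthetic generator
(clearly synthetic, never a silent approximation of real geography); every
quantity that depends on those distances therefore depends on the seed,
while supply/demand-derived quantities are exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .model_core import AllocationPlan, Instance, WaitingCostCurve

__all__ = [
    "SCHEMA_VERSION",
    "InstanceFormatError",
    "load_instance",
    "save_instance",
    "instance_to_document",
    "instance_from_document",
    "wenzhou_case",
    "CASE_CURVE",
    "SyntheticConfig",
    "synthetic_instance",
    "synthetic_distances",
    "plan_to_flows",
    "flows_to_plan",
    "flows_to_csv",
    "csv_to_flows",
    "save_solution",
    "load_solution",
]

SCHEMA_VERSION = 1

#: The case study's shared waiting-cost curve: quadratic growth reaching a
#: 50 000 yuan/kg plateau after one week (604 800 s).
CASE_CURVE = WaitingCostCurve(quad_coeff=1 / 7315661, breakpoint=604800.0,
                              plateau=50000.0)

_MASS_FACTORS = {"kg": 1.0, "1000kg": 1000.0, "t": 1000.0}
_DIST_FACTORS = {"m": 1.0, "km": 1000.0}
_TIME_FACTORS = {"s": 1.0}
_CURRENCY_FACTORS = {"yuan": 1.0}

#: tables measured in the declared mass unit (vehicle load capacity is
#: always kg/vehicle, like the case's vehicle table)
_MASS_TABLES = ("demand", "ppe_supply", "dc_ppe_cap")


class InstanceFormatError(ValueError):
    """Schema or referential-integrity failure in an instance document."""


def _require(mapping: dict, key: str, path: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise InstanceFormatError(f"missing required entry: {path}.{key}")
    return mapping[key]


def _table_1d(doc: dict, name: str, ids: Sequence[str], factor: float) -> np.ndarray:
    table = _require(doc, name, "document")
    out = np.empty(len(ids))
    for pos, key in enumerate(ids):
        out[pos] = float(_require(table, key, name)) * factor
    extra = set(table) - set(ids)
    if extra:
        raise InstanceFormatError(
            f"{name} refers to unknown ids: {sorted(extra)}")
    return out


def _table_2d(doc: dict, name: str, rows: Sequence[str], cols: Sequence[str],
              factor: float) -> np.ndarray:
    table = _require(doc, name, "document")
    out = np.empty((len(rows), len(cols)))
    for r, rk in enumerate(rows):
        row = _require(table, rk, name)
        for c, ck in enumerate(cols):
            out[r, c] = float(_require(row, ck, f"{name}.{rk}")) * factor
    extra = set(table) - set(rows)
    if extra:
        raise InstanceFormatError(f"{name} refers to unknown ids: {sorted(extra)}")
    return out


def instance_from_document(doc: dict) -> Instance:
    """Build an :class:`Instance` from a parsed document (canonicalising units)."""
    units = doc.get("units", {})
    try:
        mass = _MASS_FACTORS[units.get("mass", "kg")]
        dist = _DIST_FACTORS[units.get("distance", "m")]
        _TIME_FACTORS[units.get("time", "s")]
        _CURRENCY_FACTORS[units.get("currency", "yuan")]
    except KeyError as exc:
        raise InstanceFormatError(f"unknown unit in units block: {exc}") from exc

    sets = _require(doc, "sets", "document")
    reserves = list(_require(sets, "reserves", "sets"))
    dcs = list(_require(sets, "dcs", "sets"))
    areas = list(_require(sets, "areas", "sets"))
    ppes = list(_require(sets, "ppes", "sets"))
    vehicles = list(_require(sets, "vehicles", "sets"))

    dist_doc = _require(doc, "distance", "document")
    D = np.empty((len(reserves), len(dcs), len(areas)))
    for h, hk in enumerate(reserves):
        row = _require(dist_doc, hk, "distance")
        for i, ik in enumerate(dcs):
            cell = _require(row, ik, f"distance.{hk}")
            for j, jk in enumerate(areas):
                D[h, i, j] = float(_require(cell, jk, f"distance.{hk}.{ik}")) * dist

    curves_doc = _require(doc, "curves", "document")
    curves = []
    for pk in ppes:
        cd = _require(curves_doc, pk, "curves")
        curves.append(WaitingCostCurve(
            quad_coeff=float(_require(cd, "quad_coeff", f"curves.{pk}")),
            breakpoint=float(_require(cd, "breakpoint", f"curves.{pk}")),
            plateau=float(_require(cd, "plateau", f"curves.{pk}")),
        ))

    mass_f = {name: mass for name in _MASS_TABLES}
    return Instance(
        name=str(doc.get("name", "instance")),
        reserve_ids=reserves, dc_ids=dcs, area_ids=areas,
        ppe_ids=ppes, vehicle_ids=vehicles,
        distance=D,
        coverage=float(_require(doc, "coverage", "document")) * dist,
        ppe_weight=_table_1d(doc, "ppe_weight", ppes, 1.0),
        vehicle_capacity=_table_1d(doc, "vehicle_capacity", vehicles, 1.0),
        vehicle_supply=_table_2d(doc, "vehicle_supply", reserves, vehicles, 1.0),
        ppe_supply=_table_2d(doc, "ppe_supply", reserves, ppes,
                             mass_f["ppe_supply"]),
        dc_vehicle_cap=_table_2d(doc, "dc_vehicle_cap", dcs, vehicles, 1.0),
        dc_ppe_cap=_table_2d(doc, "dc_ppe_cap", dcs, ppes,
                             mass_f["dc_ppe_cap"]),
        demand=_table_2d(doc, "demand", areas, ppes, mass_f["demand"]),
        unit_cost=_table_1d(doc, "unit_cost", vehicles, 1.0),
        unit_time=_table_1d(doc, "unit_time", vehicles, 1.0),
        rent=_table_1d(doc, "rent", dcs, 1.0),
        curves=curves,
    )


def instance_to_document(instance: Instance) -> dict:
    """Serialize an instance to a plain document in canonical units."""
    def d1(ids, arr):
        return {k: float(v) for k, v in zip(ids, arr)}

    def d2(rows, cols, arr):
        return {rk: {ck: float(arr[r, c]) for c, ck in enumerate(cols)}
                for r, rk in enumerate(rows)}

    return {
        "schema_version": SCHEMA_VERSION,
        "name": instance.name,
        "units": {"mass": "kg", "distance": "m", "time": "s",
                  "currency": "yuan"},
        "sets": {
            "reserves": list(instance.reserve_ids),
            "dcs": list(instance.dc_ids),
            "areas": list(instance.area_ids),
            "ppes": list(instance.ppe_ids),
            "vehicles": list(instance.vehicle_ids),
        },
        "coverage": float(instance.coverage),
        "distance": {
            hk: {ik: {jk: float(instance.distance[h, i, j])
                      for j, jk in enumerate(instance.area_ids)}
                 for i, ik in enumerate(instance.dc_ids)}
            for h, hk in enumerate(instance.reserve_ids)
        },
        "ppe_weight": d1(instance.ppe_ids, instance.ppe_weight),
        "vehicle_capacity": d1(instance.vehicle_ids, instance.vehicle_capacity),
        "vehicle_supply": d2(instance.reserve_ids, instance.vehicle_ids,
                             instance.vehicle_supply),
        "ppe_supply": d2(instance.reserve_ids, instance.ppe_ids,
                         instance.ppe_supply),
        "dc_vehicle_cap": d2(instance.dc_ids, instance.vehicle_ids,
                             instance.dc_vehicle_cap),
        "dc_ppe_cap": d2(instance.dc_ids, instance.ppe_ids,
                         instance.dc_ppe_cap),
        "demand": d2(instance.area_ids, instance.ppe_ids, instance.demand),
        "unit_cost": d1(instance.vehicle_ids, instance.unit_cost),
        "unit_time": d1(instance.vehicle_ids, instance.unit_time),
        "rent": d1(instance.dc_ids, instance.rent),
        "curves": {pk: {"quad_coeff": c.quad_coeff,
                        "breakpoint": c.breakpoint,
                        "plateau": c.plateau}
                   for pk, c in zip(instance.ppe_ids, instance.curves)},
    }


def load_instance(source: Union[str, Path, io.TextIOBase, dict]) -> Instance:
    """Load an instance from a YAML path, stream or parsed document."""
    if isinstance(source, dict):
        doc = source
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, dict):
        raise InstanceFormatError("instance document must be a mapping")
    return instance_from_document(doc)


def save_instance(instance: Instance, path: Union[str, Path]) -> None:
    """Write an instance to a YAML document in canonical units."""
    with open(path, "w") as fh:
        yaml.safe_dump(instance_to_document(instance), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Wenzhou case fixture
# ---------------------------------------------------------------------------

_WENZHOU = {
    "reserves": ["Shiqu", "Yongjia", "Yueqing"],
    "dcs": ["DC1", "DC2"],
    "areas": ["Ruian", "Pingyang", "Cangnan", "Wencheng", "Taishun"],
    "ppes": ["masks", "protective_clothing"],
    "vehicles": ["light", "medium", "heavy"],
    # demand table, thousands of kg (masks, protective clothing)
    "demand_kkg": [[146.0, 0.0], [150.0, 0.0], [165.0, 0.16],
                   [150.0, 11.4], [320.0, 3.04]],
    # reserve stocks: PPE in thousands of kg, vehicles in counts
    "ppe_supply_kkg": [[500.0, 6.0], [150.0, 2.0], [300.0, 4.0]],
    "vehicle_supply": [[30, 15, 10], [10, 5, 2], [20, 10, 5]],
    # DC capacities: PPE in thousands of kg, vehicles in counts
    "dc_ppe_cap_kkg": [[800.0, 10.0], [600.0, 8.0]],
    "dc_vehicle_cap": [[50, 25, 12], [40, 20, 10]],
    "rent": [800000.0, 600000.0],
    "ppe_weight": [0.6, 0.4],
    "vehicle_capacity": [5000.0, 10000.0, 20000.0],
    "unit_cost": [0.1, 0.2, 0.3],
    "unit_time": [0.06, 0.07, 0.09],
    "coverage": 150000.0,
}


def wenzhou_case(distances: Optional[np.ndarray] = None, *,
                 seed: Optional[int] = None) -> Instance:
    """The Wenzhou PPE case study instance.

    The published data fixes everything except the 3 x 2 x 5 path-distance
    matrix; supply either ``distances`` (meters, strictly positive) or a
    ``seed`` for the synthetic planar generator, which guarantees that each
    area is reachable within the 150 km coverage radius from at least one
    reserve-DC path.
    """
    W = _WENZHOU
    if distances is None:
        if seed is None:
            raise ValueError("supply either a distance matrix or a seed")
        distances = synthetic_distances(
            n_reserves=3, n_dcs=2, n_areas=5, region=80000.0,
            road_factor=1.3, coverage=W["coverage"], seed=seed)
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (3, 2, 5):
        raise ValueError(f"distances must have shape (3, 2, 5), "
                         f"got {distances.shape}")
    if np.any(distances <= 0):
        raise ValueError("distances must be strictly positive")

    return Instance(
        name="wenzhou",
        reserve_ids=W["reserves"], dc_ids=W["dcs"], area_ids=W["areas"],
        ppe_ids=W["ppes"], vehicle_ids=W["vehicles"],
        distance=distances,
        coverage=W["coverage"],
        ppe_weight=np.array(W["ppe_weight"]),
        vehicle_capacity=np.array(W["vehicle_capacity"]),
        vehicle_supply=np.array(W["vehicle_supply"], dtype=float),
        ppe_supply=np.array(W["ppe_supply_kkg"]) * 1000.0,
        dc_vehicle_cap=np.array(W["dc_vehicle_cap"], dtype=float),
        dc_ppe_cap=np.array(W["dc_ppe_cap_kkg"]) * 1000.0,
        demand=np.array(W["demand_kkg"]) * 1000.0,
        unit_cost=np.array(W["unit_cost"]),
        unit_time=np.array(W["unit_time"]),
        rent=np.array(W["rent"]),
        curves=[CASE_CURVE, CASE_CURVE],
    )


# ---------------------------------------------------------------------------
# synthetic instances
# ---------------------------------------------------------------------------

def synthetic_distances(*, n_reserves: int, n_dcs: int, n_areas: int,
                        region: float, road_factor: float, coverage: float,
                        seed: int, max_tries: int = 1000) -> np.ndarray:
    """Seeded planar path-distance matrix with guaranteed coverage.

    Reserve centers, DCs and areas are placed uniformly in a square region;
    the path distance is ``road_factor`` times the two-leg Euclidean length.
    Layouts are re-sampled until every area is within ``coverage`` of at
    least one reserve-DC path.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        res = rng.uniform(0, region, size=(n_reserves, 2))
        dcs = rng.uniform(0, region, size=(n_dcs, 2))
        areas = rng.uniform(0, region, size=(n_areas, 2))
        leg1 = np.linalg.norm(res[:, None, :] - dcs[None, :, :], axis=2)
        leg2 = np.linalg.norm(dcs[:, None, :] - areas[None, :, :], axis=2)
        D = road_factor * (leg1[:, :, None] + leg2[None, :, :])
        D = np.maximum(D, 1.0)
        if np.all(D.min(axis=(0, 1)) <= coverage):
            return D
    raise RuntimeError(
        f"could not place a layout with full coverage in {max_tries} tries; "
        "enlarge coverage or shrink the region")


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic instance generator.

    Defaults emulate the case study's magnitudes: an 80 km planar region
    inside a 150 km coverage radius, road distances 1.3x Euclidean,
    demands of tens to hundreds of tonnes per area, vehicle fleets of a
    few to a few tens of vehicles, and a supply shortage
    (``shortage_ratio`` = total supply / total demand < 1), which is the
    regime the loss function is designed for.
    """

    n_reserves: int = 3
    n_dcs: int = 2
    n_areas: int = 5
    n_ppes: int = 2
    n_vehicles: int = 3
    region: float = 80000.0
    road_factor: float = 1.3
    coverage: float = 150000.0
    shortage_ratio: float = 0.8
    seed: int = 0
    demand_range: tuple[float, float] = (20000.0, 350000.0)
    vehicle_supply_range: tuple[int, int] = (2, 30)
    vehicle_capacity_range: tuple[float, float] = (5000.0, 20000.0)
    rent_range: tuple[float, float] = (500000.0, 1000000.0)
    curve: WaitingCostCurve = field(default=CASE_CURVE)

    def __post_init__(self) -> None:
        if min(self.n_reserves, self.n_dcs, self.n_areas,
               self.n_ppes, self.n_vehicles) < 1:
            raise ValueError("all set sizes must be >= 1")
        if self.shortage_ratio <= 0:
            raise ValueError("shortage_ratio must be positive")
        if self.road_factor < 1:
            raise ValueError("road_factor must be >= 1")


def synthetic_instance(config: SyntheticConfig) -> Instance:
    """Generate a random instance; identical seeds give identical instances.

    Total PPE supply is tied to total demand through the shortage ratio:
    for each PPE type, supply is split across reserves so that it sums to
    ``shortage_ratio`` times the type's total demand.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, I, J, K, M = (cfg.n_reserves, cfg.n_dcs, cfg.n_areas,
                     cfg.n_ppes, cfg.n_vehicles)

    D = synthetic_distances(
        n_reserves=H, n_dcs=I, n_areas=J, region=cfg.region,
        road_factor=cfg.road_factor, coverage=cfg.coverage,
        seed=int(rng.integers(0, 2**31 - 1)))

    demand = rng.uniform(*cfg.demand_range, size=(J, K))
    total_k = demand.sum(axis=0)
    shares = rng.dirichlet(np.ones(H), size=K).T  # (H, K)
    ppe_supply = cfg.shortage_ratio * total_k[None, :] * shares

    vehicle_capacity = np.sort(rng.uniform(*cfg.vehicle_capacity_range, size=M))
    lo, hi = cfg.vehicle_supply_range
    vehicle_supply = rng.integers(lo, hi + 1, size=(H, M)).astype(float)
    dc_vehicle_cap = np.ceil(
        vehicle_supply.sum(axis=0)[None, :] * rng.uniform(0.4, 0.9, size=(I, M)))
    dc_ppe_cap = total_k[None, :] * rng.uniform(0.5, 1.0, size=(I, K))

    unit_cost = np.sort(rng.uniform(0.1, 0.3, size=M))
    unit_time = np.sort(rng.uniform(0.06, 0.09, size=M))
    rent = rng.uniform(*cfg.rent_range, size=I)
    weights = rng.dirichlet(np.ones(K))

    return Instance(
        name=f"synthetic-{cfg.seed}",
        reserve_ids=[f"R{h}" for h in range(H)],
        dc_ids=[f"DC{i}" for i in range(I)],
        area_ids=[f"A{j}" for j in range(J)],
        ppe_ids=[f"P{k}" for k in range(K)],
        vehicle_ids=[f"V{m}" for m in range(M)],
        distance=D, coverage=cfg.coverage,
        ppe_weight=weights, vehicle_capacity=vehicle_capacity,
        vehicle_supply=vehicle_supply, ppe_supply=ppe_supply,
        dc_vehicle_cap=dc_vehicle_cap, dc_ppe_cap=dc_ppe_cap,
        demand=demand, unit_cost=unit_cost, unit_time=unit_time,
        rent=rent, curves=[cfg.curve] * K,
    )


# ---------------------------------------------------------------------------
# solution / flow serialization
# ---------------------------------------------------------------------------

def plan_to_flows(instance: Instance, plan: AllocationPlan) -> list[dict]:
    """Non-zero flows as records (one per path/PPE/vehicle combination)."""
    flows = []
    H, I, J, K, M = instance.shape()
    for h, i, j, m in zip(*np.nonzero(plan.vehicles > 0.5)):
        path_rows = []
        for k in range(K):
            kg = float(plan.shipped[h, i, j, k, m])
            if kg > 0:
                path_rows.append((k, kg))
        if not path_rows:  # vehicles routed empty: keep the count visible
            path_rows = [(0, 0.0)]
        for k, kg in path_rows:
            flows.append({
                "reserve": instance.reserve_ids[h],
                "dc": instance.dc_ids[i],
                "area": instance.area_ids[j],
                "ppe": instance.ppe_ids[k],
                "vehicle": instance.vehicle_ids[m],
                "vehicles": int(round(plan.vehicles[h, i, j, m])),
                "kg": kg,
            })
    return flows


def flows_to_plan(instance: Instance, flows: Sequence[dict],
                  open_dcs: Sequence[str]) -> AllocationPlan:
    """Rebuild a plan from flow records plus the list of opened DCs."""
    plan = AllocationPlan.zero(instance)
    idx = {
        "reserve": {k: p for p, k in enumerate(instance.reserve_ids)},
        "dc": {k: p for p, k in enumerate(instance.dc_ids)},
        "area": {k: p for p, k in enumerate(instance.area_ids)},
        "ppe": {k: p for p, k in enumerate(instance.ppe_ids)},
        "vehicle": {k: p for p, k in enumerate(instance.vehicle_ids)},
    }
    for name in open_dcs:
        if name not in idx["dc"]:
            raise InstanceFormatError(f"unknown DC in solution: {name}")
        plan.open_dc[idx["dc"][name]] = 1.0
    for f in flows:
        try:
            h = idx["reserve"][f["reserve"]]
            i = idx["dc"][f["dc"]]
            j = idx["area"][f["area"]]
            k = idx["ppe"][f["ppe"]]
            m = idx["vehicle"][f["vehicle"]]
        except KeyError as exc:
            raise InstanceFormatError(f"unknown id in flow record: {exc}") from exc
        plan.vehicles[h, i, j, m] = float(f["vehicles"])
        plan.shipped[h, i, j, k, m] = float(f["kg"])
    return plan


def flows_to_csv(flows: Sequence[dict], path: Union[str, Path]) -> None:
    cols = ["reserve", "dc", "area", "ppe", "vehicle", "vehicles", "kg"]
    pd.DataFrame(list(flows), columns=cols).to_csv(path, index=False)


def csv_to_flows(path: Union[str, Path]) -> list[dict]:
    return pd.read_csv(path).to_dict("records")


def save_solution(path: Union[str, Path], instance: Instance,
                  plan: AllocationPlan, *, meta: Optional[dict] = None) -> None:
    """Write a solution document: opened DCs, objectives, flows, metadata."""
    from .model_core import evaluate

    obj = evaluate(instance, plan)
    doc = {
        "instance": instance.name,
        "open_dcs": [instance.dc_ids[i]
                     for i in np.nonzero(plan.open_dc > 0.5)[0]],
        "objectives": {"total_loss": obj.total_loss,
                       "logistics_cost": obj.logistics_cost},
        "flows": plan_to_flows(instance, plan),
    }
    if meta:
        doc["meta"] = meta
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_solution(path: Union[str, Path],
                  instance: Instance) -> tuple[AllocationPlan, dict]:
    """Read a solution document back into a plan (plus raw metadata)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    plan = flows_to_plan(instance, doc.get("flows", []),
                         doc.get("open_dcs", []))
    return plan, doc
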