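"""Shared fixtures: the case instance, tiny solvable instances, random plans."""

from __future__ import annotations

import numpy as np
import pytest

from ppealloc import AllocationPlan, Instance, WaitingCostCurve, wenzhou_case
from ppealloc.data_io import SyntheticConfig, synthetic_instance

# shapes (H, I, J) kept small enough for exhaustive enumeration
TINY_SHAPES = [(1, 1, 2), (2, 1, 1), (1, 2, 1), (2, 1, 2), (1, 2, 2), (2, 2, 1)]


def tiny_instance(seed: int) -> Instance:
    """A seeded instance small enough for the exhaustive oracle."""
    H, I, J = TINY_SHAPES[seed % len(TINY_SHAPES)]
    cfg = SyntheticConfig(
        n_reserves=H, n_dcs=I, n_areas=J, n_ppes=1, n_vehicles=1,
        vehicle_supply_range=(1, 2), demand_range=(5000.0, 40000.0),
        seed=seed)
    return synthetic_instance(cfg)


@pytest.fixture(scope="session")
def wenzhou() -> Instance:
    return wenzhou_case(seed=1)


@pytest.fixture(scope="session")
def tiny_fleet() -> list[Instance]:
    """Twenty seeded tiny instances for oracle-equivalence checks."""
    return [tiny_instance(seed) for seed in range(100, 120)]


@pytest.fixture()
def square_curve() -> WaitingCostCurve:
    """A curve with exact continuity: quad * breakpoint^2 == plateau."""
    plateau = 50000.0
    quad = 1e-4
    return WaitingCostCurve(quad_coeff=quad,
                            breakpoint=float(np.sqrt(plateau / quad)),
                            plateau=plateau)


def random_feasible_plan(instance: Instance, rng: np.random.Generator,
                         *, open_all: bool = False) -> AllocationPlan:
    """Sample a plan satisfying all constraints by greedy construction."""
    H, I, J, K, M = instance.shape()
    plan = AllocationPlan.zero(instance)
    plan.open_dc = (np.ones(I) if open_all
                    else (rng.random(I) < 0.7).astype(float))

    veh_left = instance.vehicle_supply.copy()          # (H, M)
    dc_veh_left = instance.dc_vehicle_cap * plan.open_dc[:, None]
    for h in range(H):
        for i in range(I):
            for j in range(J):
                for m in range(M):
                    if instance.distance[h, i, j] > instance.coverage:
                        continue
                    cap = int(min(veh_left[h, m], dc_veh_left[i, m]))
                    if cap <= 0:
                        continue
                    n = int(rng.integers(0, cap + 1))
                    plan.vehicles[h, i, j, m] = n
                    veh_left[h, m] -= n
                    dc_veh_left[i, m] -= n

    supply_left = instance.ppe_supply.copy()           # (H, K)
    dc_ppe_left = instance.dc_ppe_cap * plan.open_dc[:, None]
    demand_left = instance.demand.copy()               # (J, K)
    for h in range(H):
        for i in range(I):
            for j in range(J):
                for m in range(M):
                    load_left = (instance.vehicle_capacity[m]
                                 * plan.vehicles[h, i, j, m])
                    for k in range(K):
                        cap = min(load_left, supply_left[h, k],
                                  dc_ppe_left[i, k], demand_left[j, k])
                        if cap <= 0:
                            continue
                        q = rng.uniform(0, cap)
                        plan.shipped[h, i, j, k, m] = q
                        load_left -= q
                        supply_left[h, k] -= q
                        dc_ppe_left[i, k] -= q
                        demand_left[j, k] -= q
    return plan
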