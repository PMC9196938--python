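"""Evaluation machinery: ideal/worst levels, deviations, tradeoffs, robustness.

The goal-programming workflow needs reference levels for each objective:
the *ideal* level is the single-objective minimum over the feasible region
and the *worst* level the single-objective maximum.  Percentage deviation
places an achieved objective value on the [ideal, worst] scale.  The Pareto
tradeoff between victims' losses and logistics cost is traced by relaxing
the ideal loss level and recording the minimal cost attainable at each
relaxation; the robustness scan re-solves the same grid and compares the
improved search against a reference solver.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formulation import GoalSpec, build_formulation
from .model_core import Instance
from .solver import (BnBOptions, SolveResult, branch_and_bound,
                     improved_solve, lexicographic_solve)

__all__ = [
    "TradeoffPoint",
    "ideal_levels",
    "worst_values",
    "worst_loss_closed_form",
    "percentage_deviation",
    "pareto_trace",
    "tradeoff_table",
    "sensitivity_scan",
]


@dataclass(frozen=True)
class TradeoffPoint:
    """One point of the loss/cost tradeoff curve."""

    multiplier: float
    ideal_level_r1: float
    min_g2: float
    achieved_g1: float
    theta1_plus: float
    nodes: int


def ideal_levels(instance: Instance,
                 options: Optional[BnBOptions] = None,
                 *, solve=improved_solve,
                 strict: bool = True) -> tuple[float, float]:
    """Single-objective minima (R1, R2) over the full constraint set.

    R2 is always attainable at zero cost by the do-nothing plan (no DC
    opened, nothing shipped), so the solve mainly certifies R2 = 0 while R1
    requires the full loss minimisation.

    With ``strict=False`` a solve stopped by the node limit contributes its
    incumbent value (an upper bound on the true ideal level) instead of
    raising; a warning records how far the proof got.
    """
    options = options or BnBOptions()
    form = build_formulation(instance)
    r1 = solve(form, options, objective=form.obj_g1, offset=form.offset_g1)
    r2 = solve(form, options, objective=form.obj_g2, offset=form.offset_g2)
    for label, res in (("R1", r1), ("R2", r2)):
        if res.status == "optimal":
            continue
        if strict or res.status != "node-limit" or res.plan is None:
            raise RuntimeError(f"{label} solve ended with status {res.status}")
        warnings.warn(
            f"{label} not proven within the node limit: using incumbent "
            f"{res.objective:g} (lower bound {res.bound:g}, gap {res.gap:.2%})",
            stacklevel=2)
    return float(r1.objective), float(r2.objective)


def worst_loss_closed_form(instance: Instance) -> float:
    """Worst-case weighted loss: nothing delivered, every kg at plateau cost."""
    return float((instance.demand * instance.plateaus[None, :]
                  * instance.ppe_weight[None, :]).sum())


def worst_values(instance: Instance,
                 options: Optional[BnBOptions] = None,
                 *, solve=improved_solve,
                 cross_check: bool = False) -> tuple[float, float]:
    """Single-objective maxima (worst G1, worst G2).

    The worst loss has a closed form — the unit waiting cost never exceeds
    its plateau, so the zero-delivery plan maximises G1.  The worst cost is
    a genuine maximisation MILP (fill every vehicle bound on the longest
    admissible paths).  With ``cross_check=True`` the closed form is also
    verified by solving the G1 maximisation.
    """
    options = options or BnBOptions()
    form = build_formulation(instance)
    max_g1 = worst_loss_closed_form(instance)
    if cross_check:
        res = solve(form, options, objective=-form.obj_g1,
                    offset=-form.offset_g1)
        solved = -res.objective
        if abs(solved - max_g1) > 1e-6 * max(1.0, max_g1):
            raise AssertionError(
                f"closed-form worst loss {max_g1:g} != solved {solved:g}")
    res2 = solve(form, options, objective=-form.obj_g2, offset=0.0)
    if res2.status != "optimal":
        raise RuntimeError(f"worst-G2 solve ended with status {res2.status}")
    return max_g1, float(-res2.objective)


def percentage_deviation(current: float, lower: float, upper: float) -> float:
    """(current - lower) / (upper - lower): position on the ideal-worst scale.

    Returns a fraction in [0, 1] when ``lower <= current <= upper``;
    out-of-range inputs are allowed but flagged with a warning, as is a
    degenerate scale (``upper == lower``, which yields 0).
    """
    if upper < lower:
        raise ValueError(f"upper bound {upper:g} below lower bound {lower:g}")
    if upper == lower:
        warnings.warn("degenerate deviation scale (upper == lower); returning 0",
                      stacklevel=2)
        return 0.0
    if not (lower <= current <= upper):
        warnings.warn(
            f"value {current:g} outside [{lower:g}, {upper:g}]", stacklevel=2)
    return (current - lower) / (upper - lower)


def pareto_trace(instance: Instance,
                 multipliers: Sequence[float],
                 options: Optional[BnBOptions] = None,
                 *,
                 ideals: Optional[tuple[float, float]] = None,
                 solve=improved_solve) -> list[TradeoffPoint]:
    """Trace the loss/cost tradeoff by relaxing the ideal loss level.

    For each multiplier ``kappa >= 1`` (ascending) the goal program is
    solved lexicographically with the loss ideal replaced by
    ``kappa * R1``; the minimal attainable cost is recorded.  Growing the
    loss budget can only enlarge the feasible set of the cost stage, so the
    resulting cost sequence is non-increasing.
    """
    multipliers = list(multipliers)
    if any(k < 1 for k in multipliers):
        raise ValueError("multipliers must be >= 1")
    if sorted(multipliers) != multipliers:
        raise ValueError("multipliers must be ascending")
    options = options or BnBOptions()
    if ideals is None:
        ideals = ideal_levels(instance, options, solve=solve)
    r1, r2 = ideals

    form = build_formulation(instance)
    points = []
    for kappa in multipliers:
        spec = GoalSpec(ideals=(kappa * r1, r2), mode="lexicographic")
        lex = lexicographic_solve(form, spec, options, solve=solve)
        nodes = lex.stage1.stats.nodes + lex.stage2.stats.nodes
        points.append(TradeoffPoint(
            multiplier=float(kappa), ideal_level_r1=float(kappa * r1),
            min_g2=lex.logistics_cost, achieved_g1=lex.total_loss,
            theta1_plus=lex.theta1_plus, nodes=nodes))
    return points


def tradeoff_table(points: Sequence[TradeoffPoint]) -> pd.DataFrame:
    """Tradeoff points as a DataFrame (CSV-ready)."""
    return pd.DataFrame([{
        "multiplier": p.multiplier,
        "ideal_level_R1": p.ideal_level_r1,
        "min_G2": p.min_g2,
        "achieved_G1": p.achieved_g1,
        "theta1_plus": p.theta1_plus,
        "nodes": p.nodes,
    } for p in points])


def sensitivity_scan(instance: Instance,
                     multipliers: Sequence[float],
                     options: Optional[BnBOptions] = None,
                     *,
                     reference=branch_and_bound,
                     ideals: Optional[tuple[float, float]] = None) -> pd.DataFrame:
    """Robustness of the improved search across loss-ideal relaxations.

    For each multiplier the goal program is solved lexicographically twice
    — with the improved procedure and with the reference solver — and the
    relative difference of the final (cost-deviation) objectives is
    reported together with node counts.  Runtimes are informational only:
    they depend on the machine, never on correctness.
    """
    options = options or BnBOptions()
    if ideals is None:
        ideals = ideal_levels(instance, options)
    r1, r2 = ideals
    form = build_formulation(instance)

    records = []
    for kappa in multipliers:
        spec = GoalSpec(ideals=(kappa * r1, r2), mode="lexicographic")
        t0 = time.perf_counter()
        imp = lexicographic_solve(form, spec, options, solve=improved_solve)
        t_imp = time.perf_counter() - t0
        t0 = time.perf_counter()
        ref = lexicographic_solve(form, spec, options, solve=reference)
        t_ref = time.perf_counter() - t0
        ref_obj = ref.stage2.objective
        err = abs(imp.stage2.objective - ref_obj) / max(1.0, abs(ref_obj))
        records.append({
            "multiplier": float(kappa),
            "objective": imp.stage2.objective,
            "reference_objective": ref_obj,
            "solution_error": err,
            "nodes": imp.stage1.stats.nodes + imp.stage2.stats.nodes,
            "reference_nodes": ref.stage1.stats.nodes + ref.stage2.stats.nodes,
            "runtime_s": t_imp,
            "reference_runtime_s": t_ref,
        })
    return pd.DataFrame(records)
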