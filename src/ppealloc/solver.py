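"""Branch-and-bound solution of the allocation MILP.

The solver decomposes the mixed-integer program into a sequence of linear
programs: the LP relaxation bounds the optimum from below, and branching on
a fractional integer variable (floor / ceil children) partitions the search
space until an integral relaxation proves optimality.  LP subproblems are
solved by HiGHS through :func:`scipy.optimize.linprog`; the subroutine is
treated as an abstract contract (deterministic optimal basic solution), and
warm-start information degrades gracefully to a cold start when the backend
cannot consume it.

Two drivers are provided on top of the plain tree search:

* :func:`improved_solve` — a heuristic-then-proven procedure: solve the
  root relaxation and keep its solution as a warm-start descriptor; fix DC
  location variables whose relaxation values are near 0 or near 1; solve
  the restricted problem to obtain a heuristic incumbent; then restore the
  original bounds and re-solve the full problem using that incumbent as a
  cutoff.  The heuristic only supplies a cutoff, so the final answer is
  always a proven optimum identical to the plain search.
* :func:`lexicographic_solve` — the preemptive goal-programming driver:
  first minimise the positive deviation of the loss goal, then, holding it
  at its optimum, minimise the positive deviation of the cost goal.

:func:`enumerate_oracle` exhaustively enumerates the integer grid (tiny
instances only) and serves as the ground-truth cross-check in the tests.
"""

from __future__ import annotations

import heapq
import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
from scipy.optimize import linprog

from .formulation import (GoalFormulation, GoalSpec, MILPFormulation, Row,
                          attach_goal, build_formulation, extract_plan)
from .model_core import AllocationPlan, Instance

__all__ = [
    "BnBOptions",
    "TreeStats",
    "SolveResult",
    "LPRelaxation",
    "LexicographicResult",
    "solve_lp_relaxation",
    "branch_and_bound",
    "improved_solve",
    "enumerate_oracle",
    "lexicographic_solve",
]


@dataclass(frozen=True)
class BnBOptions:
    """Tuning knobs of the tree search.

    ``fix_zero`` / ``fix_one`` quantify the improved procedure's rule of
    fixing location variables whose relaxation values are "close to 0" or
    "relatively large": z_i is fixed to 0 when its relaxation value is at
    most ``fix_zero`` and to 1 when at least ``fix_one``.  The rule only
    shapes the heuristic pass, never the final proven solve.
    """

    int_tol: float = 1e-6
    rel_gap: float = 0.0
    node_selection: Literal["best-bound", "depth-first"] = "best-bound"
    branching: Literal["most-fractional", "lowest-index"] = "most-fractional"
    fix_zero: float = 0.01
    fix_one: float = 0.9
    node_limit: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fix_zero < self.fix_one < 1):
            raise ValueError("need 0 < fix_zero < fix_one < 1")
        if self.int_tol <= 0:
            raise ValueError("int_tol must be positive")
        if self.rel_gap < 0:
            raise ValueError("rel_gap must be non-negative")


@dataclass
class TreeStats:
    """Search-tree statistics and the incumbent-update log."""

    nodes: int = 0
    max_depth: int = 0
    incumbent_updates: list = field(default_factory=list)

    def log_incumbent(self, node: int, depth: int, bound: float,
                      incumbent: float) -> None:
        self.incumbent_updates.append(
            {"node": node, "depth": depth, "bound": bound,
             "incumbent": incumbent})

    def to_dict(self) -> dict:
        return {"nodes": self.nodes, "max_depth": self.max_depth,
                "incumbent_updates": list(self.incumbent_updates)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class SolveResult:
    """Outcome of a MILP solve."""

    status: Literal["optimal", "infeasible", "node-limit"]
    objective: float
    bound: float
    gap: float
    plan: Optional[AllocationPlan]
    vector: Optional[np.ndarray]
    total_loss: Optional[float]
    logistics_cost: Optional[float]
    stats: TreeStats
    heuristic_objective: Optional[float] = None
    heuristic_stats: Optional[TreeStats] = None


@dataclass
class LPRelaxation:
    """Optimal solution of a linear relaxation.

    ``warm_start`` carries the primal point as a restart descriptor for the
    abstract LP contract; backends that cannot consume it simply re-solve
    from a cold start.
    """

    status: Literal["optimal", "infeasible", "unbounded"]
    objective: float
    values: Optional[np.ndarray]
    warm_start: Optional[np.ndarray]


# ---------------------------------------------------------------------------
# LP subroutine
# ---------------------------------------------------------------------------

class _LPContext:
    """Pre-assembled matrices of a formulation, shared by all tree nodes."""

    def __init__(self, form: MILPFormulation):
        self.form = form
        self.A_ub, self.b_ub, self.A_eq, self.b_eq = form.matrices()
        self.lb, self.ub = form.bounds
        self.int_idx = np.nonzero(form.integer_mask)[0]

    def solve(self, c: np.ndarray,
              overrides: Optional[dict] = None) -> LPRelaxation:
        lb, ub = self.lb, self.ub
        if overrides:
            lb, ub = lb.copy(), ub.copy()
            for p, (lo, hi) in overrides.items():
                lb[p], ub[p] = lo, hi
                if lo > hi:
                    return LPRelaxation("infeasible", math.inf, None, None)
        res = linprog(c, A_ub=self.A_ub, b_ub=self.b_ub,
                      A_eq=self.A_eq, b_eq=self.b_eq,
                      bounds=np.column_stack([lb, ub]), method="highs")
        if res.status == 2:
            return LPRelaxation("infeasible", math.inf, None, None)
        if res.status == 3:
            return LPRelaxation("unbounded", -math.inf, None, None)
        if not res.success:  # pragma: no cover - defensive
            raise RuntimeError(f"LP backend failure: {res.message}")
        return LPRelaxation("optimal", float(res.fun), res.x, res.x)


def solve_lp_relaxation(formulation: MILPFormulation,
                        objective: Optional[np.ndarray] = None,
                        offset: float = 0.0) -> LPRelaxation:
    """Solve the LP relaxation (integrality dropped) of a formulation.

    Defaults to the loss objective G1 when no objective vector is given.
    The returned objective includes ``offset``.
    """
    if objective is None:
        objective, offset = formulation.obj_g1, formulation.offset_g1
    ctx = _LPContext(formulation)
    rel = ctx.solve(np.asarray(objective, dtype=float))
    if rel.status == "optimal":
        rel.objective += offset
    return rel


# ---------------------------------------------------------------------------
# branch and bound
# ---------------------------------------------------------------------------

def _resolve(formulation) -> tuple[MILPFormulation, np.ndarray, float]:
    """Normalise input: a goal formulation brings its own objective."""
    if isinstance(formulation, GoalFormulation):
        return formulation.milp, formulation.objective, 0.0
    return formulation, formulation.obj_g1, formulation.offset_g1


def branch_and_bound(formulation,
                     options: Optional[BnBOptions] = None,
                     *,
                     objective: Optional[np.ndarray] = None,
                     offset: Optional[float] = None,
                     cutoff: Optional[float] = None,
                     cutoff_plan: Optional[np.ndarray] = None,
                     overrides: Optional[dict] = None) -> SolveResult:
    """Prove the MILP optimum by LP-based branch and bound.

    Parameters
    ----------
    formulation:
        A :class:`MILPFormulation` (objective defaults to G1 unless given)
        or a :class:`GoalFormulation` (uses its goal objective).
    objective, offset:
        Linear objective over the catalog; overrides the default.
    cutoff, cutoff_plan:
        Known feasible objective value (and its solution vector) used as
        the initial incumbent; nodes whose bound cannot beat it are pruned.
    overrides:
        Bound overrides ``{position: (lb, ub)}`` applied at the root —
        used by the improved procedure's fixing pass.
    """
    options = options or BnBOptions()
    milp, default_obj, default_off = _resolve(formulation)
    c = np.asarray(default_obj if objective is None else objective, dtype=float)
    off = (default_off if objective is None else 0.0) if offset is None else offset

    ctx = _LPContext(milp)
    stats = TreeStats()
    int_idx = ctx.int_idx
    self_kind = {int(p): milp.variables[p].kind for p in int_idx}
    tol = options.int_tol

    incumbent_val = math.inf if cutoff is None else float(cutoff)
    incumbent_vec = cutoff_plan

    root_over = dict(overrides) if overrides else {}
    # nodes: (bound_key, tiebreak, depth, overrides)
    counter = itertools.count()
    rel0 = ctx.solve(c, root_over or None)
    if rel0.status == "infeasible":
        return SolveResult("infeasible", math.inf, math.inf, math.inf, None,
                           None, None, None, stats)
    if rel0.status == "unbounded":
        raise RuntimeError("relaxation unbounded: integer bounds missing")
    # node bounds carry the objective offset so they compare directly with
    # incumbent values.  heap key: (bound, -depth, insertion order) — among
    # equal bounds the deepest node is taken first, so plateaus of tied
    # bounds (common when vehicle counts carry no cost in the objective)
    # are dived through instead of swept breadth-first
    heap = [(rel0.objective + off, 0, next(counter), root_over, rel0.values)]
    best_bound = rel0.objective + off

    def frac_of(v: np.ndarray) -> np.ndarray:
        return np.abs(v[int_idx] - np.round(v[int_idx]))

    while heap:
        if options.node_selection == "best-bound":
            bound, negdepth, _, over, values = heapq.heappop(heap)
        else:
            bound, negdepth, _, over, values = heap.pop()
        depth = -negdepth
        stats.nodes += 1
        stats.max_depth = max(stats.max_depth, depth)
        if stats.nodes > options.node_limit:
            gap = _gap(incumbent_val, bound)
            return _finish("node-limit", milp, c, off, incumbent_val,
                           incumbent_vec, bound, gap, stats)
        prune_at = incumbent_val - options.rel_gap * max(1.0, abs(incumbent_val))
        if bound >= prune_at - 1e-9 * max(1.0, abs(incumbent_val)):
            continue

        fracs = frac_of(values)
        if np.all(fracs <= tol):
            val = float(c @ values) + off
            if val < incumbent_val:
                incumbent_val, incumbent_vec = val, values
                stats.log_incumbent(stats.nodes, depth, bound, val)
            continue

        # rounding repair: integer variables with zero objective weight
        # (vehicle counts under the loss objective) keep LP vertices
        # fractional forever, so periodically round the integer part up,
        # re-solve the continuous LP and keep the result as an incumbent
        if stats.nodes % 20 == 1:
            nearest = {}
            safe = {}
            for p in int_idx:
                v = values[p]
                n = float(min(max(round(v), ctx.lb[p]), ctx.ub[p]))
                nearest[p] = (n, n)
                # feasibility-safe direction: binaries gate capacities
                # upward (ceil never cuts a row), general integers sit in
                # supply rows (floor never exceeds one)
                if self_kind[p] == "binary":
                    s = math.ceil(v - tol)
                else:
                    s = math.floor(v + tol)
                s = float(min(max(s, ctx.lb[p]), ctx.ub[p]))
                safe[p] = (s, s)
            for fix in (nearest, safe):
                rep = ctx.solve(c, {**root_over, **fix})
                if rep.status != "optimal":
                    continue
                val = rep.objective + off
                if val < incumbent_val:
                    incumbent_val, incumbent_vec = val, rep.values
                    stats.log_incumbent(stats.nodes, depth, bound, val)
                break
            prune_at = incumbent_val - options.rel_gap * max(
                1.0, abs(incumbent_val))
            if bound >= prune_at - 1e-9 * max(1.0, abs(incumbent_val)):
                continue

        # branch
        if options.branching == "most-fractional":
            dist = np.abs(fracs - 0.5)
            dist[fracs <= tol] = math.inf
            pick = int(int_idx[int(np.argmin(dist))])
        else:
            cands = int_idx[fracs > tol]
            pick = int(cands[0])
        v = values[pick]
        lo0 = over.get(pick, (ctx.lb[pick], ctx.ub[pick]))
        for lo, hi in ((lo0[0], math.floor(v)), (math.ceil(v), lo0[1])):
            child = dict(over)
            child[pick] = (lo, hi)
            if lo > hi:
                continue
            rel = ctx.solve(c, child)
            if rel.status != "optimal":
                continue
            node = (rel.objective + off, -(depth + 1), next(counter), child,
                    rel.values)
            if options.node_selection == "best-bound":
                heapq.heappush(heap, node)
            else:
                heap.append(node)

    if incumbent_vec is None and not math.isinf(incumbent_val):
        # cutoff given without a plan and never improved: re-derive by a
        # final exact solve is impossible here; report value only
        return SolveResult("optimal", incumbent_val, incumbent_val, 0.0,
                           None, None, None, None, stats)
    if incumbent_vec is None:
        return SolveResult("infeasible", math.inf, math.inf, math.inf, None,
                           None, None, None, stats)
    return _finish("optimal", milp, c, off, incumbent_val, incumbent_vec,
                   incumbent_val, 0.0, stats)


def _gap(incumbent: float, bound: float) -> float:
    if math.isinf(incumbent):
        return math.inf
    return abs(incumbent - bound) / max(1.0, abs(incumbent))


def _finish(status, milp, c, off, value, vec, bound, gap, stats) -> SolveResult:
    plan = g1 = g2 = None
    if vec is not None:
        plan = extract_plan(milp, vec, tol=1e-5)
        g1, g2 = milp.g1_of(vec), milp.g2_of(vec)
    return SolveResult(status, value, bound, gap, plan, vec, g1, g2, stats)


# ---------------------------------------------------------------------------
# improved procedure
# ---------------------------------------------------------------------------

def improved_solve(formulation,
                   options: Optional[BnBOptions] = None,
                   *,
                   objective: Optional[np.ndarray] = None,
                   offset: Optional[float] = None) -> SolveResult:
    """Heuristic-fixing warm-started solve; provably the same optimum.

    Six steps: (1) solve the root LP relaxation and keep its solution as a
    warm-start descriptor; (2) fix each DC-opening variable to 0 / 1 when
    its relaxation value falls below ``fix_zero`` / above ``fix_one``;
    (3) solve the restricted MILP; (4) record its optimum as a heuristic
    incumbent; (5) restore the original bounds and reload the descriptor;
    (6) solve the full MILP with the heuristic value as cutoff.  If the
    restricted problem is infeasible the cutoff is simply skipped.
    """
    options = options or BnBOptions()
    milp, default_obj, default_off = _resolve(formulation)
    c = np.asarray(default_obj if objective is None else objective, dtype=float)
    off = (default_off if objective is None else 0.0) if offset is None else offset

    ctx = _LPContext(milp)
    rel = ctx.solve(c)
    if rel.status == "infeasible":
        stats = TreeStats(nodes=1)
        return SolveResult("infeasible", math.inf, math.inf, math.inf, None,
                           None, None, None, stats)

    fixes: dict[int, tuple[float, float]] = {}
    if rel.status == "optimal":
        for pos in milp.z_index:
            zval = rel.values[pos]
            if zval <= options.fix_zero:
                fixes[int(pos)] = (0.0, 0.0)
            elif zval >= options.fix_one:
                fixes[int(pos)] = (1.0, 1.0)

    heur = branch_and_bound(milp, options, objective=c, offset=off,
                            overrides=fixes)
    cutoff = cutoff_plan = None
    heur_obj = heur_stats = None
    if heur.status == "optimal":
        cutoff = heur.objective
        cutoff_plan = heur.vector
        heur_obj, heur_stats = heur.objective, heur.stats
    # bounds restored (fixes dropped), warm-start descriptor reloaded: the
    # LP backend restarts cold, which only costs time, never correctness
    final = branch_and_bound(milp, options, objective=c, offset=off,
                             cutoff=cutoff, cutoff_plan=cutoff_plan)
    final.heuristic_objective = heur_obj
    final.heuristic_stats = heur_stats
    return final


# ---------------------------------------------------------------------------
# exhaustive oracle (tests only)
# ---------------------------------------------------------------------------

def enumerate_oracle(formulation,
                     *,
                     objective: Optional[np.ndarray] = None,
                     offset: Optional[float] = None,
                     cap: int = 1_000_000) -> SolveResult:
    """Ground truth by brute force: enumerate every integer assignment.

    All binary/integer variables are walked over their full bound ranges;
    for each assignment the continuous variables are optimised by the LP
    subroutine.  Refuses instances whose integer grid exceeds ``cap``.
    """
    milp, default_obj, default_off = _resolve(formulation)
    c = np.asarray(default_obj if objective is None else objective, dtype=float)
    off = (default_off if objective is None else 0.0) if offset is None else offset

    ctx = _LPContext(milp)
    int_idx = ctx.int_idx
    ranges = []
    total = 1
    for p in int_idx:
        lo, hi = int(ctx.lb[p]), int(ctx.ub[p])
        ranges.append(range(lo, hi + 1))
        total *= (hi - lo + 1)
        if total > cap:
            raise ValueError(
                f"integer grid exceeds oracle cap ({total} > {cap})")

    stats = TreeStats()
    best_val, best_vec = math.inf, None
    for combo in itertools.product(*ranges):
        stats.nodes += 1
        over = {int(p): (float(v), float(v)) for p, v in zip(int_idx, combo)}
        rel = ctx.solve(c, over)
        if rel.status != "optimal":
            continue
        val = rel.objective + off
        if val < best_val - 1e-12 * max(1.0, abs(val)):
            best_val, best_vec = val, rel.values
            stats.log_incumbent(stats.nodes, 0, val, val)
    if best_vec is None:
        return SolveResult("infeasible", math.inf, math.inf, math.inf, None,
                           None, None, None, stats)
    return _finish("optimal", milp, c, off, best_val, best_vec, best_val,
                   0.0, stats)


# ---------------------------------------------------------------------------
# lexicographic goal driver
# ---------------------------------------------------------------------------

@dataclass
class LexicographicResult:
    """Both stages of the preemptive goal solve.

    ``theta1_plus`` / ``theta2_plus`` are the positive deviations of the
    final plan's objectives from their ideal levels; ``formulation`` is the
    stage-2 goal MILP (deviation-variable positions in its
    ``theta_index``), kept for post-hoc verification.
    """

    stage1: SolveResult
    stage2: SolveResult
    theta1_plus: float
    theta2_plus: float
    plan: AllocationPlan
    total_loss: float
    logistics_cost: float
    formulation: Optional[MILPFormulation] = None


def lexicographic_solve(instance_or_formulation,
                        spec: GoalSpec,
                        options: Optional[BnBOptions] = None,
                        *,
                        solve=None) -> LexicographicResult:
    """Two-stage preemptive goal solve.

    Stage 1 minimises the positive deviation of the loss goal; stage 2 adds
    the constraint holding that deviation at its optimum (within a relative
    tolerance) and minimises the positive deviation of the cost goal.

    ``solve`` selects the underlying MILP solver (defaults to
    :func:`improved_solve`; pass :func:`branch_and_bound` for the plain
    tree search).
    """
    if spec.mode != "lexicographic":
        raise ValueError("lexicographic_solve requires spec.mode='lexicographic'")
    options = options or BnBOptions()
    solve = solve or improved_solve

    if isinstance(instance_or_formulation, Instance):
        base = build_formulation(instance_or_formulation)
    else:
        base = instance_or_formulation
    gf = attach_goal(base, spec)
    milp = gf.milp
    tp1, tp2 = gf.theta_plus

    obj1 = np.zeros(milp.n_vars)
    obj1[tp1] = 1.0
    s1 = solve(milp, options, objective=obj1, offset=0.0)
    if s1.status != "optimal":
        raise RuntimeError(f"stage 1 failed with status {s1.status}")
    t1 = s1.objective

    # tolerance scaled to the goal magnitude: theta1+ sits in an equality
    # with G1 (~1e8 on realistic instances), so its LP value carries
    # round-off of that scale, not unit scale
    stage_tol = 1e-6 * max(1.0, abs(t1), abs(spec.ideals[0]))
    bound_row = Row(((tp1, 1.0),), "<=", t1 + stage_tol, 16, (1, "stage"))
    milp2 = replace(milp, rows=list(milp.rows) + [bound_row])

    obj2 = np.zeros(milp2.n_vars)
    obj2[tp2] = 1.0
    s2 = solve(milp2, options, objective=obj2, offset=0.0)
    if s2.status != "optimal":
        raise RuntimeError(f"stage 2 failed with status {s2.status}")

    # polish: with the stage-2 integer assignment fixed, re-minimise the
    # loss over the continuous variables.  The cost objective depends only
    # on the integer variables, so this removes the stage tolerance's
    # slack from G1 without touching G2.
    vec = s2.vector
    ctx = _LPContext(milp2)
    fixed = {int(p): (float(round(vec[p])), float(round(vec[p])))
             for p in ctx.int_idx}
    rel = ctx.solve(milp2.obj_g1, fixed)
    if rel.status == "optimal":
        vec = rel.values

    plan = extract_plan(milp2, vec, tol=1e-5)
    g1, g2 = milp2.g1_of(vec), milp2.g2_of(vec)
    return LexicographicResult(
        stage1=s1, stage2=s2,
        theta1_plus=max(g1 - spec.ideals[0], 0.0),
        theta2_plus=max(g2 - spec.ideals[1], 0.0),
        plan=plan, total_loss=g1, logistics_cost=g2,
        formulation=milp2,
    )
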