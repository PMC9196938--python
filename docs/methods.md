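# Methods

## Model

The planning network has three layers: reserve centers `h ∈ H` holding
PPE stocks `W_hk` (kg) and vehicle fleets `U_hm`; candidate distribution
centers `i ∈ I` with renting cost `c_i`, vehicle throughput caps `P_im`
and PPE throughput caps `Q_ik`, opened or not by the binary `z_i`; and
affected areas `j ∈ J` with demands `d_jk` (kg). Integer `x_hijm` routes
vehicles of type `m` (capacity `V_m` kg, cost `f_m` yuan/m, speed
`e_m` s/m) along the full path `h → i → j`; continuous `y_hijkm` is the
cargo. A path is admissible only within the coverage radius `C`; each
vehicle travels its path once (no round trips or reuse), which is what
indexing `x` by the whole path encodes.

### Waiting-cost curve

`λ_k(t)` prices a kilogram of PPE `k` that arrives after `t` seconds of
waiting. The implemented family is quadratic-then-flat:

    λ_k(t) = a_k t²  for t ≤ T_k,   λ_k(t) = λ_k^MAX  for t > T_k

with `a_k > 0` (yuan·s⁻²/kg), breakpoint `T_k` (s) and plateau `λ_k^MAX`
(yuan/kg). Construction enforces continuity at the breakpoint to a
relative 1e-4 (the case curve `t²/7315661` with `T = 604 800` s and
plateau 50 000 meets it at 49 999.9986). The quadratic shape encodes an
accelerating erosion of victims' bearing capacity; the plateau is the
loss of never being served. Any convex-increasing-then-flat curve fits
the model's logic; the quadratic family is fixed because it is fully
determined by three interpretable parameters, and per-PPE curves are
allowed (the case study shares one curve across both PPE types, so that
is the default).

Units are canonical throughout: kg, m, s, yuan. `λ` is yuan per kg —
demand tables are in mass, so "one unit" of PPE is one kilogram; this is
also the only reading under which the case's zero-delivery loss comes out
at 2.8222e10 exactly.

### Loss function and objectives

`L_jk = (d_jk − Σ y) λ_k^MAX + Σ y · λ_k(e_m D_hij)` charges unmet
demand as infinite delay and deliveries at their route time. Since
`λ ≤ λ^MAX`, delivering more (feasibly) never increases the loss; the
single expression therefore trades fairness (unmet demand anywhere is
expensive) against efficiency (slow routes are expensive) without a
second criterion. `G1 = Σ L_jk w_k` weights PPE types by importance;
`G2` adds DC rents and distance-proportional transport cost.

### MILP and goal transformation

Once distances are fixed, `λ_k(e_m D_hij)` are constants and both
objectives are linear. The formulation keeps the coverage rule as a
variable bound (`x = 0` where `D > C`) rather than a big-M row — a
tighter relaxation with fewer rows. Vehicle-count bounds are
`min(U_hm, P_im)` per path, which also makes exhaustive enumeration and
branching finite. Delivery bounds are
`min(d_jk, W_hk, Q_ik, V_m · x_ub)`.

The goal program adds `θ_n± ≥ 0` and `G_n + θ_n⁻ − θ_n⁺ = R_n` against
ideal levels `R_n`, penalising only positive deviations. The
complementarity `θ_n⁻ θ_n⁺ = 0` is *not* imposed (it would be
nonlinear): with both deviations in one equality and only `θ⁺`
penalised, an optimal basic solution never needs both positive; the
property is asserted after solving. The preemptive priority
`λ_1 ≫ λ_2` is realised lexicographically — minimise `θ_1⁺`, bound it at
its optimum, minimise `θ_2⁺` — because no finite weights are part of the
problem statement; a weighted mode (default ratio 1e6, refusing ratios
below 1e3) exists for comparison.

## Solver

The solver is an LP-based branch and bound: HiGHS (via
`scipy.optimize.linprog`) solves each relaxation; a fractional integer
variable is branched floor/ceil; nodes are pruned against the incumbent.
The LP backend is an abstract contract (deterministic optimal basic
solution); warm-start information is carried as the primal point and
degrades to a cold start, which costs time but never correctness.

Design choices that matter:

* **Node selection** is best-bound with ties broken deepest-first.
  Vehicle counts carry zero cost under the loss objective, so large
  plateaus of tied bounds are common; a FIFO tie-break sweeps them
  breadth-first and stalls, while the dive reaches integral leaves
  quickly. Depth-first selection is available as an option.
* **Branching** picks the most fractional variable (closest to .5), ties
  to the lowest catalog index — reproducible and standard.
* **Rounding repair.** Every 20 nodes the integer part of the node's LP
  solution is rounded and re-optimised over the continuous variables;
  nearest rounding is tried first, then a feasibility-safe direction
  (binaries up — they only gate capacities; general integers down — they
  sit in supply rows). Every repaired point is LP-verified feasible, so
  this only supplies incumbents, never replaces the proof. Without it,
  zero-cost integer variables keep every LP vertex fractional and no
  incumbent is ever found.
* **Improved procedure** (heuristic-then-proven): solve the root
  relaxation and keep its solution as a warm-start descriptor; fix each
  DC variable whose relaxation value is ≤ 0.01 to 0 or ≥ 0.9 to 1
  (thresholds configurable — the fixing rule is inherently a
  quantification choice); solve the restricted MILP to get a heuristic
  incumbent; restore bounds and re-solve the full problem with that
  incumbent as cutoff. The restricted stage runs to optimality of the
  restricted problem; if it is infeasible the cutoff is skipped. The
  final answer is always the same proven optimum as the plain search.
* **Exhaustive oracle** (tests only): enumerate every integer assignment
  within bounds (refusing grids beyond a cap), LP-optimise the
  continuous part, return the true optimum. This is the ground truth the
  tree searches are checked against.

The lexicographic driver bounds stage 2 by
`θ_1⁺ ≤ t_1 + 1e-6 · max(1, |t_1|, |R_1|)`: the deviation variable sits
in an equality with `G1` (~1e8 on realistic instances) and inherits LP
round-off of that scale, so a unit-scale tolerance makes stage 2
spuriously infeasible. A polish step then refixes the stage-2 integer
assignment and re-minimises `G1` over the continuous variables — `G2`
depends only on the integers, so this removes the tolerance slack from
the reported loss and restores `θ_1⁺ = 0` exactly whenever `R_1` is
attainable.

Tolerances: integrality 1e-6 (extraction rounds within it and rejects
beyond), pruning margin 1e-9 relative to the incumbent, optimality gap 0
by default. Identical inputs, options and seed give identical results
including tree statistics.

## Analysis

Ideal levels are the single-objective minima; `R_2 = 0` always, via the
empty plan. Worst levels: the worst loss has the closed form
`Σ d_jk λ_k^MAX w_k` (the zero-delivery plan maximises `G1` because
`λ ≤ λ^MAX`), optionally cross-checked by an explicit maximisation solve;
the worst cost is a genuine maximisation MILP. Percentage deviation
`(current − lower)/(upper − lower)` uses these levels as the scale, the
convention under which the case study's printed 86.17% is reproduced
from its printed triple. The Pareto trace relaxes `R_1` by ascending
multipliers and records the minimal cost per budget (non-increasing by
construction, asserted on every instance); the sensitivity scan re-solves
the same grid with the improved and the plain search and reports their
relative objective difference, node counts, and wall-clock times —
runtimes are recorded but never asserted, they are hardware facts.

## Synthetic data

The generator places reserves, DCs and areas uniformly in a planar
region (default 80 km square), sets path distances to a road factor
(default 1.3) times the two-leg Euclidean length, and re-samples layouts
until every area is reachable within the coverage radius (default
150 km) — the packaged case study ships with such a matrix because its
real path distances are not published, and the synthetic matrix is
always labelled as such. Demands default to 20–350 t per area-PPE cell,
fleets to 2–30 vehicles per reserve and type, capacities 5–20 t,
rents 0.5–1.0 M yuan — the magnitudes of the case tables. Total supply
per PPE type is tied to total demand by the shortage ratio (default 0.8,
i.e. a 20% shortfall), which is the regime the loss function exists for:
with `ρ < 1` every loss-optimal plan still leaves unmet demand.

What the generator does not emulate: real road networks (distances are
scaled Euclidean, so triangle-inequality violations and detours are
absent), demand correlation between neighbouring areas, heterogeneous
curves per PPE type, and any temporal dynamics. Tests passing on
synthetic instances therefore certify the optimisation machinery — not
the realism of any particular geography.

## Problem sizes and limitations

Correctness tests run the three solvers against each other on twenty
seeded instances with at most 2 reserves/DCs/areas, one PPE and one
vehicle type, and fleets of 1–2 vehicles — small enough that exhaustive
enumeration is the independent ground truth and the whole suite stays in
tens of seconds. The case-scale loss minimisation (90 integer variables)
has an ~8% root integrality gap that a plain branch and bound — no
cutting planes, no presolve, both deliberately out of scope — cannot
close at desk scale: the published solve relied on a commercial solver's
internals. The solver therefore reports an honest `node-limit` status
with incumbent, bound and gap (the incumbent reaches the true optimum,
verified against an independent MILP backend, within a few thousand
nodes), and `ideal_levels(strict=False)` / `ppealloc bounds
--node-limit` expose exactly that. All distance-independent case
quantities are exact regardless.

Other known limitations: demands are deterministic and single-period;
vehicles run one path each; the curve family is fixed (though any
monotone curve object with the same three-parameter interface slots in);
and LP degeneracy means alternative optimal *plans* may differ across
platforms even though objective values, being proven optima, do not.
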