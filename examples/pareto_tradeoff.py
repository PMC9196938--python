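"""Tracing the loss/cost tradeoff (Pareto front) on a small instance.

The ideal loss level R1 is relaxed by increasing multipliers; for each
budget the goal program returns the cheapest plan whose loss stays within
it.  The minimal cost can only fall as the budget grows — each row is one
point of the Pareto front.
"""

from ppealloc import pareto_trace, tradeoff_table
from ppealloc.data_io import SyntheticConfig, synthetic_instance

config = SyntheticConfig(n_reserves=2, n_dcs=2, n_areas=2, n_ppes=1,
                         n_vehicles=1, vehicle_supply_range=(1, 3),
                         demand_range=(20000.0, 60000.0), seed=11)
instance = synthetic_instance(config)

points = pareto_trace(instance, [1.0, 1.5, 2.0, 5.0, 50.0])
table = tradeoff_table(points)
print(table.to_string(index=False,
                      float_format=lambda v: f"{v:.6g}"))
print("\nmin_G2 is non-increasing: accepting more waiting loss can only "
      "make the logistics plan cheaper (down to 0: do nothing).")
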