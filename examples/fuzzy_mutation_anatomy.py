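"""Anatomy of the centroid-based fuzzy mutation probability.

Shows how the two membership degrees combine: crowding (distance to the
population centroid) and stagnation (generations without improvement),
plus the quadratically decaying step bound.
"""

import numpy as np

from mhgs import (FuzzyMutationParams, SearchSpace, distance_contribution,
                  history_contribution, mutation_probability, mutation_step)

params = FuzzyMutationParams()
space = SearchSpace(10, -100.0, 100.0)
centroid = np.zeros(10)

print("crowding degree P_d = 1/(1 + dist/diagonal):")
for offset in (0.0, 50.0, 200.0):
    position = np.full(10, offset / np.sqrt(10))
    p_d = distance_contribution(position, centroid, space, params)
    print(f"  agent {offset:6.1f} units from centroid -> P_d = {p_d:.3f}")

print("stagnation degree P_c = 0.5 + 0.5*tanh(unchanged/4 - 5):")
for unchanged in (0, 10, 20, 40):
    print(f"  {unchanged:3d} stagnant generations -> "
          f"P_c = {history_contribution(unchanged, params):.5f}")

p_l = mutation_probability(0.8, 0.5, params)
print(f"combined: P_d=0.8, P_c=0.5 -> P_l = 0.6*0.8 + 0.4*0.5 = {p_l:.2f}")

print("step bound dq = 0.5*range*(1 - progress)^2 for range 200:")
for frac in (0.0, 0.5, 0.9, 1.0):
    dq = mutation_step(200.0, int(frac * 1000), 1000)
    print(f"  {frac:4.0%} of budget spent -> dq = {float(dq):.2f}")
print("Crowded agents under a stalled incumbent are mutated most, with "
      "perturbations that anneal to zero over the run.")
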