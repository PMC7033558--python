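"""Recover generating parameters by grid search on group-level means.

Group-level accuracy and mean correct RT are simulated at a known
threshold and drift, then a 3x3 grid is searched for the parameter pair
whose simulated means come closest (weighted squared error).
"""

import numpy as np

from handrace import congenital_architecture, fit_parameters, simulate_group

truth = congenital_architecture(threshold=0.138, drift_rate=0.10)
target = simulate_group(truth, 10_000, np.random.default_rng(1))
print("target means (simulated at threshold=0.138, drift=0.10):")
for hand in ("intact", "missing"):
    print(f"  {hand:8s}: accuracy {target.accuracy[hand]:.3f}, "
          f"RT {target.mean_correct_rt[hand]:.3f} s")

grid = {"threshold": [0.118, 0.138, 0.158], "drift_rate": [0.08, 0.10, 0.12]}
res = fit_parameters(target, grid, n_per_hand=3_000, seed=2)

print("\nloss surface (threshold, drift_rate -> loss):")
for point, loss in res.trace:
    marker = "  <- best" if point == res.best_params else ""
    print(f"  {point['threshold']:.3f}, {point['drift_rate']:.2f}: {loss:.5f}{marker}")
print(f"\nrecovered: {res.best_params} (truth: threshold=0.138, drift_rate=0.10)")
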