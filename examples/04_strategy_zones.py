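"""Partition the theta-phi plane into four moral-strategy zones.

Simulates Trustee behavior at 101 x 101 evenly spaced parameter points,
clusters the 10,201 behavior vectors hierarchically, names the four
clusters by their nearest strategy prototype, and assigns a few example
parameter points to zones. The zone partition depends only on model
simulations, never on a participant sample.
"""

from hmtg import MSParams, assign_strategy, cluster_grid, simulate_grid

grid = simulate_grid()
zones = cluster_grid(grid)

print(f"grid points: {grid.n_points}")
print("zone share of parameter-space area:")
for label in ("IA", "GA", "MO", "GR"):
    share = (zones.labels == label).mean()
    print(f"  {label}: {share:5.1%}")

print("\nexample assignments:")
for theta, phi in [(0.02, 0.1), (0.02, -0.1), (0.02, 0.0), (0.45, 0.0), (0.2, 0.05)]:
    label = assign_strategy(MSParams(theta, phi), zones)
    print(f"  (theta={theta:.2f}, phi={phi:+.2f}) -> {label}")
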