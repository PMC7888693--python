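"""Generate a seeded synthetic study region and inspect its layers.

The monocentric preset emulates the structure such analyses run on: a
100 m population grid with an urban core, clustered practice sites with
small integer capacities, and a car road lattice with one-way streets.
"""

import numpy as np

from fcaccess import make_scenario, preset

cfg = preset("monocentric", seed=42)
demand, supply, net = make_scenario(cfg)

print(f"region: {cfg.width_m/1000:.0f} x {cfg.height_m/1000:.0f} km, "
      f"{cfg.cell_size_m:.0f} m cells")
print(f"demand: {len(demand)} populated cells, "
      f"{demand.total_population:.0f} inhabitants")
print(f"supply: {len(supply)} sites, {supply.total_capacity:.0f} practitioners")
print(f"network: {net.n_nodes} nodes, {len(net.edges)} directed edges")

pairs = set(zip(net.edges["from_node"], net.edges["to_node"]))
oneway = sum((v, u) not in pairs for u, v in pairs)
print(f"one-way street segments: {oneway}")

r = np.hypot(demand.table["x"] - cfg.width_m / 2, demand.table["y"] - cfg.height_m / 2)
core = demand.table.loc[r < 2000, "pop"].mean()
rim = demand.table.loc[r > 5000, "pop"].mean()
print(f"mean inhabitants/cell: {core:.1f} in the core vs {rim:.1f} at the rim")
# the density gradient is what later produces the urban-rural access contrast
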