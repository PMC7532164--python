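"""Merge trajectories into a disease trajectory network and export it.

The network unions all adjacent pairs of all trajectories: shared codes
become shared nodes, so the multimorbidity spectrum appears as one
directed graph.  Exports apply the privacy rule (no node, edge or
trajectory below five patients) and round-trip through Cytoscape JSON.
"""

from pathlib import Path

import trajmine as tm

config = tm.SimulationConfig(n_patients=50_000)
registry = tm.simulate_registry(config, seed=5)
result = tm.mine_directional_pairs(registry, tm.ThresholdConfig(n_controls=100), seed=5)
trajectories = [
    tm.trajectory_summary(registry, t)
    for t in tm.build_trajectories(result.directional, registry, min_followers=20)
]

network = tm.merge_network(trajectories, registry, provenance={"seed": 5})
print(f"network: {network.graph.number_of_nodes()} nodes, "
      f"{network.graph.number_of_edges()} edges")

selection = tm.neighbourhood(network, "I50", mode="both")
print(f"I50 neighbourhood: {sorted(selection.edges)}")

strong = tm.apply_filters(network, rr_range=(10.0, float("inf")))
print(f"edges with RR >= 10: {sorted(strong.graph.edges)}")

out = Path("scratch")
out.mkdir(exist_ok=True)
tm.export_cyjs(network, out / "network.cyjs", min_patients=5)
tm.export_edges_csv(network, out / "edges.csv", min_patients=5)
reloaded = tm.read_cyjs(out / "network.cyjs")
print(f"re-imported {reloaded.graph.number_of_edges()} edges from "
      f"{out/'network.cyjs'} (counts below 5 suppressed)")
# The .cyjs file opens directly in the Cytoscape desktop application;
# the CSV holds one edge per row with RR and both P-values.
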