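"""Extract and prune a seed-induced protein-interaction subnetwork.

Seeds (e.g. low-TO genes mapped to proteins) are expanded to their connected
components, then nonseed proteins are pruned in three phases operating on
the seed-pair geodesics, keeping the fewest nonseeds that preserve every
originally connected seed pair.
"""

import topodiff as td

graph, seeds = td.simulate_ppi(n_nodes=150, edge_prob=0.03, n_seeds=12, seed=5)
print(f"full PPI: {graph.number_of_nodes()} proteins, "
      f"{graph.number_of_edges()} interactions, {len(seeds)} seeds")

expanded = td.seed_expansion(graph, seeds)
print(f"seed-expanded network: {expanded.number_of_nodes()} proteins")

pruned = td.prune(expanded, seeds)
nonseeds = pruned.retained_nodes - pruned.seeds
print(f"pruned network: {len(pruned.retained_nodes)} proteins "
      f"({len(pruned.seeds)} seeds + {len(nonseeds)} connector nonseeds), "
      f"{len(pruned.retained_edges)} interactions")
# The surviving nonseeds are the high-traffic connectors: proteins that lie
# on the seed-richest, most frequently used geodesics between seed pairs.
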