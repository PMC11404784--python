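"""Seed-anchored PPI networks at zero, first and minimum order.

Simulates a scale-free interactome and a DEG table, uses the significant
DEGs as seed nodes, builds networks at all three orders, scores hubs by
betweenness centrality, and tests the first-order node set for enriched
pathways.
"""

import warnings

from pathkit import (
    PlantedSet,
    SimulationConfig,
    build_ppi_network,
    enrich_network,
    score_hubs,
    select_degs,
    simulate_deg_table,
    simulate_interactions,
    simulate_pathway_db,
)

cfg = SimulationConfig(
    seed=3,
    n_genes=800,
    n_pathways=10,
    pathway_size_range=(20, 40),
    planted_sets=(PlantedSet("P001", "up", 3.0, 0.9),),
)
db = simulate_pathway_db(cfg)
table = simulate_deg_table(cfg, db, "treated_vs_control")
interactome = simulate_interactions(n_nodes=800, edges_per_node=2, seed=3)

up, down = select_degs(table)
seeds = up | down
print(f"{len(seeds)} significant DEGs used as seed nodes")

for order in ("zero", "first", "minimum"):
    net = build_ppi_network(seeds, interactome, order=order, deg_table=table)
    print(
        f"{order:>7} order: {len(net):4d} nodes, {len(net.edges):4d} edges "
        f"({net.seed_count} seeds kept, {net.dropped_seed_count} absent from "
        f"the interactome)"
    )

net = build_ppi_network(seeds, interactome, order="first", deg_table=table)
score_hubs(net, measure="betweenness", top_n=3)
hubs = sorted(
    (v for v in net.nodes if net.graph.nodes[v]["is_hub"]),
    key=lambda v: -net.graph.nodes[v]["hub_score"],
)
print("\ntop hubs by betweenness centrality:")
for v in hubs:
    a = net.graph.nodes[v]
    print(f"  {v}: score={a['hub_score']:.3f}, degree={a['degree']}, role={a['role']}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = enrich_network(net, db, method="ora")
best = res.sort_values("p_value").iloc[0]
print(
    f"\nnetwork enrichment: best pathway {best['set_id']} "
    f"(k={best['k']}/{best['K']}, p_adj={best['p_adjusted']:.2e}) — "
    "hub-heavy networks seeded by planted DEGs recover the planted pathway."
)
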