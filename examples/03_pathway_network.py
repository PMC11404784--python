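"""A pathway-crosstalk network ("pathnet") from enrichment results.

Overlapping pathways are linked when their Jaccard distance falls below a
threshold; the final network keeps the significantly enriched pathways
(filled nodes) plus their direct neighbours (hollow candidate nodes).
"""

import warnings

from pathkit import (
    PlantedSet,
    SimulationConfig,
    build_pathnet,
    create_foundation,
    pathway_distance_matrix,
    pathway_enrichment,
    simulate_deg_table,
    simulate_pathway_db,
)
from pathkit.viz import plot_network

cfg = SimulationConfig(
    seed=11,
    n_genes=400,
    n_pathways=10,
    pathway_size_range=(10, 30),
    overlap_fraction=0.5,   # heavy sharing so crosstalk edges exist
    planted_sets=(PlantedSet("P001", "up", 3.0, 0.9),),
)
db = simulate_pathway_db(cfg)
table = simulate_deg_table(cfg, db, "treated_vs_control")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    results = pathway_enrichment(table, db, method="ora")

dm = pathway_distance_matrix(db, metric="jaccard")
print("pairwise Jaccard distances (1 = no shared genes):")
print(dm.to_frame().round(2).iloc[:4, :4])

# These simulated sets overlap far less than curated hierarchies do, so a
# looser threshold than the curated-database default is used here.
foundation = create_foundation(dm, threshold=0.995)
print(f"\nfoundation: {foundation.number_of_nodes()} pathways, "
      f"{foundation.number_of_edges()} crosstalk edges")

net = build_pathnet(foundation, results, "treated_vs_control")
enriched = [v for v in net.nodes if net.graph.nodes[v]["enriched"]]
print(f"pathnet: {len(net)} nodes ({len(enriched)} enriched, "
      f"{len(net) - len(enriched)} candidate neighbours), "
      f"{net.graph.number_of_edges()} edges")
for v in enriched:
    a = net.graph.nodes[v]
    print(f"  enriched: {v} direction={a['direction']} p_adj={a['p_adjusted']:.2e}")

plot = plot_network(net, layout_seed=0, out="example_output/pathnet.png")
print(f"\nstatic figure written to {plot.figure_path}")
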