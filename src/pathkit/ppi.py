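"""Protein-protein interaction networks grown from differential-expression seeds.

A network is built from a set of seed genes and an undirected interaction
table at one of three orders:

* **zero** — the subgraph induced on the seeds alone;
* **first** — induced on the seeds plus every direct neighbour of a seed
  (an *interactor*), including interactor-interactor edges;
* **minimum** — the first-order network with every interactor that has
  exactly one edge to a seed removed, then re-induced.

Isolated nodes (degree 0 after induction or trimming) are removed and
counted.  Nodes carry their role (seed/interactor), optional fold-change
and adjusted-p attributes joined from a DEG table, a degree, and hub
annotations from :func:`score_hubs`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .io import DEGTable, GeneSetDatabase, InteractionTable

__all__ = [
    "PPINetwork",
    "build_ppi_network",
    "score_hubs",
    "enrich_network",
    "extract_subnetwork",
]

_HUB_MEASURES = ("betweenness", "degree", "pagerank")


@dataclass
class PPINetwork:
    """An undirected gene network plus build provenance."""

    graph: nx.Graph
    order: Literal["zero", "first", "minimum"]
    seed_count: int = 0
    dropped_seed_count: int = 0
    dropped_seeds: tuple[str, ...] = ()
    isolated_removed: int = 0
    hub_measure: str | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def node_table(self) -> pd.DataFrame:
        rows = []
        for g, attrs in sorted(self.graph.nodes(data=True)):
            rows.append({"gene_id": g, **attrs})
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["gene_a", "gene_b"])

    # -- serialisation ------------------------------------------------------

    def to_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        g.graph.update(
            order=self.order,
            seed_count=self.seed_count,
            dropped_seed_count=self.dropped_seed_count,
        )
        # GraphML cannot carry None values
        for _, attrs in g.nodes(data=True):
            for key in [k for k, v in attrs.items() if v is None]:
                del attrs[key]
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path: str | Path) -> "PPINetwork":
        g = nx.read_graphml(path)
        meta = g.graph
        return cls(
            graph=nx.Graph(g),
            order=meta.get("order", "zero"),
            seed_count=int(meta.get("seed_count", 0)),
            dropped_seed_count=int(meta.get("dropped_seed_count", 0)),
        )

    def to_tsv(self, node_path: str | Path, edge_path: str | Path) -> None:
        self.node_table().to_csv(node_path, sep="\t", index=False, lineterminator="\n")
        self.edge_table().to_csv(edge_path, sep="\t", index=False, lineterminator="\n")


def build_ppi_network(
    seeds: Iterable[str],
    interactions: InteractionTable,
    order: Literal["zero", "first", "minimum"] = "zero",
    deg_table: DEGTable | None = None,
) -> PPINetwork:
    """Build a seed-anchored network at the requested order.

    Seeds absent from the interaction data are dropped (reported on the
    result); it is an error for *all* seeds to be absent.  When a DEG table
    is supplied, each node picks up ``log2_fc`` and ``p_adjusted``
    attributes where the gene is measured.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValidationError("seed list is empty")
    if len(interactions) == 0:
        raise ValidationError("interaction table is empty")
    if order not in ("zero", "first", "minimum"):
        raise ValidationError(f"unknown network order {order!r}")

    full = nx.Graph()
    full.add_edges_from(interactions.edges)
    present = seeds & set(full.nodes)
    dropped = tuple(sorted(seeds - present))
    if not present:
        raise ValidationError("no seed gene appears in the interaction data")

    if order == "zero":
        keep = present
    else:
        neighbours = {nb for s in present for nb in full.neighbors(s)}
        keep = present | neighbours
        if order == "minimum":
            sub = full.subgraph(keep)
            trimmed = {
                v for v in keep - present
                if sum(1 for nb in sub.neighbors(v) if nb in present) == 1
            }
            keep = keep - trimmed

    sub = nx.Graph(full.subgraph(keep))
    isolated = [v for v in sub.nodes if sub.degree(v) == 0]
    sub.remove_nodes_from(isolated)

    de_attrs: dict[str, dict] = {}
    if deg_table is not None:
        df = deg_table.data
        for row in df.itertuples():
            de_attrs[row.gene_id] = {
                "log2_fc": float(row.log2_fc),
                "p_adjusted": float(row.p_adjusted),
            }
    for v in sub.nodes:
        sub.nodes[v]["role"] = "seed" if v in present else "interactor"
        sub.nodes[v]["degree"] = sub.degree(v)
        sub.nodes[v]["hub_score"] = 0.0
        sub.nodes[v]["is_hub"] = False
        attrs = de_attrs.get(v)
        if attrs:
            sub.nodes[v].update(attrs)

    return PPINetwork(
        graph=sub,
        order=order,
        seed_count=len(present),
        dropped_seed_count=len(dropped),
        dropped_seeds=dropped,
        isolated_removed=len(isolated),
    )


def score_hubs(
    network: PPINetwork,
    measure: Literal["betweenness", "degree", "pagerank"] = "betweenness",
    top_n: int | None = None,
) -> PPINetwork:
    """Score every node and flag the top ``top_n`` as hubs (in place).

    Default measure is betweenness centrality — hubs are the nodes binding
    the network together.  ``top_n`` defaults to max(2, 2% of nodes).  Ties
    are broken by (score desc, degree desc, gene_id asc).
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot score hubs on an empty network")
    if measure not in _HUB_MEASURES:
        raise ValidationError(f"unknown hub measure {measure!r}; use {_HUB_MEASURES}")
    if top_n is None:
        top_n = max(2, round(0.02 * g.number_of_nodes()))
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")

    if measure == "betweenness":
        scores = nx.betweenness_centrality(g, normalized=True)
    elif measure == "degree":
        scores = {v: float(d) for v, d in g.degree()}
    else:
        scores = nx.pagerank(g)

    if top_n >= g.number_of_nodes():
        warnings.warn(
            f"top_n={top_n} >= node count {g.number_of_nodes()}; "
            "flagging every node as a hub",
            stacklevel=2,
        )
    ranked = sorted(
        g.nodes, key=lambda v: (-scores[v], -g.degree(v), v)
    )
    hubs = set(ranked[:top_n])
    for v in g.nodes:
        g.nodes[v]["hub_score"] = float(scores[v])
        g.nodes[v]["is_hub"] = v in hubs
    network.hub_measure = measure
    return network


def enrich_network(
    network: PPINetwork,
    db: GeneSetDatabase,
    method: Literal["ora", "gene_pair_ora"] = "ora",
    universe: Literal["database", "network"] = "database",
    min_set_size: int = 1,
    max_set_size: int = 10**9,
) -> pd.DataFrame:
    """Test a network's node set for enriched pathways.

    Delegates to the enrichment module with the node gene set as the query
    and direction ``all``.  GSEA is rejected — a node set carries no
    ranking.  The default universe is every database gene.
    """
    from . import enrichment as enr

    if method == "gsea":  # type: ignore[comparison-overlap]
        raise ValidationError("GSEA needs a ranked list; a network node set has none")
    if len(network) == 0:
        raise ValidationError("network is empty")
    query = network.nodes
    uni = db.all_genes() if universe == "database" else db.all_genes() | query
    rows = []
    if method == "ora":
        filtered = db.filter_size(min_set_size, max_set_size)
        q = query & uni
        for s in filtered:
            members = s.genes & uni
            if not members or not q:
                continue
            res = enr.ora_hypergeometric(q, members, uni)
            rows.append({
                "comparison": "network", "direction": "all",
                "set_id": s.set_id, "set_name": s.set_name,
                "category": s.category, "method": "ora",
                "k": res.k, "K": res.K, "n": res.n, "N": res.N,
                "statistic": res.enrichment_ratio, "p_value": res.p_value,
                "hit_genes": ";".join(res.hit_genes),
            })
    else:
        index = enr.build_gene_pair_signatures(db, min_set_size, max_set_size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = enr.ora_gene_pairs(query, index)
        for r in df.itertuples():
            rows.append({
                "comparison": "network", "direction": "all",
                "set_id": r.set_id, "set_name": index.set_names[r.set_id],
                "category": index.set_categories[r.set_id],
                "method": "gene_pair_ora",
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "statistic": r.enrichment_ratio, "p_value": r.p_value,
                "hit_genes": ";".join(r.hit_genes),
            })
    result = pd.DataFrame(
        rows, columns=[c for c in enr.ENRICHMENT_COLUMNS if c != "p_adjusted"]
    )
    result["p_adjusted"] = enr.adjust_bh(result["p_value"].tolist()) if len(result) else []
    return result[enr.ENRICHMENT_COLUMNS]


def extract_subnetwork(
    network: PPINetwork,
    pathway_genes: Iterable[str],
    pathway_name: str = "pathway",
) -> PPINetwork:
    """Induce the network on the genes of one pathway.

    Roles and DE attributes are preserved; isolated nodes are removed with
    their count reported.  An empty intersection is an error.
    """
    members = set(pathway_genes)
    if not members:
        raise ValidationError("pathway gene set is empty")
    keep = network.nodes & members
    if not keep:
        raise ValidationError(
            f"no network node belongs to pathway {pathway_name!r}"
        )
    sub = nx.Graph(network.graph.subgraph(keep))
    isolated = [v for v in sub.nodes if sub.degree(v) == 0]
    sub.remove_nodes_from(isolated)
    if sub.number_of_nodes() == 0:
        warnings.warn(
            f"pathway {pathway_name!r} intersects the network only in "
            "isolated nodes; result is empty",
            stacklevel=2,
        )
    for v in sub.nodes:
        sub.nodes[v]["degree"] = sub.degree(v)
    return PPINetwork(
        graph=sub,
        order=network.order,
        seed_count=sum(1 for v in sub.nodes if sub.nodes[v].get("role") == "seed"),
        isolated_removed=len(isolated),
        hub_measure=network.hub_measure,
    )
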