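"""Pathway-crosstalk networks ("pathnets").

Pathways that share member genes are connected: a distance matrix over the
database (Jaccard by default), a thresholded *foundation* graph over all
pathways, and finally a network restricted to significantly enriched
pathways plus their direct foundation neighbours (drawn hollow — candidate
crosstalk partners that did not themselves reach significance).

The Jaccard distance between sets A and B is 1 - |A∩B| / |A∪B|; Euclidean
and Manhattan distances act on unnormalised binary membership vectors over
the union of database genes.  An edge is drawn when distance is *strictly
below* the threshold (default 0.8 for Jaccard; the other metrics are
unbounded, so their thresholds must be user-supplied).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .io import GeneSetDatabase

__all__ = [
    "DEFAULT_METRIC",
    "DEFAULT_JACCARD_THRESHOLD",
    "PathwayDistanceMatrix",
    "PathwayNetwork",
    "pathway_distance_matrix",
    "create_foundation",
    "build_pathnet",
]

DEFAULT_METRIC = "jaccard"
DEFAULT_JACCARD_THRESHOLD = 0.8

_METRICS = {"jaccard": "jaccard", "euclidean": "euclidean", "manhattan": "cityblock"}


@dataclass
class PathwayDistanceMatrix:
    set_ids: list[str]
    distances: np.ndarray          # symmetric, zero diagonal
    shared_genes: np.ndarray       # integer co-membership counts
    metric: str

    def distance(self, a: str, b: str) -> float:
        i, j = self.set_ids.index(a), self.set_ids.index(b)
        return float(self.distances[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.set_ids, columns=self.set_ids)


@dataclass
class PathwayNetwork:
    """Enriched pathways and their crosstalk neighbours.

    Node attributes: ``set_name``, ``category``, ``enriched`` (flag),
    ``p_adjusted`` and ``direction`` for enriched nodes.  Edge attributes:
    ``distance`` (< the construction threshold) and ``shared_gene_count``.
    """

    graph: nx.Graph
    comparison: str
    threshold: float
    metric: str

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def node_table(self) -> pd.DataFrame:
        rows = [{"set_id": v, **attrs} for v, attrs in sorted(self.graph.nodes(data=True))]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"set_a": min(a, b), "set_b": max(a, b), **attrs}
            for a, b, attrs in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows).sort_values(
            ["set_a", "set_b"], ignore_index=True
        ) if rows else pd.DataFrame(
            columns=["set_a", "set_b", "distance", "shared_gene_count"]
        )


def pathway_distance_matrix(
    db: GeneSetDatabase,
    metric: Literal["jaccard", "euclidean", "manhattan"] = DEFAULT_METRIC,
) -> PathwayDistanceMatrix:
    """Pairwise inter-pathway distances from gene membership."""
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}; use {sorted(_METRICS)}")
    if len(db) < 2:
        raise ValidationError("need at least 2 gene sets for a distance matrix")
    genes = sorted(db.all_genes())
    idx = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(db), len(genes)), dtype=bool)
    ids = []
    for r, s in enumerate(db):
        ids.append(s.set_id)
        for g in s.genes:
            mat[r, idx[g]] = True
    dist = squareform(pdist(mat, metric=_METRICS[metric]))
    shared = (mat.astype(np.int64) @ mat.astype(np.int64).T)
    np.fill_diagonal(dist, 0.0)
    return PathwayDistanceMatrix(
        set_ids=ids, distances=dist, shared_genes=shared, metric=metric
    )


def create_foundation(
    dm: PathwayDistanceMatrix,
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
) -> nx.Graph:
    """Threshold the distance matrix into a graph over all pathways.

    An edge joins two distinct pathways iff their distance is strictly
    below ``threshold``; isolated pathways are kept as nodes at this stage.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    g = nx.Graph(metric=dm.metric, threshold=float(threshold))
    g.add_nodes_from(dm.set_ids)
    n = len(dm.set_ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(dm.distances[i, j])
            if d < threshold:
                g.add_edge(
                    dm.set_ids[i], dm.set_ids[j],
                    distance=d, shared_gene_count=int(dm.shared_genes[i, j]),
                )
    return g


def build_pathnet(
    foundation: nx.Graph,
    results: pd.DataFrame,
    comparison: str,
    p_cutoff: float = 0.05,
) -> PathwayNetwork:
    """Restrict the foundation to enriched pathways and their neighbours.

    Nodes are the pathways significant for ``comparison`` (adjusted p
    strictly below ``p_cutoff``) plus every foundation neighbour of one;
    non-significant neighbours are marked ``enriched=False``.  A pathway
    significant in both directions carries the direction with the lower p.
    """
    if comparison not in set(results["comparison"]):
        raise ValidationError(f"comparison {comparison!r} not present in results")
    sub = results[results["comparison"] == comparison]
    sig = sub[sub["p_adjusted"] < p_cutoff]
    if sig.empty:
        raise ValidationError(
            f"no significant pathways for comparison {comparison!r} "
            f"at p_adjusted < {p_cutoff}"
        )
    # per pathway, keep the row with the lowest adjusted p
    best = sig.sort_values(["p_adjusted", "p_value"]).drop_duplicates("set_id")
    sig_ids = [sid for sid in best["set_id"] if sid in foundation]
    keep = set(sig_ids)
    for sid in sig_ids:
        keep |= set(foundation.neighbors(sid))

    g = nx.Graph(foundation.subgraph(keep))
    info = best.set_index("set_id")
    for v in g.nodes:
        if v in info.index:
            row = info.loc[v]
            g.nodes[v].update(
                enriched=True,
                p_adjusted=float(row["p_adjusted"]),
                direction=row["direction"],
                set_name=row["set_name"],
                category=row.get("category"),
            )
        else:
            g.nodes[v].update(enriched=False, p_adjusted=None, direction=None)
    return PathwayNetwork(
        graph=g,
        comparison=comparison,
        threshold=float(foundation.graph.get("threshold", float("nan"))),
        metric=str(foundation.graph.get("metric", "unknown")),
    )
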