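"""Synthetic fixtures: DEG tables, pathway databases and interactomes.

These generators define the study conditions under which the statistical
machinery is validated offline:

* a gene-set database drawn from a fixed gene universe with controllable
  pairwise overlap and round-robin category labels;
* DEG tables in which non-planted genes carry null signal (log2 fold
  changes ~ Normal(0, 0.3), p ~ Uniform(0, 1)) while a chosen fraction of
  each planted pathway's genes get a directional fold-change shift and
  p ~ Uniform(0, 0.001), with BH-adjusted p over the whole table;
* scale-free interactomes grown by preferential attachment.

Every generator is a pure function of its configuration: the same seed
yields byte-identical outputs.  No count-level RNA-Seq simulation is
attempted — the toolkit consumes post-differential-expression tables, so
the noise model targets the statistics (uniform null p-values, Gaussian
null fold changes) rather than read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import adjust_bh
from .errors import ValidationError
from .io import DEGTable, GeneSet, GeneSetDatabase, InteractionTable

__all__ = [
    "PlantedSet",
    "SimulationConfig",
    "gene_universe",
    "simulate_pathway_db",
    "simulate_deg_table",
    "simulate_interactions",
]

DEFAULT_CATEGORIES = (
    "Immune System", "Metabolism", "Signal Transduction", "Cell Cycle",
)


@dataclass(frozen=True)
class PlantedSet:
    """A pathway carrying true signal in a simulated comparison."""

    set_id: str
    direction: str = "up"            # sign of the planted fold changes
    effect_size: float = 3.0         # mean |log2 fc| shift of hit genes
    hit_fraction: float = 0.9        # fraction of member genes shifted

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError("planted direction must be 'up' or 'down'")
        if not (0 < self.hit_fraction <= 1):
            raise ValidationError("hit_fraction must lie in (0, 1]")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 2000
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (20, 50)
    overlap_fraction: float = 0.0
    planted_sets: tuple[PlantedSet, ...] = ()
    null_fc_sd: float = 0.3
    planted_p_max: float = 0.001
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValidationError("invalid pathway_size_range")
        if not (0 <= self.overlap_fraction < 1):
            raise ValidationError("overlap_fraction must lie in [0, 1)")
        if self.n_pathways < 1:
            raise ValidationError("n_pathways must be >= 1")


def gene_universe(n_genes: int) -> list[str]:
    """Deterministic synthetic gene identifiers G000001..G<n>."""
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


def simulate_pathway_db(config: SimulationConfig) -> GeneSetDatabase:
    """Draw ``n_pathways`` gene sets from the universe.

    Each set takes a fraction ``overlap_fraction`` of its members from
    genes already used by earlier sets (when any exist) and the rest from
    unused genes, so overlap 0 yields pairwise-disjoint sets while the
    universe permits.  Categories are assigned round-robin.
    """
    lo, hi = config.pathway_size_range
    if hi > config.n_genes:
        raise ValidationError("pathway size max exceeds the gene universe")
    rng = np.random.default_rng(config.seed)
    universe = gene_universe(config.n_genes)
    unused = list(universe)
    used: list[str] = []
    sets: list[GeneSet] = []
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_shared = min(int(round(size * config.overlap_fraction)), len(used))
        members: set[str] = set()
        if n_shared:
            members |= set(rng.choice(used, size=n_shared, replace=False))
        n_fresh = size - len(members)
        pool = unused if len(unused) >= n_fresh \
            else [g for g in universe if g not in members]
        if len(pool) < n_fresh:
            raise ValidationError("gene universe too small for requested sets")
        fresh = rng.choice(pool, size=n_fresh, replace=False)
        members |= set(fresh)
        for g in fresh:
            if g in unused:
                unused.remove(g)
                used.append(g)
        sid = f"P{i + 1:03d}"
        sets.append(
            GeneSet(
                set_id=sid,
                set_name=f"Pathway {i + 1}",
                genes=frozenset(members),
                category=config.categories[i % len(config.categories)],
            )
        )
    return GeneSetDatabase(sets)


def simulate_deg_table(
    config: SimulationConfig,
    db: GeneSetDatabase,
    comparison_name: str = "simulated",
) -> DEGTable:
    """One DEG comparison over the gene universe with planted signal.

    Planted pathways must exist in ``db``; a ``hit_fraction`` of each one's
    genes get |log2 fc| ~ effect_size + |Normal(0, null_fc_sd)| with the
    planted sign and p ~ Uniform(0, planted_p_max).  All other genes are
    null.  Adjusted p-values are BH over the whole table.
    """
    for ps in config.planted_sets:
        if ps.set_id not in db:
            raise ValidationError(f"planted set {ps.set_id!r} not in database")
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config.n_genes)
    idx = {g: i for i, g in enumerate(genes)}

    fc = rng.normal(0.0, config.null_fc_sd, size=config.n_genes)
    p = rng.uniform(0.0, 1.0, size=config.n_genes)
    for ps in config.planted_sets:
        members = sorted(db[ps.set_id].genes & set(genes))
        n_hit = max(1, int(round(ps.hit_fraction * len(members))))
        hits = rng.choice(members, size=n_hit, replace=False)
        sign = 1.0 if ps.direction == "up" else -1.0
        for g in hits:
            i = idx[g]
            fc[i] = sign * (ps.effect_size + abs(rng.normal(0.0, config.null_fc_sd)))
            p[i] = rng.uniform(0.0, config.planted_p_max)
    padj = adjust_bh(p.tolist())
    df = pd.DataFrame({
        "gene_id": genes,
        "log2_fc": fc,
        "p_value": p,
        "p_adjusted": padj,
    })
    return DEGTable(comparison_name=comparison_name, data=df)


def simulate_interactions(
    n_nodes: int,
    edges_per_node: int = 2,
    seed: int = 0,
    universe: Sequence[str] | None = None,
) -> InteractionTable:
    """Scale-free interactome by Barabasi-Albert preferential attachment.

    The result is connected, free of self-loops and duplicate pairs, with
    node identifiers drawn from the gene universe (or ``universe``).
    """
    if n_nodes < 3:
        raise ValidationError("n_nodes must be >= 3")
    if edges_per_node < 1 or edges_per_node >= n_nodes:
        raise ValidationError("need 1 <= edges_per_node < n_nodes")
    g = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=seed)
    names = list(universe) if universe is not None else gene_universe(n_nodes)
    if len(names) < n_nodes:
        raise ValidationError("universe smaller than n_nodes")
    edges = sorted(
        tuple(sorted((names[a], names[b]))) for a, b in g.edges
    )
    return InteractionTable(edges=edges, n_dropped=0, source="simulated")
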