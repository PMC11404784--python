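"""Pathway enrichment: hypergeometric ORA, gene-pair ORA, and permutation GSEA.

All three methods share one tabular output schema so that results from any
number of comparisons, directions and methods can be concatenated and
compared directly:

``comparison, direction, set_id, set_name, category, method,
k, K, n, N, statistic, p_value, p_adjusted, hit_genes``

For the ORA methods ``statistic`` is the enrichment ratio (k/n)/(K/N); for
GSEA it is the normalised enrichment score.  ``direction`` is ``up``/``down``
when DEGs are split by fold-change sign, ``all`` otherwise; GSEA rows take
their direction from the sign of the enrichment score.

Benjamini-Hochberg correction is applied within each
(comparison, direction, method) stratum by default, mirroring independent
testing of up- and down-regulated gene sets; a global-correction flag pools
all rows instead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import DEGTable, GeneSetDatabase

__all__ = [
    "ENRICHMENT_COLUMNS",
    "DEFAULT_P_CUTOFF",
    "DEFAULT_FC_CUTOFF",
    "OraResult",
    "GenePairSignatureIndex",
    "RankedGeneList",
    "GseaResult",
    "select_degs",
    "ora_hypergeometric",
    "build_gene_pair_signatures",
    "ora_gene_pairs",
    "gsea",
    "adjust_bh",
    "pathway_enrichment",
]

ENRICHMENT_COLUMNS = [
    "comparison", "direction", "set_id", "set_name", "category", "method",
    "k", "K", "n", "N", "statistic", "p_value", "p_adjusted", "hit_genes",
]

DEFAULT_P_CUTOFF = 0.05
DEFAULT_FC_CUTOFF = math.log2(1.5)
DEFAULT_MIN_SET_SIZE = 10
DEFAULT_MAX_SET_SIZE = 500


# ---------------------------------------------------------------------------
# DEG selection
# ---------------------------------------------------------------------------

def select_degs(
    table: DEGTable,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    use_adjusted: bool = True,
) -> tuple[set[str], set[str]]:
    """Split significant genes by fold-change direction.

    ``up`` collects genes with p (or adjusted p) strictly below ``p_cutoff``
    and log2 fold change >= ``fc_cutoff``; ``down`` uses <= -``fc_cutoff``.
    A gene with log2 fold change exactly 0 belongs to neither set.
    """
    if p_cutoff <= 0 or fc_cutoff <= 0:
        raise ValidationError("p_cutoff and fc_cutoff must be > 0")
    df = table.data
    pcol = "p_adjusted" if use_adjusted else "p_value"
    pvals = df[pcol].to_numpy(dtype=float)
    if use_adjusted and np.isnan(pvals).all():
        raise ValidationError(
            f"comparison {table.comparison_name!r} has no adjusted p-values; "
            "pass use_adjusted=False to filter on raw p-values"
        )
    sig = pvals < p_cutoff  # NaN compares False
    fc = df["log2_fc"].to_numpy(dtype=float)
    up = set(df["gene_id"][sig & (fc >= fc_cutoff)])
    down = set(df["gene_id"][sig & (fc <= -fc_cutoff)])
    return up, down


# ---------------------------------------------------------------------------
# Gene-level ORA
# ---------------------------------------------------------------------------

class OraResult(NamedTuple):
    k: int
    K: int
    n: int
    N: int
    p_value: float
    enrichment_ratio: float
    hit_genes: tuple[str, ...]


def ora_hypergeometric(
    query: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> OraResult:
    """Upper-tail hypergeometric over-representation test.

    With k = |query ∩ set|, K = |set ∩ universe|, n = |query|, N = |universe|,
    the p-value is P(X >= k) for X ~ Hypergeom(N, K, n).  The query and the
    gene set are intersected with the universe first.
    """
    universe = set(universe)
    q = set(query) & universe
    s = set(gene_set) & universe
    if not q:
        raise ValidationError("query is empty after intersection with the universe")
    if not s:
        raise ValidationError("gene set has no members in the universe")
    hits = q & s
    k, K, n, N = len(hits), len(s), len(q), len(universe)
    p = float(hypergeom.sf(k - 1, N, K, n))
    ratio = (k / n) / (K / N)
    return OraResult(k, K, n, N, min(p, 1.0), ratio, tuple(sorted(hits)))


# ---------------------------------------------------------------------------
# Gene-pair ORA
# ---------------------------------------------------------------------------

@dataclass
class GenePairSignatureIndex:
    """Signature pairs: within-set gene pairs unique to exactly one set.

    Every unordered pair of genes co-occurring in exactly one retained set
    is indexed to that set; pairs shared by two or more sets carry no
    discriminating signal and are discarded at construction.
    """

    pairs: dict[frozenset[str], str]
    set_pair_counts: dict[str, int] = field(default_factory=dict)
    set_names: dict[str, str] = field(default_factory=dict)
    set_categories: dict[str, str | None] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_gene_pair_signatures(
    db: GeneSetDatabase,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> GenePairSignatureIndex:
    """Enumerate signature pairs over the size-filtered database."""
    retained = db.filter_size(min_size, max_size)
    if len(retained) == 0:
        raise ValidationError(
            f"no gene sets retained with size in [{min_size}, {max_size}]"
        )
    owner: dict[frozenset[str], str | None] = {}
    for s in retained:
        for a, b in itertools.combinations(sorted(s.genes), 2):
            pair = frozenset((a, b))
            if pair in owner:
                owner[pair] = None  # shared between >=2 sets: excluded
            else:
                owner[pair] = s.set_id
    pairs = {p: sid for p, sid in owner.items() if sid is not None}
    counts: dict[str, int] = {s.set_id: 0 for s in retained}
    for sid in pairs.values():
        counts[sid] += 1
    return GenePairSignatureIndex(
        pairs=pairs,
        set_pair_counts=counts,
        set_names={s.set_id: s.set_name for s in retained},
        set_categories={s.set_id: s.category for s in retained},
    )


def ora_gene_pairs(
    query: Iterable[str],
    index: GenePairSignatureIndex,
) -> pd.DataFrame:
    """Hypergeometric test on signature pairs instead of single genes.

    The query contributes every unordered pair of its genes that exists in
    the index (n pairs, drawn from the N indexed pairs); per set, k is the
    number of those owned by the set and K the set's total signature pairs.
    Returns one row per set with k > 0 columns
    ``set_id, k, K, n, N, p_value, enrichment_ratio, hit_genes``; empty
    DataFrame (with a warning) when the query yields no indexed pairs.
    """
    q = sorted(set(query))
    qpairs = [
        frozenset(p) for p in itertools.combinations(q, 2)
        if frozenset(p) in index.pairs
    ]
    n, N = len(qpairs), index.n_pairs
    cols = ["set_id", "k", "K", "n", "N", "p_value", "enrichment_ratio", "hit_genes"]
    if n == 0:
        warnings.warn("query forms no signature pairs; empty result", stacklevel=2)
        return pd.DataFrame(columns=cols)
    per_set_hits: dict[str, list[frozenset[str]]] = {}
    for p in qpairs:
        per_set_hits.setdefault(index.pairs[p], []).append(p)
    rows = []
    for sid, hit_pairs in sorted(per_set_hits.items()):
        k = len(hit_pairs)
        K = index.set_pair_counts[sid]
        p = float(hypergeom.sf(k - 1, N, K, n))
        genes = sorted({g for pr in hit_pairs for g in pr})
        rows.append((sid, k, K, n, N, min(p, 1.0), (k / n) / (K / N), tuple(genes)))
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

@dataclass
class RankedGeneList:
    """Genes ordered by a ranking statistic, descending, ties resolved.

    Ties in the statistic are broken by gene identifier (lexicographic,
    ascending) so the materialised order is deterministic.
    """

    genes: list[str]
    stats: np.ndarray

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "RankedGeneList":
        items = list(pairs)
        ids = [g for g, _ in items]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate gene ids in ranked list")
        items.sort(key=lambda gv: (-gv[1], gv[0]))
        return cls(
            genes=[g for g, _ in items],
            stats=np.array([v for _, v in items], dtype=float),
        )

    @classmethod
    def from_deg_table(cls, table: DEGTable, by: str = "log2_fc") -> "RankedGeneList":
        df = table.data
        if by not in df.columns:
            raise ValidationError(f"no column {by!r} to rank by")
        return cls.from_pairs(zip(df["gene_id"], df[by].astype(float)))

    def __len__(self) -> int:
        return len(self.genes)


class GseaResult(NamedTuple):
    es: float
    nes: float
    p_value: float
    leading_edge: tuple[str, ...]
    n_hits: int


def _running_extremum(hit_mask: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Signed maximum deviation of the GSEA running sum and its position.

    Hits step up by their weight normalised over the in-set weight total;
    misses step down by 1/(N - Nh).  Returns (es, index of extremum).
    """
    n = hit_mask.size
    nh = int(hit_mask.sum())
    wsum = weights[hit_mask].sum()
    steps = np.where(hit_mask, weights / wsum, -1.0 / (n - nh))
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def gsea(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Gene set enrichment analysis by running-sum with label permutations.

    The enrichment score is the signed maximum deviation of the running sum
    over the ranked list (weight 0 recovers the classic Kolmogorov-Smirnov
    statistic).  Significance comes from ``n_perm`` permutations of the hit
    labels over list positions (the ranking statistics stay in place), with
    the p-value computed one-sided among permutation scores of matching
    sign and the NES as es / mean(|permuted es| of matching sign).
    """
    if weight < 0:
        raise ValidationError("weight must be >= 0")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    members = set(gene_set)
    hit_mask = np.array([g in members for g in ranked.genes], dtype=bool)
    nh = int(hit_mask.sum())
    if nh == 0:
        raise ValidationError("gene set has no members in the ranked list")
    if nh == len(ranked):
        raise ValidationError("gene set equals the ranked universe; ES undefined")
    weights = np.abs(ranked.stats) ** weight

    es, idx = _running_extremum(hit_mask, weights)
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.genes) if hit_mask[i] and i <= idx]
    else:
        leading = [g for i, g in enumerate(ranked.genes) if hit_mask[i] and i >= idx]

    rng = np.random.default_rng(seed)
    n = len(ranked)
    perm_es = np.empty(n_perm)
    mask = np.zeros(n, dtype=bool)
    for j in range(n_perm):
        mask[:] = False
        mask[rng.choice(n, size=nh, replace=False)] = True
        perm_es[j], _ = _running_extremum(mask, weights)

    if es >= 0:
        same = perm_es[perm_es >= 0]
        exceed = int((same >= es).sum())
    else:
        same = perm_es[perm_es < 0]
        exceed = int((same <= es).sum())
    p = (1 + exceed) / (1 + same.size) if same.size else 1.0
    nes = es / float(np.mean(np.abs(same))) if same.size else float("nan")
    return GseaResult(es, nes, min(p, 1.0), tuple(leading), nh)


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------

def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return []
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    return np.minimum(adjusted, 1.0).tolist()


# ---------------------------------------------------------------------------
# Unified driver
# ---------------------------------------------------------------------------

def _ora_rows_for_query(
    query: set[str],
    db: GeneSetDatabase,
    universe: set[str],
    min_set_size: int,
    max_set_size: int,
) -> list[dict]:
    rows = []
    q = query & universe
    if not q:
        return rows
    for s in db.filter_size(min_set_size, max_set_size):
        members = s.genes & universe
        if not members:
            continue
        res = ora_hypergeometric(q, members, universe)
        rows.append({
            "set_id": s.set_id, "set_name": s.set_name, "category": s.category,
            "k": res.k, "K": res.K, "n": res.n, "N": res.N,
            "statistic": res.enrichment_ratio, "p_value": res.p_value,
            "hit_genes": ";".join(res.hit_genes),
        })
    return rows


def pathway_enrichment(
    tables: DEGTable | Sequence[DEGTable],
    db: GeneSetDatabase,
    method: Literal["ora", "gene_pair_ora", "gsea"] = "ora",
    split: bool = True,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    use_adjusted: bool = True,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
    universe: Literal["measured", "database"] = "measured",
    global_correction: bool = False,
    gsea_params: dict | None = None,
) -> pd.DataFrame:
    """Run one enrichment method over one or more DEG comparisons.

    For the ORA-family methods with ``split=True``, up- and down-regulated
    DEGs are tested independently per comparison and rows labelled with
    their direction; GSEA consumes the full ranking instead (``split`` must
    be off) and derives direction from the enrichment-score sign.

    The ORA universe defaults to genes present in both the measured table
    and the database (``universe="measured"``); ``"database"`` uses all
    database genes regardless of measurement.

    Returns the unified table (see module docstring), BH-corrected within
    each (comparison, direction, method) stratum unless
    ``global_correction``.
    """
    if isinstance(tables, DEGTable):
        tables = [tables]
    if not tables:
        raise ValidationError("need at least one DEG table")
    if len(db) == 0:
        raise ValidationError("gene set database is empty")
    if method == "gsea" and split:
        raise ValidationError(
            "GSEA consumes the full gene ranking; run with split=False "
            "(direction is derived from the enrichment-score sign)"
        )
    gsea_params = dict(gsea_params or {})
    rank_by = gsea_params.pop("rank_by", "log2_fc")

    all_rows: list[dict] = []
    for table in tables:
        measured = set(table.genes)
        if method in ("ora", "gene_pair_ora"):
            up, down = select_degs(table, p_cutoff, fc_cutoff, use_adjusted)
            if split:
                strata = [("up", up), ("down", down)]
            else:
                strata = [("all", up | down)]
            for direction, query in strata:
                if not query:
                    warnings.warn(
                        f"no {direction!r} DEGs for comparison "
                        f"{table.comparison_name!r}; stratum skipped",
                        stacklevel=2,
                    )
                    continue
                if method == "ora":
                    uni = (db.all_genes() & measured) if universe == "measured" \
                        else db.all_genes()
                    rows = _ora_rows_for_query(
                        query, db, uni, min_set_size, max_set_size
                    )
                else:
                    index = build_gene_pair_signatures(db, min_set_size, max_set_size)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        df = ora_gene_pairs(query, index)
                    rows = [
                        {
                            "set_id": r.set_id,
                            "set_name": index.set_names[r.set_id],
                            "category": index.set_categories[r.set_id],
                            "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                            "statistic": r.enrichment_ratio,
                            "p_value": r.p_value,
                            "hit_genes": ";".join(r.hit_genes),
                        }
                        for r in df.itertuples()
                    ]
                for row in rows:
                    row.update(
                        comparison=table.comparison_name,
                        direction=direction,
                        method=method,
                    )
                all_rows.extend(rows)
        else:  # gsea
            ranked = RankedGeneList.from_deg_table(table, by=rank_by)
            gkw = {
                "weight": gsea_params.get("weight", 1.0),
                "n_perm": gsea_params.get("n_perm", 1000),
            }
            base_seed = gsea_params.get("seed", 0)
            for i, s in enumerate(db.filter_size(min_set_size, max_set_size)):
                members = s.genes & set(ranked.genes)
                if not members or len(members) == len(ranked):
                    continue
                res = gsea(ranked, members, seed=base_seed + i, **gkw)
                all_rows.append({
                    "comparison": table.comparison_name,
                    "direction": "up" if res.es >= 0 else "down",
                    "set_id": s.set_id, "set_name": s.set_name,
                    "category": s.category, "method": "gsea",
                    "k": len(res.leading_edge), "K": res.n_hits,
                    "n": len(members), "N": len(ranked),
                    "statistic": res.nes, "p_value": res.p_value,
                    "hit_genes": ";".join(res.leading_edge),
                })

    result = pd.DataFrame(
        all_rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "p_adjusted"]
    )
    result["p_adjusted"] = np.nan
    if len(result):
        if global_correction:
            result["p_adjusted"] = adjust_bh(result["p_value"].tolist())
        else:
            # GSEA directions are an outcome, not a test stratum: pool them.
            strata_cols = ["comparison", "method"] if method == "gsea" \
                else ["comparison", "direction", "method"]
            for _, idx in result.groupby(strata_cols).groups.items():
                result.loc[idx, "p_adjusted"] = adjust_bh(
                    result.loc[idx, "p_value"].tolist()
                )
    return result[ENRICHMENT_COLUMNS].reset_index(drop=True)
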