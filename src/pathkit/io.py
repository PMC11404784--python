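"""Readers, writers and domain containers for the toolkit's external formats.

Supported formats
-----------------
* DEG tables — delimited text in the DESeq2 dialect (``log2FoldChange`` /
  ``pvalue`` / ``padj``), the edgeR dialect (``logFC`` / ``PValue`` / ``FDR``),
  or a generic dialect with caller-supplied column names.
* Gene-set databases — GMT (tab-separated: name, description, genes...),
  optionally paired with a two-column (set_id, category) mapping file.
* Protein-protein interactions — two-column delimited edge lists.
* Identifier mappings — two-column (source, target) TSV.

Gene identifiers are opaque, case-sensitive strings throughout; no case
folding or whitespace normalisation is applied beyond stripping field ends.
All writers emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguousDialectError, FormatError, ValidationError

__all__ = [
    "DEGTable",
    "GeneSet",
    "GeneSetDatabase",
    "InteractionTable",
    "IdMapping",
    "read_deg_table",
    "read_gmt",
    "write_gmt",
    "read_interactions",
    "write_interactions",
    "read_id_mapping",
    "map_ids",
]

DEG_COLUMNS = ["gene_id", "log2_fc", "p_value", "p_adjusted"]

_DIALECTS = {
    "deseq2": {"log2_fc": "log2FoldChange", "p_value": "pvalue", "p_adjusted": "padj"},
    "edger": {"log2_fc": "logFC", "p_value": "PValue", "p_adjusted": "FDR"},
}


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class DEGTable:
    """One differential-expression comparison.

    ``data`` holds one row per gene with columns ``gene_id``, ``log2_fc``,
    ``p_value``, ``p_adjusted`` (p columns may contain NaN for missing).
    """

    comparison_name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in DEG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"DEG table missing required columns: {missing}")
        dup = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(
                f"duplicate gene_id values in comparison "
                f"{self.comparison_name!r}: {sorted(dup)}"
            )
        if not np.isfinite(df["log2_fc"].to_numpy(dtype=float)).all():
            raise ValidationError("log2_fc contains non-finite values")
        for col in ("p_value", "p_adjusted"):
            vals = df[col].to_numpy(dtype=float)
            present = ~np.isnan(vals)
            if ((vals[present] < 0) | (vals[present] > 1)).any():
                raise ValidationError(f"{col} outside [0, 1]")

    @property
    def genes(self) -> list[str]:
        return self.data["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    set_name: str
    genes: frozenset[str]
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetDatabase:
    """An ordered collection of named gene sets, unique by ``set_id``."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate set_id values: {sorted(dup)}")
        self._by_id = {s.set_id: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        try:
            return self._by_id[set_id]
        except KeyError:
            raise KeyError(f"no gene set with id {set_id!r}") from None

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return out

    def filter_size(self, min_size: int, max_size: int) -> "GeneSetDatabase":
        kept = [s for s in self.sets if min_size <= len(s) <= max_size]
        return GeneSetDatabase(kept)


@dataclass
class InteractionTable:
    """Undirected, de-duplicated gene-gene interaction edges.

    Edges are stored as sorted 2-tuples; ``n_dropped`` counts input rows
    discarded as self-loops or duplicate pairs.
    """

    edges: list[tuple[str, str]]
    n_dropped: int = 0
    source: str | None = None

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
        norm = [tuple(sorted(e)) for e in self.edges]
        if len(set(norm)) != len(norm):
            raise ValidationError("duplicate undirected pairs in edge list")
        self.edges = norm  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}


@dataclass
class IdMapping:
    """One-to-at-most-one mapping between identifier namespaces."""

    entries: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override is not None:
        return override
    return "," if path.suffix.lower() == ".csv" else "\t"


def _detect_dialect(header: Sequence[str]) -> str:
    cols = set(header)
    matches = [
        name for name, mapping in _DIALECTS.items()
        if set(mapping.values()) <= cols
    ]
    if len(matches) > 1:
        raise AmbiguousDialectError(
            f"header matches multiple dialects {matches}; pass dialect= explicitly"
        )
    if not matches:
        raise FormatError(
            "could not auto-detect DEG table dialect from header "
            f"{list(header)}; expected DESeq2 (log2FoldChange/pvalue/padj) or "
            "edgeR (logFC/PValue/FDR) columns, or pass dialect='generic' with "
            "explicit column names"
        )
    return matches[0]


def read_deg_table(
    path: str | Path,
    dialect: Literal["auto", "deseq2", "edger", "generic"] = "auto",
    *,
    comparison_name: str | None = None,
    delimiter: str | None = None,
    gene_column: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> DEGTable:
    """Read a differential-expression table from delimited text.

    Parameters
    ----------
    dialect
        ``"deseq2"``, ``"edger"``, ``"generic"`` (requires ``columns``
        mapping ``log2_fc``/``p_value``/``p_adjusted`` to header names), or
        ``"auto"`` to resolve strictly by header names.  A header matching
        more than one dialect raises :class:`AmbiguousDialectError`.
    gene_column
        Header name holding gene identifiers; defaults to ``gene_id`` or
        ``gene`` if present, else the first column.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file")
    header = list(df.columns)

    if dialect == "auto":
        dialect = _detect_dialect(header)  # type: ignore[assignment]
    if dialect == "generic":
        if columns is None:
            raise FormatError("dialect='generic' requires a columns= mapping")
        mapping = dict(columns)
    else:
        mapping = _DIALECTS[dialect]
    for target, source in mapping.items():
        if source not in header:
            raise FormatError(
                f"{path}: missing required column {source!r} for dialect {dialect!r}"
            )

    if gene_column is None:
        for cand in ("gene_id", "gene", "Gene", "ensembl_id"):
            if cand in header and cand not in mapping.values():
                gene_column = cand
                break
        else:
            gene_column = header[0]
    elif gene_column not in header:
        raise FormatError(f"{path}: gene column {gene_column!r} not in header")

    out = pd.DataFrame({"gene_id": df[gene_column].astype(str).str.strip()})
    for target in ("log2_fc", "p_value", "p_adjusted"):
        raw = df[mapping[target]]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "") \
            & (raw.astype(str).str.upper() != "NA")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: unparseable numeric in column "
                f"{mapping[target]!r} at line {line}: {raw[bad].iloc[0]!r}"
            )
        out[target] = num.astype(float)
    name = comparison_name if comparison_name is not None else path.stem
    return DEGTable(comparison_name=name, data=out.reset_index(drop=True))


def write_deg_table(table: DEGTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write in the DESeq2 dialect so the file round-trips via dialect=auto."""
    out = table.data.rename(columns={
        "log2_fc": "log2FoldChange", "p_value": "pvalue", "p_adjusted": "padj",
    })
    out.to_csv(Path(path), sep=delimiter, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene-set databases
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path,
    category_map: str | Path | None = None,
) -> GeneSetDatabase:
    """Read a GMT file (one set per line: name, description, >=1 gene).

    Duplicate genes within a line are de-duplicated.  Category labels, when
    a ``category_map`` two-column (set_id, category) TSV is given, are
    attached to matching sets; sets absent from the map get no category.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    categories: dict[str, str] = {}
    if category_map is not None:
        cm = pd.read_csv(Path(category_map), sep="\t", header=None, dtype=str)
        if cm.shape[1] < 2:
            raise FormatError(f"{category_map}: category map needs 2 columns")
        categories = dict(zip(cm[0].str.strip(), cm[1].str.strip()))

    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            set_id = fields[0].strip()
            desc = fields[1].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: set {set_id!r} has no genes")
            sets.append(
                GeneSet(
                    set_id=set_id,
                    set_name=desc if desc else set_id,
                    genes=frozenset(genes),
                    category=categories.get(set_id),
                )
            )
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetDatabase(sets)


def write_gmt(db: GeneSetDatabase, path: str | Path) -> None:
    """Write a database to GMT; genes sorted for byte-stable output."""
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        for s in db:
            fh.write("\t".join([s.set_id, s.set_name, *sorted(s.genes)]) + "\n")


def write_category_map(db: GeneSetDatabase, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        for s in db:
            if s.category is not None:
                fh.write(f"{s.set_id}\t{s.category}\n")


# ---------------------------------------------------------------------------
# Interaction edge lists
# ---------------------------------------------------------------------------

def read_interactions(path: str | Path, delimiter: str = "\t") -> InteractionTable:
    """Read an undirected edge list from >=2-column delimited text.

    Self-loops are dropped and duplicate undirected pairs (a-b vs b-a)
    collapsed; the number of dropped rows is recorded on the result.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [r for r in reader if r and any(f.strip() for f in r)]
    if not rows:
        raise FormatError(f"{path}: empty interaction file")
    header = rows[0]
    if len(header) < 2:
        raise FormatError(f"{path}: need >=2 columns of gene identifiers")
    body = rows[1:]
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    dropped = 0
    for r in body:
        a, b = r[0].strip(), r[1].strip()
        if a == b:
            dropped += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        edges.append(key)
    if not edges:
        warnings.warn(f"{path}: no interaction edges after filtering", stacklevel=2)
    return InteractionTable(edges=edges, n_dropped=dropped, source=str(path))


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(table.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------

def read_id_mapping(path: str | Path) -> IdMapping:
    """Read a two-column (source, target) TSV; later rows override earlier."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: id mapping needs 2 columns")
    return IdMapping(dict(zip(df[0].str.strip(), df[1].str.strip())))


def map_ids(
    genes: Iterable[str],
    mapping: IdMapping,
    on_unmapped: Literal["keep", "drop"] = "keep",
) -> tuple[list[str], int]:
    """Translate identifiers, preserving order.

    Unmapped entries are kept verbatim or dropped per ``on_unmapped``; the
    count of unmapped inputs is always returned.
    """
    if on_unmapped not in ("keep", "drop"):
        raise ValidationError(f"on_unmapped must be 'keep' or 'drop', got {on_unmapped!r}")
    out: list[str] = []
    unmapped = 0
    for g in genes:
        if g in mapping.entries:
            out.append(mapping.entries[g])
        else:
            unmapped += 1
            if on_unmapped == "keep":
                out.append(g)
    return out, unmapped
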