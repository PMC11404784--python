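# pathkit

Pathway enrichment and network-based analysis of differential-expression
results from human RNA-Seq experiments.

A list of differentially expressed genes (DEGs) is rarely interpretable on
its own. `pathkit` takes the tables produced by the standard
differential-expression tools (DESeq2- or edgeR-style delimited text) and
provides, in one package with one shared result schema:

* **Pathway enrichment** by three methods — classic hypergeometric
  over-representation analysis (ORA), gene-pair signature ORA (which tests
  unordered gene pairs unique to a single pathway, reducing redundancy
  across overlapping gene sets), and rank-based GSEA with permutation
  p-values — over any number of comparisons, with up-/down-regulated genes
  tested independently and Benjamini–Hochberg correction per stratum.
* **Protein–protein-interaction (PPI) networks** grown from the significant
  DEGs as seed nodes at *zero* order (seeds only), *first* order (seeds plus
  direct interactors) or *minimum* order (first order with single-seed-edge
  interactors trimmed), with betweenness-centrality hub scoring, pathway
  enrichment of node sets, and pathway subnetwork extraction.
* **Pathway-crosstalk networks** ("pathnets"): pathways become nodes, joined
  when the distance between their gene memberships falls below a threshold
  (Jaccard distance < 0.8 by default), keeping enriched pathways and their
  immediate non-significant neighbours.
* **Publication-style figures** — volcano plots, fold-change heatmaps,
  enrichment glyph grids, and force-directed network plots — each paired
  with a machine-readable companion table encoding exactly what was drawn.
* **Synthetic fixtures** — seeded generators for gene-set databases, DEG
  tables with planted pathway signals, and scale-free interactomes — so the
  whole pipeline can be exercised and statistically validated offline.

Gene-set databases are read from GMT files (with an optional two-column
pathway→category map), interactions from two-column edge lists, so any
Reactome/KEGG/MSigDB/InnateDB export in those carrier formats plugs in.

## The statistics in brief

For a query of $n$ genes drawn from a universe of $N$, a pathway with $K$
testable members and $k$ hits is scored by the upper-tail hypergeometric
probability

$$p = P(X \ge k), \qquad X \sim \mathrm{Hypergeom}(N, K, n),$$

with enrichment ratio $(k/n)/(K/N)$. Gene-pair ORA applies the same test to
*signature pairs*: the unordered within-pathway gene pairs that occur in
exactly one pathway of the (size-filtered) database. GSEA computes the
signed maximum deviation of the classic running sum (hits weighted by
$|r|^w$, misses by $1/(N-N_h)$) and calibrates it against gene-label
permutations; the normalised enrichment score divides by the mean
magnitude of same-sign permutation scores.

## Worked example

`examples/01_pathway_enrichment.py` simulates a 1000-gene comparison in
which pathway `P001` carries a planted up-regulated signal (effect size 3
on the log2 scale in 90 % of its genes) and tests it by all three methods:

```
== ora — top 3 pathways (one row per pathway/direction) ==
set_id direction  k  K  statistic      p_value   p_adjusted
  P001        up 26 29  10.517241 1.129351e-34 1.355222e-33
  P002        up  3 26   1.353550 3.856922e-01 1.000000e+00
  P003        up  2 24   0.977564 6.294665e-01 1.000000e+00

== gene_pair_ora — top 3 pathways (one row per pathway/direction) ==
set_id direction   k   K  statistic  p_value  p_adjusted
  P001        up 320 401  11.653367      0.0         0.0

== gsea — top 3 pathways (one row per pathway/direction) ==
set_id direction  k  K  statistic  p_value  p_adjusted
  P001        up 26 29   2.405754 0.002725    0.032698
```

Reading the ORA row: 26 of the 29 testable members of `P001` appear among
the up-regulated DEGs (a 10.5-fold enrichment over chance), so the planted
pathway tops the ranking in the planted direction; the null pathways sit at
adjusted p ≈ 1. The other examples build PPI networks at all three orders
(`02`), a pathway-crosstalk network (`03`), and the figure set (`04`).

## Command line

Each analysis is also a subcommand (`pathkit enrich`, `ppi-build`,
`ppi-enrich`, `ppi-subnet`, `pathnet`, `volcano`, `heatmap`,
`pathway-grid`, `simulate`), writing TSV/GraphML/PNG artifacts plus a JSON
run-manifest; exit code 0 on success, 1 on data errors, 2 on usage errors.

```bash
pathkit simulate --seed 7 --planted P001:up:3.0:0.9 --out fixtures/
pathkit enrich --deg fixtures/deg_table.tsv --gmt fixtures/pathways.gmt \
    --categories fixtures/categories.tsv --out results/
```

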