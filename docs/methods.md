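# Methods

This note records the statistical models, the defaults and why they were
chosen, the behaviour of the synthetic-data generators, and the numerical
conventions the implementation commits to.

## Input model

A DEG table is one differential-expression comparison: per gene, a log2
fold change, a raw p-value and a multiplicity-adjusted p-value (either p
column may be missing; fold changes must be finite; gene identifiers are
opaque case-sensitive strings and must be unique). The DESeq2 dialect
(`log2FoldChange`/`pvalue`/`padj`) and the edgeR dialect
(`logFC`/`PValue`/`FDR`) are recognised strictly by header names; a header
matching both raises rather than guessing, and a `generic` dialect with
explicit column names covers everything else. Gene-set databases travel as
GMT; top-level category labels (e.g. "Immune System") ride in a separate
two-column map because GMT description fields are unreliable in the wild.
Interaction data is an undirected two-column edge list; self-loops and
duplicate undirected pairs are dropped and counted.

## DEG selection

A gene is *up* when its (adjusted, by default) p-value is strictly below
`p_cutoff` and its log2 fold change is ≥ `fc_cutoff`; *down* mirrors this
at ≤ −`fc_cutoff`. Defaults are `p_cutoff = 0.05` and
`fc_cutoff = log2(1.5) ≈ 0.585` — the conventional thresholds in human
transcriptomics; a fold change of exactly 0 belongs to neither direction.
Requesting adjusted-p filtering on a table without adjusted p-values is an
error rather than a silent fallback.

## Over-representation analysis

With query size n, testable set size K, universe size N and k hits, the
p-value is the upper-tail hypergeometric probability P(X ≥ k) and the
reported statistic is the enrichment ratio (k/n)/(K/N). The universe is,
by default, the intersection of the measured genes with the database's
genes: restricting to measured genes avoids the anti-conservative bias of
pretending unmeasured genes could have been drawn. A `universe="database"`
switch uses all database genes instead (this is also the default when
testing a PPI network's node set, where no measured table exists). Gene
sets are size-filtered to [10, 500] members before testing — smaller sets
are statistically unstable, larger ones uninformative.

## Gene-pair signature ORA

Within the size-filtered database, every unordered within-set gene pair is
enumerated; pairs occurring in two or more sets are discarded, and each
surviving *signature pair* is indexed to its unique owner. A query
contributes every pair of its genes present in the index, and each set is
scored by the same hypergeometric upper tail on pair counts (k owned query
pairs, K set signature pairs, n query pairs, N indexed pairs). Pairs are
unweighted and extracted at the flat set level; a pathway-hierarchy-aware
pair weighting could be layered on top of the index without changing the
test, but none is defined here because no principled default exists for
arbitrary GMT input.

## GSEA

Genes are ranked by a statistic (log2 fold change by default), descending,
with ties broken lexicographically by gene identifier so the order is
deterministic. The enrichment score is the signed maximum deviation of the
running sum in which an in-set gene at rank i adds |r_i|^w normalised by
the in-set total and a miss subtracts 1/(N − N_h); weight w = 0 recovers
the classic Kolmogorov–Smirnov form. Significance comes from gene-label
permutations (default 1000) — hit labels are redistributed over list
positions while the ranking statistics stay in place — because the package
consumes post-DE tables and has no expression matrix for sample
permutation. The p-value is one-sided among same-sign permutation scores
with the +1 continuity correction, and NES = ES / mean(|same-sign
permutation ES|). The leading edge is the in-set genes at or before the
score extremum for positive scores and at or after it for negative scores
(the tail where the set concentrates). A set equal to the ranked universe
is rejected (the miss step is undefined), as is an empty intersection.

## The shared result schema and multiple testing

All methods emit the same table: comparison, direction, set id/name,
category, method, the four count fields, a statistic (enrichment ratio or
NES), raw and BH-adjusted p, and the hit genes. For the ORA family with
direction splitting, BH runs within each (comparison, direction, method)
stratum, matching the design in which up- and down-regulated gene sets are
independent tests; for GSEA the direction is an outcome (the ES sign), not
a stratum, so correction pools each comparison. A `global_correction` flag
pools everything instead.

## PPI network order semantics

Zero order induces the interaction subgraph on the seeds; first order on
seeds plus their direct neighbours, keeping interactor–interactor edges
(the induced subgraph is the natural reading of "growing the network with
the available data"); minimum order removes from the first-order network
every interactor with exactly one edge to a seed, counting edges to seeds
only, in a single pass (not iterated to a fixpoint — iteration would let
removals cascade far from the seeds and is not obviously the intended
semantics; the single-pass choice is flagged in the docstrings). Seeds
absent from the interaction data are dropped and reported, erroring only
when none remain; isolated nodes are removed and counted because the
networks exist for connectivity analysis. Hubs default to betweenness
centrality — "binding the network together" is what betweenness measures —
with the top max(2, 2 % of nodes) flagged and ties broken by (score,
degree, identifier) for determinism.

## Pathway-crosstalk networks

The Jaccard distance 1 − |A∩B|/|A∪B| is the default inter-pathway metric;
Euclidean and Manhattan distances act on unnormalised binary membership
vectors over the union of database genes (a normalisation hook would be a
preprocessing step on the membership matrix). The foundation graph
connects pathways at distance strictly below the threshold — ties at the
threshold are not connected — with 0.8 the default for Jaccard; the other
metrics are unbounded so their thresholds must be user-supplied. The final
pathnet keeps the significantly enriched pathways plus their direct
foundation neighbours; a pathway significant in both directions carries
the direction of the lower adjusted p, mirroring the glyph-grid rule. The
foundation should be computed over the same size-filtered database the
enrichment saw, so distances and tests share a universe.

## Figures

Every figure writes PNG (300 dpi) or SVG by extension and returns a
companion table so visual encodings are testable without pixel
comparisons. Volcano classification reuses the DEG-selection thresholds
exactly; zero p-values are replaced by the smallest positive float with a
warning; labels go to the genes with the best product of the |fold-change|
rank and the significance rank. Heatmap cells for unmeasured genes are
missing, never zero; optional row clustering is complete-linkage on
pairwise euclidean distances with missing cells pairwise-excluded, off by
default for determinism. Grid glyphs: triangles encode direction, circles
appear when enrichment ran without splitting, and a pathway significant in
both directions shows the lower-p triangle with an asterisk. Network
layouts are spring layouts under a caller-supplied seed, so identical
inputs give identical coordinates. The interactive HTML export is an
experimental stub outside the stable interface.

## Synthetic data

The generators produce the study conditions for validation, not realistic
RNA-Seq: the toolkit consumes post-DE tables, so the noise model targets
the statistics directly. Null genes draw log2 fold changes from
Normal(0, 0.3) and p-values from Uniform(0, 1) — the regime in which BH
and the hypergeometric test have known behaviour; planted pathways shift a
hit fraction (default 0.9) of their genes by a directional effect (default
3 on the log2 scale, plus half-normal noise) with p ~ Uniform(0, 0.001),
and adjusted p-values are BH over the whole table. Databases draw sets of
20–50 genes from a 2000-gene universe by default, with a controllable
fraction of members reused from earlier sets (overlap 0 gives disjoint
sets while the universe permits) and categories assigned round-robin.
Interactomes are Barabási–Albert preferential-attachment graphs: connected
and heavy-tailed, which is all the network code depends on. Every
generator is a pure function of its config; one seeded NumPy generator per
call, no global state. What passing tests on these fixtures do *not* show:
robustness to correlated genes, to p-value miscalibration from the
upstream DE model, or to the hierarchical redundancy of curated pathway
databases beyond the overlap fraction modelled here.

## Validation problem sizes

The statistical validation runs at 1000 genes and 12 pathways of 20–40
genes: null false-discovery is averaged over 200 seeded simulations and
planted-signal recovery (effect 3, hit fraction 0.9, overlap 0.1) over 100
runs per ORA method — sizes at which the planted design separates cleanly
from the null while the whole validation stays fast enough to run
routinely. Exhaustive hypergeometric enumeration covers every universe up
to N = 12; GSEA brute-force agreement uses 200 random lists of length ≤ 20;
network-order checks use 500 random graphs of ≤ 50 nodes; pathnet
soundness uses 100 simulated databases at overlap 0.5 and threshold 0.995
(simulated sets overlap far less than curated hierarchies, so the curated
default of 0.8 would rarely draw an edge there).

## Known limitations

No organism-specific identifier handling beyond a generic one-to-one id
map; no PSI-MITAB parsing (two-column extracts suffice); no directed,
signed or confidence-weighted interactions; gene-pair signatures ignore
pathway hierarchy; GSEA cannot use sample permutation; figures aim for
information parity with the field's standard plots, not pixel fidelity.
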