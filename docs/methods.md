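# Methods

## Scope and model

`netpharm` implements the desk half of a multi-herb network-pharmacology
study. The study objects are: herb constituents (compounds) with two ADME
screening parameters; component→target records naming the proteins each
compound is known or predicted to hit; disease gene lists; a
confidence-scored protein-protein interaction (PPI) graph over the
putative therapeutic targets; and annotation collections (GO BP/MF/CC and
pathways). The pipeline is a fixed composition of set logic, graph
statistics and one classical test — there is no model fitting. All
database retrieval (compound tables, target prediction, disease gene
queries, PPI retrieval, annotation snapshots) is out of scope: those
artifacts enter as files, and the synthetic generator stands in for them
during testing.

## Stage definitions and defaults

**ADME screen.** Active iff `ob >= ob_min` and `dl >= dl_min`, or the
compound id is whitelisted. Defaults `ob_min = 30` (percent oral
bioavailability) and `dl_min = 0.18` (dimensionless drug-likeness), the
conventional cutoffs for herbal compound screening. Both comparisons are
inclusive. Rescue is an explicit id list — curation is input, not
computation — and a rescue id absent from the table warns rather than
fails, since whitelists routinely outlive their tables.

**Symbol standardization.** A raw-name→symbol table maps source protein
names to official human gene symbols; symbols are uppercased on ingest so
all later set operations are case-insensitive. Unmapped records are
returned and logged, never dropped silently: record conservation
(`mapped + unmapped = input`) is asserted in the result object. A raw name
bound to two symbols is a curation error and aborts.

**Per-herb accounting.** Each deduplicated (compound, symbol) record is
attributed to every herb its compound belongs to. For single-herb
compounds the per-herb counts partition the mapped total; for multi-herb
compounds they intentionally double-count, because the question answered
is "how many target records does this herb contribute".

**Disease intersection.** The operative screen is against the *combined*
disease gene list (the joint-disease query as retrieved from a disease
database); intersections with the individual disease lists are reported
as descriptive Venn statistics. An empty putative set aborts the run with
the counts in the message — every downstream stage is undefined on an
empty seed set.

**Networks.** Simple undirected graphs with a `node_type` attribute
(`component | target | disease_target | disease | pathway`). Compounds
with no surviving edge are omitted. In the disease-mapping network the
putative targets are typed `target` but counted *inside* the disease set,
so the node count decomposes as
`qualifying components + |combined| + 1`; this is the only reading under
which the published component/disease-set/total arithmetic of such
networks is consistent, and it is asserted as an invariant. Exports are
SIF (edge list plus isolated-node lines) and GraphML (attributes
preserved); round-trips reproduce node and edge sets exactly.

**Topological screen.** DC is the raw degree; BC is shortest-path
betweenness with all geodesics counted and endpoints excluded (optionally
normalized by `(n-1)(n-2)/2`); CC is component-scaled closeness
`((s-1)/(n-1)) * ((s-1)/Σd)` with `s` the node's component size, so
confidence-filtered (and therefore often disconnected) PPI graphs are
handled without dropping nodes; an isolated node scores 0. The
computations are delegated to networkx, whose definitions match these
exactly; the test suite checks them against hand-written all-pairs BFS
oracles. Stage 1 keeps nodes with `DC >= 2 × median(DC)` over the whole
graph; a `strict_hub` switch makes the comparison strict, since both
dialects appear in practice and the non-strict form is the one usually
applied. Stage 2 recomputes all three centralities *on the hub-induced
subgraph* (the screen is defined on the extracted hub network, not
inherited from the full graph) and keeps nodes at or above all three
medians; ties at the median are kept, reading "satisfy the median" as
non-strict. Medians use the mean-of-central-order-statistics convention
for even counts. Both stage medians are recorded in the result so any run
is auditable. An empty hub set (e.g. a regular graph, where everyone sits
at the median) yields an empty, warned result rather than an error.

**Enrichment.** For a query of n genes inside an N-gene universe and a
term with K annotated genes overlapping the query in k, the score is the
hypergeometric upper tail P(X ≥ k) (scipy). The universe defaults to the
union of genes annotated in the loaded collection, with an explicit
background flag, because tool-internal backgrounds of online services are
not recoverable. Only terms with k ≥ 1 are tested, and exactly those form
the Benjamini–Hochberg family, computed separately per category since
each category is reported as its own family. GO categories flag at
FDR < 0.01 and pathways at raw p < 0.05. The rich factor k/K is emitted
per row for dot plots. BH step-up (statsmodels) was chosen as the FDR
flavor as the standard convention; it is a documented choice, not an
inference about any specific online tool's internals.

## Synthetic study generator

`generate_study(seed, params)` emits a complete, ground-truthed study.
Defaults model a six-herb study at its published scale:

| parameter | default | meaning |
| --- | --- | --- |
| `n_raw_components` | 265 | raw compounds before screening |
| `herb_weights` | 9:8:51:10:14:6 | relative herb sizes |
| `ob_range` | U(5, 60) % | oral bioavailability draw |
| `dl_beta` | Beta(1, 2.6) | drug-likeness draw; with the OB law, ~86/265 pass the 30/0.18 cutoffs |
| `n_rescued` | 8 | whitelisted failing compounds (total actives ≈ 94) |
| `n_union_targets` | 182 | distinct target genes |
| `promiscuous_counts` | 164, 104, 50 | planted hub-compound target counts |
| `target_lognorm` | logN(2.3, 1.0) | other compounds' target counts (heavy-tailed) |
| `unmapped_fraction` | 0.04 | records left without a symbol mapping |
| `n_combined`, `putative_count` | 232, 38 | combined disease list and its exact union overlap |
| `af/osahs_union_overlap` | 50, 75 | descriptive Venn overlaps (exact) |
| `ppi_n_neighbors` | 50 | non-putative PPI nodes (88-node graph) |
| `ppi_target_edges` | 505 | PPI edge budget |
| `n_core`, `core_peripheral_frac` | 6, 0.5 | planted clique size and shared periphery fraction |
| `planted_odds_ratio` | 12 | putative-gene over-sampling in planted terms |
| `n_planted_terms`, `n_null_terms` | 3, 22 | per category |

Set overlaps (union∩disease lists) are constructed exactly rather than
sampled so Venn-logic tests are deterministic and separable from sampling
noise. The planted PPI core is a clique whose members all share one
sampled peripheral neighbor set: a bare clique can fail the betweenness
criterion, and independently-sampled peripheries leave one-edge degree
ties inside the small hub subgraph, so the shared set is what makes the
planted core symmetric and jointly dominant in all three centralities.
Edge confidence scores are drawn in [0.40, 0.95] (core-incident edges
[0.70, 0.99]), all above the default 0.4 filter. Everything derives from
one `numpy.random.default_rng(seed)` stream; the same seed reproduces the
fixture byte-for-byte.

What the generator does **not** emulate: real compound chemistry, real
interactome topology beyond a heavy-tailed degree mix, annotation-term
hierarchy (GO's DAG), or database-version effects. Passing tests
therefore demonstrate the *logic* of the pipeline — set accounting,
screen behavior, error control — not agreement with any specific database
snapshot; published term counts and specific core-gene identities depend
on those snapshots and are deliberately not targets.

## Numerical and degenerate-input choices

- Duplicate PPI rows keep the maximum combined score (conservative
  confidence); self-loops are dropped with a warning.
- Hypergeometric tails are clipped to `[tiny, 1]`; the exactness
  requirement (≤1e-12 relative against integer-combinatorics oracles for
  N ≤ 60) is enforced in tests.
- The screen on a complete (or any regular) graph returns an empty hub
  set by construction: `2 × median` exceeds every degree. This is treated
  as a degenerate-but-valid outcome.
- BH on an empty vector returns an empty vector; a single p-value is
  returned unchanged.
- Problem sizes used by the test suite and the acceptance script — 100
  random graphs of n ≤ 25 for the centrality oracles, all N ≤ 60 for the
  hypergeometric oracle, 100–200 generated studies for recovery rates —
  were chosen as the smallest sizes at which the checked properties are
  meaningfully exercised.

## Known limitations

- The first-shell interactor expansion that some PPI services apply to a
  seed list is not reproduced; extra neighbor edges can be supplied in
  the PPI table, but selecting which neighbors a service would have added
  is not recoverable. The generator plants its own neighbor set instead.
- Multi-herb compound overlap between per-herb counts is supported but no
  attempt is made to reproduce any particular published overlap, which is
  unidentifiable from published totals alone.
- The enrichment module is a plain over-representation test; it does not
  implement EASE-style corrections or annotation-DAG-aware pruning.
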