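# netpharm

A tested, reusable network-pharmacology pipeline for multi-herb traditional
medicine studies. It models the standard workflow for asking *how does a
mixture of herbal compounds act on a disease*: screen raw herb constituents
by ADME parameters, map their protein targets to official gene symbols,
intersect those targets with disease gene lists, build the
compound-target-disease networks, nominate *core targets* from the
protein-protein interaction (PPI) network by a two-stage median-centrality
screen, and characterize the putative therapeutic targets by hypergeometric
GO/pathway over-representation analysis. The shipped study configuration
models six liver-regulating herbs (SZR, GS, YHS, XHC, JL, ML) against
atrial fibrillation combined with obstructive sleep apnea hypopnea syndrome
(AF + OSAHS).

Because the real inputs live behind commercial/online databases (TCMSP,
BATMAN-TCM, GeneCards, STRING, DAVID), the package ships a ground-truthed
synthetic study generator that emulates every input file at realistic
scale, with planted structure (promiscuous hub compounds, a
high-centrality PPI core clique, enriched annotation terms) so every stage
is testable offline.

## The methods in brief

- **ADME screen** — a compound is active iff OB ≥ 30 % and DL ≥ 0.18
  (both inclusive), or it is on an explicit literature-rescue whitelist.
- **Target assembly** — raw protein names → official human gene symbols
  via a mapping table; records deduplicated per (compound, symbol);
  per-herb counts attribute each record to every herb of its compound.
- **Disease intersection** — putative therapeutic targets are
  `herb target union ∩ combined disease gene list`; intersections with the
  individual disease lists are reported descriptively.
- **Core-target screen** — on the PPI graph (edges kept when the combined
  confidence score passes a cutoff), stage 1 keeps hubs with
  `DC ≥ 2 × median(DC)`; stage 2 recomputes degree (DC), betweenness (BC)
  and closeness (CC) on the hub-induced subgraph and keeps nodes meeting
  all three subgraph medians simultaneously.
- **Enrichment** — hypergeometric upper tail
  `P(X ≥ k)` for a term with K of N universe genes against an n-gene
  query, Benjamini–Hochberg FDR per category (BP/MF/CC/pathway); GO terms
  flagged at FDR < 0.01, pathways at p < 0.05; each row carries the rich
  factor k / K.

## Worked example

```bash
netpharm simulate --seed 1 --out fixtures/
netpharm run --config study.yaml          # or drive it from Python:
```

```python
from netpharm import generate_study
from netpharm.pipeline import run_study

fixture = generate_study(seed=1)
result = run_study(fixture)
print(result.report["stages"]["adme_filter"])
print(result.report["stages"]["disease_intersection"])
print(sorted(result.screen.core_targets))
```

prints

```
{'raw_components': 265, 'passed': 86, 'rescued': 8, 'dropped': 171, 'active': 94}
{'herb_af': 50, 'herb_osahs': 75, 'herb_both': 27, 'putative_targets': 38}
['TG0019', 'TG0024', 'TG0070', 'TG0102', 'TG0129', 'TG0140', 'TG0166', 'TG0181']
```

Of 265 raw compounds, 86 pass the ADME cutoffs and 8 are rescued by
literature evidence, giving 94 active compounds. Their 182-gene target
union shares 50 genes with the AF list, 75 with the OSAHS list, and 38
with the combined disease list — those 38 are the putative therapeutic
targets. The two-stage median screen of the 88-node PPI then nominates 8
core targets, which include all 6 genes of the fixture's planted
high-centrality clique (`fixture.truth["planted_core"]`).

The equivalent CLI stages are `netpharm filter`, `netpharm assemble`,
`netpharm screen` and `netpharm enrich`; `netpharm run --config study.yaml`
executes them all and writes SIF/GraphML networks, a DC/BC/CC centrality
table, an enrichment table and a JSON run report.

## Layout

| module | contents |
| --- | --- |
| `netpharm.models` | domain dataclasses (Component, GeneSet, InteractionEdge, …) |
| `netpharm.io` | TSV/CSV, GMT, PPI-table readers; SIF/GraphML export |
| `netpharm.adme` | OB/DL screen with literature rescue |
| `netpharm.assembly` | symbol standardization, per-herb accounting, disease intersection |
| `netpharm.networks` | typed component/target/disease/pathway network builders |
| `netpharm.topology` | DC/BC/CC and the two-stage median screen |
| `netpharm.enrichment` | hypergeometric ORA with per-category BH FDR |
| `netpharm.simulate` | ground-truthed synthetic study generator |
| `netpharm.pipeline`, `netpharm.cli` | orchestration, YAML config, `netpharm` command |

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
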