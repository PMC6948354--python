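"""Ground-truthed synthetic study generator.

Emulates every input the pipeline consumes — an ADME component table, a
protein-name-to-symbol mapping, component-target records, disease gene
lists, a confidence-scored PPI edge table and GMT annotation collections —
at the scale of a six-herb network-pharmacology study: ~265 raw compounds
of which ~94 are active (86 passing OB >= 30 / DL >= 0.18 plus 8
literature rescues), a 182-gene target union with a few promiscuous
flavonoid-like hub compounds, a 232-gene combined disease list overlapping
the union in exactly 38 genes, an 88-node PPI with a planted 6-clique core
wired into the periphery so it dominates degree, betweenness and closeness
simultaneously, and annotation terms that over-sample the putative target
set at a fixed odds ratio next to uniform null terms.

Set overlaps are constructed exactly (not sampled) so Venn-logic tests are
deterministic; everything else is drawn from a single seeded generator, so
the same seed yields a byte-identical fixture.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adme import filter_components
from .io import write_gmt, write_interaction_table
from .models import (
    DEFAULT_HERBS,
    AnnotationTerm,
    Component,
    GeneSet,
    InteractionEdge,
    RawTargetRecord,
)


@dataclass
class StudyParams:
    """Sizes and effect settings of the synthetic study (defaults at the
    scale described in the module docstring)."""

    herbs: tuple[str, ...] = DEFAULT_HERBS
    #: relative herb frequencies (matches the per-herb active-component
    #: profile 9:8:51:10:14:6 of the six-herb study)
    herb_weights: tuple[float, ...] = (9, 8, 51, 10, 14, 6)
    n_raw_components: int = 265
    p_multi_herb: float = 0.04
    ob_range: tuple[float, float] = (5.0, 60.0)
    dl_beta: tuple[float, float] = (1.0, 2.6)
    ob_min: float = 30.0
    dl_min: float = 0.18
    n_rescued: int = 8

    n_union_targets: int = 182
    #: distinct-target counts planted on the most promiscuous compounds
    promiscuous_counts: tuple[int, ...] = (164, 104, 50)
    target_lognorm: tuple[float, float] = (2.3, 1.0)
    max_targets_per_component: int = 80
    unmapped_fraction: float = 0.04

    n_af: int = 120
    af_union_overlap: int = 50
    n_osahs: int = 140
    osahs_union_overlap: int = 75
    n_combined: int = 232
    putative_count: int = 38

    n_core: int = 6
    ppi_n_neighbors: int = 50
    ppi_target_edges: int = 505
    core_peripheral_frac: float = 0.5
    score_background: tuple[float, float] = (0.40, 0.95)
    score_core: tuple[float, float] = (0.70, 0.99)

    n_planted_terms: int = 3
    n_null_terms: int = 22
    term_size_range: tuple[int, int] = (15, 40)
    planted_odds_ratio: float = 12.0

    def validate(self) -> None:
        if len(self.herbs) < 2:
            raise ValueError("need at least 2 herbs")
        if len(self.herb_weights) != len(self.herbs):
            raise ValueError("herb_weights must match herbs")
        if self.n_raw_components < 10:
            raise ValueError("need at least 10 components")
        if self.n_union_targets < 20:
            raise ValueError("need at least 20 genes")
        for overlap, a, b, what in (
            (self.putative_count, self.n_union_targets, self.n_combined, "putative"),
            (self.af_union_overlap, self.n_union_targets, self.n_af, "AF"),
            (self.osahs_union_overlap, self.n_union_targets, self.n_osahs, "OSAHS"),
        ):
            if overlap > min(a, b):
                raise ValueError(f"infeasible {what} overlap {overlap} > min({a}, {b})")
        if self.n_core > self.putative_count:
            raise ValueError("planted core cannot exceed the putative set")
        if max(self.promiscuous_counts, default=0) > self.n_union_targets:
            raise ValueError("promiscuous target count exceeds the target union")


@dataclass
class StudyFixture:
    """A complete generated study plus its ground truth."""

    components: list[Component]
    rescue_ids: frozenset[str]
    mapping: dict[str, str]
    raw_records: list[RawTargetRecord]
    af: GeneSet
    osahs: GeneSet
    combined: GeneSet
    ppi_edges: list[InteractionEdge]
    terms: list[AnnotationTerm]
    truth: dict
    params: StudyParams = field(default_factory=StudyParams)


def _symbols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate_study(seed: int, params: StudyParams | None = None) -> StudyFixture:
    """Generate a full ground-truthed study fixture.

    Deterministic in ``seed``: the same seed and params yield an identical
    fixture, byte-for-byte once written.
    """
    params = params or StudyParams()
    params.validate()
    rng = np.random.default_rng(seed)
    herbs = list(params.herbs)
    weights = np.asarray(params.herb_weights, dtype=float)
    weights = weights / weights.sum()

    # --- components with ADME parameters -------------------------------
    components: list[Component] = []
    for i in range(params.n_raw_components):
        cid = f"C{i + 1:04d}"
        primary = rng.choice(len(herbs), p=weights)
        herb_set = {herbs[primary]}
        if rng.random() < params.p_multi_herb and len(herbs) > 1:
            extra = rng.choice([j for j in range(len(herbs)) if j != primary])
            herb_set.add(herbs[extra])
        ob = float(rng.uniform(*params.ob_range))
        dl = float(rng.beta(*params.dl_beta))
        components.append(
            Component(cid, f"compound-{i + 1:04d}", frozenset(herb_set), round(ob, 2), round(dl, 3))
        )

    failing = [c.component_id for c in components if not (c.ob >= params.ob_min and c.dl >= params.dl_min)]
    n_rescue = min(params.n_rescued, len(failing))
    rescue_ids = frozenset(rng.choice(failing, size=n_rescue, replace=False).tolist()) if n_rescue else frozenset()

    active, _ = filter_components(components, params.ob_min, params.dl_min, rescue_ids)
    active_ids = [c.component_id for c in active]

    # --- component -> target edges (heavy-tailed promiscuity) -----------
    union = _symbols("TG", params.n_union_targets)
    n_active = len(active_ids)
    counts = np.clip(
        np.rint(rng.lognormal(*params.target_lognorm, size=n_active)).astype(int),
        1,
        min(params.max_targets_per_component, params.n_union_targets),
    )
    # plant promiscuous hub compounds on the first few active components
    order = rng.permutation(n_active)
    promiscuous: dict[str, int] = {}
    for slot, want in zip(order, params.promiscuous_counts):
        counts[slot] = min(want, params.n_union_targets)
        promiscuous[active_ids[slot]] = int(counts[slot])

    pair_set: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    for cid, c in zip(active_ids, counts):
        for sym in rng.choice(union, size=int(c), replace=False):
            pair = (cid, str(sym))
            if pair not in pair_set:
                pair_set.add(pair)
                pairs.append(pair)
    hit = {sym for _, sym in pairs}
    for sym in union:  # every union gene must be hit at least once
        if sym not in hit:
            cid = active_ids[int(rng.integers(n_active))]
            if (cid, sym) not in pair_set:
                pair_set.add((cid, sym))
                pairs.append((cid, sym))

    # raw protein names + mapping table; a slice of extra records is left
    # intentionally unmappable to exercise the unmapped path
    mapping = {f"protein {sym.lower()}": sym for sym in union}
    raw_records = [RawTargetRecord(cid, f"protein {sym.lower()}") for cid, sym in pairs]
    n_unmapped = int(round(params.unmapped_fraction * len(raw_records)))
    for j in range(n_unmapped):
        cid = active_ids[int(rng.integers(n_active))]
        raw_records.append(RawTargetRecord(cid, f"uncharacterized protein {j + 1}"))

    # --- disease gene lists with exact union overlaps -------------------
    putative = sorted(rng.choice(union, size=params.putative_count, replace=False).tolist())
    planted_core = sorted(rng.choice(putative, size=params.n_core, replace=False).tolist())
    combined_genes = putative + _symbols("DG", params.n_combined - params.putative_count)
    af_genes = (
        sorted(rng.choice(union, size=params.af_union_overlap, replace=False).tolist())
        + _symbols("AG", params.n_af - params.af_union_overlap)
    )
    osahs_genes = (
        sorted(rng.choice(union, size=params.osahs_union_overlap, replace=False).tolist())
        + _symbols("OG", params.n_osahs - params.osahs_union_overlap)
    )
    af = GeneSet("AF", frozenset(af_genes))
    osahs = GeneSet("OSAHS", frozenset(osahs_genes))
    combined = GeneSet("AF_OSAHS", frozenset(combined_genes))

    # --- PPI with a planted high-centrality clique ----------------------
    periphery_pool = sorted(set(union) - set(putative))
    neighbors = sorted(
        rng.choice(periphery_pool, size=min(params.ppi_n_neighbors, len(periphery_pool)), replace=False).tolist()
    )
    ppi_nodes = sorted(set(putative) | set(neighbors))
    non_core = [g for g in ppi_nodes if g not in planted_core]

    edge_set: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str) -> None:
        if a != b:
            edge_set.add((min(a, b), max(a, b)))

    for i, a in enumerate(planted_core):  # clique
        for b in planted_core[i + 1:]:
            add_edge(a, b)
    # boosted external degree: all clique members share one peripheral
    # neighbor set, so inside any hub-induced subgraph their degree,
    # betweenness and closeness stay symmetric and jointly dominant
    n_periph = int(round(params.core_peripheral_frac * len(non_core)))
    shared = rng.choice(non_core, size=n_periph, replace=False)
    for a in planted_core:
        for b in shared:
            add_edge(a, str(b))

    # heavy-tailed background among non-core nodes
    w = rng.pareto(2.5, size=len(non_core)) + 1.0
    w = w / w.sum()
    attempts = 0
    while len(edge_set) < params.ppi_target_edges and attempts < 50 * params.ppi_target_edges:
        i, j = rng.choice(len(non_core), size=2, replace=False, p=w)
        add_edge(non_core[int(i)], non_core[int(j)])
        attempts += 1

    core_set = set(planted_core)
    ppi_edges = []
    for a, b in sorted(edge_set):
        lo, hi = params.score_core if (a in core_set or b in core_set) else params.score_background
        ppi_edges.append(InteractionEdge(a, b, round(float(rng.uniform(lo, hi)), 3)))

    # --- annotation collections with planted enrichment -----------------
    universe = sorted(set(union) | af.genes | osahs.genes | combined.genes)
    putative_set = set(putative)
    term_weights = np.asarray([params.planted_odds_ratio if g in putative_set else 1.0 for g in universe])
    term_weights = term_weights / term_weights.sum()
    uni_arr = np.asarray(universe)

    terms: list[AnnotationTerm] = []
    planted_terms: dict[str, list[str]] = {}
    lo, hi = params.term_size_range
    for category in ("BP", "MF", "CC", "pathway"):
        ids = []
        for t in range(params.n_planted_terms):
            size = int(rng.integers(lo, hi + 1))
            genes = rng.choice(uni_arr, size=size, replace=False, p=term_weights)
            tid = f"{category}:P{t + 1:03d}"
            terms.append(AnnotationTerm(tid, f"planted {category} term {t + 1}", category, frozenset(map(str, genes))))
            ids.append(tid)
        for t in range(params.n_null_terms):
            size = int(rng.integers(lo, hi + 1))
            genes = rng.choice(uni_arr, size=size, replace=False)
            tid = f"{category}:N{t + 1:03d}"
            terms.append(AnnotationTerm(tid, f"null {category} term {t + 1}", category, frozenset(map(str, genes))))
        planted_terms[category] = ids

    truth = {
        "seed": int(seed),
        "params": dataclasses.asdict(params),
        "n_raw_components": len(components),
        "active_ids": active_ids,
        "rescue_ids": sorted(rescue_ids),
        "promiscuous_components": promiscuous,
        "union_targets": union,
        "putative_targets": putative,
        "planted_core": planted_core,
        "ppi_nodes": ppi_nodes,
        "planted_terms": planted_terms,
    }
    return StudyFixture(
        components=components,
        rescue_ids=rescue_ids,
        mapping=mapping,
        raw_records=raw_records,
        af=af,
        osahs=osahs,
        combined=combined,
        ppi_edges=ppi_edges,
        terms=terms,
        truth=truth,
        params=params,
    )


def write_fixture(fixture: StudyFixture, outdir) -> dict[str, Path]:
    """Write every pipeline input file plus truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = paths["components"] = outdir / "components.tsv"
    with p.open("w") as fh:
        fh.write("component_id\tname\therbs\tob\tdl\trescued\tsource\n")
        for c in fixture.components:
            fh.write(
                f"{c.component_id}\t{c.name}\t{';'.join(sorted(c.herbs))}\t{c.ob}\t{c.dl}"
                f"\t{'true' if c.rescued else 'false'}\tsynthetic\n"
            )

    p = paths["rescue"] = outdir / "rescue.txt"
    p.write_text("".join(f"{cid}\n" for cid in sorted(fixture.rescue_ids)))

    p = paths["mapping"] = outdir / "mapping.tsv"
    with p.open("w") as fh:
        fh.write("raw_name\tsymbol\n")
        for raw in sorted(fixture.mapping):
            fh.write(f"{raw}\t{fixture.mapping[raw]}\n")

    p = paths["raw_targets"] = outdir / "raw_targets.tsv"
    with p.open("w") as fh:
        fh.write("component_id\traw_name\tevidence\n")
        for r in fixture.raw_records:
            fh.write(f"{r.component_id}\t{r.raw_name}\t{r.evidence}\n")

    for label, gs in (("af", fixture.af), ("osahs", fixture.osahs), ("combined", fixture.combined)):
        p = paths[label] = outdir / f"{label}_genes.txt"
        p.write_text("".join(f"{g}\n" for g in sorted(gs.genes)))

    p = paths["ppi"] = outdir / "ppi.tsv"
    write_interaction_table(fixture.ppi_edges, p)

    for category in ("BP", "MF", "CC", "pathway"):
        name = f"go_{category.lower()}.gmt" if category != "pathway" else "pathways.gmt"
        p = paths[f"gmt_{category}"] = outdir / name
        write_gmt([t for t in fixture.terms if t.category == category], p)

    p = paths["truth"] = outdir / "truth.json"
    p.write_text(json.dumps(fixture.truth, indent=2, sort_keys=True) + "\n")
    return paths
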