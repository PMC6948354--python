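"""End-to-end orchestration: filter -> assemble -> intersect -> networks ->
topology screen -> enrichment, with a machine-readable run report.

A run is driven either by a YAML config naming every input file or by a
``simulate`` block that generates a synthetic study in memory. Stages
execute in fixed order; every intermediate is written to the artifact
directory and every count in the report is recomputable from those files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .adme import DL_MIN_DEFAULT, OB_MIN_DEFAULT, filter_components
from .assembly import assemble, intersect_disease, standardize_symbols
from .enrichment import FDR_GO_DEFAULT, P_PATHWAY_DEFAULT, enrich, rows_to_table
from .errors import PipelineError
from .io import (
    read_component_table,
    read_gene_list,
    read_gmt,
    read_interaction_table,
    read_mapping_table,
    read_raw_target_table,
    write_network,
)
from .models import GeneSet
from .networks import (
    build_component_target_network,
    build_disease_mapping_network,
    build_target_pathway_network,
    count_network,
)
from .simulate import StudyFixture, StudyParams, generate_study, write_fixture
from .topology import build_ppi_graph, compute_centralities, median_screen

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    ob_min: float = OB_MIN_DEFAULT
    dl_min: float = DL_MIN_DEFAULT
    score_min: float = 0.4
    strict_hub: bool = False
    fdr_go: float = FDR_GO_DEFAULT
    p_pathway: float = P_PATHWAY_DEFAULT


@dataclass
class RunResult:
    """In-memory artifacts of a pipeline run plus the JSON-able report."""

    report: dict
    active: list = field(default_factory=list)
    venn: object = None
    screen: object = None
    enrichment_rows: list = field(default_factory=list)
    component_target_graph: object = None
    disease_graph: object = None
    pathway_graph: object = None
    ppi_graph: object = None


def run_study(fixture: StudyFixture, thresholds: Thresholds | None = None) -> RunResult:
    """Run the whole pipeline on an in-memory study fixture."""
    th = thresholds or Thresholds()
    report: dict = {"tool_version": __version__, "thresholds": dataclasses_asdict(th), "stages": {}}

    active, filt = filter_components(fixture.components, th.ob_min, th.dl_min, fixture.rescue_ids)
    report["stages"]["adme_filter"] = {
        "raw_components": filt.total,
        "passed": filt.passed,
        "rescued": filt.rescued,
        "dropped": filt.dropped,
        "active": filt.kept,
    }
    logger.info("ADME screen: %d of %d components active (%d rescued)", filt.kept, filt.total, filt.rescued)

    mapres = standardize_symbols(fixture.raw_records, fixture.mapping)
    asm = assemble(mapres.edges, active, total_raw=mapres.n_input)
    report["stages"]["target_assembly"] = {
        "raw_records": mapres.n_input,
        "mapped_records": mapres.n_mapped_records,
        "unmapped_records": len(mapres.unmapped),
        "deduplicated_edges": len(mapres.edges),
        "per_herb_counts": asm.per_herb_counts,
        "union_targets": len(asm.union_targets),
    }
    logger.info("assembly: %d mapped records, %d unique targets", mapres.n_mapped_records, len(asm.union_targets))

    venn = intersect_disease(asm.union_targets, fixture.af, fixture.osahs, fixture.combined)
    report["stages"]["disease_intersection"] = {
        "herb_af": venn.herb_af,
        "herb_osahs": venn.herb_osahs,
        "herb_both": venn.herb_both,
        "putative_targets": len(venn.putative_targets),
    }
    logger.info("disease intersection: %d putative therapeutic targets", len(venn.putative_targets))

    ct_graph = build_component_target_network(active, mapres.edges)
    n, m, per_type = count_network(ct_graph)
    report["stages"]["component_target_network"] = {"nodes": n, "edges": m, "per_type": per_type}

    disease_graph = build_disease_mapping_network(
        active, mapres.edges, venn.putative_targets, fixture.combined, fixture.combined.label
    )
    n, m, per_type = count_network(disease_graph)
    report["stages"]["disease_mapping_network"] = {"nodes": n, "edges": m, "per_type": per_type}

    kept_edges = [e for e in fixture.ppi_edges if e.combined_score >= th.score_min]
    ppi = build_ppi_graph(kept_edges)
    screen = median_screen(ppi, strict_hub=th.strict_hub)
    report["stages"]["topology_screen"] = {
        "ppi_nodes": ppi.number_of_nodes(),
        "ppi_edges": ppi.number_of_edges(),
        "hub_nodes": sorted(screen.hub_nodes),
        "core_targets": sorted(screen.core_targets),
        "thresholds": screen.thresholds,
    }
    logger.info(
        "topology screen: %d hubs -> %d core targets on %d-node PPI",
        len(screen.hub_nodes), len(screen.core_targets), ppi.number_of_nodes(),
    )

    rows = enrich(venn.putative_targets, fixture.terms, fdr_go=th.fdr_go, p_pathway=th.p_pathway)
    sig_counts = {}
    for cat in ("BP", "MF", "CC", "pathway"):
        sig_counts[cat] = sum(1 for r in rows if r.category == cat and r.significant)
    report["stages"]["enrichment"] = {
        "tested_terms": len(rows),
        "significant_per_category": sig_counts,
    }
    logger.info("enrichment: significant terms per category %s", sig_counts)

    sig_pathways = [r for r in rows if r.category == "pathway" and r.significant]
    pw_graph = build_target_pathway_network(active, mapres.edges, venn.putative_targets, sig_pathways)
    n, m, per_type = count_network(pw_graph)
    report["stages"]["target_pathway_network"] = {"nodes": n, "edges": m, "per_type": per_type}

    return RunResult(
        report=report,
        active=active,
        venn=venn,
        screen=screen,
        enrichment_rows=rows,
        component_target_graph=ct_graph,
        disease_graph=disease_graph,
        pathway_graph=pw_graph,
        ppi_graph=ppi,
    )


def dataclasses_asdict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_fixture_from_files(inputs: dict, score_min: float = 0.0) -> StudyFixture:
    """Assemble a StudyFixture from the input files named in a config
    ``inputs`` block (keys: components, rescue, mapping, raw_targets, af,
    osahs, combined, ppi, gmt: {BP, MF, CC, pathway})."""
    components = read_component_table(inputs["components"])
    rescue = frozenset(read_gene_list(inputs["rescue"])) if inputs.get("rescue") else frozenset()
    mapping = read_mapping_table(inputs["mapping"])
    raw_records = read_raw_target_table(inputs["raw_targets"])
    af = GeneSet("AF", frozenset(read_gene_list(inputs["af"])))
    osahs = GeneSet("OSAHS", frozenset(read_gene_list(inputs["osahs"])))
    combined = GeneSet("AF_OSAHS", frozenset(read_gene_list(inputs["combined"])))
    ppi_edges = read_interaction_table(inputs["ppi"], score_min=score_min)
    terms = []
    for category, path in (inputs.get("gmt") or {}).items():
        terms.extend(read_gmt(path, category=category))
    return StudyFixture(
        components=components,
        rescue_ids=rescue,
        mapping=mapping,
        raw_records=raw_records,
        af=af,
        osahs=osahs,
        combined=combined,
        ppi_edges=ppi_edges,
        terms=terms,
        truth={},
    )


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the pipeline from a YAML config (path or already-loaded dict).

    The config either names every input file under ``inputs`` or carries a
    ``simulate`` block (``seed`` plus optional :class:`StudyParams` field
    overrides). Artifacts (networks, centrality table, screen, enrichment
    table, report.json) are written to ``outdir``.
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        if not config_path.exists():
            raise PipelineError(f"config file not found: {config_path}")
        config = yaml.safe_load(config_path.read_text())

    th = Thresholds(**(config.get("thresholds") or {}))
    outdir = Path(outdir or config.get("outdir") or "netpharm_run")
    outdir.mkdir(parents=True, exist_ok=True)

    input_hashes = {}
    if "simulate" in config:
        sim = dict(config["simulate"])
        seed = int(sim.pop("seed", 0))
        params = StudyParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
        fixture = generate_study(seed, params)
        fixture_dir = outdir / "fixture"
        write_fixture(fixture, fixture_dir)
        config_echo = {"simulate": {"seed": seed, **sim}}
    elif "inputs" in config:
        inputs = config["inputs"]
        missing = [
            str(p) for p in _iter_paths(inputs) if not Path(p).exists()
        ]
        if missing:
            raise PipelineError(f"missing input file(s): {', '.join(missing)}")
        input_hashes = {str(p): _sha256(p) for p in _iter_paths(inputs)}
        fixture = load_fixture_from_files(inputs)
        config_echo = {"inputs": inputs}
    else:
        raise PipelineError("config must contain an 'inputs' or a 'simulate' block")

    result = run_study(fixture, th)
    report = result.report
    report["config"] = config_echo
    report["input_hashes"] = input_hashes

    write_network(result.component_target_graph, outdir / "component_target.sif", "sif")
    write_network(result.disease_graph, outdir / "disease_mapping.graphml", "graphml")
    if result.pathway_graph.number_of_nodes():
        write_network(result.pathway_graph, outdir / "target_pathway.sif", "sif")
    if result.ppi_graph.number_of_nodes():
        write_network(result.ppi_graph, outdir / "ppi.graphml", "graphml")
        cents = compute_centralities(result.ppi_graph)
        with (outdir / "centrality.tsv").open("w") as fh:
            fh.write("node\tdc\tbc\tcc\n")
            for node in sorted(result.ppi_graph.nodes):
                fh.write(f"{node}\t{cents['dc'][node]}\t{cents['bc'][node]:.6g}\t{cents['cc'][node]:.6g}\n")
    rows_to_table(result.enrichment_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    (outdir / "screen.json").write_text(
        json.dumps(
            {
                "hub_nodes": sorted(result.screen.hub_nodes),
                "core_targets": sorted(result.screen.core_targets),
                "thresholds": result.screen.thresholds,
            },
            indent=2,
        )
        + "\n"
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _iter_paths(inputs: dict):
    for key, value in inputs.items():
        if key == "gmt":
            yield from (value or {}).values()
        elif value:
            yield value
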