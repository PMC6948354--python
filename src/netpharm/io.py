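"""Readers and writers for every file format the pipeline touches.

Canonical table dialect is tab-separated with a header row; comma-separated
is accepted via ``sep=","``. Gene symbols are uppercased on ingest so all
downstream comparisons are case-insensitive by construction. Networks are
exported as SIF or GraphML (both consumable by Cytoscape-class tools).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

from .errors import MappingConflictError, ParseError, SchemaError
from .models import AnnotationTerm, Component, InteractionEdge, RawTargetRecord

logger = logging.getLogger(__name__)

_COMPONENT_COLUMNS = ("component_id", "name", "herbs", "ob", "dl")
_INTERACTION_COLUMNS = ("gene_a", "gene_b", "combined_score")

HERB_DELIMITER = ";"


def _check_header(fieldnames: Iterable[str] | None, required: Iterable[str], path) -> None:
    present = set(fieldnames or ())
    for col in required:
        if col not in present:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_component_table(path, sep: str = "\t") -> list[Component]:
    """Read a component table into :class:`Component` records.

    Required columns: component_id, name, herbs (``;``-delimited herb codes),
    ob, dl. Optional: rescued (truthy flag), source. Rows with missing OB or
    DL are rejected unless their rescued flag is set.
    """
    path = Path(path)
    components: list[Component] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        _check_header(reader.fieldnames, _COMPONENT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            rescued = _parse_flag(row.get("rescued", ""))
            ob_s, dl_s = (row["ob"] or "").strip(), (row["dl"] or "").strip()
            if not ob_s or not dl_s:
                if rescued:
                    # literature-rescued entries may lack ADME values; they
                    # bypass the cutoffs anyway
                    ob_s, dl_s = ob_s or "0", dl_s or "0"
                else:
                    raise ParseError(f"missing OB/DL for non-rescued component {row['component_id']!r}", lineno)
            try:
                ob = float(ob_s)
            except ValueError:
                raise ParseError(f"non-numeric ob value {ob_s!r}", lineno) from None
            try:
                dl = float(dl_s)
            except ValueError:
                raise ParseError(f"non-numeric dl value {dl_s!r}", lineno) from None
            herbs = frozenset(h.strip() for h in row["herbs"].split(HERB_DELIMITER) if h.strip())
            try:
                components.append(
                    Component(
                        component_id=row["component_id"].strip(),
                        name=row["name"].strip(),
                        herbs=herbs,
                        ob=ob,
                        dl=dl,
                        rescued=rescued,
                        source=(row.get("source") or "").strip(),
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
    ids = [c.component_id for c in components]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"duplicate component_id values: {dup}")
    return components


def _parse_flag(value: str | None) -> bool:
    return (value or "").strip().lower() in ("1", "true", "yes", "y")


def read_raw_target_table(path, sep: str = "\t") -> list[RawTargetRecord]:
    """Read component->raw-protein-name records (columns: component_id,
    raw_name, optional evidence)."""
    path = Path(path)
    records: list[RawTargetRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        _check_header(reader.fieldnames, ("component_id", "raw_name"), path)
        for lineno, row in enumerate(reader, start=2):
            evidence = (row.get("evidence") or "validated").strip() or "validated"
            if evidence not in ("validated", "predicted"):
                raise ParseError(f"unknown evidence class {evidence!r}", lineno)
            records.append(RawTargetRecord(row["component_id"].strip(), row["raw_name"].strip(), evidence))
    return records


def read_mapping_table(path, sep: str = "\t") -> dict[str, str]:
    """Read a raw-protein-name -> official-gene-symbol mapping table.

    Duplicate raw names mapping to different symbols are a curation error
    and raise :class:`MappingConflictError`.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        _check_header(reader.fieldnames, ("raw_name", "symbol"), path)
        for lineno, row in enumerate(reader, start=2):
            raw = row["raw_name"].strip()
            symbol = row["symbol"].strip().upper()
            if not symbol:
                raise ParseError(f"empty symbol for raw name {raw!r}", lineno)
            if raw in mapping and mapping[raw] != symbol:
                raise MappingConflictError(
                    f"{path}: raw name {raw!r} maps to both {mapping[raw]!r} and {symbol!r}"
                )
            mapping[raw] = symbol
    return mapping


def read_gene_list(path, label: str | None = None) -> list[str]:
    """Read a one-symbol-per-line gene list (blank lines and ``#`` comments
    ignored); returns uppercased symbols, duplicates preserved in order."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.upper())
    return genes


def read_gmt(path, category: str = "pathway") -> list[AnnotationTerm]:
    """Read a GMT annotation collection: one term per line, tab-separated
    ``term_id<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are collapsed. A line with fewer than three
    fields is a parse error carrying its line number.
    """
    path = Path(path)
    terms: list[AnnotationTerm] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line has {len(fields)} fields, need >= 3", lineno)
            term_id, description = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(f"term {term_id!r} has no genes", lineno)
            terms.append(AnnotationTerm(term_id, description, category, genes))
    return terms


def write_gmt(terms: Iterable[AnnotationTerm], path) -> None:
    with Path(path).open("w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.genes)]) + "\n")


def read_interaction_table(path, score_min: float = 0.0, sep: str = "\t") -> list[InteractionEdge]:
    """Read a PPI edge table (columns gene_a, gene_b, combined_score).

    Edges below ``score_min`` are dropped; self-loops are dropped with a
    warning; duplicate unordered pairs are collapsed keeping the maximum
    combined score (conservative confidence).
    """
    if not (0.0 <= score_min <= 1.0):
        raise ValueError(f"score_min must be in [0, 1], got {score_min}")
    path = Path(path)
    best: dict[tuple[str, str], InteractionEdge] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        _check_header(reader.fieldnames, _INTERACTION_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                score = float(row["combined_score"])
            except ValueError:
                raise ParseError(f"non-numeric combined_score {row['combined_score']!r}", lineno) from None
            if not (0.0 <= score <= 1.0):
                raise ParseError(f"combined_score {score} outside [0, 1]", lineno)
            a, b = row["gene_a"].strip().upper(), row["gene_b"].strip().upper()
            if a == b:
                logger.warning("%s line %d: dropping self-loop on %s", path, lineno, a)
                continue
            if score < score_min:
                continue
            edge = InteractionEdge(a, b, score)
            prev = best.get(edge.pair)
            if prev is None or score > prev.combined_score:
                best[edge.pair] = edge
    return [best[p] for p in sorted(best)]


def write_interaction_table(edges: Iterable[InteractionEdge], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.combined_score:.3f}\n")


# ---------------------------------------------------------------------------
# network export / import

SIF_RELATION = "pp"


def write_network(graph: nx.Graph, path, fmt: str = "sif") -> None:
    """Export a graph as SIF or GraphML.

    A round-trip read of the written file reconstructs the same node and
    edge sets. The graph must be nonempty.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty graph")
    path = Path(path)
    if fmt == "sif":
        with path.open("w") as fh:
            for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in graph.edges()):
                fh.write(f"{u}\t{SIF_RELATION}\t{v}\n")
            for node in sorted(str(n) for n in nx.isolates(graph)):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {fmt!r} (expected 'sif' or 'graphml')")


def read_network(path, fmt: str = "sif") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if fmt == "sif":
        g = nx.Graph()
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 1 and fields[0].strip():
                    g.add_node(fields[0].strip())
                elif len(fields) >= 3:
                    source, _rel, targets = fields[0], fields[1], fields[2:]
                    for t in targets:
                        g.add_edge(source.strip(), t.strip())
                elif any(f.strip() for f in fields):
                    raise ParseError(f"malformed SIF line {line!r}", lineno)
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {fmt!r} (expected 'sif' or 'graphml')")
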