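"""Construction of the study's typed networks.

Three networks are built over the screened data: (1) the bipartite
component-target network; (2) the disease-mapping network joining
components, putative therapeutic targets, the remaining disease genes and a
single disease node; (3) the component-target-pathway network adding
pathway-typed nodes from the enrichment output. All are simple undirected
``networkx`` graphs carrying a ``node_type`` attribute on every node.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import networkx as nx

from .models import Component, ComponentTargetEdge, EnrichmentRow, GeneSet

NODE_TYPES = ("component", "target", "disease_target", "disease", "pathway")


def _check_simple_typed(graph: nx.Graph) -> None:
    assert not any(u == v for u, v in graph.edges()), "self-loop in typed graph"
    for node, data in graph.nodes(data=True):
        assert data.get("node_type") in NODE_TYPES, f"untyped node {node!r}"


def build_component_target_network(
    components: Sequence[Component],
    edges: Sequence[ComponentTargetEdge],
) -> nx.Graph:
    """Bipartite component-target graph.

    Components with zero edges are omitted (isolated nodes carry no
    information and distort degree statistics); every edge must reference a
    supplied component. Per-component degree equals its distinct target
    count.
    """
    known = {c.component_id for c in components}
    g = nx.Graph()
    for edge in edges:
        if edge.component_id not in known:
            raise KeyError(f"edge references unknown component {edge.component_id!r}")
        g.add_node(edge.component_id, node_type="component")
        g.add_node(edge.symbol, node_type="target")
        g.add_edge(edge.component_id, edge.symbol)
    _check_simple_typed(g)
    # bipartiteness: no component-component or target-target edges
    for u, v in g.edges():
        assert g.nodes[u]["node_type"] != g.nodes[v]["node_type"]
    return g


def build_disease_mapping_network(
    components: Sequence[Component],
    edges: Sequence[ComponentTargetEdge],
    putative_targets: Iterable[str],
    combined: GeneSet,
    disease_label: str = "AF_OSAHS",
) -> nx.Graph:
    """Component - putative target - disease gene - disease network.

    Nodes are: every component with at least one edge to a putative target;
    every gene of the combined disease set (putative ones typed ``target``,
    the rest ``disease_target``); and one ``disease`` node linked to every
    disease gene. The putative targets are counted once, inside the disease
    set, so the node count decomposes as
    ``qualifying components + |combined| + 1``.
    """
    putative = frozenset(g.upper() for g in putative_targets)
    if not putative:
        raise ValueError("putative target set is empty")
    if not putative <= combined.genes:
        raise ValueError("putative targets must be a subset of the combined disease set")
    known = {c.component_id for c in components}
    g = nx.Graph()
    for gene in combined.genes:
        g.add_node(gene, node_type="target" if gene in putative else "disease_target")
    g.add_node(disease_label, node_type="disease")
    for gene in combined.genes:
        g.add_edge(gene, disease_label)
    for edge in edges:
        if edge.symbol in putative:
            if edge.component_id not in known:
                raise KeyError(f"edge references unknown component {edge.component_id!r}")
            g.add_node(edge.component_id, node_type="component")
            g.add_edge(edge.component_id, edge.symbol)
    _check_simple_typed(g)
    return g


def build_target_pathway_network(
    components: Sequence[Component],
    edges: Sequence[ComponentTargetEdge],
    putative_targets: Iterable[str],
    pathways: Sequence[EnrichmentRow],
) -> nx.Graph:
    """Component - putative therapeutic target - pathway network.

    Component-target edges are kept for putative targets; each significant
    pathway row contributes a pathway node linked to its overlap genes.
    """
    putative = frozenset(g.upper() for g in putative_targets)
    known = {c.component_id for c in components}
    g = nx.Graph()
    for edge in edges:
        if edge.symbol in putative:
            if edge.component_id not in known:
                raise KeyError(f"edge references unknown component {edge.component_id!r}")
            g.add_node(edge.component_id, node_type="component")
            g.add_node(edge.symbol, node_type="target")
            g.add_edge(edge.component_id, edge.symbol)
    for row in pathways:
        if row.category != "pathway":
            continue
        g.add_node(row.term_id, node_type="pathway")
        for gene in row.overlap_genes & putative:
            g.add_node(gene, node_type="target")
            g.add_edge(gene, row.term_id)
    _check_simple_typed(g)
    return g


def count_network(graph: nx.Graph) -> tuple[int, int, dict[str, int]]:
    """Exact node / edge / per-type tallies; per-type counts sum to the
    node count."""
    per_type = Counter(data.get("node_type", "untyped") for _, data in graph.nodes(data=True))
    counts = dict(sorted(per_type.items()))
    assert sum(counts.values()) == graph.number_of_nodes()
    return graph.number_of_nodes(), graph.number_of_edges(), counts
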