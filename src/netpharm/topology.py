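"""Topological screening of the PPI network for core targets.

Three node statistics drive the screen: degree centrality (DC, raw incident
edge count), betweenness centrality (BC, fraction of shortest paths passing
through the node, endpoints excluded) and closeness centrality (CC, inverse
mean geodesic distance, scaled by component size so disconnected graphs are
handled rather than truncated).

The screen is two-stage. Stage 1 keeps *hub* nodes whose degree is at least
twice the network-wide median degree. Stage 2 extracts the hub-induced
subgraph, recomputes all three centralities on it, and keeps as *core
targets* the hubs meeting or exceeding the subgraph median of DC, BC and CC
simultaneously. Medians for even counts are the mean of the two central
order statistics; all thresholds are recorded so runs are auditable.
"""

from __future__ import annotations

import logging
from statistics import median
from typing import Mapping

import networkx as nx

from .models import ScreenResult

logger = logging.getLogger(__name__)


def degree_centrality(graph: nx.Graph) -> dict[str, int]:
    """Raw degree (incident-edge count), not normalized."""
    return {n: d for n, d in graph.degree()}


def betweenness_centrality(graph: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness, all shortest paths counted, endpoints
    excluded; if normalized, divided by (n-1)(n-2)/2."""
    return nx.betweenness_centrality(graph, normalized=normalized)


def closeness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Component-scaled closeness: for a node v in a connected component of
    size s inside a graph of n nodes,
    ``cc(v) = ((s-1)/(n-1)) * ((s-1)/sum of distances from v)``;
    an isolated node scores 0."""
    return nx.closeness_centrality(graph, wf_improved=True)


def compute_centralities(graph: nx.Graph) -> dict[str, dict]:
    """DC, BC and CC for every node, as a column-oriented table."""
    return {
        "dc": degree_centrality(graph),
        "bc": betweenness_centrality(graph, normalized=False),
        "cc": closeness_centrality(graph),
    }


def _at_least_median(values: Mapping[str, float], strict: bool = False) -> tuple[set, float]:
    med = float(median(values.values()))
    if strict:
        keep = {n for n, v in values.items() if v > med}
    else:
        keep = {n for n, v in values.items() if v >= med}
    return keep, med


def median_screen(graph: nx.Graph, strict_hub: bool = False) -> ScreenResult:
    """Two-stage median screen nominating core targets.

    Stage 1: hub nodes satisfy ``dc >= 2 * median(dc)`` over the whole
    graph (``>`` instead when ``strict_hub``). Stage 2: on the hub-induced
    subgraph, core targets meet or exceed the recomputed medians of DC, BC
    and CC simultaneously. An empty hub set yields an empty (warned, not
    erroneous) result.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot screen an empty graph")
    dc = degree_centrality(graph)
    stage1_median = float(median(dc.values()))
    threshold = 2.0 * stage1_median
    if strict_hub:
        hubs = {n for n, d in dc.items() if d > threshold}
    else:
        hubs = {n for n, d in dc.items() if d >= threshold}
    thresholds: dict = {
        "stage1_median_dc": stage1_median,
        "stage1_dc_threshold": threshold,
        "stage1_strict": strict_hub,
    }
    if not hubs:
        logger.warning("degree screen kept no hub nodes (median dc=%.3g); core set is empty", stage1_median)
        return ScreenResult(hub_nodes=frozenset(), core_targets=frozenset(), thresholds=thresholds)

    sub = graph.subgraph(hubs)
    cents = compute_centralities(sub)
    keep_dc, med_dc = _at_least_median(cents["dc"])
    keep_bc, med_bc = _at_least_median(cents["bc"])
    keep_cc, med_cc = _at_least_median(cents["cc"])
    core = keep_dc & keep_bc & keep_cc
    thresholds.update({
        "stage2_median_dc": med_dc,
        "stage2_median_bc": med_bc,
        "stage2_median_cc": med_cc,
    })
    return ScreenResult(hub_nodes=frozenset(hubs), core_targets=frozenset(core), thresholds=thresholds)


def build_ppi_graph(edges) -> nx.Graph:
    """Assemble interaction edges into a simple undirected graph with the
    combined score as edge attribute."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b, combined_score=e.combined_score)
    return g
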