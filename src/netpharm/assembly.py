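"""Target standardization, per-herb accounting, and disease intersection.

Raw component-target records carry protein names as emitted by source
databases; they are standardized to official human gene symbols through a
mapping table, deduplicated per (component, symbol) pair, attributed to
herbs, and intersected with disease gene sets to yield the putative
therapeutic targets that seed all downstream network analysis.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import EmptyIntersectionError, MappingConflictError
from .models import AssemblyReport, Component, ComponentTargetEdge, GeneSet, RawTargetRecord, VennResult

logger = logging.getLogger(__name__)


@dataclass
class MappingResult:
    """Outcome of symbol standardization.

    ``edges`` are deduplicated (component, symbol) pairs; ``unmapped``
    records are returned, never silently dropped. Record-level conservation
    holds as ``n_mapped_records + len(unmapped) == n_input``.
    """

    edges: list[ComponentTargetEdge]
    unmapped: list[RawTargetRecord]
    n_input: int
    n_mapped_records: int
    duplicates_collapsed: int = 0

    def __post_init__(self):
        assert self.n_mapped_records + len(self.unmapped) == self.n_input


def standardize_symbols(
    records: Sequence[RawTargetRecord],
    mapping: Mapping[str, str] | Iterable[tuple[str, str]],
) -> MappingResult:
    """Convert raw protein names to official gene symbols.

    ``mapping`` is a raw-name -> symbol table (a mapping or (raw, symbol)
    pairs); it must be nonempty and single-valued — a raw name bound to two
    different symbols raises :class:`MappingConflictError` naming the
    conflict. Records whose raw name is absent from the table are collected
    in the unmapped list and logged.
    """
    items = list(mapping.items()) if isinstance(mapping, Mapping) else list(mapping)
    if not items:
        raise ValueError("mapping table is empty")
    clean: dict[str, str] = {}
    for raw, symbol in items:
        up = symbol.upper()
        if raw in clean and clean[raw] != up:
            raise MappingConflictError(f"raw name {raw!r} maps to both {clean[raw]!r} and {up!r}")
        clean[raw] = up

    seen: set[tuple[str, str]] = set()
    edges: list[ComponentTargetEdge] = []
    unmapped: list[RawTargetRecord] = []
    n_mapped = 0
    dups = 0
    for rec in records:
        symbol = clean.get(rec.raw_name)
        if symbol is None:
            unmapped.append(rec)
            continue
        n_mapped += 1
        key = (rec.component_id, symbol)
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        edges.append(ComponentTargetEdge(rec.component_id, symbol, rec.evidence))
    if unmapped:
        logger.info(
            "%d of %d raw target records had no symbol mapping (e.g. %r)",
            len(unmapped), len(records), unmapped[0].raw_name,
        )
    return MappingResult(
        edges=edges,
        unmapped=unmapped,
        n_input=len(records),
        n_mapped_records=n_mapped,
        duplicates_collapsed=dups,
    )


def assemble(
    edges: Iterable[ComponentTargetEdge],
    components: Iterable[Component],
    total_raw: int | None = None,
) -> AssemblyReport:
    """Compute per-herb mapped-record counts and the global target union.

    Each mapped edge is attributed to every herb its component belongs to,
    so multi-herb compounds contribute to several per-herb counts (the herb
    counts then sum to more than total_mapped). An edge referencing an
    unknown component is an error.
    """
    edges = list(edges)
    by_id = {c.component_id: c for c in components}
    per_herb: dict[str, int] = {}
    union: set[str] = set()
    for edge in edges:
        comp = by_id.get(edge.component_id)
        if comp is None:
            raise KeyError(f"edge references unknown component {edge.component_id!r}")
        for herb in comp.herbs:
            per_herb[herb] = per_herb.get(herb, 0) + 1
        union.add(edge.symbol)
    return AssemblyReport(
        total_raw=len(edges) if total_raw is None else total_raw,
        total_mapped=len(edges),
        per_herb_counts=dict(sorted(per_herb.items())),
        union_targets=frozenset(union),
    )


def intersect_disease(
    union_targets: Iterable[str],
    af: GeneSet,
    osahs: GeneSet,
    combined: GeneSet,
) -> VennResult:
    """Intersect herb targets with the disease gene sets.

    The putative therapeutic targets are ``union_targets & combined.genes``
    (the combined disease list is the operative screen; the per-disease
    intersections are descriptive statistics). An empty putative set aborts
    with :class:`EmptyIntersectionError` because every downstream stage is
    undefined on an empty seed set.
    """
    union = frozenset(g.upper() for g in union_targets)
    if not combined.genes:
        raise ValueError("combined disease gene set is empty")
    herb_af = len(union & af.genes)
    herb_osahs = len(union & osahs.genes)
    herb_both = len(union & af.genes & osahs.genes)
    putative = union & combined.genes
    if not putative:
        raise EmptyIntersectionError(
            "no herb target intersects the combined disease set "
            f"(|union|={len(union)}, |combined|={len(combined.genes)}, "
            f"herb∩AF={herb_af}, herb∩OSAHS={herb_osahs}, herb∩both={herb_both})"
        )
    return VennResult(herb_af=herb_af, herb_osahs=herb_osahs, herb_both=herb_both, putative_targets=putative)
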