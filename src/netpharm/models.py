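"""Domain types shared across the pipeline.

The pipeline models a traditional-herbal-medicine study: herb constituents
(compounds) with ADME screening parameters, the protein targets they hit
(standardized to official human gene symbols), disease gene sets, a
protein-protein interaction graph with per-edge confidence, and annotation
collections (GO categories and pathways) used for over-representation
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

HUMAN = "Homo sapiens"

#: Herb codes used by the default study: Ziziphi Spinosae Semen (SZR),
#: Nardostachys Chinensis (GS), Corydalis Rhizoma (YHS), Agrimony (XHC),
#: Tribulus terrestris (JL), Concha Ostreae (ML).
DEFAULT_HERBS = ("SZR", "GS", "YHS", "XHC", "JL", "ML")


@dataclass(frozen=True)
class Component:
    """A herb constituent with its ADME screening parameters.

    Parameters
    ----------
    component_id:
        Opaque unique key within a study.
    name:
        Display name of the compound.
    herbs:
        Nonempty set of herb codes the compound belongs to (a compound may
        occur in more than one herb).
    ob:
        Oral bioavailability in percent, finite and >= 0.
    dl:
        Drug-likeness, dimensionless in [0, 1].
    rescued:
        True if the compound is kept as active on literature evidence even
        though it fails the ADME cutoffs.
    source:
        Free-text provenance tag.
    """

    component_id: str
    name: str
    herbs: frozenset[str]
    ob: float
    dl: float
    rescued: bool = False
    source: str = ""

    def __post_init__(self):
        if not self.component_id:
            raise ValueError("component_id must be nonempty")
        if not self.herbs:
            raise ValueError(f"component {self.component_id}: herbs must be nonempty")
        if not isinstance(self.herbs, frozenset):
            object.__setattr__(self, "herbs", frozenset(self.herbs))
        if not (math.isfinite(self.ob) and self.ob >= 0):
            raise ValueError(f"component {self.component_id}: ob must be finite and >= 0, got {self.ob}")
        if not (0.0 <= self.dl <= 1.0):
            raise ValueError(f"component {self.component_id}: dl must be in [0, 1], got {self.dl}")

    def with_rescued(self) -> "Component":
        return replace(self, rescued=True)


@dataclass(frozen=True)
class TargetGene:
    """A target protein standardized to an official (human) gene symbol."""

    raw_name: str
    symbol: str | None = None
    organism: str = HUMAN

    def __post_init__(self):
        if self.symbol is not None:
            if not self.symbol or any(c.isspace() for c in self.symbol):
                raise ValueError(f"symbol must be nonempty and whitespace-free, got {self.symbol!r}")
            object.__setattr__(self, "symbol", self.symbol.upper())
        if self.organism != HUMAN:
            raise ValueError(f"organism is fixed to {HUMAN!r}")


@dataclass(frozen=True)
class ComponentTargetEdge:
    """One (component, target gene) link, with its evidence class."""

    component_id: str
    symbol: str
    evidence: str = "validated"  # "validated" | "predicted"

    def __post_init__(self):
        if self.evidence not in ("validated", "predicted"):
            raise ValueError(f"evidence must be 'validated' or 'predicted', got {self.evidence!r}")
        object.__setattr__(self, "symbol", self.symbol.upper())


@dataclass(frozen=True)
class RawTargetRecord:
    """A component-target record as emitted by a source database, before
    the protein name is standardized to a gene symbol."""

    component_id: str
    raw_name: str
    evidence: str = "validated"


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene symbols (e.g. a disease gene list)."""

    label: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.label!r}: genes must be nonempty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


ANNOTATION_CATEGORIES = ("BP", "MF", "CC", "pathway")


@dataclass(frozen=True)
class AnnotationTerm:
    """One annotation term (a GO category or a pathway) and its gene set."""

    term_id: str
    term_name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self):
        if self.category not in ANNOTATION_CATEGORIES:
            raise ValueError(
                f"term {self.term_id}: category must be one of {ANNOTATION_CATEGORIES}, got {self.category!r}"
            )
        if not self.genes:
            raise ValueError(f"term {self.term_id}: genes must be nonempty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected protein-protein interaction with a confidence score.

    The combined score is the interaction confidence in [0, 1]; higher means
    more confident. Self-loops are rejected.
    """

    gene_a: str
    gene_b: str
    combined_score: float

    def __post_init__(self):
        object.__setattr__(self, "gene_a", self.gene_a.upper())
        object.__setattr__(self, "gene_b", self.gene_b.upper())
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop not allowed: {self.gene_a}")
        if not (0.0 <= self.combined_score <= 1.0):
            raise ValueError(f"combined_score must be in [0, 1], got {self.combined_score}")

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical unordered node pair."""
        a, b = sorted((self.gene_a, self.gene_b))
        return a, b


@dataclass
class FilterReport:
    """Counts from the ADME screen."""

    total: int = 0
    passed: int = 0  # passed both cutoffs
    rescued: int = 0  # failed cutoffs but whitelisted
    dropped: int = 0
    missing_rescue_ids: list[str] = field(default_factory=list)

    @property
    def kept(self) -> int:
        return self.passed + self.rescued


@dataclass
class AssemblyReport:
    """Accounting of target standardization and per-herb attribution."""

    total_raw: int
    total_mapped: int
    per_herb_counts: dict[str, int]
    union_targets: frozenset[str]


@dataclass
class VennResult:
    """Intersection cardinalities between herb targets and disease gene sets."""

    herb_af: int
    herb_osahs: int
    herb_both: int
    putative_targets: frozenset[str]


@dataclass
class ScreenResult:
    """Result of the two-stage median-centrality screen."""

    hub_nodes: frozenset[str]
    core_targets: frozenset[str]
    thresholds: dict

    def __post_init__(self):
        assert self.core_targets <= self.hub_nodes


@dataclass
class EnrichmentRow:
    """One annotation term's over-representation statistics.

    k of the n query genes fall in the term, which annotates K of the N
    universe genes; p_value is the hypergeometric upper tail P(X >= k),
    fdr the Benjamini-Hochberg adjusted value within the term's category,
    and rich_factor the overlap fraction k / K.
    """

    term_id: str
    term_name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float
    rich_factor: float
    overlap_genes: frozenset[str]
    significant: bool
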