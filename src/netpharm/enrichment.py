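"""Over-representation analysis of gene sets against annotation collections.

For a query of n genes drawn from a universe of N annotated genes, a term
annotating K universe genes and overlapping the query in k genes is scored
with the hypergeometric upper tail P(X >= k). P-values are adjusted with
Benjamini-Hochberg step-up separately within each annotation category (BP,
MF, CC, pathway), since each category is its own test family. GO categories
are flagged significant at FDR < 0.01; pathways at raw p < 0.05. Each row
also carries the rich factor k / K, the overlap fraction used as the x-axis
of enrichment dot plots.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ANNOTATION_CATEGORIES, AnnotationTerm, EnrichmentRow

FDR_GO_DEFAULT = 0.01
P_PATHWAY_DEFAULT = 0.05


def hypergeom_upper(N, K, n, k):
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the query genes falling in a term of size K when n genes are
    drawn from a universe of N. Accepts scalars or array-likes
    (broadcast together). Requires 0 <= K <= N, 0 <= n <= N,
    0 <= k <= min(K, n).
    """
    N, K, n, k = (np.asarray(x) for x in (N, K, n, k))
    if np.any(K > N) or np.any(n > N) or np.any(k > np.minimum(K, n)) or np.any(
        (N < 0) | (K < 0) | (n < 0) | (k < 0)
    ):
        raise ValueError("require 0 <= K <= N, 0 <= n <= N, 0 <= k <= min(K, n)")
    p = stats.hypergeom.sf(k - 1, N, K, n)
    # clip floating noise; the tail probability is in (0, 1]
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return float(p) if p.ndim == 0 else p


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, clamped at 1; output order
    matches input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich(
    query: Iterable[str],
    terms: Sequence[AnnotationTerm],
    universe: Iterable[str] | None = None,
    fdr_go: float = FDR_GO_DEFAULT,
    p_pathway: float = P_PATHWAY_DEFAULT,
) -> list[EnrichmentRow]:
    """Over-representation analysis of ``query`` against ``terms``.

    The universe defaults to the union of all genes annotated in the
    collection; an explicit background list may be supplied instead. Only
    terms overlapping the query (k >= 1) are tested and emitted; the BH
    family within each category consists of exactly those tested terms.
    Rows are sorted by ascending p-value within category.
    """
    query_set = frozenset(g.upper() for g in query)
    if universe is None:
        universe_set: frozenset[str] = frozenset().union(*(t.genes for t in terms)) if terms else frozenset()
    else:
        universe_set = frozenset(g.upper() for g in universe)
    query_in_universe = query_set & universe_set
    N = len(universe_set)
    n = len(query_in_universe)
    if n == 0:
        raise ValueError("query does not intersect the annotation universe")

    tested: list[tuple[AnnotationTerm, int, int, frozenset[str]]] = []
    for term in terms:
        term_genes = term.genes & universe_set
        overlap = term_genes & query_in_universe
        if overlap:
            tested.append((term, len(overlap), len(term_genes), overlap))

    rows: list[EnrichmentRow] = []
    for category in ANNOTATION_CATEGORIES:
        fam = [t for t in tested if t[0].category == category]
        if not fam:
            continue
        pvals = [hypergeom_upper(N, K, n, k) for _, k, K, _ in fam]
        fdrs = bh_fdr(pvals)
        for (term, k, K, overlap), p, fdr in zip(fam, pvals, fdrs):
            significant = (p < p_pathway) if category == "pathway" else (fdr < fdr_go)
            rows.append(
                EnrichmentRow(
                    term_id=term.term_id,
                    term_name=term.term_name,
                    category=category,
                    k=k, K=K, n=n, N=N,
                    p_value=p,
                    fdr=fdr,
                    rich_factor=k / K,
                    overlap_genes=overlap,
                    significant=significant,
                )
            )
    rows.sort(key=lambda r: (ANNOTATION_CATEGORIES.index(r.category), r.p_value, r.term_id))
    return rows


def rows_to_table(rows: Sequence[EnrichmentRow]):
    """EnrichmentRows as a tidy DataFrame (dot-plot-ready: rich_factor,
    p_value, k per term)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "term_name": [r.term_name for r in rows],
            "category": [r.category for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "p_value": [r.p_value for r in rows],
            "fdr": [r.fdr for r in rows],
            "rich_factor": [r.rich_factor for r in rows],
            "significant": [r.significant for r in rows],
            "overlap_genes": [";".join(sorted(r.overlap_genes)) for r in rows],
        }
    )
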