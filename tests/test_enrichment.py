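"""Hypergeometric tail, BH step-up, and over-representation analysis."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm import AnnotationTerm, bh_fdr, enrich, hypergeom_upper

from oracles import oracle_bh, oracle_hypergeom_upper


class TestHypergeomUpper:
    def test_k_zero_is_one(self):
        assert hypergeom_upper(100, 10, 20, 0) == pytest.approx(1.0)

    def test_term_equals_universe_is_one(self):
        assert hypergeom_upper(20, 20, 7, 7) == pytest.approx(1.0)

    def test_exact_rational_example(self):
        # N=20, K=5, n=10, k=5: only C(5,5)*C(15,5)/C(20,10)
        expected = Fraction(math.comb(5, 5) * math.comb(15, 5), math.comb(20, 10))
        assert hypergeom_upper(20, 5, 10, 5) == pytest.approx(float(expected), rel=1e-12)
        assert oracle_hypergeom_upper(20, 5, 10, 5) == expected

    def test_invalid_parameters_rejected(self):
        for bad in [(10, 11, 5, 0), (10, 5, 11, 0), (10, 5, 5, 6), (-1, 0, 0, 0)]:
            with pytest.raises(ValueError):
                hypergeom_upper(*bad)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_matches_exact_oracle(self, data):
        N = data.draw(st.integers(1, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        exact = float(oracle_hypergeom_upper(N, K, n, k))
        assert hypergeom_upper(N, K, n, k) == pytest.approx(exact, rel=1e-12)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        # m=4: adjusted = min over j>=i of 4*p_(j)/j = (0.04, 0.04, 0.04, 0.04)
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_equal_stay_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40), seed=st.integers(0, 99))
    def test_matches_textbook_oracle_and_is_equivariant(self, ps, seed):
        adj = bh_fdr(ps)
        assert adj == pytest.approx(oracle_bh(ps), rel=1e-12)
        # permutation equivariance
        perm = np.random.default_rng(seed).permutation(len(ps))
        adj_perm = bh_fdr([ps[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm], rel=1e-12)
        # step-up monotonicity: sorted by p, adjusted values are nondecreasing
        order = np.argsort(ps)
        sorted_adj = [adj[i] for i in order]
        assert all(a <= b + 1e-15 for a, b in zip(sorted_adj, sorted_adj[1:]))


def term(tid, genes, category="BP"):
    return AnnotationTerm(tid, tid, category, frozenset(genes))


class TestEnrich:
    def test_query_equals_single_term(self):
        rows = enrich({"A", "B", "C"}, [term("T1", {"A", "B", "C"})])
        (row,) = rows
        assert row.k == row.K == row.n == 3
        assert row.rich_factor == pytest.approx(1.0)
        assert row.p_value == pytest.approx(1.0)

    def test_disjoint_term_not_emitted(self):
        rows = enrich({"A"}, [term("T1", {"A", "B"}), term("T2", {"X", "Y"})])
        assert [r.term_id for r in rows] == ["T1"]

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich({"Z"}, [term("T1", {"A", "B"})])

    def test_per_category_families_and_flags(self):
        genes = [f"G{i}" for i in range(40)]
        terms = [
            term("BP1", genes[:10], "BP"),
            term("BP2", genes[20:40], "BP"),
            term("PW1", genes[:10], "pathway"),
        ]
        rows = enrich(set(genes[:10]), terms, universe=genes)
        by_id = {r.term_id: r for r in rows}
        # identical statistics, but BP is flagged via FDR and pathway via raw p
        assert "BP2" not in by_id  # k = 0, never tested
        assert by_id["BP1"].p_value == pytest.approx(by_id["PW1"].p_value)
        assert by_id["BP1"].fdr == pytest.approx(by_id["BP1"].p_value)  # family of one tested term
        assert by_id["PW1"].significant == (by_id["PW1"].p_value < 0.05)
        assert by_id["BP1"].significant == (by_id["BP1"].fdr < 0.01)

    def test_growing_query_never_decreases_k(self):
        genes = [f"G{i}" for i in range(30)]
        terms = [term(f"T{j}", genes[j: j + 10]) for j in range(0, 20, 5)]
        query = set(genes[:8])
        base = {r.term_id: r.k for r in enrich(query, terms, universe=genes)}
        grown = {r.term_id: r.k for r in enrich(query | {genes[25]}, terms, universe=genes)}
        assert all(grown.get(tid, 0) >= k for tid, k in base.items())

    def test_rows_sorted_by_p_within_category(self, study):
        rows = enrich(study.truth["putative_targets"], study.terms)
        for cat in ("BP", "MF", "CC", "pathway"):
            ps = [r.p_value for r in rows if r.category == cat]
            assert ps == sorted(ps)

    def test_planted_terms_flagged_in_default_study(self, study):
        rows = enrich(study.truth["putative_targets"], study.terms)
        planted = {t for ids in study.truth["planted_terms"].values() for t in ids}
        flagged = {r.term_id for r in rows if r.fdr < 0.01}
        assert planted <= flagged
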