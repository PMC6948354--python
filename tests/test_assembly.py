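"""Symbol standardization, per-herb accounting, and disease intersection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm import Component, ComponentTargetEdge, GeneSet, RawTargetRecord, assemble, intersect_disease, standardize_symbols
from netpharm.errors import EmptyIntersectionError, MappingConflictError


def comp(cid, herbs=("SZR",)):
    return Component(cid, cid, frozenset(herbs), 50.0, 0.5)


class TestStandardize:
    MAPPING = {"tumor necrosis factor": "TNF", "interleukin 6": "IL6", "il-6": "IL6"}

    def test_maps_to_official_symbol(self):
        res = standardize_symbols([RawTargetRecord("C1", "tumor necrosis factor")], self.MAPPING)
        assert res.edges == [ComponentTargetEdge("C1", "TNF")]
        assert res.unmapped == []

    def test_unmapped_conserved_not_dropped(self):
        recs = [RawTargetRecord("C1", "tumor necrosis factor"), RawTargetRecord("C1", "mystery protein")]
        res = standardize_symbols(recs, self.MAPPING)
        assert [r.raw_name for r in res.unmapped] == ["mystery protein"]
        assert res.n_mapped_records + len(res.unmapped) == len(recs)

    def test_two_raw_names_one_symbol_dedup(self):
        recs = [RawTargetRecord("C1", "interleukin 6"), RawTargetRecord("C1", "il-6")]
        res = standardize_symbols(recs, self.MAPPING)
        assert res.edges == [ComponentTargetEdge("C1", "IL6")]
        assert res.duplicates_collapsed == 1
        assert res.n_mapped_records == 2  # record-level conservation intact

    def test_conflicting_mapping_rejected(self):
        with pytest.raises(MappingConflictError, match="nppb"):
            standardize_symbols([RawTargetRecord("C1", "nppb")], [("nppb", "NPPB"), ("nppb", "BNP")])

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            standardize_symbols([RawTargetRecord("C1", "x")], {})


class TestAssemble:
    def test_six_single_herb_lists_sum(self):
        sizes = {"SZR": 80, "GS": 90, "YHS": 1493, "XHC": 232, "JL": 143, "ML": 33}
        comps, edges = [], []
        for herb, size in sizes.items():
            cid = f"C_{herb}"
            comps.append(comp(cid, (herb,)))
            edges += [ComponentTargetEdge(cid, f"{herb}G{i}") for i in range(size)]
        report = assemble(edges, comps)
        assert report.total_mapped == 2071
        assert report.per_herb_counts == sizes

    def test_multi_herb_component_counted_per_herb(self):
        edges = [ComponentTargetEdge("C1", "A"), ComponentTargetEdge("C1", "B")]
        report = assemble(edges, [comp("C1", ("SZR", "YHS"))])
        assert report.per_herb_counts == {"SZR": 2, "YHS": 2}
        assert report.total_mapped == 2

    def test_union_dedup_across_components(self):
        edges = [ComponentTargetEdge("C1", "A"), ComponentTargetEdge("C2", "A"), ComponentTargetEdge("C2", "B")]
        report = assemble(edges, [comp("C1"), comp("C2")])
        assert report.union_targets == {"A", "B"}

    def test_empty_edges(self):
        report = assemble([], [comp("C1")])
        assert report.total_mapped == 0 and report.union_targets == frozenset()

    def test_unknown_component_rejected(self):
        with pytest.raises(KeyError):
            assemble([ComponentTargetEdge("C9", "A")], [comp("C1")])


class TestIntersectDisease:
    AF = GeneSet("AF", frozenset("BCD"))
    OSAHS = GeneSet("OSAHS", frozenset("CDE"))
    COMBINED = GeneSet("AF_OSAHS", frozenset("BCDE"))

    def test_enumerated_five_symbol_example(self):
        # exhaustive enumeration over {A..E}: union={A,B,C} so
        # union∩AF={B,C}, union∩OSAHS={C}, union∩AF∩OSAHS={C},
        # union∩combined={B,C}
        venn = intersect_disease({"A", "B", "C"}, self.AF, self.OSAHS, self.COMBINED)
        assert (venn.herb_af, venn.herb_osahs, venn.herb_both) == (2, 1, 1)
        assert venn.putative_targets == {"B", "C"}

    def test_identity_when_combined_equals_union(self):
        union = {"B", "C", "D", "E"}
        venn = intersect_disease(union, self.AF, self.OSAHS, self.COMBINED)
        assert venn.putative_targets == union

    def test_disjoint_sets_abort(self):
        with pytest.raises(EmptyIntersectionError, match="herb∩AF=0"):
            intersect_disease({"X", "Y"}, self.AF, self.OSAHS, self.COMBINED)

    def test_case_insensitive_merge(self):
        venn = intersect_disease({"b", "c"}, self.AF, self.OSAHS, self.COMBINED)
        assert venn.putative_targets == {"B", "C"}


@st.composite
def assembly_instances(draw):
    n_comp = draw(st.integers(1, 8))
    comps = [comp(f"C{i}", tuple(draw(st.sets(st.sampled_from(["SZR", "GS", "YHS"]), min_size=1)))) for i in range(n_comp)]
    mapping = {f"p{j}": f"G{j % 12}" for j in range(20)}
    recs = [
        RawTargetRecord(f"C{draw(st.integers(0, n_comp - 1))}", draw(st.sampled_from([f"p{j}" for j in range(25)])))
        for _ in range(draw(st.integers(0, 40)))
    ]
    return comps, mapping, recs


@settings(max_examples=60, deadline=None, derandomize=True)
@given(inst=assembly_instances(), shuffle_seed=st.integers(0, 999))
def test_conservation_and_order_invariance(inst, shuffle_seed):
    import random

    comps, mapping, recs = inst
    res = standardize_symbols(recs, mapping)
    assert res.n_mapped_records + len(res.unmapped) == len(recs)
    report = assemble(res.edges, comps)
    assert len(report.union_targets) <= res.n_mapped_records or res.n_mapped_records == 0

    shuffled = recs[:]
    random.Random(shuffle_seed).shuffle(shuffled)
    res2 = standardize_symbols(shuffled, mapping)
    report2 = assemble(res2.edges, comps)
    assert report2.per_herb_counts == report.per_herb_counts
    assert report2.union_targets == report.union_targets
    assert res2.n_mapped_records == res.n_mapped_records
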