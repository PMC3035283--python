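"""Metric formula and batch-computation tests.

Closed-form expectations for the normalization were frozen from the formula
endpoints (ln(M+1) at k=0, 0 at k=M); probability expectations come from a
naive per-term recount oracle independent of the propagation pass.
"""

import math

import pytest

from termspec import (
    MetricConfig,
    compute_all,
    go_proportion,
    information_content,
    offspring_set,
    offsp_n,
    term_probability,
)
from termspec.errors import BoundsError, UnknownTermError


class TestOffspN:
    @pytest.mark.parametrize(
        "k, M, expected_2dp",
        [(0, 8267, 9.02), (1, 8267, 8.33), (5, 8267, 7.23), (8267, 8267, 0.0)],
    )
    def test_reference_cells(self, k, M, expected_2dp):
        assert round(offsp_n(k, M), 2) == expected_2dp

    def test_endpoints_closed_form(self):
        M = 100
        assert offsp_n(0, M) == pytest.approx(math.log(M + 1))
        assert offsp_n(M, M) == 0.0

    def test_strictly_decreasing(self):
        values = [offsp_n(k, 50) for k in range(51)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_bounds(self):
        with pytest.raises(BoundsError):
            offsp_n(11, 10)
        with pytest.raises(BoundsError):
            offsp_n(-1, 10)
        with pytest.raises(BoundsError):
            offsp_n(0, 0)


class TestGoProportion:
    @pytest.mark.parametrize(
        "n_off, n_anc, expected_2dp",
        [(0, 8, 1.0), (1, 5, 0.83), (5, 2, 0.29)],
    )
    def test_reference_cells(self, n_off, n_anc, expected_2dp):
        assert round(go_proportion(n_off, n_anc), 2) == expected_2dp

    def test_zero_zero_is_undefined(self):
        assert go_proportion(0, 0) is None

    def test_root_of_nontrivial_dag_is_zero(self):
        assert go_proportion(10, 0) == 0.0

    def test_range(self):
        for n_off in range(6):
            for n_anc in range(6):
                p = go_proportion(n_off, n_anc)
                if p is not None:
                    assert 0.0 <= p <= 1.0

    def test_negative_rejected(self):
        with pytest.raises(BoundsError):
            go_proportion(-1, 2)


class TestTermProbability:
    def test_worked_example(self, fig1):
        dag, ann = fig1
        assert term_probability(dag, ann, "GO:Term_3") == pytest.approx(4 / 11)

    def test_root_probability_is_one(self, fig1):
        dag, ann = fig1
        assert term_probability(dag, ann, dag.root_id) == 1.0

    def test_unannotated_leaf_is_zero(self, implementation_dag):
        from termspec import AnnotationSet

        dag = implementation_dag
        ann = AnnotationSet(by_gene={"g1": frozenset({"GO:0005488"})})
        assert term_probability(dag, ann, "GO:0070052") == 0.0

    def test_unknown_term(self, fig1):
        dag, ann = fig1
        with pytest.raises(UnknownTermError):
            term_probability(dag, ann, "GO:Term_99")

    def test_unit_in_closure_counted_once(self, fig1):
        from termspec import AnnotationSet

        dag, _ = fig1
        # one unit annotated to a term AND its offspring still counts once
        ann = AnnotationSet(
            by_gene={
                "u1": frozenset({"GO:Term_3", "GO:Term_4"}),
                "u2": frozenset({"GO:Term_2"}),
            }
        )
        assert term_probability(dag, ann, "GO:Term_3") == pytest.approx(1 / 2)


class TestInformationContent:
    def test_worked_example_1dp(self):
        assert round(information_content(4 / 11), 1) == 1.5

    def test_certain_term_is_zero(self):
        assert information_content(1.0) == 0.0

    def test_quarter(self):
        assert information_content(0.25) == pytest.approx(2.0)

    def test_zero_is_undefined(self):
        assert information_content(0.0) is None

    def test_bounds(self):
        with pytest.raises(BoundsError):
            information_content(1.5)
        with pytest.raises(BoundsError):
            information_content(-0.1)


class TestComputeAll:
    def test_worked_example_record(self, fig1):
        dag, ann = fig1
        records = compute_all(dag, ann)
        r = records["GO:Term_3"]
        assert r.p == pytest.approx(4 / 11)
        assert r.ic == pytest.approx(1.4594316, abs=1e-6)
        assert r.n_ancestors == 1
        assert r.n_offspring == 2

    def test_without_annotations(self, chain_dag):
        records = compute_all(chain_dag)
        assert all(r.p is None and r.ic is None for r in records.values())
        assert records["B"].n_ancestors == 2
        assert records["R"].offsp_n == 0.0

    def test_agrees_with_naive_recount(self, seeded_instance):
        dag, ann = seeded_instance
        records = compute_all(dag, ann)
        for term_id, r in records.items():
            # oracle: independent per-term closure enumeration
            closure = set(offspring_set(dag, term_id)) | {term_id}
            hits = sum(1 for terms in ann.by_gene.values() if terms & closure)
            assert r.p == pytest.approx(hits / ann.n_genes)

    def test_monotonicity_along_edges(self, seeded_instance):
        dag, ann = seeded_instance
        records = compute_all(dag, ann)
        for term in dag.active_terms():
            child = records[term.term_id]
            for parent_id in term.parents:
                parent = records[parent_id]
                assert child.p <= parent.p + 1e-12
                if child.ic is not None and parent.ic is not None:
                    assert child.ic >= parent.ic - 1e-12
                assert child.offsp_n > parent.offsp_n
                assert child.n_ancestors > parent.n_ancestors

    def test_root_ic_zero_when_all_units_survive(self, seeded_instance):
        dag, ann = seeded_instance
        records = compute_all(dag, ann)
        assert records[dag.root_id].p == 1.0
        assert records[dag.root_id].ic == 0.0

    def test_offsp_n_range(self, seeded_instance):
        dag, ann = seeded_instance
        records = compute_all(dag, ann)
        M = records[dag.root_id].n_offspring
        for r in records.values():
            assert 0.0 <= r.offsp_n <= math.log(M + 1) + 1e-12
            if r.go_prop is not None:
                assert 0.0 <= r.go_prop <= 1.0

    def test_max_offspring_override(self, fig1):
        dag, ann = fig1
        records = compute_all(dag, ann, MetricConfig(max_offspring=8267))
        leaf = records["GO:Term_4"]
        assert leaf.n_offspring == 0
        assert round(leaf.offsp_n, 2) == 9.02

    def test_max_offspring_below_root_rejected(self, fig1):
        dag, ann = fig1
        with pytest.raises(BoundsError):
            compute_all(dag, ann, MetricConfig(max_offspring=1))

    def test_sum_mode_reproduces_literal_reading(self, fig1):
        from termspec import AnnotationSet

        dag, _ = fig1
        ann = AnnotationSet(
            by_gene={
                "u1": frozenset({"GO:Term_3", "GO:Term_4"}),
                "u2": frozenset({"GO:Term_2"}),
            }
        )
        unique = compute_all(dag, ann)["GO:Term_3"]
        literal = compute_all(dag, ann, MetricConfig(count_mode="sum"))["GO:Term_3"]
        assert unique.p == pytest.approx(0.5)
        assert literal.p == pytest.approx(1.0)  # u1 counted at both depths

    def test_sum_and_unique_agree_without_overlap(self, fig1):
        dag, ann = fig1
        unique = compute_all(dag, ann)
        literal = compute_all(dag, ann, MetricConfig(count_mode="sum"))
        for term_id in unique:
            assert unique[term_id].p == pytest.approx(literal[term_id].p)
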