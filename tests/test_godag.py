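import math

import numpy as np
import pytest

import _oracles
from simlink.godag import (
    MEASURES,
    GeneSetSimilarityCache,
    NoCommonAncestorError,
    OntologyDag,
    compute_ic,
    geneset_sim,
    mica,
    read_obo,
    term_sim,
    write_obo,
)

from conftest import TOY_ANNOTATIONS


def random_dag(seed: int, n_terms: int = 18, n_genes: int = 12):
    """Random rooted DAG with 1-2 parents per term and random annotations."""
    rng = np.random.default_rng(seed)
    terms = [f"t{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        for parent in rng.choice(i, size=min(i, rng.integers(1, 3)), replace=False):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            edges.append((terms[i], terms[int(parent)], rel))
    annotations = {
        f"g{j}": set(rng.choice(terms[1:], size=rng.integers(1, 4), replace=False))
        for j in range(n_genes)
    }
    return OntologyDag(edges, annotations=annotations)


class TestDagStructure:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyDag([("a", "b", "is_a"), ("b", "a", "is_a")])

    def test_annotation_to_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown term"):
            OntologyDag([("a", "r", "is_a")], annotations={"g": {"nope"}})

    def test_ancestors_include_self_and_root(self, toy_dag):
        assert toy_dag.ancestors("Xa") == {"Xa", "X3", "X2", "X1", "R"}

    def test_obo_round_trip(self, toy_dag, tmp_path):
        path = tmp_path / "toy.obo"
        write_obo(toy_dag, path)
        back = read_obo(path)
        assert back.terms == toy_dag.terms
        assert all(set(back.parents[t]) == set(toy_dag.parents[t]) for t in toy_dag.terms)


class TestInformationContent:
    def test_root_ic_zero(self, toy_ic):
        assert toy_ic.ic["R"] == 0.0

    def test_two_term_chain_hand_value(self):
        dag = OntologyDag(
            [("A", "root", "is_a")],
            annotations={"g1": {"A"}, "g2": {"A"}, "g3": {"root"}},
        )
        ic = compute_ic(dag)
        assert ic.p["A"] == pytest.approx(2 / 3)
        assert ic.ic["A"] == pytest.approx(-math.log(2 / 3))

    def test_diamond_counts_gene_once(self):
        # g reaches top via both mid1 and mid2 but contributes one count
        dag = OntologyDag(
            [("leaf", "mid1", "is_a"), ("leaf", "mid2", "is_a"),
             ("mid1", "top", "is_a"), ("mid2", "top", "is_a")],
            annotations={"g": {"leaf"}, "h": {"top"}},
        )
        ic = compute_ic(dag)
        assert ic.p["top"] == 1.0
        assert ic.p["mid1"] == pytest.approx(0.5)

    def test_matches_naive_oracle_on_toy(self, toy_parents, toy_dag, toy_ic):
        oracle_ic, oracle_p = _oracles.ic_table(toy_parents, TOY_ANNOTATIONS)
        assert set(toy_ic.ic) == set(oracle_ic)
        for term in oracle_ic:
            assert toy_ic.ic[term] == pytest.approx(oracle_ic[term], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_parent_ic_never_exceeds_child(self, seed):
        dag = random_dag(seed)
        ic = compute_ic(dag)
        for child, parents in dag.parents.items():
            for parent, _ in parents:
                if child in ic.ic and parent in ic.ic:
                    assert ic.ic[parent] <= ic.ic[child] + 1e-12


class TestMica:
    def test_self(self, toy_dag, toy_ic):
        assert mica("Xa", "Xa", toy_dag, toy_ic) == "Xa"

    def test_siblings_share_parent(self, toy_dag, toy_ic):
        assert mica("Xa", "Xb", toy_dag, toy_ic) == "X3"

    def test_parent_child_pair(self, toy_dag, toy_ic):
        assert mica("Xa", "X3", toy_dag, toy_ic) == "X3"

    def test_cross_branch_is_root(self, toy_dag, toy_ic):
        assert mica("Xa", "Ya", toy_dag, toy_ic) == "R"

    def test_disconnected_roots_error(self):
        dag = OntologyDag(
            [("a", "r1", "is_a"), ("b", "r2", "is_a")],
            annotations={"g": {"a"}, "h": {"b"}},
        )
        ic = compute_ic(dag)
        with pytest.raises(NoCommonAncestorError):
            mica("a", "b", dag, ic)


class TestTermSim:
    def test_wang_chain_hand_value(self):
        dag = OntologyDag([("C", "P", "is_a"), ("P", "root", "is_a")])
        assert term_sim("C", "P", "wang", dag) == pytest.approx(3.24 / 4.24, abs=1e-12)

    def test_self_similarity_one(self, toy_dag, toy_ic):
        for measure in ("wang", "lin", "jiang"):
            assert term_sim("Xa", "Xa", measure, toy_dag, toy_ic) == pytest.approx(1.0)

    def test_resnik_cross_branch_near_root_zero(self, toy_dag, toy_ic):
        # branches meet only at the root, whose IC is 0
        assert term_sim("Xa", "Ya", "resnik", toy_dag, toy_ic) == 0.0

    @pytest.mark.parametrize("measure", MEASURES)
    def test_matches_naive_oracle_matrix_on_toy(self, measure, toy_parents, toy_dag, toy_ic):
        terms = sorted(t for t in toy_dag.terms if t in toy_ic.ic)
        for t1 in terms:
            for t2 in terms:
                expected = _oracles.term_similarity(toy_parents, TOY_ANNOTATIONS, t1, t2, measure)
                got = term_sim(t1, t2, measure, toy_dag, toy_ic)
                assert got == pytest.approx(expected, abs=1e-9), (measure, t1, t2)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_range_on_random_dags(self, seed):
        dag = random_dag(seed)
        ic = compute_ic(dag)
        terms = sorted(dag.terms)
        rng = np.random.default_rng(seed)
        for _ in range(30):
            t1, t2 = rng.choice(terms, 2)
            for measure in MEASURES:
                s12 = term_sim(t1, t2, measure, dag, ic)
                s21 = term_sim(t2, t1, measure, dag, ic)
                assert s12 == pytest.approx(s21, abs=1e-12)
                assert s12 >= 0
                if measure != "resnik":
                    assert s12 <= 1 + 1e-12


class TestGenesetSim:
    def test_identity_is_one(self, toy_dag, toy_ic):
        genes = ["gx1", "gx2", "gy1"]
        for measure in ("wang", "lin", "jiang"):
            assert geneset_sim(genes, genes, measure, toy_dag, toy_ic) == pytest.approx(1.0)

    def test_singletons_with_same_term(self, toy_dag, toy_ic):
        # gx1 and a set annotated to the identical single term
        assert geneset_sim(["gx1"], ["gx1"], "wang", toy_dag, toy_ic) == pytest.approx(1.0)

    def test_disjoint_branches_score_low(self, toy_dag, toy_ic):
        a = ["gx1", "gx2", "gx3"]
        b = ["gy1", "gy2"]
        for measure in ("wang", "lin", "jiang", "rel"):
            assert geneset_sim(a, b, measure, toy_dag, toy_ic) < 0.1

    def test_invariant_to_order_and_duplication(self, toy_dag, toy_ic):
        a = ["gx1", "gx3", "gz1"]
        b = ["gy1", "gz2"]
        ref = geneset_sim(a, b, "wang", toy_dag, toy_ic)
        assert geneset_sim(a[::-1] + ["gx1"], b + ["gy1"], "wang", toy_dag, toy_ic) == pytest.approx(ref)

    def test_unannotated_set_errors(self, toy_dag, toy_ic):
        with pytest.raises(ValueError, match="no annotated"):
            geneset_sim(["nope"], ["gx1"], "wang", toy_dag, toy_ic)

    @pytest.mark.parametrize("measure", MEASURES)
    def test_bma_matches_naive_oracle(self, measure, toy_parents, toy_dag, toy_ic):
        a = ["gx1", "gx3", "gz2"]
        b = ["gy1", "gy3", "gz1"]
        expected = _oracles.geneset_similarity(toy_parents, TOY_ANNOTATIONS, a, b, measure)
        assert geneset_sim(a, b, measure, toy_dag, toy_ic) == pytest.approx(expected, abs=1e-9)

    def test_cache_agrees_with_direct_computation(self, toy_dag, toy_ic):
        pool = sorted(TOY_ANNOTATIONS)
        cache = GeneSetSimilarityCache(pool, "lin", toy_dag, toy_ic)
        a, b = ["gx1", "gz2"], ["gy1", "gy2", "gz1"]
        assert cache.set_sim(a, b) == pytest.approx(geneset_sim(a, b, "lin", toy_dag, toy_ic), abs=1e-12)
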