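import math

import numpy as np
import pytest

from conftest import oracle_fnsemsim, random_dag, random_gene_setup
from metnet.disease_sim import (
    all_pairs_similarity,
    disease_fun_sim,
    find_mica,
    fnsemsim,
    gene_to_set_weight,
    information_content,
    propagated_counts,
    read_similarity_matrix,
    write_similarity_matrix,
)
from metnet.io import (
    GeneAnnotation,
    GeneFunctionalNetwork,
    OntologyDAG,
    unordered_pair,
)


def net_of(*edges):
    return GeneFunctionalNetwork(
        edges={unordered_pair(a, b): w for a, b, w in edges}
    )


class TestGeneToSetWeight:
    def test_membership(self):
        assert gene_to_set_weight("g", {"g", "h"}, net_of()) == 1.0

    def test_max_over_edges(self):
        net = net_of(("g", "a", 0.3), ("g", "b", 0.8))
        assert gene_to_set_weight("g", {"a", "b"}, net) == 0.8

    def test_no_edges(self):
        assert gene_to_set_weight("g", {"a"}, net_of()) == 0.0


class TestDiseaseFunSim:
    def test_identical_sets(self):
        assert disease_fun_sim({"x", "y"}, {"x", "y"}, net_of()) == 1.0

    def test_single_cross_edge(self):
        net = net_of(("x", "y", 0.6))
        assert disease_fun_sim({"x"}, {"y"}, net) == pytest.approx(0.6)

    def test_disjoint_no_edges(self):
        assert disease_fun_sim({"x"}, {"y"}, net_of()) == 0.0

    def test_both_empty_warns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert disease_fun_sim(set(), set(), net_of()) == 0.0
        assert any("empty" in r.message for r in caplog.records)

    def test_monotone_in_added_cross_edge(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            na, nb = rng.integers(1, 4, size=2)
            Ga = {f"a{i}" for i in range(na)}
            Gb = {f"b{i}" for i in range(nb)}
            edges = [
                (a, b, round(float(rng.uniform(0, 1)), 4))
                for a in Ga
                for b in Gb
                if rng.random() < 0.3
            ]
            net = net_of(*edges)
            before = disease_fun_sim(Ga, Gb, net)
            missing = [(a, b) for a in Ga for b in Gb if net.weight(a, b) == 0.0]
            if not missing:
                continue
            a, b = missing[0]
            net2 = net_of(*edges, (a, b, 0.9))
            assert disease_fun_sim(Ga, Gb, net2) >= before


@pytest.fixture
def family_dag():
    """root <- p <- {a, b}; sibling s under root."""
    dag = OntologyDAG(
        terms={"root", "p", "a", "b", "s"},
        parents={
            "root": set(),
            "p": {"root"},
            "a": {"p"},
            "b": {"p"},
            "s": {"root"},
        },
    )
    dag.validate()
    return dag


class TestFindMica:
    def test_self_case(self, family_dag):
        ann = GeneAnnotation({"a": {"g1", "g2"}, "p": {"g3"}, "root": {"g4"}})
        mica, count = find_mica("a", "a", family_dag, ann)
        assert mica == "a"
        assert count == 2  # propagated count of the leaf itself

    def test_internal_beats_root(self, family_dag):
        ann = GeneAnnotation({"p": {"g1", "g2"}, "root": {"g1", "g2", "g3"}})
        mica, count = find_mica("a", "b", family_dag, ann)
        assert mica == "p"
        assert count == 2

    def test_siblings_fall_to_root(self, family_dag):
        ann = GeneAnnotation({"a": {"g1"}, "s": {"g2"}})
        mica, _ = find_mica("a", "s", family_dag, ann)
        assert mica == "root"

    def test_no_common_ancestor_errors(self):
        forest = OntologyDAG(
            terms={"x", "y"}, parents={"x": set(), "y": set()}
        )
        forest.validate()
        with pytest.raises(Exception, match="common ancestor"):
            find_mica("x", "y", forest, GeneAnnotation({}))


class TestPropagatedCounts:
    def test_union_not_sum(self, family_dag):
        ann = GeneAnnotation({"a": {"g1"}, "b": {"g1"}, "p": {"g1"}})
        counts = propagated_counts(family_dag, ann)
        assert counts["p"] == 1
        assert counts["root"] == 1

    def test_root_aggregates_all(self, family_dag):
        ann = GeneAnnotation({"a": {"g1"}, "b": {"g2"}, "s": {"g3"}})
        assert propagated_counts(family_dag, ann)["root"] == 3


class TestFnsemsim:
    def test_self_similarity_one(self, family_dag):
        # leaf whose direct set equals its propagated set
        ann = GeneAnnotation({"a": {"g1", "g2"}, "root": {"g9"}})
        val = fnsemsim("a", "a", family_dag, ann, net_of())
        assert val == pytest.approx(1.0)

    def test_disconnected_sets_zero(self, family_dag):
        ann = GeneAnnotation({"a": {"g1"}, "b": {"g2"}})
        assert fnsemsim("a", "b", family_dag, ann, net_of()) == 0.0

    def test_direct_substitution(self, family_dag):
        # |G_mica| = 2 via p; 0.6 connectivity; 0.6 * 1/4 = 0.15
        ann = GeneAnnotation({"a": {"x"}, "b": {"y"}})
        net = net_of(("x", "y", 0.6))
        val = fnsemsim("a", "b", family_dag, ann, net)
        assert val == pytest.approx(0.15)

    def test_symmetry_random(self, family_dag):
        rng = np.random.default_rng(3)
        for _ in range(25):
            ann, net = random_gene_setup(rng, family_dag, ["a", "b", "s"], 6)
            assert fnsemsim("a", "b", family_dag, ann, net) == fnsemsim(
                "b", "a", family_dag, ann, net
            )

    def test_ic_argmax_equals_count_argmin(self, family_dag):
        ann = GeneAnnotation({"a": {"g1"}, "b": {"g2"}, "p": {"g3"}, "root": {"g4"}})
        counts = propagated_counts(family_dag, ann)
        common = family_dag.ancestors("a") & family_dag.ancestors("b")
        root_count = counts["root"]
        by_ic = max(
            sorted(common),
            key=lambda t: information_content(t, counts, root_count),
        )
        by_count = min(sorted(common), key=lambda t: (counts[t], t))
        assert by_ic == by_count


class TestAllPairs:
    def test_two_diseases_normalize_to_one(self, family_dag):
        ann = GeneAnnotation({"a": {"x"}, "b": {"y"}})
        net = net_of(("x", "y", 0.4))
        dsm = all_pairs_similarity(["a", "b"], family_dag, ann, net)
        assert dsm.get("a", "b") == pytest.approx(1.0)

    def test_divide_by_max(self, family_dag):
        ann = GeneAnnotation({"a": {"x"}, "b": {"y"}, "s": {"z"}})
        net = net_of(("x", "y", 0.2), ("x", "z", 0.4))
        dsm = all_pairs_similarity(["a", "b", "s"], family_dag, ann, net)
        raw_ab = fnsemsim("a", "b", family_dag, ann, net)
        raw_as = fnsemsim("a", "s", family_dag, ann, net)
        hi, lo = max(raw_ab, raw_as), min(raw_ab, raw_as)
        assert dsm.get("a", "s") == pytest.approx(raw_as / hi)
        assert sorted([dsm.get("a", "b"), dsm.get("a", "s")]) == pytest.approx(
            [lo / hi, 1.0]
        )

    def test_all_zero_stays_zero(self, family_dag, caplog):
        ann = GeneAnnotation({"a": {"x"}, "b": {"y"}})
        with caplog.at_level("WARNING"):
            dsm = all_pairs_similarity(["a", "b"], family_dag, ann, net_of())
        assert dsm.get("a", "b") == 0.0
        assert dsm.get("a", "a") == 1.0

    def test_entries_in_unit_interval_random(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            dag, terms = random_dag(rng, 8)
            ann, net = random_gene_setup(rng, dag, terms, 8)
            picked = [t for t in terms if rng.random() < 0.6][:5]
            if len(picked) < 2:
                continue
            dsm = all_pairs_similarity(picked, dag, ann, net)
            assert np.all(dsm.sim >= 0.0) and np.all(dsm.sim <= 1.0 + 1e-12)
            assert np.allclose(dsm.sim, dsm.sim.T)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            dag, terms = random_dag(rng, 9)
            ann, net = random_gene_setup(rng, dag, terms, 7)
            picked = sorted(str(t) for t in rng.choice(terms, size=5, replace=False))
            dsm = all_pairs_similarity(picked, dag, ann, net)
            raw_oracle = np.zeros((5, 5))
            for i in range(5):
                for j in range(5):
                    raw_oracle[i, j] = oracle_fnsemsim(
                        picked[i], picked[j], dag, ann, net
                    )
            assert np.array_equal(dsm.raw, raw_oracle)

    def test_round_trip_tsv(self, tmp_path, family_dag):
        ann = GeneAnnotation({"a": {"x"}, "b": {"y"}, "s": {"z"}})
        net = net_of(("x", "y", 0.2), ("y", "z", 0.7))
        dsm = all_pairs_similarity(["a", "b", "s"], family_dag, ann, net)
        path = tmp_path / "dsim.tsv"
        write_similarity_matrix(path, dsm)
        back = read_similarity_matrix(path)
        assert back.diseases == dsm.diseases
        assert np.array_equal(back.sim, dsm.sim)
        assert np.array_equal(back.raw, dsm.raw)

    def test_needs_two_diseases(self, family_dag):
        with pytest.raises(ValueError):
            all_pairs_similarity(["a"], family_dag, GeneAnnotation({}), net_of())
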