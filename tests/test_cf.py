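import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_dmn
from metnet.cf import (
    build_dmn,
    build_profiles,
    cosine_similarity,
    read_profiles,
    relevance_score,
    write_profiles,
)
from metnet.disease_sim import DiseaseSimilarityMatrix
from metnet.io import AssociationTable


def dsm_from(diseases, offdiag):
    """Build a similarity matrix with diagonal 1 and given off-diagonal dict."""
    n = len(diseases)
    sim = np.eye(n)
    idx = {d: i for i, d in enumerate(diseases)}
    for (a, b), v in offdiag.items():
        sim[idx[a], idx[b]] = sim[idx[b], idx[a]] = v
    return DiseaseSimilarityMatrix(diseases=list(diseases), sim=sim)


class TestRelevanceScore:
    def setup_method(self):
        self.assoc = AssociationTable(records={("d1", "m"), ("d2", "m")})
        self.dsim = dsm_from(
            ["d1", "d2", "d3"], {("d1", "d3"): 0.2, ("d2", "d3"): 0.7}
        )

    def test_direct_association_is_one(self):
        assert relevance_score("d1", "m", self.assoc, self.dsim) == 1.0

    def test_max_over_related(self):
        assert relevance_score("d3", "m", self.assoc, self.dsim) == 0.7

    def test_all_zero(self):
        dsim = dsm_from(["d1", "d2", "d3"], {})
        assert relevance_score("d3", "m", self.assoc, dsim) == 0.0

    def test_empty_dr_rejected(self):
        with pytest.raises(ValueError):
            relevance_score("d1", "other", self.assoc, self.dsim)


class TestBuildProfiles:
    def test_single_cell(self):
        assoc = AssociationTable(records={("d1", "m1")})
        profiles = build_profiles(assoc, dsm_from(["d1"], {}))
        assert profiles.PA.shape == (1, 1)
        assert profiles.PA[0, 0] == 1.0

    def test_similarity_fills_all_cells(self):
        assoc = AssociationTable(records={("d1", "m1"), ("d2", "m2")})
        dsim = dsm_from(["d1", "d2"], {("d1", "d2"): 0.4})
        profiles = build_profiles(assoc, dsim)
        assert np.all(profiles.PA > 0.0)
        assert profiles.vector("m1").tolist() == [1.0, 0.4]

    def test_zero_similarity_gives_incidence(self):
        assoc = AssociationTable(
            records={("d1", "m1"), ("d2", "m2"), ("d2", "m1")}
        )
        profiles = build_profiles(assoc, dsm_from(["d1", "d2"], {}))
        assert profiles.vector("m1").tolist() == [1.0, 1.0]
        assert profiles.vector("m2").tolist() == [0.0, 1.0]

    def test_direct_cells_exactly_one(self):
        assoc = AssociationTable(records={("d1", "m1"), ("d2", "m1")})
        dsim = dsm_from(["d1", "d2"], {("d1", "d2"): 0.123})
        profiles = build_profiles(assoc, dsim)
        assert profiles.vector("m1").tolist() == [1.0, 1.0]

    def test_round_trip(self, tmp_path):
        assoc = AssociationTable(records={("d1", "m1"), ("d2", "m2")})
        profiles = build_profiles(
            assoc, dsm_from(["d1", "d2"], {("d1", "d2"): 0.3})
        )
        path = tmp_path / "profiles.tsv"
        write_profiles(path, profiles)
        back = read_profiles(path)
        assert back.metabolites == profiles.metabolites
        assert back.diseases == profiles.diseases
        assert np.array_equal(back.PA, profiles.PA)


class TestCosine:
    def test_identity(self):
        v = np.array([0.2, 0.9, 0.1])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_derived_value(self):
        val = cosine_similarity(np.array([1.0, 0.5]), np.array([0.5, 1.0]))
        assert val == pytest.approx(0.8)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(2), np.ones(2))


class TestBuildDmn:
    def make_profiles(self, records, offdiag=None):
        diseases = sorted({d for d, _ in records})
        return build_profiles(
            AssociationTable(records=set(records)),
            dsm_from(diseases, offdiag or {}),
        )

    def test_threshold_filters(self):
        # orthogonal-ish pairs: one similarity below 0.01, one above
        dsim = dsm_from(["d1", "d2", "d3"], {("d1", "d2"): 0.02})
        profiles = build_profiles(
            AssociationTable(
                records={("d1", "m1"), ("d2", "m2"), ("d3", "m3")}
            ),
            dsim,
        )
        net = build_dmn(profiles, threshold=0.01)
        # m1-m2 cosine ~0.04, m1-m3 and m2-m3 are 0
        assert set(net.edges) == {("m1", "m2")}

    def test_boundary_strict(self):
        profiles = self.make_profiles(
            {("d1", "m1"), ("d2", "m2")}, {("d1", "d2"): 0.3}
        )
        w = build_dmn(profiles, threshold=0.0).weight("m1", "m2")
        assert 0.0 < w < 1.0
        # similarity exactly equal to the threshold is dropped (strict >)
        net = build_dmn(profiles, threshold=w)
        assert ("m1", "m2") not in net.edges
        net_loose = build_dmn(profiles, threshold=w, strict=False)
        assert ("m1", "m2") in net_loose.edges

    def test_complete_graph_at_zero_threshold(self):
        offdiag = {("d1", "d2"): 0.5, ("d1", "d3"): 0.5, ("d2", "d3"): 0.5}
        profiles = self.make_profiles(
            {("d1", "m1"), ("d2", "m2"), ("d3", "m3"), ("d1", "m4")}, offdiag
        )
        net = build_dmn(profiles, threshold=0.0)
        assert len(net.edges) == math.comb(4, 2)

    def test_identical_disease_sets_weight_one(self):
        offdiag = {("d1", "d2"): 0.37}
        profiles = self.make_profiles(
            {("d1", "m1"), ("d1", "m2"), ("d2", "m3")}, offdiag
        )
        net = build_dmn(profiles, threshold=0.0)
        assert net.weight("m1", "m2") == pytest.approx(1.0, abs=1e-12)

    def test_isolated_nodes_kept(self):
        profiles = self.make_profiles({("d1", "m1"), ("d2", "m2")})
        net = build_dmn(profiles, threshold=0.5)
        assert net.nodes == {"m1", "m2"}
        assert net.edges == {}

    def test_identity_dsim_reduces_to_incidence_cosine(self):
        records = {
            ("d1", "m1"),
            ("d2", "m1"),
            ("d2", "m2"),
            ("d3", "m3"),
            ("d1", "m4"),
            ("d3", "m4"),
        }
        profiles = self.make_profiles(records)
        net = build_dmn(profiles, threshold=0.0)
        # hand oracle on raw 0/1 incidence vectors
        mets = sorted({m for _, m in records})
        diseases = sorted({d for d, _ in records})
        inc = {
            m: [1.0 if (d, m) in records else 0.0 for d in diseases] for m in mets
        }
        for i, a in enumerate(mets):
            for b in mets[i + 1 :]:
                dot = sum(x * y for x, y in zip(inc[a], inc[b]))
                cos = dot / (
                    math.sqrt(sum(x * x for x in inc[a]))
                    * math.sqrt(sum(x * x for x in inc[b]))
                )
                assert net.weight(a, b) == pytest.approx(cos, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=0.99))
    @settings(max_examples=40, deadline=None)
    def test_edge_count_non_increasing_in_threshold(self, t):
        offdiag = {("d1", "d2"): 0.6, ("d1", "d3"): 0.2, ("d2", "d3"): 0.05}
        profiles = self.make_profiles(
            {("d1", "m1"), ("d2", "m2"), ("d3", "m3"), ("d2", "m4")}, offdiag
        )
        lo = build_dmn(profiles, threshold=t * 0.5)
        hi = build_dmn(profiles, threshold=t)
        assert len(hi.edges) <= len(lo.edges)

    def test_bad_threshold(self):
        profiles = self.make_profiles({("d1", "m1")})
        with pytest.raises(ValueError):
            build_dmn(profiles, threshold=1.0)


class TestBruteForceOracle:
    def test_matches_nested_loop_recomputation(self):
        rng = np.random.default_rng(41)
        for trial in range(10):
            n_d, n_m = 6, 8
            diseases = [f"d{i}" for i in range(n_d)]
            mets = [f"m{i}" for i in range(n_m)]
            records = set()
            for m in mets:
                k = 1 + int(rng.integers(0, 3))
                for d in rng.choice(diseases, size=k, replace=False):
                    records.add((str(d), m))
            offdiag = {}
            for i in range(n_d):
                for j in range(i + 1, n_d):
                    offdiag[(diseases[i], diseases[j])] = round(
                        float(rng.uniform(0, 1)), 6
                    )
            used = sorted({d for d, _ in records})
            dsim = dsm_from(used, {
                p: v for p, v in offdiag.items() if p[0] in used and p[1] in used
            })
            profiles = build_profiles(AssociationTable(records=records), dsim)
            net = build_dmn(profiles, threshold=0.01)

            lookup = dict(offdiag)

            def sim(a, b):
                if a == b:
                    return 1.0
                return lookup.get((a, b), lookup.get((b, a), 0.0))

            vec, edges = oracle_dmn(records, sim, 0.01)
            assert set(net.edges) == set(edges)
            for pair, w in edges.items():
                assert abs(net.edges[pair] - w) <= 1e-12
            for m in profiles.metabolites:
                assert np.allclose(profiles.vector(m), vec[m], atol=1e-12, rtol=0)
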