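"""Family clustering, relationship classification and pair selection."""

import collections

import numpy as np
import pandas as pd
import pytest

from conftest import make_registry
from sibace.pedigree import (
    FamilyCluster,
    SiblingPair,
    classify_pair,
    select_study_pairs,
    sibling_clusters,
)
from sibace.simulate import SimulationParams, simulate_registry


def rec(person, mother, father, **kw):
    return {"person_id": person, "mother_id": mother, "father_id": father, **kw}


class TestClassifyPair:
    def test_full(self):
        assert classify_pair(rec("A", "M", "F"), rec("B", "M", "F")) == "full"

    def test_paternal_half(self):
        assert classify_pair(rec("A", "M1", "F"), rec("B", "M2", "F")) == "paternal_half"

    def test_maternal_half(self):
        assert classify_pair(rec("A", "M", "F1"), rec("B", "M", "F2")) == "maternal_half"

    def test_unrelated_raises(self):
        with pytest.raises(ValueError):
            classify_pair(rec("A", "M1", "F1"), rec("B", "M2", "F2"))


class TestSiblingClusters:
    def test_full_only_cluster(self):
        reg = make_registry([("A", "M", "F", 1970, 0, 0), ("B", "M", "F", 1971, 0, 0)])
        (c,) = sibling_clusters(reg)
        assert c.member_ids == ("A", "B")
        assert c.kind == "full_only"

    def test_transitive_closure_through_shared_mother(self):
        reg = make_registry(
            [
                ("A", "M1", "F1", 1970, 0, 0),
                ("B", "M1", "F1", 1971, 0, 0),
                ("C", "M1", "F2", 1975, 0, 0),
            ]
        )
        (c,) = sibling_clusters(reg)
        assert c.member_ids == ("A", "B", "C")
        assert c.kind == "mixed"

    def test_singletons_excluded(self):
        reg = make_registry(
            [(f"P{i}", f"M{i}", f"F{i}", 1970, 0, 0) for i in range(4)]
        )
        assert sibling_clusters(reg) == []

    def test_each_individual_in_at_most_one_cluster(self):
        reg = simulate_registry(SimulationParams(n_clusters=500, seed=2))
        clusters = sibling_clusters(reg)
        members = [m for c in clusters for m in c.member_ids]
        assert len(members) == len(set(members))

    def test_self_parent_raises(self):
        reg = make_registry([("A", "A", "F", 1970, 0, 0), ("B", "A", "F", 1971, 0, 0)])
        with pytest.raises(ValueError):
            sibling_clusters(reg)


class TestSiblingPairType:
    def test_k_additive_derived_from_relationship(self):
        assert SiblingPair("A", "B", "full").k_additive == 0.5
        assert SiblingPair("A", "B", "maternal_half").k_additive == 0.25
        with pytest.raises(ValueError):
            SiblingPair("A", "A", "full")
        with pytest.raises(ValueError):
            SiblingPair("A", "B", "full", k_additive=0.25)
        with pytest.raises(ValueError):
            SiblingPair("A", "B", "full", k_shared_env=0.5)


class TestSelectStudyPairs:
    def test_two_member_cluster_unique_pair(self):
        reg = make_registry([("A", "M", "F", 1970, 0, 0), ("B", "M", "F", 1971, 0, 0)])
        clusters = sibling_clusters(reg)
        for seed in range(10):
            (pair,) = select_study_pairs(clusters, reg, seed=seed)
            assert {pair.index_id, pair.sibling_id} == {"A", "B"}
            assert pair.relationship == "full"

    def test_mixed_cluster_always_paternal_and_all_indexes_reachable(self, mini_registry):
        """Full sibs A,B plus paternal half-sib C: every selection is a
        paternal-half pair, and each member occurs as index over seeds."""
        clusters = sibling_clusters(mini_registry)
        assert clusters[0].kind == "mixed"
        indexes = set()
        for seed in range(60):
            (pair,) = select_study_pairs(clusters, mini_registry, seed=seed)
            assert pair.relationship == "paternal_half"
            assert "C" in (pair.index_id, pair.sibling_id)
            indexes.add(pair.index_id)
        assert indexes == {"A", "B", "C"}

    def test_full_only_clusters_of_three(self):
        rows = []
        for i in range(1000):
            for j in range(3):
                rows.append((f"P{i}_{j}", f"M{i}", f"F{i}", 1970 + j, 0, 0))
        reg = make_registry(rows)
        clusters = sibling_clusters(reg)
        pairs = select_study_pairs(clusters, reg, seed=0)
        assert len(pairs) == 1000
        assert all(p.relationship == "full" for p in pairs)
        used = [x for p in pairs for x in (p.index_id, p.sibling_id)]
        assert len(set(used)) == 2000

    def test_vertex_disjoint_one_pair_per_cluster(self):
        reg = simulate_registry(SimulationParams(n_clusters=2000, seed=7))
        clusters = sibling_clusters(reg)
        pairs = select_study_pairs(clusters, reg, seed=1)
        assert len(pairs) == len(clusters)
        used = [x for p in pairs for x in (p.index_id, p.sibling_id)]
        assert len(used) == len(set(used))

    def test_paternal_priority_in_mixed_clusters(self):
        """A maternal-half pair is returned only when the chosen index has no
        paternal half-sibling in the cluster."""
        reg = simulate_registry(
            SimulationParams(n_clusters=3000, seed=5,
                             cluster_type_mix={"full_2": 0.2, "mixed": 0.8})
        )
        idx = reg.set_index("person_id")
        clusters = sibling_clusters(reg)
        pairs = select_study_pairs(clusters, reg, seed=3)
        counts = collections.Counter(p.relationship for p in pairs)
        assert counts["paternal_half"] > 0 and counts["maternal_half"] > 0
        father = idx["father_id"].to_dict()
        mother = idx["mother_id"].to_dict()
        by_member = {}
        for c in clusters:
            for m in c.member_ids:
                by_member[m] = c
        for p in pairs:
            if p.relationship != "maternal_half":
                continue
            cluster = by_member[p.index_id]
            has_paternal = any(
                o != p.index_id
                and father[o] == father[p.index_id]
                and mother[o] != mother[p.index_id]
                for o in cluster.member_ids
            )
            assert not has_paternal

    def test_twin_partners_excluded(self):
        reg = make_registry(
            [("A", "M", "F", 1970, 1, 0), ("B", "M", "F", 1970, 1, 0)]
        )
        clusters = sibling_clusters(reg)
        assert select_study_pairs(clusters, reg, seed=0) == []
        # a flagged twin born in a different year is not the index's co-twin
        reg2 = make_registry(
            [("A", "M", "F", 1970, 1, 0), ("B", "M", "F", 1973, 1, 0)]
        )
        pairs = select_study_pairs(sibling_clusters(reg2), reg2, seed=0)
        assert len(pairs) == 1

    def test_deterministic_given_seed(self):
        reg = simulate_registry(SimulationParams(n_clusters=800, seed=4))
        clusters = sibling_clusters(reg)
        p1 = select_study_pairs(clusters, reg, seed=9)
        p2 = select_study_pairs(clusters, reg, seed=9)
        assert p1 == p2
        p3 = select_study_pairs(clusters, reg, seed=10)
        assert p1 != p3

    def test_empty_cluster_list(self):
        reg = make_registry([("A", "M", "F", 1970, 0, 0)])
        assert select_study_pairs([], reg, seed=0) == []
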