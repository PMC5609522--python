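"""Neighbor-joining, distance matrices, subfamily assignment, bootstrap."""

import numpy as np
import pytest

from beetaqp import synthetic_data as sd
from beetaqp.classify import (DistanceMatrix, assign_subfamily,
                              bootstrap_support, build_distance_matrix,
                              bipartitions, nearest_reference, next_free_name,
                              nj_tree, tree_distances)


def random_additive_matrix(n, rng):
    """Distances induced by a random binary tree with random positive branch
    lengths — the independent oracle for NJ recovery."""
    # build a random topology by sequential leaf attachment
    # edges: dict node -> (parent, length); leaves are 0..n-1
    next_id = n
    # start from a 3-star
    center = next_id
    next_id += 1
    parent = {0: center, 1: center, 2: center}
    length = {i: rng.uniform(0.05, 1.0) for i in range(3)}
    edges = [(0, center), (1, center), (2, center)]
    for leaf in range(3, n):
        # split a random existing edge with a new internal node
        a, b = edges[rng.integers(len(edges))]
        mid = next_id
        next_id += 1
        la = length[a]
        parent[a] = mid
        length[a] = la * 0.5
        parent[mid] = b
        length[mid] = la * 0.5
        parent[leaf] = mid
        length[leaf] = rng.uniform(0.05, 1.0)
        edges.remove((a, b))
        edges.extend([(a, mid), (mid, b), (leaf, mid)])
    # distances by walking to root
    def path_to_root(x):
        out = {}
        acc = 0.0
        while x in parent:
            out[x] = acc
            acc += length[x]
            x = parent[x]
        out[x] = acc
        return out

    D = np.zeros((n, n))
    paths = [path_to_root(i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(paths[i]) & set(paths[j])
            d = min(paths[i][k] + paths[j][k] for k in shared)
            D[i, j] = D[j, i] = d
    return D


class TestDistanceMatrix:
    def test_identical_sequences_distance_zero(self):
        s = sd.subgroup_scaffold("PIP1")
        dm = build_distance_matrix([("a", s), ("b", s)])
        assert dm.get("a", "b") == 0.0

    def test_matches_elementwise_oracle(self):
        from beetaqp.align_extract import pairwise_identity

        records = [(sg, sd.subgroup_scaffold(sg)) for sg in ("PIP1", "TIP2", "SIP1")]
        dm = build_distance_matrix(records)
        for i, (ida, sa) in enumerate(records):
            for j, (idb, sb) in enumerate(records):
                if i < j:
                    assert dm.get(ida, idb) == pytest.approx(
                        1.0 - pairwise_identity(sa, sb), abs=1e-12)

    def test_invariant_to_input_order(self):
        records = [(sg, sd.subgroup_scaffold(sg)) for sg in ("PIP1", "NIP5", "XIP1")]
        dm1 = build_distance_matrix(records)
        dm2 = build_distance_matrix(records[::-1])
        assert dm1.get("PIP1", "XIP1") == dm2.get("PIP1", "XIP1")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_distance_matrix([("a", "ACDE"), ("a", "ACDF")])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        ids = ["a", "b", "c", "d"]
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10],
                      [8, 9, 0, 9], [9, 10, 9, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, D))
        td = tree_distances(tree)
        for i in range(4):
            for j in range(i + 1, 4):
                assert td[frozenset((ids[i], ids[j]))] == pytest.approx(
                    D[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["a"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["b"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["c"] == pytest.approx((6 + 8 - 4) / 2)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_recovery_up_to_eight_taxa(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(3):
            D = random_additive_matrix(n, rng)
            ids = [f"t{i}" for i in range(n)]
            td = tree_distances(nj_tree(DistanceMatrix(ids, D)))
            for i in range(n):
                for j in range(i + 1, n):
                    assert td[frozenset((ids[i], ids[j]))] == pytest.approx(
                        D[i, j], abs=1e-9)

    def test_topology_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(23)
        D = random_additive_matrix(6, rng)
        ids = [f"t{i}" for i in range(6)]
        mine = nj_tree(DistanceMatrix(ids, D))
        ref = skbio_nj(SkbioDM(D, ids))
        anchor_leaf = sorted(ids)[0]
        ref_splits = set()
        for node in ref.non_tips():
            below = {t.name for t in node.tips()}
            if 2 <= len(below) <= len(ids) - 2:
                side = below if anchor_leaf not in below else set(ids) - below
                ref_splits.add(frozenset(side))
        assert bipartitions(mine) == ref_splits

    def test_star_matrix_total_length_matches_minimum(self):
        # equidistant taxa: every resolution has the same total length
        n = 5
        D = np.full((n, n), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], D))

        def total(node):
            return node.length + sum(total(c) for c in node.children)

        assert total(tree) == pytest.approx(n * 1.0, abs=1e-9)

    def test_two_taxa_rejected(self):
        with pytest.raises(ValueError, match="3"):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.]])))


class TestAssignment:
    def test_query_identical_to_reference(self, panel):
        records, labels = panel
        query = ("q", dict(records)["ref_PIP2"])
        dm = build_distance_matrix(records + [query])
        tree = nj_tree(dm)
        a = assign_subfamily("q", tree, labels, dm)
        assert (a.family, a.subgroup) == ("PIP", "PIP2")
        assert a.support == 1.0

    def test_twenty_mutated_queries_all_correct(self, panel):
        records, labels = panel
        queries, truth = sd.make_proteome(n_aqp=20, n_decoy=0,
                                          mutation_rate=0.1, seed=11)
        dm = build_distance_matrix(records + queries)
        tree = nj_tree(dm)
        correct = sum(
            assign_subfamily(q, tree, labels, dm).subgroup
            == truth.planted_aqps[q].subgroup
            for q, _ in queries
        )
        assert correct == 20

    def test_invariant_to_panel_order(self, panel):
        records, labels = panel
        queries, _ = sd.make_proteome(n_aqp=3, n_decoy=0, seed=5)
        dm1 = build_distance_matrix(records + queries)
        dm2 = build_distance_matrix(records[::-1] + queries)
        a1 = [assign_subfamily(q, nj_tree(dm1), labels, dm1).subgroup
              for q, _ in queries]
        a2 = [assign_subfamily(q, nj_tree(dm2), labels, dm2).subgroup
              for q, _ in queries]
        assert a1 == a2

    def test_query_closer_to_sister_subgroup_goes_there(self, panel):
        # a SIP2-named sequence nearer the SIP1 references is assigned SIP1
        records, labels = panel
        near_sip1 = sd.subgroup_scaffold("SIP1")
        seq = list(near_sip1)
        rng = np.random.default_rng(3)
        for p in rng.choice(len(seq), size=12, replace=False):
            seq[p] = "G"
        query = ("q_sip_like", "".join(seq))
        dm = build_distance_matrix(records + [query])
        a = assign_subfamily("q_sip_like", nj_tree(dm), labels, dm)
        assert a.subgroup == "SIP1"
        assert a.method in ("nj_clade", "nearest_ref")

    def test_proposed_name_numbers_after_existing(self):
        existing = ["BvPIP2;1", "BvPIP2;2", "BvPIP2;4", "BvTIP1;1"]
        assert next_free_name("PIP2", existing) == "BvPIP2;5"
        assert next_free_name("NIP3", existing) == "BvNIP3;1"

    def test_empty_panel_rejected(self, panel):
        records, _ = panel
        queries, _ = sd.make_proteome(n_aqp=1, n_decoy=0, seed=5)
        dm = build_distance_matrix(records + queries)
        tree = nj_tree(dm)
        with pytest.raises(ValueError, match="panel"):
            assign_subfamily(queries[0][0], tree, {}, dm)

    def test_nearest_reference_tie_breaks_lexicographically(self):
        dm = DistanceMatrix(["q", "a", "b"],
                            np.array([[0, .2, .2], [.2, 0, .1], [.2, .1, 0.]]))
        assert nearest_reference("q", {"a": "X", "b": "Y"}, dm) == "a"


@pytest.fixture(scope="module")
def two_clades():
    rng = np.random.default_rng(5)

    def mutate(seq, k):
        s = list(seq)
        for p in rng.choice(len(s), size=k, replace=False):
            s[p] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
        return "".join(s)

    return ([(f"A{i}", mutate(sd.subgroup_scaffold("PIP1"), 8))
             for i in range(3)]
            + [(f"B{i}", mutate(sd.subgroup_scaffold("SIP2"), 8))
               for i in range(3)])


class TestBootstrap:

    def test_separating_edge_strongly_supported(self, two_clades):
        boot = bootstrap_support(two_clades, replicates=100, seed=3)
        split = frozenset({"B0", "B1", "B2"})
        assert boot.supports[split] >= 0.95

    def test_single_replicate_supports_are_binary(self, two_clades):
        boot = bootstrap_support(two_clades, replicates=1, seed=9)
        assert set(boot.supports.values()) <= {0.0, 1.0}

    def test_same_seed_reproduces(self, two_clades):
        b1 = bootstrap_support(two_clades, replicates=25, seed=4)
        b2 = bootstrap_support(two_clades, replicates=25, seed=4)
        assert b1.supports == b2.supports

    def test_zero_replicates_rejected(self, two_clades):
        with pytest.raises(ValueError):
            bootstrap_support(two_clades, replicates=0, seed=1)
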