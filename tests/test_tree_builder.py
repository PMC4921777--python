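import dendropy
import numpy as np
import pytest

from cladesig.msa_pipeline import Msa
from cladesig.sequence_io import SequenceRecord
from cladesig.synthetic_data import simulate_tree
from cladesig.tree_builder import (DistanceMatrix, bootstrap_support,
                                   distance_matrix, midpoint_root,
                                   neighbor_joining, rf_distance)


def _leaf_depths(tree):
    out = {}
    for leaf in tree.leaf_node_iter():
        d, n = 0.0, leaf
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        out[leaf.taxon.label] = d
    return out


def _tree_pdm(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], d


class TestDistanceMatrix:
    def _msa(self, rows):
        return Msa([SequenceRecord(f"s{i}", f"t{i}", r)
                    for i, r in enumerate(rows)])

    def test_identical_rows_zero_distance(self):
        dm = distance_matrix(self._msa(["ACDEFGHIKL"] * 3), model="p")
        assert np.allclose(dm.d, 0.0)

    def test_p_distance_arithmetic(self):
        rows = ["ACDEFGHIKL", "ACDEFGHWYV", "ACDEFGHIKL"]
        dm = distance_matrix(self._msa(rows), model="p")
        assert dm[("t0", "t1")] == pytest.approx(0.3)

    def test_pairwise_deletion_of_gap_columns(self):
        rows = ["ACDEFGHIKL", "-CDEFGHIKW", "ACDEFGHIK-"]
        dm = distance_matrix(self._msa(rows), model="p")
        # t0 vs t1: 9 comparable, 1 mismatch
        assert dm[("t0", "t1")] == pytest.approx(1 / 9)

    def test_matches_brute_force_count(self, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        rows = ["".join(rng.choice(alphabet, 200)) for _ in range(5)]
        dm = distance_matrix(self._msa(rows), model="p")
        for i in range(5):
            for j in range(5):
                num = den = 0
                for a, b in zip(rows[i], rows[j]):
                    if a != "-" and b != "-":
                        den += 1
                        num += a != b
                assert dm.d[i, j] == pytest.approx(num / den)

    def test_poisson_transform_and_overflow(self):
        rows = ["AAAAAAAAAA", "AAAAACCCCC", "AAAAAAAACC"]
        dm = distance_matrix(self._msa(rows), model="poisson")
        assert dm[("t0", "t1")] == pytest.approx(-np.log(0.5))
        with pytest.raises(ValueError, match="Poisson"):
            distance_matrix(self._msa(["AAAA", "CCCC", "AAAA"]),
                            model="poisson")

    def test_disjoint_gap_pattern_error_names_pair(self):
        rows = ["AC--", "--DE", "ACDE"]
        with pytest.raises(ValueError, match="t0.*t1"):
            distance_matrix(self._msa(rows), model="p")


class TestNeighborJoining:
    def test_recovers_hand_worked_additive_matrix(self):
        """Tree ((A:1,B:2):1,(C:3,D:1)); the matrix satisfies the
        four-point condition and NJ must invert it exactly."""
        taxa = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], dtype=float)
        # four-point condition check (the matrix is additive)
        sums = sorted([d[0, 1] + d[2, 3], d[0, 2] + d[1, 3],
                       d[0, 3] + d[1, 2]])
        assert sums[1] == sums[2] and sums[0] <= sums[1]
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        labels, pd = _tree_pdm(tree)
        assert labels == taxa
        assert np.allclose(pd, d, atol=1e-12)
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0}

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("seed", range(3))
    def test_inverts_random_additive_matrices(self, seed):
        for rep in range(20):
            true = simulate_tree(8, 1000 * seed + rep, 0.2)
            labels, d = _tree_pdm(true)
            got = neighbor_joining(DistanceMatrix(labels, d))
            assert rf_distance(got, true) == 0

    def test_agrees_with_skbio_on_additive_input(self):
        skbio_nj = pytest.importorskip("skbio.tree").nj
        from skbio import DistanceMatrix as SkDM
        true = simulate_tree(7, 99, 0.3)
        labels, d = _tree_pdm(true)
        ours = neighbor_joining(DistanceMatrix(labels, d))
        theirs = dendropy.Tree.get(data=str(skbio_nj(SkDM(d, labels))),
                                   schema="newick")
        assert rf_distance(ours, true) == 0
        assert rf_distance(ours, theirs) == 0


class TestMidpointRoot:
    def test_symmetric_tree_roots_on_central_edge(self):
        t = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                              schema="newick")
        r = midpoint_root(t)
        depths = _leaf_depths(r)
        assert all(d == pytest.approx(2.0) for d in depths.values())
        assert len(r.seed_node.child_nodes()) == 2

    def test_caterpillar_midpoint_position(self):
        # longest path A-C/A-D has length 9; midpoint 4.5 along A's branch
        t = dendropy.Tree.get(data="((A:5,B:1):2,(C:1,D:1):1);",
                              schema="newick")
        r = midpoint_root(t)
        depths = _leaf_depths(r)
        assert depths["A"] == pytest.approx(4.5)
        assert depths["C"] == pytest.approx(4.5)
        assert depths["D"] == pytest.approx(4.5)
        assert depths["B"] == pytest.approx(1.5)

    def test_farthest_leaves_equidistant_on_random_trees(self):
        for seed in range(5):
            t = simulate_tree(10, seed, 0.5)
            r = midpoint_root(t)
            depths = _leaf_depths(r)
            assert max(depths.values()) == pytest.approx(
                _longest_path(t) / 2, abs=1e-9)

    def test_idempotent(self):
        t = dendropy.Tree.get(data="((A:5,B:1):2,(C:1,D:1):1);",
                              schema="newick")
        r1 = midpoint_root(t)
        r2 = midpoint_root(r1)
        assert _leaf_depths(r1) == pytest.approx(_leaf_depths(r2))
        assert rf_distance(r1, r2) == 0

    def test_zero_length_tree_rejected(self):
        t = dendropy.Tree.get(data="((A:0,B:0):0,(C:0,D:0):0);",
                              schema="newick")
        with pytest.raises(ValueError):
            midpoint_root(t)


def _longest_path(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    return max(pdm.distance(a, b) for a in taxa for b in taxa)


class TestRfDistance:
    def test_identical_trees(self):
        t1 = simulate_tree(8, 3)
        t2 = simulate_tree(8, 3)
        assert rf_distance(t1, t2) == 0

    def test_two_resolutions_of_quartet(self):
        a = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        b = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
        assert rf_distance(a, b) == 2

    def test_leaf_set_mismatch_rejected(self):
        a = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        b = dendropy.Tree.get(data="((A,B),(C,E));", schema="newick")
        with pytest.raises(ValueError, match="leaf sets"):
            rf_distance(a, b)

    def test_matches_dendropy_bipartition_oracle(self):
        for seed in range(10):
            t1 = simulate_tree(8, seed)
            t2 = simulate_tree(8, seed + 100)
            ns = dendropy.TaxonNamespace()
            a = dendropy.Tree.get(data=t1.as_string("newick"),
                                  schema="newick", taxon_namespace=ns)
            b = dendropy.Tree.get(data=t2.as_string("newick"),
                                  schema="newick", taxon_namespace=ns)
            expect = dendropy.calculate.treecompare.symmetric_difference(a, b)
            assert rf_distance(t1, t2) == expect


class TestBootstrap:
    def _supermatrix_like(self, seed=0, length=300):
        # strong signal: evolve one long alignment down a known tree
        from cladesig.synthetic_data import evolve_family
        tree = simulate_tree(6, seed, 0.15)
        seqs, _ = evolve_family(tree, length, 1.0, seed)
        msa = Msa([SequenceRecord(k, k, v) for k, v in sorted(seqs.items())])
        return tree, msa

    def test_true_bipartitions_supported_on_clean_signal(self):
        tree, msa = self._supermatrix_like(2, 800)
        booted = bootstrap_support(msa, 100, seed=5)
        assert rf_distance(booted, tree) == 0
        supports = [n.support for n in booted.preorder_node_iter()
                    if hasattr(n, "support")]
        assert supports and all(s >= 0.9 for s in supports)

    def test_single_replicate_supports_are_binary(self):
        _, msa = self._supermatrix_like(3)
        booted = bootstrap_support(msa, 1, seed=9)
        supports = [n.support for n in booted.preorder_node_iter()
                    if hasattr(n, "support")]
        assert supports and all(s in (0.0, 1.0) for s in supports)

    def test_same_seed_reproduces_supports(self):
        _, msa = self._supermatrix_like(4)
        b1 = bootstrap_support(msa, 25, seed=11)
        b2 = bootstrap_support(msa, 25, seed=11)
        s1 = [n.support for n in b1.preorder_node_iter()
              if hasattr(n, "support")]
        s2 = [n.support for n in b2.preorder_node_iter()
              if hasattr(n, "support")]
        assert s1 == s2
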