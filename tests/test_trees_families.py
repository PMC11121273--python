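import numpy as np
import pytest

from popconserve import (
    SimConfig,
    assign_females,
    build_families,
    cluster_males,
    grm,
    nj_tree,
    simulate_population,
)
from popconserve.families import FamilyError
from popconserve.relatedness import KinshipMatrix
from popconserve.trees import TreeError, TreeNode

from oracles import random_additive_tree


def kin(ids, values):
    return KinshipMatrix(ids, np.asarray(values, dtype=float), "G")


class TestNJ:
    def test_two_taxa_split_edge_evenly(self):
        tree = nj_tree(np.array([[0.0, 0.4], [0.4, 0.0]]), ids=["A", "B"])
        assert sorted(tree.leaves()) == ["A", "B"]
        assert [bl for _, bl in tree.children] == pytest.approx([0.2, 0.2])

    def test_three_taxa_closed_form_branch_lengths(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = nj_tree(d, ids=["A", "B", "C"])
        lengths = {}
        for child, bl in tree.children:
            if child.is_leaf:
                lengths[child.label] = bl
            else:
                for grand, gbl in child.children:
                    lengths[grand.label] = gbl
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_additive_six_taxon_topology_recovered(self, rng):
        labels, d, true_splits = random_additive_tree(rng, 6)
        tree = nj_tree(d, ids=labels)
        assert tree.splits() == true_splits

    def test_random_additive_matrices_recovered(self, rng):
        for n in (6, 7, 8):
            for _ in range(15):
                labels, d, true_splits = random_additive_tree(rng, n)
                assert nj_tree(d, ids=labels).splits() == true_splits

    def test_matches_skbio_on_additive_matrices(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix

        for _ in range(5):
            labels, d, _ = random_additive_tree(rng, 7)
            mine = nj_tree(d, ids=labels).splits()
            theirs_tree = skbio.tree.nj(DistanceMatrix(d, ids=labels))
            theirs = set()
            n_taxa = len(labels)
            for node in theirs_tree.non_tips():
                clade = frozenset(t.name for t in node.tips())
                if 1 < len(clade) < n_taxa - 1:
                    comp = frozenset(labels) - clade
                    theirs.add(min(clade, comp, key=sorted))
            assert mine == theirs

    def test_branch_lengths_never_negative(self, rng):
        for _ in range(10):
            n = 6
            m = rng.random((n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            stack = [nj_tree(d, ids=[f"t{i}" for i in range(n)])]
            while stack:
                node = stack.pop()
                for child, bl in node.children:
                    assert bl >= 0.0
                    stack.append(child)

    def test_newick_round_trip_through_skbio(self):
        skbio = pytest.importorskip("skbio")
        import io

        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = nj_tree(d, ids=["A", "B", "C"])
        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        assert sorted(t.name for t in parsed.tips()) == ["A", "B", "C"]

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(TreeError):
            nj_tree(np.array([[0.0, 1.0], [0.5, 0.0]]), ids=["a", "b"])

    def test_single_taxon_rejected(self):
        with pytest.raises(TreeError):
            nj_tree(np.zeros((1, 1)), ids=["a"])


class TestClusterMales:
    IDS = ["m1", "m2", "m3", "m4"]

    def base_matrix(self, pairs):
        v = np.zeros((4, 4))
        np.fill_diagonal(v, 1.0)
        for a, b, val in pairs:
            i, j = self.IDS.index(a), self.IDS.index(b)
            v[i, j] = v[j, i] = val
        return kin(self.IDS, v)

    def test_one_related_pair_gives_three_families(self):
        k = self.base_matrix([("m1", "m3", 0.3)])
        assert cluster_males(k, self.IDS, 0.1) == [["m1", "m3"], ["m2"], ["m4"]]

    def test_all_unrelated_gives_singletons(self):
        k = self.base_matrix([])
        assert cluster_males(k, self.IDS, 0.1) == [["m1"], ["m2"], ["m3"], ["m4"]]

    def test_all_related_gives_one_family(self):
        v = np.full((4, 4), 0.2)
        np.fill_diagonal(v, 1.0)
        assert cluster_males(kin(self.IDS, v), self.IDS, 0.1) == [self.IDS]

    def test_transitive_closure_links_indirectly_related_males(self):
        k = self.base_matrix([("m1", "m2", 0.15), ("m2", "m4", 0.15)])
        assert cluster_males(k, self.IDS, 0.1) == [["m1", "m2", "m4"], ["m3"]]

    def test_no_males_rejected(self):
        with pytest.raises(FamilyError):
            cluster_males(self.base_matrix([]), [], 0.1)

    def test_threshold_monotonicity_refines_partition(self, rng):
        m = rng.random((6, 6)) * 0.4
        v = (m + m.T) / 2
        np.fill_diagonal(v, 1.0)
        ids = [f"m{i}" for i in range(6)]
        k = kin(ids, v)
        low = cluster_males(k, ids, 0.1)
        high = cluster_males(k, ids, 0.25)
        for comp in high:
            assert any(set(comp) <= set(big) for big in low)


class TestAssignFemales:
    def test_female_joins_best_family_at_threshold(self):
        ids = ["m1", "m2", "f1"]
        v = np.eye(3)
        v[0, 2] = v[2, 0] = 0.05
        v[1, 2] = v[2, 1] = 0.26
        fam = assign_females(kin(ids, v), [["m1"], ["m2"]], ["f1"], 0.1)
        assert fam.families[1].females == ["f1"]
        assert fam.other == []

    def test_unrelated_female_goes_to_other(self):
        ids = ["m1", "f1"]
        v = np.eye(2)
        v[0, 1] = v[1, 0] = 0.09
        fam = assign_females(kin(ids, v), [["m1"]], ["f1"], 0.1)
        assert fam.other == ["f1"]
        assert fam.families[0].females == []

    def test_tie_goes_to_lowest_family_id(self):
        ids = ["m1", "m2", "f1"]
        v = np.eye(3)
        v[0, 2] = v[2, 0] = 0.3
        v[1, 2] = v[2, 1] = 0.3
        fam = assign_females(kin(ids, v), [["m1"], ["m2"]], ["f1"], 0.1)
        assert fam.families[0].females == ["f1"]

    def test_membership_covers_every_sample_once(self):
        ids = ["m1", "m2", "f1", "f2", "f3"]
        v = np.eye(5)
        v[0, 2] = v[2, 0] = 0.4
        fam = assign_females(kin(ids, v), [["m1"], ["m2"]], ["f1", "f2", "f3"], 0.1)
        members = fam.membership()
        assert set(members) == set(ids)


class TestPedigreeRecovery:
    CFG = SimConfig(
        n_chrom=8, chrom_length_bp=80_000_000, n_snps=10_000,
        n_sire_families=3, n_daughters=28, target_froh=0.0, seed=31,
    )

    def test_paternity_recovered_from_genomic_kinship(self):
        gm, ped = simulate_population(self.CFG)
        g = grm(gm)
        males = [f"M{i + 1}" for i in range(4)]
        females = [f"F{i + 1}" for i in range(28)]
        fam = build_families(g, males, females, 0.1)
        assert [f.males for f in fam.families] == ped.families
        fam_of_sire = {
            m: i for i, f in enumerate(fam.families) for m in f.males
        }
        correct = sum(
            1
            for f in fam.families
            for fem in f.females
            if fam_of_sire[ped.paternity[fem]] == f.family_id - 1
        )
        assert correct >= 0.95 * 28

    def test_partition_invariant_to_sample_order(self, rng):
        gm, _ = simulate_population(self.CFG)
        g = grm(gm)
        males = [f"M{i + 1}" for i in range(4)]
        females = [f"F{i + 1}" for i in range(28)]
        base = build_families(g, males, females, 0.1).partition()
        perm = rng.permutation(gm.n_samples)
        gm_p = gm.subset(sample_ids=[gm.sample_ids[i] for i in perm])
        g_p = grm(gm_p)
        shuffled = build_families(
            g_p,
            [m for m in gm_p.sample_ids if m.startswith("M")],
            [f for f in gm_p.sample_ids if f.startswith("F")],
            0.1,
        ).partition()
        assert shuffled == base
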