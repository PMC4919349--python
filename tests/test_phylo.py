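"""Distances, neighbor joining, outgroup rooting, and clade membership."""

import itertools

import numpy as np
import pytest

from oracles import p_distance_oracle
from sterolscan.align import MultipleAlignment
from sterolscan.core_io import ProteinRecord
from sterolscan.phylo import (
    DistanceMatrix,
    IncomparablePairError,
    PhyloTree,
    clade_membership,
    neighbor_joining,
    pairwise_distances,
    root_with_outgroup,
)
from sterolscan.simulate import SimulationConfig, simulate_family


def random_additive_tree(rng, n_leaves):
    """A random binary tree with random branch lengths, as nested tuples."""
    nodes = [(f"t{i}", 0.0) for i in range(n_leaves)]
    trees = [(name, None) for name, _ in nodes]
    items = [f"t{i}" for i in range(n_leaves)]
    # represent as dict: leaf -> None; build by repeated joining
    subtrees = [(f"t{i}",) for i in range(n_leaves)]
    structure = list(range(n_leaves))
    nested = [f"t{i}" for i in range(n_leaves)]
    lengths = {}
    while len(nested) > 1:
        i, j = sorted(rng.choice(len(nested), size=2, replace=False))
        li = round(float(rng.uniform(0.5, 5.0)), 3)
        lj = round(float(rng.uniform(0.5, 5.0)), 3)
        merged = (nested[i], li, nested[j], lj)
        nested = [nested[k] for k in range(len(nested)) if k not in (i, j)] + [merged]
    return nested[0]


def path_lengths(tree):
    """Leaf-to-leaf path length matrix of a nested-tuple tree."""
    def depths(node, acc):
        if isinstance(node, str):
            return {node: acc}
        left, ll, right, rl = node
        out = {}
        out.update(depths(left, acc + ll))
        out.update(depths(right, acc + rl))
        return out

    def collect(node):
        if isinstance(node, str):
            return {node: 0.0}, {}
        left, ll, right, rl = node
        dl, pl = collect(left)
        dr, pr = collect(right)
        paths = {}
        paths.update(pl)
        paths.update(pr)
        for a, da in dl.items():
            for b, db in dr.items():
                paths[(a, b)] = da + ll + db + rl
        merged = {k: v + ll for k, v in dl.items()}
        merged.update({k: v + rl for k, v in dr.items()})
        return merged, paths

    _, paths = collect(tree)
    leaves = sorted({x for pair in paths for x in pair})
    mat = np.zeros((len(leaves), len(leaves)))
    idx = {l: i for i, l in enumerate(leaves)}
    for (a, b), d in paths.items():
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = d
    return tuple(leaves), mat


class TestPairwiseDistances:
    def test_identical_rows_have_zero_distance(self):
        msa = MultipleAlignment(ids=("a", "b", "c"), rows=("MKLV", "MKLV", "MKLW"))
        dm = pairwise_distances(msa)
        assert dm.distance("a", "b") == 0.0

    def test_quarter_mismatch(self):
        msa = MultipleAlignment(ids=("a", "b", "c"), rows=("MKLV", "MKLW", "MMMM"))
        dm = pairwise_distances(msa)
        assert dm.distance("a", "b") == pytest.approx(0.25)

    def test_random_msa_matches_column_scan_oracle(self):
        rng = np.random.default_rng(67)
        alphabet = list("ACDEFG-")
        rows = tuple(
            "".join(rng.choice(alphabet, size=30)) for _ in range(5)
        )
        msa = MultipleAlignment(ids=tuple(f"r{i}" for i in range(5)), rows=rows)
        dm = pairwise_distances(msa)
        for i, j in itertools.combinations(range(5), 2):
            assert dm.values[i, j] == pytest.approx(p_distance_oracle(rows[i], rows[j]))

    def test_poisson_correction_exceeds_p_distance(self):
        msa = MultipleAlignment(ids=("a", "b", "c"), rows=("MKLV", "MKWW", "MMMM"))
        p = pairwise_distances(msa, "p_distance")
        c = pairwise_distances(msa, "poisson_corrected")
        assert c.distance("a", "b") > p.distance("a", "b") > 0

    def test_incomparable_pair_is_named(self):
        msa = MultipleAlignment(ids=("a", "b", "c"), rows=("AA--", "--AA", "AAAA"))
        with pytest.raises(IncomparablePairError, match="'a' and 'b'"):
            pairwise_distances(msa)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(ids=("A", "B", "C"), values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = neighbor_joining(dm)
        assert tree.leaf_distance("A", "B") == pytest.approx(3)
        assert tree.leaf_distance("A", "C") == pytest.approx(4)
        assert tree.leaf_distance("B", "C") == pytest.approx(5)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):3,(C:4,D:5))
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float)
        dm = DistanceMatrix(ids=tuple("ABCD"), values=D)
        tree = neighbor_joining(dm)
        for i, a in enumerate("ABCD"):
            for b in "ABCD"[i + 1 :]:
                assert tree.leaf_distance(a, b) == pytest.approx(dm.distance(a, b), abs=1e-9)
        # cherry {A,B} must exist: the split is recovered
        newick = tree.newick()
        assert "(A:1,B:2)" in newick or "(B:2,A:1)" in newick

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_random_additive_matrices_recovered(self, n_leaves):
        rng = np.random.default_rng(1000 + n_leaves)
        nested = random_additive_tree(rng, n_leaves)
        leaves, mat = path_lengths(nested)
        dm = DistanceMatrix(ids=leaves, values=mat)
        tree = neighbor_joining(dm)
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                assert tree.leaf_distance(a, b) == pytest.approx(dm.distance(a, b), abs=1e-9)

    def test_ultrametric_eight_taxa_additivity(self):
        # balanced clock tree: pairwise path lengths reproduce the matrix
        rng = np.random.default_rng(321)
        nested = ("t0", 1.0, "t1", 1.0)
        nested = (nested, 1.0, ("t2", 1.0, "t3", 1.0), 1.0)
        right = ((("t4", 1.0, "t5", 1.0), 1.0, ("t6", 1.0, "t7", 1.0), 1.0))
        nested = (nested, 1.0, right, 1.0)
        leaves, mat = path_lengths(nested)
        dm = DistanceMatrix(ids=leaves, values=mat)
        tree = neighbor_joining(dm)
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                assert abs(tree.leaf_distance(a, b) - dm.distance(a, b)) <= 1e-9

    def test_agrees_with_skbio_on_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(88)
        nested = random_additive_tree(rng, 6)
        leaves, mat = path_lengths(nested)
        ours = neighbor_joining(DistanceMatrix(ids=leaves, values=mat))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(mat, ids=list(leaves)))
        ours_sk = skbio.TreeNode.read([ours.newick()])
        assert theirs.compare_rfd(ours_sk) == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(ids=("A", "B"), values=np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            neighbor_joining(dm)


class TestRootingAndClades:
    @pytest.fixture()
    def four_taxon_tree(self):
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float)
        return neighbor_joining(DistanceMatrix(ids=tuple("ABCD"), values=D))

    def test_single_leaf_outgroup_roots_on_its_branch(self, four_taxon_tree):
        rooted = root_with_outgroup(four_taxon_tree, ["A"])
        assert rooted.rooted
        children = rooted.dtree.seed_node.child_nodes()
        assert len(children) == 2
        sides = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in children]
        assert frozenset({"A"}) in sides

    def test_rooting_preserves_leaf_path_lengths(self, four_taxon_tree):
        rooted = root_with_outgroup(four_taxon_tree, ["A"])
        for a, b in itertools.combinations("ABCD", 2):
            assert rooted.leaf_distance(a, b) == pytest.approx(
                four_taxon_tree.leaf_distance(a, b), abs=1e-9
            )

    def test_scattered_outgroup_raises_with_intruders(self, four_taxon_tree):
        with pytest.raises(ValueError, match="not monophyletic"):
            root_with_outgroup(four_taxon_tree, ["A", "C"])

    def test_deep_split_family_separates_at_the_root(self):
        """Two divergent simulated families (Osc-like vs Shc-like outgroup)."""
        osc, _ = simulate_family(SimulationConfig(seed=41, n_taxa=4, divergence=0.1))
        shc, _ = simulate_family(
            SimulationConfig(seed=42, n_taxa=3, divergence=0.1, class_assignments="CAS")
        )
        rows, ids = [], []
        for rec in osc:
            ids.append("osc_" + rec.id)
            rows.append(rec.sequence)
        for rec in shc:
            ids.append("shc_" + rec.id)
            rows.append(rec.sequence)
        msa = MultipleAlignment(ids=tuple(ids), rows=tuple(rows))
        tree = neighbor_joining(pairwise_distances(msa))
        outgroup = [i for i in ids if i.startswith("shc_")]
        rooted = root_with_outgroup(tree, outgroup)
        sides = [
            frozenset(l.taxon.label for l in c.leaf_iter())
            for c in rooted.dtree.seed_node.child_nodes()
        ]
        assert frozenset(outgroup) in sides

    def test_clean_clades_are_monophyletic(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        mono, _ = clade_membership(tree, {"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        assert mono == {"g1": True, "g2": True}

    def test_grafted_taxon_breaks_monophyly(self):
        tree = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);", rooted=True)
        mono, _ = clade_membership(tree, {"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        assert mono == {"g1": False, "g2": False}

    def test_unlabeled_query_assigned_to_enclosing_group(self):
        tree = PhyloTree.from_newick("(((A:1,q1:1):1,B:1):1,(C:1,D:1):1);", rooted=True)
        _, assign = clade_membership(tree, {"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        assert assign == {"q1": "g1"}

    def test_unlabeled_tree_is_precondition_error(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1);", rooted=True)
        with pytest.raises(ValueError):
            clade_membership(tree, {"X": "g1"})

    def test_fragments_from_one_group_assigned_to_it(self):
        """Truncated members of group A cluster with and are assigned to A."""
        fam_a, _ = simulate_family(SimulationConfig(seed=51, n_taxa=6, divergence=0.08))
        fam_b, _ = simulate_family(
            SimulationConfig(seed=52, n_taxa=4, divergence=0.08, class_assignments="CAS")
        )
        length = len(fam_a[0].sequence)
        ids, rows, groups = [], [], {}
        for k, rec in enumerate(fam_a[:4]):
            ids.append(f"A{k}")
            rows.append(rec.sequence)
            groups[f"A{k}"] = "A"
        for k, rec in enumerate(fam_b):
            ids.append(f"B{k}")
            rows.append(rec.sequence)
            groups[f"B{k}"] = "B"
        # fragments of the two remaining A members, gap-padded at their true offsets
        frags = []
        for k, rec in enumerate(fam_a[4:]):
            start = 100 + 50 * k
            frag = rec.sequence[start : start + 420]
            rows.append("-" * start + frag + "-" * (length - start - len(frag)))
            ids.append(f"q{k}")
            frags.append(f"q{k}")
        msa = MultipleAlignment(ids=tuple(ids), rows=tuple(rows))
        tree = root_with_outgroup(
            neighbor_joining(pairwise_distances(msa)), [i for i in ids if i.startswith("B")]
        )
        _, assign = clade_membership(tree, groups)
        correct = sum(1 for q in frags if assign[q] == "A")
        assert correct / len(frags) >= 0.95


class TestNewickRoundTrip:
    def test_topology_labels_and_lengths_preserved(self):
        rng = np.random.default_rng(99)
        nested = random_additive_tree(rng, 7)
        leaves, mat = path_lengths(nested)
        tree = neighbor_joining(DistanceMatrix(ids=leaves, values=mat))
        reparsed = PhyloTree.from_newick(tree.newick())
        assert sorted(reparsed.leaf_labels) == sorted(tree.leaf_labels)
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                assert reparsed.leaf_distance(a, b) == pytest.approx(
                    tree.leaf_distance(a, b), abs=1e-9
                )

    def test_negative_branch_lengths_clamped_with_warning(self):
        # triangle-violating matrix: the C limb estimate is (3+3-10)/2 = -2
        D = np.array([[0, 10, 3], [10, 0, 3], [3, 3, 0]], float)
        dm = DistanceMatrix(ids=tuple("ABC"), values=D)
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(dm)
        for a, b in itertools.combinations("ABC", 2):
            assert tree.leaf_distance(a, b) >= 0
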