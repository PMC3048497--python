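import numpy as np
import pytest

from tlpcensus import synthetic_data as synth
from tlpcensus.io_formats import Alignment
from tlpcensus.phylo import (
    DistanceMatrix,
    assign_clades,
    bootstrap_support,
    nj_tree,
    pdistance_matrix,
    poisson_correct,
)
from tlpcensus.tree import TreeNode, robinson_foulds

from tests.oracles import least_squares_best_topology


def matrix_from(labels, mat):
    mat = np.asarray(mat, dtype=float)
    n = len(labels)
    return DistanceMatrix(
        labels=tuple(labels),
        p=mat.copy(),
        d=mat,
        usable=np.full((n, n), 100, dtype=int),
        undefined=np.zeros((n, n), dtype=bool),
    )


class TestPDistance:
    def test_identical_sequences(self):
        dm = pdistance_matrix(Alignment(("a", "b"), ("ACDE", "ACDE")))
        assert dm.p[0, 1] == 0.0 and dm.usable[0, 1] == 4

    def test_one_difference(self):
        dm = pdistance_matrix(Alignment(("a", "b"), ("ACDE", "ACDF")))
        assert dm.p[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_excludes_gap_columns(self):
        dm = pdistance_matrix(Alignment(("a", "b"), ("A-DE", "ACDF")))
        assert dm.usable[0, 1] == 3
        assert dm.p[0, 1] == pytest.approx(1 / 3)

    def test_x_treated_as_missing(self):
        dm = pdistance_matrix(Alignment(("a", "b"), ("AXDE", "ACDF")))
        assert dm.usable[0, 1] == 3

    def test_zero_usable_columns_flagged_undefined(self):
        dm = pdistance_matrix(Alignment(("a", "b", "c"), ("A---", "-CDF", "ACDF")))
        assert dm.undefined_pairs() == [("a", "b")]
        with pytest.raises(ValueError, match="a.*b"):
            nj_tree(dm)


class TestPoissonCorrection:
    def test_zero(self):
        assert poisson_correct(0.0) == 0.0

    def test_half(self):
        assert poisson_correct(0.5) == pytest.approx(0.693147, abs=1e-6)

    def test_near_saturation_and_limit(self):
        assert poisson_correct(0.95) == pytest.approx(2.9957, abs=1e-4)
        assert np.isnan(poisson_correct(1.0))


class TestNeighbourJoining:
    def test_three_point_formulas(self):
        dm = matrix_from("ABC", [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = nj_tree(dm)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_additive_matrix_exact_recovery(self, n_leaves):
        for seed in range(10):
            true = synth.random_tree(n_leaves, seed=seed * 31 + n_leaves)
            labels, mat = true.distance_matrix()
            tree = nj_tree(matrix_from(labels, mat))
            assert robinson_foulds(true, tree) == 0
            el_true, el_est = true.edge_lengths(), tree.edge_lengths()
            assert set(el_true) == set(el_est)
            assert max(abs(el_true[k] - el_est[k]) for k in el_true) < 1e-9

    def test_matches_exhaustive_least_squares_on_perturbed_matrices(self):
        rng = np.random.default_rng(17)
        agree = 0
        n = 30
        for _ in range(n):
            true = synth.random_tree(5, rng=rng, bl_range=(0.05, 1.0))
            labels, mat = true.distance_matrix()
            noisy = np.asarray(mat) * (1.0 + rng.uniform(-0.05, 0.05, (5, 5)))
            noisy = (noisy + noisy.T) / 2.0
            np.fill_diagonal(noisy, 0.0)
            nj_splits = nj_tree(matrix_from(labels, noisy)).bipartitions()
            ls_splits = least_squares_best_topology(labels, noisy)
            agree += nj_splits == ls_splits
        assert agree >= int(0.95 * n)

    def test_identical_sequences_give_unresolved_star(self):
        aln = Alignment(tuple("abcd"), ("ACDE",) * 4)
        tree = nj_tree(pdistance_matrix(aln))
        assert all(child.is_leaf for child in tree.children)
        assert tree.bipartitions() == set()

    def test_rf_agrees_with_dendropy(self):
        import dendropy

        t1 = synth.random_tree(8, seed=1)
        t2 = synth.random_tree(8, seed=2)
        ours = robinson_foulds(t1, t2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.format_newick(), schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.format_newick(), schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert ours == theirs

    def test_matches_scikit_bio_on_additive_matrix(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        true = synth.random_tree(7, seed=99)
        labels, mat = true.distance_matrix()
        ours = nj_tree(matrix_from(labels, mat))
        theirs = skbio_nj(SkbioDM(np.asarray(mat), ids=list(labels)))
        their_tree = TreeNode.from_newick(str(theirs))
        assert robinson_foulds(ours, their_tree) == 0


class TestDistanceRecovery:
    def test_poisson_process_distance_recovered(self):
        d = 0.5
        tree = TreeNode(
            children=[TreeNode(name="L1", length=d / 2), TreeNode(name="L2", length=d / 2)]
        )
        rng = np.random.default_rng(3)
        root = synth.random_protein_sequence(10_000, rng)
        aln = synth.evolve_alignment(tree, root, seed=4)
        p = pdistance_matrix(aln).p[0, 1]
        assert abs(synth.corrected_distance(p) - d) < 0.05


@pytest.fixture(scope="module")
def sim_alignment():
    tree = TreeNode.from_newick(
        "((A:0.1,B:0.1):0.5,(C:0.1,D:0.1):0.5,(E:0.1,F:0.1):0.5);"
    )
    rng = np.random.default_rng(5)
    root = synth.random_protein_sequence(2_000, rng)
    return tree, synth.evolve_alignment(tree, root, seed=6)


class TestBootstrap:
    def test_same_seed_reproduces_supports_bit_identically(self, sim_alignment):
        _, aln = sim_alignment
        t1, d1 = bootstrap_support(aln, n_reps=100, seed=42)
        t2, d2 = bootstrap_support(aln, n_reps=100, seed=42)
        assert t1.format_newick() == t2.format_newick()
        assert d1 == d2

    def test_supports_are_fractions(self, sim_alignment):
        _, aln = sim_alignment
        tree, _ = bootstrap_support(aln, n_reps=100, seed=1)
        sup = [n.support for n in tree.walk() if n.support is not None]
        assert sup and all(0.0 <= s <= 1.0 for s in sup)

    def test_true_splits_strongly_supported(self, sim_alignment):
        true, aln = sim_alignment
        tree, diag = bootstrap_support(aln, n_reps=200, seed=2)
        assert robinson_foulds(true, tree) == 0
        support_of = {
            split: node.support
            for node, split in _node_splits(tree)
            if node.support is not None
        }
        for split in true.bipartitions():
            assert support_of[split] >= 0.95
        assert diag["n_undefined_replicates"] == 0

    def test_identical_sequences_star_without_supports(self):
        aln = Alignment(tuple("abcd"), ("ACDEFG",) * 4)
        tree, _ = bootstrap_support(aln, n_reps=20, seed=0)
        assert tree.bipartitions() == set()
        assert all(n.support is None for n in tree.walk())


def _node_splits(tree):
    leafsets = tree._leafsets()
    all_leaves = leafsets[id(tree)]
    ref = min(all_leaves)
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = leafsets[id(node)]
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            yield node, side


class TestCladeAssignment:
    @pytest.fixture
    def quartet(self):
        return TreeNode.from_newick("((A:1,B:1):1,(C:1,D:1):1);")

    def test_single_anchor_clades_leave_neighbours_unplaced(self, quartet):
        got = assign_clades(quartet, {"c1": {"A"}, "c2": {"C"}}).assignment
        assert got == {"A": "c1", "C": "c2", "B": "unplaced", "D": "unplaced"}

    def test_cherry_anchors_recover_full_bipartition(self, quartet):
        got = assign_clades(quartet, {"c1": {"A", "B"}, "c2": {"C", "D"}}).assignment
        assert got == {"A": "c1", "B": "c1", "C": "c2", "D": "c2"}

    def test_anchors_spanning_root_absorb_everything(self, quartet):
        got = assign_clades(quartet, {"c1": {"A", "C"}}).assignment
        assert got == {leaf: "c1" for leaf in "ABCD"}

    def test_missing_anchor_raises(self, quartet):
        with pytest.raises(ValueError, match="not in tree"):
            assign_clades(quartet, {"c1": {"Z"}})

    def test_overlapping_anchor_sets_raise(self, quartet):
        with pytest.raises(ValueError, match="overlap"):
            assign_clades(quartet, {"c1": {"A"}, "c2": {"A", "C"}})
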