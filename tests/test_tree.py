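import numpy as np
import pytest

from cgrphylo.distance import DistanceMatrix
from cgrphylo.simulate import random_additive_tree
from cgrphylo.tree import (
    annotate_supports,
    fit_branch_lengths,
    get_supports,
    leaf_labels,
    majority_consensus,
    neighbor_joining,
    parse_newick,
    robinson_foulds,
    tree_splits,
    tree_to_newick,
)


def quartet_matrix():
    labels = ("A", "B", "C", "D")
    values = np.array(
        [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
    )
    return DistanceMatrix(labels=labels, values=values)


def patristic(tree, labels=None):
    """Leaf-to-leaf path lengths, independent of reconstruction order."""
    if labels is None:
        labels = sorted(leaf_labels(tree))
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tns.get_taxon(a), tns.get_taxon(labels[j]))
            out[i, j] = out[j, i] = d
    return labels, out


class TestNeighborJoining:
    def test_additive_quartet_exact(self):
        t = neighbor_joining(quartet_matrix())
        assert tree_splits(t) == {frozenset({"C", "D"})}
        lengths = {}
        for node in t.preorder_node_iter():
            if node.parent_node is None:
                continue
            key = node.taxon.label if node.is_leaf() else "internal"
            lengths[key] = node.edge.length
        assert lengths["internal"] == pytest.approx(2.0)
        for leaf in "ABCD":
            assert lengths[leaf] == pytest.approx(1.0)

    def test_three_taxa_star(self):
        dm = DistanceMatrix(
            labels=("A", "B", "C"),
            values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        t = neighbor_joining(dm)
        got = {leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()}
        assert got == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_trees(self, seed):
        truth, dm = random_additive_tree(6 + seed % 7, seed=seed)
        rec = neighbor_joining(dm)
        assert robinson_foulds(truth, rec) == 0
        _, p = patristic(rec, list(dm.labels))
        np.testing.assert_allclose(p, dm.values, atol=1e-9)

    def test_matches_scikit_bio_topology(self):
        """Independent cross-check against another NJ implementation."""
        skbio = pytest.importorskip("skbio")
        for seed in range(5):
            truth, dm = random_additive_tree(8, seed=100 + seed)
            # perturb additivity so the check is not trivially forced
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 0.01, dm.values.shape)
            noise = np.triu(noise, 1) + np.triu(noise, 1).T
            values = np.maximum(dm.values + noise, 0.01)
            np.fill_diagonal(values, 0)
            noisy = DistanceMatrix(labels=dm.labels, values=values)
            mine = neighbor_joining(noisy)
            ref = skbio.tree.nj(
                skbio.DistanceMatrix(values, ids=list(dm.labels))
            )
            ref_tree = parse_newick(str(ref))
            assert robinson_foulds(mine, ref_tree) == 0

    def test_errors(self):
        dm = DistanceMatrix(labels=("A", "B"), values=np.zeros((2, 2)))
        with pytest.raises(ValueError, match=">= 3"):
            neighbor_joining(dm)
        bad = quartet_matrix()
        values = bad.values.copy()
        values[0, 1] = values[1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            neighbor_joining(
                DistanceMatrix(labels=bad.labels, values=values)
            )


class TestConsensus:
    def test_identical_trees_full_support(self):
        trees = [parse_newick("((A,B),(C,D),(E,F));") for _ in range(7)]
        cons = majority_consensus(trees)
        assert tree_splits(cons) == tree_splits(trees[0])
        assert set(get_supports(cons).values()) == {100.0}

    def test_two_to_one_quartet(self):
        trees = [
            parse_newick("((A,B),(C,D));"),
            parse_newick("((A,B),(C,D));"),
            parse_newick("((A,C),(B,D));"),
        ]
        cons = majority_consensus(trees)
        assert tree_splits(cons) == {frozenset({"C", "D"})}
        assert get_supports(cons)[frozenset({"C", "D"})] == pytest.approx(66.7)

    def test_all_below_threshold_gives_star(self):
        trees = [
            parse_newick("((A,B),(C,D));"),
            parse_newick("((A,C),(B,D));"),
            parse_newick("((A,D),(B,C));"),
        ]
        cons = majority_consensus(trees)
        assert tree_splits(cons) == frozenset()

    def test_leaf_mismatch_names_tree(self):
        trees = [parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));")]
        with pytest.raises(ValueError, match="tree 1"):
            majority_consensus(trees)

    def test_threshold_validation(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="threshold"):
            majority_consensus([t], threshold=0.3)


class TestFitBranchLengths:
    def test_exact_on_additive_matrix(self):
        truth, dm = random_additive_tree(9, seed=3)
        fitted = fit_branch_lengths(truth, dm)
        _, p = patristic(fitted, list(dm.labels))
        np.testing.assert_allclose(p, dm.values, atol=1e-9)

    def test_reproduces_nj_lengths(self):
        _, dm = random_additive_tree(8, seed=5)
        nj = neighbor_joining(dm)
        fitted = fit_branch_lengths(nj, dm)
        _, pn = patristic(nj)
        _, pf = patristic(fitted)
        np.testing.assert_allclose(pf, pn, atol=1e-9)

    def test_noisy_matrix_recovers_lengths(self):
        sigma = 0.01
        truth, dm = random_additive_tree(8, seed=7)
        rng = np.random.default_rng(7)
        noise = rng.normal(0, sigma, dm.values.shape)
        noise = np.triu(noise, 1) + np.triu(noise, 1).T
        values = np.maximum(dm.values + noise, 0.0)
        np.fill_diagonal(values, 0)
        noisy = DistanceMatrix(labels=dm.labels, values=values)
        fitted = fit_branch_lengths(truth, noisy)
        _, pt = patristic(truth)
        _, pf = patristic(fitted)
        assert np.abs(pf - pt).max() < 3 * sigma

    def test_zero_distance_weight_fallback_warns(self):
        values = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0.5], [1, 1, 0.5, 0]]
        )
        dm = DistanceMatrix(labels=("A", "B", "C", "D"), values=values)
        topo = parse_newick("((A,B),(C,D));")
        with pytest.warns(UserWarning, match="distance zero"):
            fitted = fit_branch_lengths(topo, dm)
        assert all(
            nd.edge.length >= 0
            for nd in fitted.preorder_node_iter()
            if nd.parent_node is not None
        )

    def test_leaf_set_mismatch(self):
        _, dm = random_additive_tree(6, seed=1)
        topo = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="leaf set"):
            fit_branch_lengths(topo, dm)


class TestNewick:
    def test_three_leaf_star(self):
        t = parse_newick("(A:1,B:1,C:1);")
        text = tree_to_newick(t)
        assert text.strip() == "(A:1,B:1,C:1);"

    def test_roundtrip_preserves_splits_lengths_supports(self):
        trees = [parse_newick("((A,B),(C,D));")] * 2 + [
            parse_newick("((A,C),(B,D));")
        ]
        cons = majority_consensus(trees)
        _, dm = random_additive_tree(4, seed=2)
        # reuse the quartet labels
        dm = DistanceMatrix(labels=("A", "B", "C", "D"), values=dm.values)
        fitted = fit_branch_lengths(cons, dm)
        text = tree_to_newick(fitted, include_supports=True)
        back = parse_newick(text)
        assert tree_splits(back) == tree_splits(fitted)
        assert get_supports(back) == get_supports(fitted)
        _, pa = patristic(fitted)
        _, pb = patristic(back)
        np.testing.assert_allclose(pb, pa, atol=1e-6)

    def test_metacharacter_labels_quoted(self):
        trees = [parse_newick("(('A x','B(y)'),(C,D));")] * 3
        cons = majority_consensus(trees)
        text = tree_to_newick(cons, include_supports=True)
        back = parse_newick(text)
        assert leaf_labels(back) == {"A x", "B(y)", "C", "D"}

    def test_parse_error(self):
        with pytest.raises(ValueError, match="newick parse error"):
            parse_newick("((A,B,(C;")


class TestRobinsonFoulds:
    def test_examples(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert robinson_foulds(t1, t1.clone(depth=1)) == 0
        assert robinson_foulds(t1, t2) == 2
        assert robinson_foulds(t2, t1) == 2

    def test_leaf_mismatch(self):
        with pytest.raises(ValueError, match="leaf sets differ"):
            robinson_foulds(
                parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));")
            )


def test_nexus_trees_block():
    from cgrphylo.tree import trees_to_nexus

    trees = [parse_newick("((A:1,B:1):1,(C:1,D:1):1);")] * 2
    text = trees_to_nexus(trees)
    assert text.lstrip().startswith("#NEXUS")
    assert text.count("TREE") >= 2 or text.count("Tree") >= 2


def test_annotate_supports_on_point_tree():
    reps = [parse_newick("((A,B),(C,D),E);")] * 3 + [
        parse_newick("((A,C),(B,D),E);")
    ]
    point = parse_newick("((A,B),(C,D),E);")
    annotated = annotate_supports(point, reps)
    sup = get_supports(annotated)
    # canonical split keys are the sides not containing the smallest label
    assert sup[frozenset({"C", "D", "E"})] == pytest.approx(75.0)
    assert sup[frozenset({"C", "D"})] == pytest.approx(75.0)
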