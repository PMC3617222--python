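"""Dendrogram-to-tree conversion, Newick round trips, subtree extraction."""

import numpy as np
import pytest

from aaclust.cluster import Dendrogram, euclidean_condensed, linkage
from aaclust.tree import (
    NewickParseError,
    dendrogram_to_tree,
    extract_subtree,
    parse_newick,
    to_newick,
    trees_equal,
)


def dend_013():
    X = np.zeros((3, 20))
    X[:, 0] = [0, 1, 3]
    return linkage(euclidean_condensed(X), "single")


@pytest.fixture
def tree_abc():
    return dendrogram_to_tree(dend_013(), ["A", "B", "C"])


def random_tree(rng, n):
    X = rng.dirichlet(np.ones(20) * 0.5, n)
    dend = linkage(euclidean_condensed(X), "average")
    return dendrogram_to_tree(dend, [f"L{i:03d}" for i in range(n)])


class TestDendrogramToTree:
    def test_two_leaves(self):
        d = Dendrogram(2, np.array([[0, 1, 1.0, 2]]))
        assert to_newick(dendrogram_to_tree(d, ["A", "B"])) == "(A:1,B:1);"

    def test_worked_three_leaf_tree(self, tree_abc):
        assert to_newick(tree_abc) == "((A:1,B:1):1,C:2);"

    def test_leaf_to_root_path_equals_root_height(self, rng):
        root = random_tree(rng, 40)
        # depth of every leaf == root merge height for monotone schemes
        def paths(node, acc):
            if node.is_leaf:
                yield acc
            for c in node.children:
                yield from paths(c, acc + c.length)
        for depth in paths(root, 0.0):
            assert depth == pytest.approx(root.height, abs=1e-9)

    def test_inversion_becomes_negative_branch_and_warns(self):
        merges = np.array([[0, 1, 1.0, 2], [2, 3, 0.5, 3]])  # inversion
        d = Dendrogram(3, merges)
        with pytest.warns(UserWarning, match="inversion"):
            root = dendrogram_to_tree(d, ["A", "B", "C"])
        lengths = [n.length for n in root.walk() if n.length is not None]
        assert min(lengths) < 0
        assert "-0.5" in to_newick(root)

    def test_label_count_mismatch(self):
        with pytest.raises(ValueError, match="labels"):
            dendrogram_to_tree(dend_013(), ["A", "B"])


class TestNewick:
    def test_exact_round_trip(self):
        text = "(A:1,B:1);"
        assert to_newick(parse_newick(text)) == text

    def test_round_trip_random_dendrogram(self, rng):
        root = random_tree(rng, 200)
        assert trees_equal(parse_newick(to_newick(root)), root, tol=1e-9)

    def test_quoted_labels_round_trip(self):
        d = Dendrogram(2, np.array([[0, 1, 1.0, 2]]))
        root = dendrogram_to_tree(d, ["needs space", "has'quote"])
        back = parse_newick(to_newick(root))
        assert back.leaf_labels() == ["needs space", "has'quote"]

    @pytest.mark.parametrize(
        "bad, match",
        [
            ("(A:1,B:1", "unbalanced"),
            ("(A:1,B:1)", "missing ';'"),
            ("(A:1,A:2);", "duplicate leaf labels"),
            ("(A:1,B:1); junk", "trailing"),
            ("(A:x,B:1);", "malformed branch length"),
        ],
    )
    def test_parse_errors_carry_position(self, bad, match):
        with pytest.raises(NewickParseError, match=match) as exc:
            parse_newick(bad)
        assert "position" in str(exc.value)

    def test_cross_check_with_dendropy(self, rng):
        import dendropy

        root = random_tree(rng, 30)
        text = to_newick(root)
        dt = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(t.label for t in dt.taxon_namespace) == sorted(root.leaf_labels())
        # root-to-leaf depths agree
        depths = {
            leaf.taxon.label: leaf.distance_from_root() for leaf in dt.leaf_node_iter()
        }
        assert all(abs(d - root.height) < 1e-6 for d in depths.values())


class TestExtractSubtree:
    def test_single_leaf_selector(self, tree_abc):
        clade = extract_subtree(tree_abc, "C")
        assert clade.is_leaf and clade.label == "C"

    def test_pair_forming_a_clade(self, tree_abc):
        clade = extract_subtree(tree_abc, ["A", "B"])
        assert to_newick(clade) == "(A:1,B:1);"

    def test_spanning_pair_returns_whole_tree(self, tree_abc):
        clade = extract_subtree(tree_abc, ["A", "C"])
        assert sorted(clade.leaf_labels()) == ["A", "B", "C"]

    def test_glob_pattern(self, rng):
        root = random_tree(rng, 20)
        clade = extract_subtree(root, "L00*")
        assert {l for l in clade.leaf_labels() if l.startswith("L00")} == {
            f"L{i:03d}" for i in range(10)
        }

    def test_idempotent(self, rng):
        root = random_tree(rng, 25)
        once = extract_subtree(root, ["L001", "L007", "L013"])
        twice = extract_subtree(once, ["L001", "L007", "L013"])
        assert trees_equal(once, twice)

    def test_prune_drops_bystanders_and_sums_lengths(self, tree_abc):
        pruned = extract_subtree(tree_abc, ["A", "C"], prune=True)
        assert sorted(pruned.leaf_labels()) == ["A", "C"]
        # A's path length to root must absorb the collapsed internal edge
        (a_leaf,) = [n for n in pruned.walk() if n.label == "A"]
        assert a_leaf.length == pytest.approx(2.0)

    def test_no_match_errors(self, tree_abc):
        with pytest.raises(ValueError, match="matches no leaf"):
            extract_subtree(tree_abc, "ZZZ*")
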