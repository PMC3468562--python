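"""NJ reconstruction, bootstrap supports and monophyly testing."""

import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix, pairwise_matrix
from barcodegap.nj_tree import Tree, bootstrap_support, neighbor_joining, species_monophyly
from barcodegap.seq_io import BarcodeAlignment, BarcodeRecord


def random_additive(rng, n):
    """Random binary unrooted tree on n leaves -> (labels, matrix, bipartitions)."""
    t = Tree()
    labels = [f"L{i}" for i in range(n)]
    nodes = [t.add_node(lab) for lab in labels[:3]]
    center = t.add_node()
    for nd in nodes:
        t.add_edge(nd, center, float(rng.uniform(0.05, 1.0)))
    for lab in labels[3:]:
        u, v, w = t.edges()[rng.integers(0, len(t.edges()))]
        # subdivide edge (u, v) and hang the new leaf off the midpoint
        mid = t.add_node()
        del t.adj[u][v]
        del t.adj[v][u]
        split = rng.uniform(0.2, 0.8) * w
        t.add_edge(u, mid, split)
        t.add_edge(mid, v, w - split)
        leaf = t.add_node(lab)
        t.add_edge(leaf, mid, float(rng.uniform(0.05, 1.0)))
    D = t.path_length_matrix(labels)
    return labels, D, set(t.bipartitions())


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, D))
        assert set(tree.bipartitions()) == {frozenset({"C", "D"})}
        np.testing.assert_allclose(tree.path_length_matrix(labels), D, atol=1e-9)
        lengths = sorted(w for _, _, w in tree.edges())
        np.testing.assert_allclose(lengths, [1, 1, 2, 3, 4], atol=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
        np.testing.assert_allclose(
            tree.path_length_matrix(["A", "B", "C"]), D, atol=1e-12
        )
        # tip lengths are (d_ab + d_ac - d_bc)/2 etc.
        adj_lengths = {
            tree.labels[n]: list(tree.adj[n].values())[0] for n in tree.leaves()
        }
        assert adj_lengths["A"] == pytest.approx(0.2)
        assert adj_lengths["B"] == pytest.approx(0.1)
        assert adj_lengths["C"] == pytest.approx(0.3)

    def test_recovers_random_additive_trees(self):
        """Additive input => exact topology and path-length matrix."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            labels, D, true_bps = random_additive(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            assert set(tree.bipartitions()) == true_bps
            np.testing.assert_allclose(tree.path_length_matrix(labels), D, atol=1e-9)

    def test_two_cluster_matrix_separating_edge(self):
        labels = [f"x{i}" for i in range(3)] + [f"y{i}" for i in range(3)]
        D = np.full((6, 6), 0.2)
        D[:3, :3] = 0.01
        D[3:, 3:] = 0.01
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(DistanceMatrix(labels, D))
        bps = set(tree.bipartitions())
        assert frozenset({"y0", "y1", "y2"}) in bps or frozenset({"x1", "x2"}) in bps
        # one bipartition exactly separates the clusters
        assert any(
            bp in (frozenset({"y0", "y1", "y2"}), frozenset({"x0", "x1", "x2"}))
            for bp in bps
        )

    def test_nonnegative_lengths_after_clamping(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0.1, 0.5, size=(7, 7))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(7)], D))
        assert all(w >= 0 for _, _, w in tree.edges())

    def test_undefined_entries_rejected(self):
        D = np.array([[0, np.nan, 0.1], [np.nan, 0, 0.1], [0.1, 0.1, 0]])
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], D))

    def test_too_few_taxa_rejected(self):
        D = np.array([[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix(["a", "b"], D))

    def test_agrees_with_skbio_on_random_matrix(self):
        """Independent implementation oracle: same topology from scikit-bio."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        labels, D, _ = random_additive(rng, 7)
        jitter = rng.uniform(0, 0.01, size=D.shape)
        D2 = D + jitter
        D2 = (D2 + D2.T) / 2
        np.fill_diagonal(D2, 0.0)
        ours = neighbor_joining(DistanceMatrix(labels, D2))
        theirs = skbio_nj(skbio.DistanceMatrix(D2, ids=labels))
        anchor = min(labels)
        their_bps = set()
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = frozenset(labels) - side
            if 1 < len(side) < len(labels) - 1:
                their_bps.add(side)
        assert set(ours.bipartitions()) == their_bps


class TestBootstrap:
    def test_single_replicate_supports_binary(self, tiny_aln):
        tree = bootstrap_support(tiny_aln, B=1, seed=0)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_duplicated_sequences_cherry_support_100(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), size=120))

        def mutate(seq, n_sub):
            arr = list(seq)
            for pos in rng.choice(len(arr), size=n_sub, replace=False):
                arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
            return "".join(arr)

        other1 = mutate(base, 12)
        other2 = mutate(other1, 6)
        aln = BarcodeAlignment(
            [
                BarcodeRecord("dup1", base),
                BarcodeRecord("dup2", base),
                BarcodeRecord("o1", other1),
                BarcodeRecord("o2", other2),
            ]
        )
        tree = bootstrap_support(aln, B=50, seed=1)
        bps = tree.bipartitions()
        key = frozenset({"dup1", "dup2"})
        comp = frozenset({"o1", "o2"})
        edge = bps.get(key) or bps.get(comp)
        assert edge is not None
        assert tree.supports[frozenset(edge)] == 100.0

    def test_supports_invariant_to_leaf_order(self, community_aln):
        sub = community_aln.subset(community_aln.seq_ids[:12])
        rev = BarcodeAlignment(list(reversed(sub.records)), frame_offset=0)
        t1 = bootstrap_support(sub, B=30, seed=7)
        t2 = bootstrap_support(rev, B=30, seed=7)
        s1 = {bp: t1.supports[frozenset(e)] for bp, e in t1.bipartitions().items()}
        s2 = {bp: t2.supports[frozenset(e)] for bp, e in t2.bipartitions().items()}
        assert s1 == s2

    def test_reproducible_given_seed(self, tiny_aln):
        t1 = bootstrap_support(tiny_aln, B=20, seed=5)
        t2 = bootstrap_support(tiny_aln, B=20, seed=5)
        assert t1.to_newick() == t2.to_newick()


class TestMonophyly:
    def test_monophyletic_pair(self):
        t = Tree.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        res = species_monophyly(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert res["A"][0] and res["B"][0]

    def test_interleaved_not_monophyletic(self):
        t = Tree.from_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        res = species_monophyly(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert not res["A"][0] and not res["B"][0]

    def test_singletons_trivially_monophyletic(self):
        t = Tree.from_newick("((a1:1,b1:1):1,c1:1,d1:1);")
        res = species_monophyly(
            t, {"a1": "A", "b1": "B", "c1": "C", "d1": "D"}
        )
        assert all(ok for ok, _ in res.values())

    def test_simulated_community_fully_monophyletic(self, community):
        aln, truth = community
        tree = neighbor_joining(pairwise_matrix(aln))
        res = species_monophyly(tree, truth.species)
        assert all(ok for ok, _ in res.values())
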