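import itertools

import numpy as np
import pytest

from oracles import (best_quartet_split, path_lengths, random_additive_tree,
                     tree_bipartitions)
from wrkyminer.phylo import (DistanceMatrix, assign_subgroup, bipartitions,
                             bootstrap_support, from_newick, nj_tree,
                             pairwise_distances, to_newick, tree_length)


def _leaf_distance_matrix(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    return d


class TestPairwiseDistances:
    def test_identical_sequences(self):
        dm = pairwise_distances({"a": "WRKYGQK", "b": "WRKYGQK"})
        assert dm.d[0, 1] == 0.0

    def test_single_substitution(self):
        dm = pairwise_distances({"a": "WRKYGQK", "b": "WRKYGKK"})
        assert dm.d[0, 1] == pytest.approx(1 / 7)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        seqs = {f"s{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 25))
                for i in range(5)}
        dm = pairwise_distances(seqs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            pairwise_distances({"a": "", "b": "MK"})


class TestNjTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(labels=["a", "b", "c"],
                            d=np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0.]]))
        tree = nj_tree(dm)
        d = _leaf_distance_matrix(tree, ["a", "b", "c"])
        # three-point formulas: pendant a = (2+4-6)/2 = 0, b = 2, c = 4
        assert d[0, 1] == pytest.approx(2)
        assert d[0, 2] == pytest.approx(4)
        assert d[1, 2] == pytest.approx(6)
        assert tree_length(tree) == pytest.approx(6)

    def test_two_taxa(self):
        dm = DistanceMatrix(labels=["x", "y"], d=np.array([[0, 1.0], [1.0, 0]]))
        assert tree_length(nj_tree(dm)) == pytest.approx(1.0)

    def test_non_symmetric_error(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], d=np.array([[0, 1], [2, 0.]]))

    @pytest.mark.parametrize("n_leaves", [3, 4, 5, 6])
    def test_additive_recovery(self, n_leaves):
        """On additive matrices NJ must recover topology and all distances."""
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(5):
            adj, labels = random_additive_tree(n_leaves, rng)
            d_true = path_lengths(adj, labels)
            tree = nj_tree(DistanceMatrix(labels=labels, d=d_true))
            d_got = _leaf_distance_matrix(tree, labels)
            assert np.allclose(d_got, d_true, atol=1e-9)
            assert bipartitions(tree) == tree_bipartitions(adj, labels)

    def test_quartet_vs_exhaustive_topology_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            adj, labels = random_additive_tree(4, rng)
            d = path_lengths(adj, labels)
            (p, q), _ = best_quartet_split(d)
            tree = nj_tree(DistanceMatrix(labels=labels, d=d))
            splits = bipartitions(tree)
            assert len(splits) == 1
            assert frozenset({labels[p], labels[q]}) in splits or \
                frozenset({labels[i] for i in range(4) if i not in (p, q)}) in splits

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            m = rng.uniform(0.1, 2.0, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            tree = nj_tree(DistanceMatrix(labels=[f"t{i}" for i in range(n)], d=d))
            assert all((e.length or 0) >= 0 for e in tree.edges())

    def test_clamping_preserves_total_length(self):
        # a matrix that forces a negative NJ limb: total length must equal the
        # sum the unclamped formulas would give (the deficit moves to siblings)
        d = np.array([[0, 2, 3, 9.0], [2, 0, 3, 9], [3, 3, 0, 8], [9, 9, 8, 0]])
        labels = ["a", "b", "c", "d"]
        tree = nj_tree(DistanceMatrix(labels=labels, d=d))
        assert all((e.length or 0) >= 0 for e in tree.edges())
        d_got = _leaf_distance_matrix(tree, labels)
        # pairwise sums through each join are preserved by clamping
        assert d_got[0, 1] == pytest.approx(d[0, 1])


class TestNewick:
    def test_roundtrip(self):
        rng = np.random.default_rng(21)
        adj, labels = random_additive_tree(6, rng)
        tree = nj_tree(DistanceMatrix(labels=labels, d=path_lengths(adj, labels)))
        for i, node in enumerate(n for n in tree.preorder_node_iter()
                                 if not n.is_leaf() and n is not tree.seed_node):
            node.label = f"0.{i}50"
        text = to_newick(tree)
        again = from_newick(text)
        assert bipartitions(again) == bipartitions(tree)
        assert tree_length(again) == pytest.approx(tree_length(tree))
        labels_got = sorted(n.label for n in again.preorder_node_iter()
                            if not n.is_leaf() and n is not again.seed_node
                            and n.label)
        labels_want = sorted(n.label for n in tree.preorder_node_iter()
                             if not n.is_leaf() and n is not tree.seed_node
                             and n.label)
        assert labels_got == labels_want


class TestBootstrap:
    def test_congruent_columns_full_support(self):
        # every column carries the same split signal -> all supports 1.0
        aln = {"a": "AAAAA", "b": "AAAAA", "c": "CCCCC", "d": "CCCCC",
               "e": "GGGGG"}
        tree = bootstrap_support(aln, replicates=50, seed=0)
        supports = [float(n.label) for n in tree.preorder_node_iter()
                    if n.label and not n.is_leaf()]
        assert supports and all(s == 1.0 for s in supports)

    def test_exact_enumeration_four_columns(self):
        aln = {"a": "AAAG", "b": "AAAC", "c": "CCCG", "d": "CCCC"}
        labels = list(aln)
        n_cols = 4
        counts = {}
        total = 0
        for cols in itertools.product(range(n_cols), repeat=n_cols):
            total += 1
            mat = {l: "".join(aln[l][c] for c in cols) for l in labels}
            n = len(labels)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = sum(
                        x != y for x, y in zip(mat[labels[i]], mat[labels[j]])
                    ) / n_cols
            t = nj_tree(DistanceMatrix(labels=labels, d=d))
            for split in bipartitions(t):
                counts[split] = counts.get(split, 0) + 1
        exact = {s: c / total for s, c in counts.items()}

        tree = bootstrap_support(aln, replicates=4000, seed=1)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is tree.seed_node or not node.label:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            other = frozenset(labels) - below
            canon = min(below, other, key=lambda s: (len(s), tuple(sorted(s))))
            assert float(node.label) == pytest.approx(exact.get(canon, 0.0),
                                                      abs=0.05)

    def test_seed_stability(self):
        rng = np.random.default_rng(8)
        base = {"a": "A", "b": "A", "c": "C", "d": "C", "e": "G"}
        cols = []
        for _ in range(40):
            if rng.random() < 0.8:
                cols.append({l: base[l] for l in base})
            else:
                cols.append({l: rng.choice(list("ACGT")) for l in base})
        aln = {l: "".join(c[l] for c in cols) for l in base}

        def supports(seed):
            tree = bootstrap_support(aln, replicates=2000, seed=seed)
            out = {}
            for node in tree.preorder_node_iter():
                if node.is_leaf() or node is tree.seed_node or not node.label:
                    continue
                below = frozenset(l.taxon.label for l in node.leaf_iter())
                out[below] = float(node.label)
            return out

        s1, s2 = supports(1), supports(2)
        assert s1.keys() == s2.keys()
        for key in s1:
            assert abs(s1[key] - s2[key]) < 0.05

    def test_zero_replicates_error(self):
        with pytest.raises(ValueError):
            bootstrap_support({"a": "AC", "b": "AC", "c": "GT"}, replicates=0)


class TestAssignSubgroup:
    NEWICK = "((r1:1,x:1):1,((r3:1,y:1):1,r2:1):2,z:6);"

    def test_clade_rule_and_identity(self):
        tree = from_newick(self.NEWICK)
        refs = {"r1": "IIa", "r2": "IIb", "r3": "IIb"}
        got = assign_subgroup(tree, refs)
        assert got["r1"] == "IIa" and got["r2"] == "IIb"   # refs map to themselves
        assert got["x"] == "IIa"    # sister to a IIa ref, no other refs in clade
        assert got["y"] == "IIb"

    def test_fallback_vote(self):
        tree = from_newick(self.NEWICK)
        refs = {"r1": "IIa", "r2": "IIb", "r3": "IIb"}
        got = assign_subgroup(tree, refs)
        # z's smallest ref-containing clade mixes subgroups -> 3-nearest vote
        assert got["z"] == "IIb"

    def test_no_refs_error(self):
        with pytest.raises(ValueError):
            assign_subgroup(from_newick(self.NEWICK), {})
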