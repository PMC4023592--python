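"""Alignment contracts, distances, NJ correctness, supports, newick IO."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cslmine.phylo import (
    MSA,
    Node,
    PhyloTree,
    TreeConfig,
    build_msa,
    nj_tree,
    pairwise_distance,
    parse_newick,
    support_values,
    to_newick,
)

from conftest import random_protein


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with positive lengths and its path-distance matrix."""
    ids = [f"t{k}" for k in range(n_taxa)]
    nodes = {i: {i} for i in ids}
    children: dict = {}
    lengths: dict = {}
    pool = list(ids)
    k = 0
    while len(pool) > 2:
        i, j = rng.choice(len(pool), 2, replace=False)
        a, b = pool[int(i)], pool[int(j)]
        parent = f"n{k}"
        k += 1
        children[parent] = (a, b)
        lengths[a] = float(rng.uniform(0.05, 1.0))
        lengths[b] = float(rng.uniform(0.05, 1.0))
        pool = [p for p in pool if p not in (a, b)] + [parent]
    for p in pool:
        lengths[p] = float(rng.uniform(0.05, 1.0))
    root_children = tuple(pool)

    # leaf-to-leaf path distances
    def build(name):
        if name in children:
            a, b = children[name]
            return Node(children=[build(a), build(b)], length=lengths[name])
        return Node(name=name, length=lengths[name])

    if len(root_children) == 2:
        # join the last two under a trifurcation-free root: merge lengths
        a, b = root_children
        lengths[a] = lengths[a] + lengths[b]
        lengths[b] = 0.0
    root = Node(children=[build(c) for c in root_children])
    tree = PhyloTree(root=root)

    # distances by traversal
    dists = {}

    def walk(node, acc):
        if node.is_leaf:
            dists[node.name] = acc
            return
        for c in node.children:
            walk(c, acc + [(c, c.length or 0.0)])

    paths: dict = {}

    def collect(node, path):
        if node.is_leaf:
            paths[node.name] = path
            return
        for c in node.children:
            collect(c, path + [c])

    collect(root, [])
    D = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            px, py = paths[ids[x]], paths[ids[y]]
            shared = 0
            for a, b in zip(px, py):
                if a is b:
                    shared += 1
                else:
                    break
            d = sum((n.length or 0.0) for n in px[shared:]) + sum(
                (n.length or 0.0) for n in py[shared:]
            )
            D[x, y] = D[y, x] = d
    return ids, tree, D


def _bipartition_lengths(tree: PhyloTree):
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out = {}
    for below, _, node in tree.edges(include_leaves=True):
        side = below if ref not in below else all_leaves - below
        out.setdefault(side, 0.0)
        out[side] += node.length or 0.0
    return out


class TestBuildMsa:
    def test_identical_pair_is_gap_free(self):
        msa = build_msa({"a": "MKLVDQRW", "b": "MKLVDQRW"})
        assert msa.rows[0] == msa.rows[1] == "MKLVDQRW"

    def test_short_fragment_gets_one_internal_gap(self):
        msa = build_msa({"a": "MKLV", "b": "MKV"}, method="ginsi")
        assert msa.rows[0] == "MKLV"
        assert msa.rows[1].count("-") == 1
        matches = sum(x == y for x, y in zip(*msa.rows))
        assert matches == 3

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(12)
        seqs = {f"s{k}": random_protein(rng, int(rng.integers(30, 60))) for k in range(6)}
        msa = build_msa(seqs)
        for k, sid in enumerate(msa.ids):
            assert msa.degapped(k) == seqs[sid]
        assert msa.n_columns >= max(len(s) for s in seqs.values())

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            MSA(ids=["a", "a"], rows=["MK", "MK"])


class TestPairwiseDistance:
    def _msa(self, rows):
        return MSA(ids=[f"s{k}" for k in range(len(rows))], rows=list(rows))

    def test_identical_rows_zero(self):
        d = pairwise_distance(self._msa(["MKLV", "MKLV"]), "raw")
        assert d[0, 1] == 0.0

    def test_raw_mismatch_fraction(self):
        d = pairwise_distance(self._msa(["AAAAAAAAAA", "AAAAAAAACC"]), "raw")
        assert d[0, 1] == pytest.approx(0.2)

    def test_poisson_correction(self):
        d = pairwise_distance(self._msa(["AAAAAAAAAA", "AAAAAAAACC"]), "poisson")
        assert d[0, 1] == pytest.approx(-math.log(0.8))

    def test_gap_columns_excluded(self):
        d = pairwise_distance(self._msa(["AA--AA", "AACCAA"]), "raw")
        assert d[0, 1] == 0.0

    def test_disjoint_pair_error_names_both(self):
        msa = self._msa(["AA--", "--CC"])
        with pytest.raises(ValueError, match="s0.*s1"):
            pairwise_distance(msa, "raw")
        d = pairwise_distance(msa, "poisson", on_disjoint="cap")
        assert d[0, 1] == pytest.approx(-math.log(0.05))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> pairwise path distances
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = nj_tree(D, ["A", "B", "C", "D"])
        lengths = _bipartition_lengths(tree)
        assert lengths[frozenset({"B"})] == pytest.approx(2.0)
        assert lengths[frozenset({"C"})] == pytest.approx(3.0)
        assert lengths[frozenset({"D"})] == pytest.approx(1.0)
        assert lengths[frozenset({"C", "D"})] == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_tree(D, ["a", "b", "c"])
        by_name = {c.name: c.length for c in tree.root.children}
        assert by_name["a"] == pytest.approx(0.0)
        assert by_name["b"] == pytest.approx(2.0)
        assert by_name["c"] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_additive_matrices_recovered_exactly(self, seed):
        rng = np.random.default_rng([seed, 55])
        n = int(rng.integers(4, 13))
        ids, true_tree, D = random_additive_tree(rng, n)
        est = nj_tree(D, ids)
        assert set(est.bipartitions()) == set(true_tree.bipartitions())
        est_len = _bipartition_lengths(est)
        true_len = _bipartition_lengths(true_tree)
        for bp, ln in true_len.items():
            assert est_len[bp] == pytest.approx(ln, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_topology_matches_scikit_bio(self, seed):
        import io

        from skbio import DistanceMatrix, TreeNode
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng([seed, 66])
        n = 8
        noise = rng.uniform(0.0, 0.2, (n, n))
        noise = noise + noise.T  # exactly symmetric
        ids, _, D = random_additive_tree(rng, n)
        D = D + noise
        np.fill_diagonal(D, 0.0)
        mine = nj_tree(D, ids)
        sk = skbio_nj(DistanceMatrix(D, ids))
        sk_bips = set()
        all_leaves = frozenset(ids)
        ref = min(all_leaves)
        for node in sk.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            side = side if ref not in side else all_leaves - side
            if 1 < len(side) < n - 1:
                sk_bips.add(side)
        assert set(mine.bipartitions()) == sk_bips

    def test_permuting_ids_gives_same_tree(self):
        rng = np.random.default_rng(77)
        ids, _, D = random_additive_tree(rng, 9)
        t1 = nj_tree(D, ids)
        perm = rng.permutation(len(ids))
        D2 = D[np.ix_(perm, perm)]
        ids2 = [ids[int(k)] for k in perm]
        t2 = nj_tree(D2, ids2)
        assert set(t1.bipartitions()) == set(t2.bipartitions())
        assert _bipartition_lengths(t1) == pytest.approx(_bipartition_lengths(t2))

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, ["a", "b", "c"])


class TestSupports:
    def _cluster_msa(self):
        # two well-separated clusters of identical sequences
        a = "A" * 30 + "C" * 30
        b = "W" * 30 + "H" * 30
        return MSA(ids=["a1", "a2", "a3", "b1", "b2"], rows=[a, a, a, b, b])

    def test_central_edge_of_separated_clusters_has_full_support(self):
        msa = self._cluster_msa()
        d = pairwise_distance(msa, "poisson")
        tree = nj_tree(d, msa.ids)
        out = support_values(msa, tree, TreeConfig(n_resamples=50, seed=5))
        bps = out.bipartitions()
        assert bps[frozenset({"b1", "b2"})] == 1.0

    def test_single_resample_gives_binary_supports(self):
        msa = self._cluster_msa()
        d = pairwise_distance(msa, "poisson")
        tree = nj_tree(d, msa.ids)
        out = support_values(msa, tree, TreeConfig(n_resamples=1, seed=5))
        sup = [s for _, s in out.bipartitions().items()]
        assert set(sup) <= {0.0, 1.0}

    def test_seeded_reproducibility(self):
        msa = self._cluster_msa()
        d = pairwise_distance(msa, "poisson")
        tree = nj_tree(d, msa.ids)
        cfg = TreeConfig(n_resamples=25, seed=9)
        t1 = support_values(msa, tree, cfg)
        t2 = support_values(msa, tree, cfg)
        assert to_newick(t1) == to_newick(t2)


class TestNewick:
    def test_three_leaf_shape(self):
        tree = PhyloTree(
            root=Node(children=[Node(name=n, length=1.0) for n in "ABC"])
        )
        assert to_newick(tree) == "(A:1.0,B:1.0,C:1.0);"

    def test_metacharacter_labels_are_quoted(self):
        tree = PhyloTree(
            root=Node(children=[
                Node(name="sp. CFD", length=1.0),
                Node(name="b", length=2.0),
                Node(name="c", length=0.5),
            ])
        )
        text = to_newick(tree)
        assert "'sp. CFD'" in text
        assert parse_newick(text) == tree

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_random_trees(self, seed):
        rng = np.random.default_rng([seed, 88])
        n = int(rng.integers(4, 51))
        ids, tree, _ = random_additive_tree(rng, n)
        # decorate internal nodes with supports
        for _, _, node in tree.edges(include_leaves=False):
            node.support = round(float(rng.uniform()), 3)
        text = to_newick(tree)
        assert parse_newick(text) == tree

    def test_dendropy_parses_our_newick(self):
        import dendropy

        rng = np.random.default_rng(3)
        ids, tree, _ = random_additive_tree(rng, 12)
        text = to_newick(tree)
        dtree = dendropy.Tree.get(data=text, schema="newick")
        assert {t.taxon.label for t in dtree.leaf_node_iter()} == set(ids)
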