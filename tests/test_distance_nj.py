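"""p-distances, neighbor joining, and divergence summaries."""

import itertools
import random

import numpy as np
import pytest

from igs.distance import DistanceMatrix, pdistance_matrix
from igs.msa import Alignment, encode_gap_events
from igs.nj import TreeNode, build_nj, tree_clusters
from igs.summaries import (cluster_divergence, divergence_summary,
                           pdistance_ratio, segment_divergence_profile)


def enc_of(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return encode_gap_events(Alignment(ids=ids, rows=rows))


class TestPDistance:
    def test_examples(self):
        dm = pdistance_matrix(enc_of(["ACGT", "ACGT"]))
        assert dm.values[0, 1] == 0.0
        dm = pdistance_matrix(enc_of(["ACGT", "ACGA"]))
        assert dm.values[0, 1] == 0.25
        dm = pdistance_matrix(enc_of(["AC-T", "ACGT"]))
        assert dm.values[0, 1] == 0.25  # event vs G over 4 compared sites

    def test_symmetry_bounds_and_zero_iff_identical(self, rng):
        rows = ["ACGTACGTAA", "ACGTACGTAA", "TTGTACGGAA", "ACG-ACGTAA"]
        dm = pdistance_matrix(enc_of(rows))
        assert np.allclose(dm.values, dm.values.T)
        off = dm.values[~np.eye(4, dtype=bool)]
        assert ((off >= 0) & (off <= 1)).all()
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] > 0

    def test_monotone_in_added_difference(self):
        base = ["ACGTACGT", "ACGTACGT"]
        p0 = pdistance_matrix(enc_of(base)).values[0, 1]
        worse = ["ACGTACGT", "ACGTACGA"]
        p1 = pdistance_matrix(enc_of(worse)).values[0, 1]
        assert p1 > p0

    def test_zero_compared_sites_flagged_undefined(self):
        enc = enc_of(["AC--", "--GT", "ACGT"])
        dm = pdistance_matrix(enc)
        # rows 0 and 1 overlap only at encoded/missing positions
        assert np.isnan(dm.values[0, 1]) or dm.counts[0, 1] > 0


def _random_additive_tree(r: random.Random, n: int):
    """Random binary tree with integer-ish branch lengths; returns
    (TreeNode, path-distance oracle matrix, labels)."""
    nodes = [TreeNode(name=chr(ord("A") + i)) for i in range(n)]
    active = list(nodes)
    while len(active) > 2:
        i, j = sorted(r.sample(range(len(active)), 2), reverse=True)
        a, b = active.pop(i), active.pop(j)
        active.append(TreeNode(children=[(a, r.uniform(0.5, 3.0)),
                                         (b, r.uniform(0.5, 3.0))]))
    root = TreeNode(children=[(active[0], r.uniform(0.5, 3.0)),
                              (active[1], r.uniform(0.5, 3.0))])

    # oracle: path lengths from root-to-leaf edge lists, independent of
    # the NJ code under test
    labels = sorted(chr(ord("A") + i) for i in range(n))
    edge_path = {}

    def walk2(node, edges):
        if node.is_leaf():
            edge_path[node.name] = edges
            return
        for k, (c, bl) in enumerate(node.children):
            walk2(c, edges + [(id(node), k, bl)])

    walk2(root, [])
    D = np.zeros((n, n))
    for x, y in itertools.combinations(labels, 2):
        ex, ey = edge_path[x], edge_path[y]
        shared = 0
        for a, b in zip(ex, ey):
            if a[:2] == b[:2]:
                shared += 1
            else:
                break
        d = sum(e[2] for e in ex[shared:]) + sum(e[2] for e in ey[shared:])
        i, j = labels.index(x), labels.index(y)
        D[i, j] = D[j, i] = d
    return root, D, labels


def _splits(tree: TreeNode, all_leaves: frozenset) -> set:
    out = set()
    for _, child, _ in tree.edges():
        s = frozenset(child.leaves())
        if 1 < len(s) < len(all_leaves) - 1:
            out.add(min(s, frozenset(all_leaves - s), key=sorted))
    return out


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(ids=["A", "B", "C"],
                            values=np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.0]]))
        tree = build_nj(dm)
        bl = {c.name: l for c, l in tree.children}
        assert bl["A"] == pytest.approx((3 + 5 - 6) / 2)
        assert bl["B"] == pytest.approx((3 + 6 - 5) / 2)
        assert bl["C"] == pytest.approx((5 + 6 - 3) / 2)

    def test_known_additive_matrix_recovered_exactly(self):
        """Tree ((A:1,B:2):1,C:3,D:1) — the unrooted form of the
        four-taxon example — is recovered with exact branch lengths."""
        ids = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
                     dtype=float)
        tree = build_nj(DistanceMatrix(ids=ids, values=D))
        # path distances on the reconstructed tree reproduce D
        got = _tree_path_matrix(tree, ids)
        assert np.allclose(got, D)
        assert _splits(tree, frozenset(ids)) == {frozenset({"A", "B"})}

    @pytest.mark.parametrize("seed,n", [(s, n) for s in range(6) for n in (5, 8)])
    def test_random_additive_trees_recovered(self, seed, n):
        r = random.Random(1000 * n + seed)
        true_tree, D, labels = _random_additive_tree(r, n)
        got = build_nj(DistanceMatrix(ids=labels, values=D))
        assert _splits(got, frozenset(labels)) == _splits(true_tree, frozenset(labels))
        assert np.allclose(_tree_path_matrix(got, labels), D, atol=1e-9)

    def test_matches_scikit_bio_on_random_matrix(self):
        """Independent implementation cross-check on a perturbed matrix."""
        skbio = pytest.importorskip("skbio")
        r = random.Random(7)
        _, D, labels = _random_additive_tree(r, 7)
        D = D + np.random.default_rng(0).uniform(0, 0.05, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        mine = build_nj(DistanceMatrix(ids=labels, values=D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        mine_splits = _splits(mine, frozenset(labels))
        their_splits = set()
        for node in theirs.non_tips():
            s = frozenset(t.name for t in node.tips())
            if 1 < len(s) < len(labels) - 1:
                their_splits.add(min(s, frozenset(set(labels) - s), key=sorted))
        assert mine_splits == their_splits

    def test_all_zero_matrix_star_with_zero_lengths(self):
        dm = DistanceMatrix(ids=list("ABCD"), values=np.zeros((4, 4)))
        tree = build_nj(dm)
        assert all(l == 0 for _, _, l in tree.edges())
        assert tree.n_edges() == 2 * 4 - 3

    def test_undefined_entries_rejected(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = np.nan
        with pytest.raises(ValueError):
            build_nj(DistanceMatrix(ids=list("ABC"), values=v))

    def test_negative_lengths_clamped(self):
        r = random.Random(3)
        _, D, labels = _random_additive_tree(r, 6)
        noisy = D + np.random.default_rng(1).normal(0, 0.4, D.shape)
        noisy = np.abs((noisy + noisy.T) / 2)
        np.fill_diagonal(noisy, 0)
        tree = build_nj(DistanceMatrix(ids=labels, values=noisy))
        assert all(l >= 0 for _, _, l in tree.edges())


def _tree_path_matrix(tree: TreeNode, labels):
    edge_path = {}

    def walk(node, edges):
        if node.is_leaf():
            edge_path[node.name] = edges
            return
        for k, (c, bl) in enumerate(node.children):
            walk(c, edges + [(id(node), k, bl)])

    walk(tree, [])
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ex, ey = edge_path[labels[i]], edge_path[labels[j]]
            shared = 0
            for a, b in zip(ex, ey):
                if a[:2] == b[:2]:
                    shared += 1
                else:
                    break
            d = sum(e[2] for e in ex[shared:]) + sum(e[2] for e in ey[shared:])
            D[i, j] = D[j, i] = d
    return D


class TestSummaries:
    def test_printed_ratio_examples(self):
        assert pdistance_ratio(0.022, 0.024) == 0.917
        assert pdistance_ratio(0.014, 0.011) == 1.273

    def test_cluster_divergence_contracts(self):
        ids = ["a1", "a2", "b1", "b2"]
        v = np.zeros((4, 4))
        for i in (0, 1):
            for j in (2, 3):
                v[i, j] = v[j, i] = 0.2
        dm = DistanceMatrix(ids=ids, values=v)
        cd = cluster_divergence(dm, [{"a1", "a2"}, {"b1", "b2"}])
        assert cd.within_mean == 0.0 and cd.between_mean == pytest.approx(0.2)
        # two singletons: within undefined, between is the pair value
        dm2 = DistanceMatrix(ids=["x", "y"], values=np.array([[0, 0.3], [0.3, 0.0]]))
        cd2 = cluster_divergence(dm2, [{"x"}, {"y"}])
        assert np.isnan(cd2.within_mean) and cd2.between_mean == pytest.approx(0.3)

    def test_equal_distances_give_ratio_one(self):
        ids = ["a1", "a2", "b1", "b2"]
        v = np.full((4, 4), 0.1)
        np.fill_diagonal(v, 0)
        dm = DistanceMatrix(ids=ids, values=v)
        s = divergence_summary(dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert s.ratio == pytest.approx(1.0)

    def test_whole_alignment_segment_equals_global(self, rng):
        rows = ["ACGTACGTAC", "ACGTACGTCC", "TCGTACGAAC", "ACGAACGTAT"]
        enc = enc_of(rows)
        sp = {"s0": "X", "s1": "X", "s2": "Y", "s3": "Y"}
        whole = segment_divergence_profile(enc, sp, [(0, enc.n_columns)])[0]
        glob = divergence_summary(pdistance_matrix(enc), sp)
        assert whole.oam == pytest.approx(glob.oam)
        assert whole.mia == pytest.approx(glob.mia)
        assert whole.mir == pytest.approx(glob.mir)

    def test_single_species_rejected(self):
        enc = enc_of(["ACGT", "ACGA"])
        with pytest.raises(ValueError):
            segment_divergence_profile(enc, {"s0": "X", "s1": "X"}, [(0, 4)])

    def test_tree_clusters_partition_leaves(self):
        r = random.Random(11)
        _, D, labels = _random_additive_tree(r, 8)
        tree = build_nj(DistanceMatrix(ids=labels, values=D))
        clusters = tree_clusters(tree, 3)
        assert len(clusters) == 3
        assert sorted(l for c in clusters for l in c) == labels
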