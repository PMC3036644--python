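"""Breakpoint scanning: candidates, JC69 likelihood, and the DP search."""

import itertools

import numpy as np
import pytest

from igs.msa import Alignment, EncodedAlignment, encode_gap_events
from igs.nj import TreeNode
from igs.recomb import (breakpoint_search, candidate_breakpoints, jc_alignment,
                        segment_fit)


def leaf(n):
    return TreeNode(name=n)


def enc_of(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return encode_gap_events(Alignment(ids=ids, rows=rows))


class TestCandidates:
    def test_invariant_alignment_empty(self):
        assert candidate_breakpoints(enc_of(["ACGT", "ACGT", "ACGT"])) == []

    def test_exactly_the_polymorphic_columns(self):
        enc = enc_of(["ACGTA", "ACGTT", "TCGAA"])
        assert candidate_breakpoints(enc) == [0, 3, 4]

    def test_gap_event_column_is_variable(self):
        enc = enc_of(["AC-T", "ACGT", "ACGT"])
        assert 2 in candidate_breakpoints(enc)


class TestSegmentFit:
    def test_pruning_matches_bruteforce_on_one_column(self):
        """Four taxa, one site: the reported log-likelihood equals the
        explicit sum over internal-node states."""
        t4 = TreeNode(children=[(leaf("A"), 0.1), (leaf("B"), 0.2),
                                (TreeNode(children=[(leaf("C"), 0.15),
                                                    (leaf("D"), 0.05)]), 0.08)])
        states = {"A": 0, "B": 0, "C": 1, "D": 2}
        m = np.array([[states[x]] for x in "ABCD"], dtype=np.int32)
        enc = EncodedAlignment(ids=list("ABCD"), matrix=m, event_columns=())

        from igs.recomb import _Phylo, _down_pass, _leaf_partials, _loglik

        ph = _Phylo(t4)
        down, ls = _down_pass(ph, _leaf_partials(ph, m, list("ABCD")), 1)
        got = _loglik(ph, down, ls, 1)

        def P(t):
            e = np.exp(-4 * t / 3)
            return lambda x, y: 0.25 + 0.75 * e if x == y else 0.25 - 0.25 * e

        p = [P(0.1), P(0.2), P(0.08), P(0.15), P(0.05)]
        tot = sum(0.25 * p[0](r, 0) * p[1](r, 0) * p[2](r, v)
                  * p[3](v, 1) * p[4](v, 2)
                  for r in range(4) for v in range(4))
        assert got == pytest.approx(np.log(tot), abs=1e-9)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_topology_recovered_from_simulated_data(self, seed):
        """1000 JC columns on a fixed 5-taxon tree recover its cherries."""
        tree = TreeNode(children=[
            (leaf("A"), 0.05),
            (TreeNode(children=[(leaf("B"), 0.05), (leaf("C"), 0.05)]), 0.1),
            (TreeNode(children=[(leaf("D"), 0.05), (leaf("E"), 0.05)]), 0.1)])
        enc = jc_alignment(tree, 1000, seed=seed)
        fit = segment_fit(enc)
        # the unrooted splits of the fitted tree are BC|ADE and DE|ABC
        from igs.sim import _parse_newick

        def splits(node, all_leaves):
            if not node.children:
                return set(), {node.name}
            got, leaves = set(), set()
            for c in node.children:
                s, l = splits(c, all_leaves)
                got |= s
                leaves |= l
            if 1 < len(leaves) < len(all_leaves) - 1:
                got.add(frozenset(leaves))
            return got, leaves

        root = _parse_newick(fit.newick)
        s, _ = splits(root, set("ABCDE"))
        norm = {min(x, frozenset(set("ABCDE")) - x,
                    key=lambda y: (len(y), sorted(y))) for x in s}
        assert frozenset("BC") in norm and frozenset("DE") in norm
        assert fit.n_params == 2 * 5 - 3

    def test_likelihood_never_positive(self):
        tree = TreeNode(children=[(leaf("A"), 0.1), (leaf("B"), 0.1),
                                  (leaf("C"), 0.1)])
        enc = jc_alignment(tree, 200, seed=2)
        assert segment_fit(enc).loglik < 0

    def test_too_few_rows_rejected(self):
        enc = enc_of(["ACGT", "ACGA"])
        with pytest.raises(ValueError):
            segment_fit(enc)


def _two_topology_alignment(n_cols_each=300, seed=0, strong=0.3):
    """Concatenation of blocks generated on AB|CD and then AC|BD."""
    tAB = TreeNode(children=[
        (TreeNode(children=[(leaf("A"), 0.02), (leaf("B"), 0.02)]), strong),
        (leaf("C"), 0.02), (leaf("D"), strong)])
    tAC = TreeNode(children=[
        (TreeNode(children=[(leaf("A"), 0.02), (leaf("C"), 0.02)]), strong),
        (leaf("B"), 0.02), (leaf("D"), strong)])
    e1 = jc_alignment(tAB, n_cols_each, seed=seed)
    e2 = jc_alignment(tAC, n_cols_each, seed=seed + 10_000)
    order = [e2.ids.index(i) for i in e1.ids]
    mat = np.hstack([e1.matrix, e2.matrix[order]])
    return EncodedAlignment(ids=e1.ids, matrix=mat, event_columns=())


class TestBreakpointSearch:
    def test_dp_equals_exhaustive_enumeration_k2(self):
        """On a 6-taxon, 300-column alignment the DP optimum for each
        K <= 2 matches brute-force enumeration over admissible
        placements."""
        tree = TreeNode(children=[
            (TreeNode(children=[(leaf("A"), 0.04), (leaf("B"), 0.04)]), 0.06),
            (TreeNode(children=[(leaf("C"), 0.04), (leaf("D"), 0.04)]), 0.06),
            (TreeNode(children=[(leaf("E"), 0.08), (leaf("F"), 0.08)]), 0.06)])
        enc = jc_alignment(tree, 300, seed=5)
        min_seg, stride = 25, 6
        bp = breakpoint_search(enc, k_max=2, min_segment=min_seg, stride=stride)

        cands = candidate_breakpoints(enc)
        points = cands[::stride]
        L = enc.n_columns
        n_var = {c: sum(1 for x in cands if x < c) for c in points}
        n_var[0], n_var[L] = 0, len(cands)
        cache = {}

        def ll(lo, hi):
            if (lo, hi) not in cache:
                cache[(lo, hi)] = segment_fit(enc, (lo, hi)).loglik
            return cache[(lo, hi)]

        best = {0: ll(0, L)}
        for k in (1, 2):
            top = -np.inf
            for combo in itertools.combinations(points, k):
                bounds = [0, *combo, L]
                if any(n_var[b] - n_var[a] < min_seg
                       for a, b in zip(bounds[:-1], bounds[1:])):
                    continue
                top = max(top, sum(ll(a, b)
                                   for a, b in zip(bounds[:-1], bounds[1:])))
            best[k] = top

        for k in (0, 1, 2):
            assert bp.loglik_by_k[k] == pytest.approx(best[k], abs=1e-6)

    def test_breakpoint_placed_at_topology_junction(self):
        enc = _two_topology_alignment(n_cols_each=300, seed=1)
        bp = breakpoint_search(enc, k_max=2, min_segment=40, stride=2)
        assert bp.k >= 1
        cands = candidate_breakpoints(enc)
        junction_rank = sum(1 for c in cands if c < 300)
        ranks = [sum(1 for c in cands if c < b) for b in bp.breakpoints]
        assert any(abs(r - junction_rank) <= 5 for r in ranks)

    def test_loglik_monotone_in_k_and_segments_tile(self):
        enc = _two_topology_alignment(n_cols_each=200, seed=2)
        bp = breakpoint_search(enc, k_max=2, min_segment=30, stride=4)
        lls = [bp.loglik_by_k[k] for k in sorted(bp.loglik_by_k)]
        assert all(a <= b + 1e-9 for a, b in zip(lls[:-1], lls[1:]))
        spans = [s.span for s in bp.segments]
        assert spans[0][0] == 0 and spans[-1][1] == enc.n_columns
        for (a, b), (c, d) in zip(spans[:-1], spans[1:]):
            assert b == c
        # breakpoints are members of the candidate list
        cands = set(candidate_breakpoints(enc))
        assert all(b in cands for b in bp.breakpoints)

    def test_invalid_kmax(self):
        enc = _two_topology_alignment(100, seed=3)
        with pytest.raises(ValueError):
            breakpoint_search(enc, k_max=-1)

    def test_reproducible(self):
        enc = _two_topology_alignment(150, seed=4)
        b1 = breakpoint_search(enc, k_max=1, min_segment=20, stride=4)
        b2 = breakpoint_search(enc, k_max=1, min_segment=20, stride=4)
        assert b1.breakpoints == b2.breakpoints and b1.k == b2.k
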