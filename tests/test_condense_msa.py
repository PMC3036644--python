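"""Consensus condensation, progressive alignment, and indel encoding."""

import random

import numpy as np
import pytest

from igs.condense import condense_igs, repeat_consensus
from igs.msa import (Alignment, GAP_EVENT_BASE, MISSING, encode_gap_events,
                     pairwise_global, progressive_align, read_alignment,
                     write_alignment)
from igs.records import IGSRecord
from igs.repeats import RepeatAnnotation, RepeatUnit, dissect

from conftest import mutate, random_dna

# oracle scoring mirrors the production constants
M, X, GO, GE = 5.0, -4.0, 10.0, 0.5


def slow_affine_global(a: str, b: str) -> float:
    """Exhaustive affine-gap global DP optimum (plain loops)."""
    NEG = -1e18
    n1, n2 = len(a), len(b)
    H = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]
    E = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]
    F = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]
    H[0][0] = 0.0
    for j in range(1, n2 + 1):
        E[0][j] = H[0][j] = -(GO + (j - 1) * GE)
    for i in range(1, n1 + 1):
        F[i][0] = H[i][0] = -(GO + (i - 1) * GE)
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            s = M if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else X
            E[i][j] = max(H[i][j - 1] - GO, E[i][j - 1] - GE)
            F[i][j] = max(H[i - 1][j] - GO, F[i - 1][j] - GE)
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[n1][n2]


class TestPairwise:
    @pytest.mark.parametrize("seed", range(6))
    def test_score_equals_exhaustive_dp(self, seed):
        r = random.Random(seed)
        a = random_dna(r, r.randint(10, 200))
        b = mutate(r, a, 0.1) if seed % 2 else random_dna(r, r.randint(10, 200))
        if seed == 4:  # indel-bearing relative
            b = b[:40] + b[55:]
        aln, score = pairwise_global(a, b)
        assert score == pytest.approx(slow_affine_global(a, b), abs=1e-6)
        assert aln.ungapped("seq1") == a and aln.ungapped("seq2") == b

    def test_single_nt_gap_example(self):
        aln, score = pairwise_global("ACGTACGT", "ACGACGT")
        joined = aln.rows[1]
        assert joined.count("-") == 1
        assert score == pytest.approx(slow_affine_global("ACGTACGT", "ACGACGT"))

    def test_identical_pair_has_no_gaps(self):
        aln, _ = pairwise_global("ACGTTGCA", "ACGTTGCA")
        assert "-" not in "".join(aln.rows)


class TestProgressive:
    def test_rows_ungap_to_inputs_and_columns_cover_longest(self, rng):
        base = random_dna(rng, 250)
        seqs = [mutate(rng, base, 0.05) for _ in range(5)]
        seqs[2] = seqs[2][:80] + seqs[2][95:]
        aln = progressive_align(seqs, ids=[f"s{i}" for i in range(5)])
        for i, s in enumerate(seqs):
            assert aln.ungapped(f"s{i}") == s
        assert aln.n_columns >= max(len(s) for s in seqs)

    def test_deterministic_for_fixed_input(self, rng):
        seqs = [random_dna(rng, 60) for _ in range(4)]
        a1 = progressive_align(seqs)
        a2 = progressive_align(seqs)
        assert a1.rows == a2.rows

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            progressive_align(["ACGT"])

    def test_io_roundtrip(self, tmp_path, rng):
        aln = progressive_align([random_dna(rng, 50), random_dna(rng, 55)],
                                ids=["a", "b"])
        write_alignment(aln, tmp_path / "a.fasta")
        back = read_alignment(tmp_path / "a.fasta")
        assert back.ids == aln.ids and back.rows == aln.rows


class TestConsensus:
    def test_identical_copies(self):
        assert repeat_consensus(["ACGT", "ACGT"]).sequence == "ACGT"

    def test_majority_base(self):
        assert repeat_consensus(["ACGT", "ACGA", "ACGT"]).sequence == "ACGT"

    def test_tie_resolved_to_earliest_array_copy(self):
        assert repeat_consensus(["ACGT", "ACGA"]).sequence == "ACGT"
        # with array order reversed, the other copy wins the tie
        assert repeat_consensus(["ACGT", "ACGA"], array_order=[1, 0]).sequence == "ACGA"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            repeat_consensus([])


class TestCondense:
    def _fixture(self, rng):
        A, B, C = random_dna(rng, 120), random_dna(rng, 80), random_dna(rng, 60)
        n1, n2 = random_dna(rng, 100), random_dna(rng, 150)
        order = ["A", "B", "A", "B", "C", "C"]
        seqs = {"A": A, "B": B, "C": C}
        body, units, pos = [], [], 100
        counts: dict[str, int] = {}
        for t in order:
            s = mutate(rng, seqs[t], 0.02)
            counts[t] = counts.get(t, 0) + 1
            units.append(RepeatUnit(type_label=t, interval=(pos, pos + len(s)),
                                    copy_index=counts[t]))
            body.append(s)
            pos += len(s)
        rec = IGSRecord(id="r", species="s", individual="i",
                        sequence=n1 + "".join(body) + n2)
        return rec, RepeatAnnotation(record_id="r", units=tuple(units))

    def test_order_and_length_arithmetic(self, rng):
        rec, ann = self._fixture(rng)
        cond, prov = condense_igs(rec, ann)
        assert list(prov["types"]) == ["A", "B", "C"]  # first-occurrence order
        expected_len = prov["n1"][1] + sum(
            t["interval"][1] - t["interval"][0] for t in prov["types"].values()
        ) + (prov["n2"][1] - prov["n2"][0])
        assert cond.length == expected_len

    def test_idempotence(self, rng):
        rec, ann = self._fixture(rng)
        cond, prov = condense_igs(rec, ann)
        units2, pos = [], None
        counts: dict[str, int] = {}
        units2 = []
        for t, info in prov["types"].items():
            counts[t] = counts.get(t, 0) + 1
            units2.append(RepeatUnit(type_label=t, interval=tuple(info["interval"]),
                                     copy_index=1))
        ann2 = RepeatAnnotation(record_id=cond.id, units=tuple(units2))
        cond2, _ = condense_igs(cond, ann2)
        assert cond2.sequence == cond.sequence

    def test_empty_annotation_rejected(self, rng):
        rec, _ = self._fixture(rng)
        with pytest.raises(ValueError):
            condense_igs(rec, RepeatAnnotation(record_id="r", units=()))


class TestGapEvents:
    def test_first_gap_position_encoded_rest_missing(self):
        enc = encode_gap_events(Alignment(ids=["a", "b"],
                                          rows=["AC--T", "ACGGT"]))
        row = enc.matrix[0]
        assert row[2] == GAP_EVENT_BASE + 2
        assert row[3] == MISSING
        assert enc.event_columns == (2,)

    def test_shared_deletion_shares_the_symbol(self):
        enc = encode_gap_events(Alignment(
            ids=["a", "b", "c"], rows=["AC--T", "AC--T", "ACGGT"]))
        assert enc.matrix[0, 2] == enc.matrix[1, 2] == GAP_EVENT_BASE + 2

    def test_gap_free_alignment_unchanged(self):
        enc = encode_gap_events(Alignment(ids=["a", "b"], rows=["ACGT", "ACGA"]))
        assert enc.event_columns == ()
        assert (enc.matrix >= 0).all()

    def test_one_counted_site_per_gap_regardless_of_length(self):
        """A 1-nt and a 4-nt deletion each contribute one difference."""
        from igs.distance import pdistance_matrix

        ref = "ACTTTTGT"
        for gapped in ("AC----GT", "ACT-TTGT"):
            enc = encode_gap_events(Alignment(ids=["g", "ref"],
                                              rows=[gapped, ref]))
            dm = pdistance_matrix(enc)
            diffs = dm.values[0, 1] * dm.counts[0, 1]
            assert diffs == pytest.approx(1.0), gapped

    def test_n_treated_as_missing(self):
        from igs.distance import pdistance_matrix

        enc = encode_gap_events(Alignment(ids=["a", "b"], rows=["ANGT", "ACGT"]))
        dm = pdistance_matrix(enc)
        assert dm.counts[0, 1] == 3 and dm.values[0, 1] == 0.0
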