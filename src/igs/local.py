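"""Local alignment with sub-optimal declumping (Waterman-Eggert).

Repeat-unit boundaries are estimated from the k best mutually
non-overlapping local self-alignments of an IGS sequence.  The DP is
Smith-Waterman with affine gaps (match +5, mismatch -4, gap open -12,
gap extend -4; a gap of length L costs 12 + 4*(L-1)).  After each
alignment is extracted, its path cells are masked and the matrix is
refilled, so no two reported alignments share an aligned cell.

For self-comparison only the strict upper triangle (j > i) is searched,
which removes the trivial identity alignment and mirror duplicates.

The row fill is vectorized.  The horizontal (in-row) affine gap state is
computed with a running-maximum scan, which is exact whenever the gap
open cost is at least the extension cost: a horizontal gap that starts
immediately after another horizontal gap is then always dominated by the
single merged gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LocalAlignment", "waterman_eggert", "kbest_self_alignments", "Scoring"]

NEG = -(2**30)


@dataclass(frozen=True)
class Scoring:
    match: int = 5
    mismatch: int = -4
    gap_open: int = 12  # cost of a length-1 gap
    gap_extend: int = 4  # additional cost per extra gapped position

    def __post_init__(self):
        if self.gap_open < self.gap_extend:
            raise ValueError("running-max fill requires gap_open >= gap_extend")


@dataclass(frozen=True)
class LocalAlignment:
    """One declumped local alignment between two sequences.

    ``runs`` are the gap-free diagonal stretches of the path, each a
    (ref_start, qry_start, length) triple in 0-based sequence
    coordinates; an alignment chained across gaps decomposes into
    several constant-offset runs.
    """

    ref: tuple[int, int]  # half-open interval on the first sequence
    qry: tuple[int, int]  # half-open interval on the second sequence
    score: int
    n_columns: int
    n_matches: int
    runs: tuple[tuple[int, int, int], ...] = ()

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def _fill(a, b, mask, sc: Scoring):
    """Fill H/E/F (int64, DP-indexed with a zero row/col) under `mask`."""
    n1, n2 = len(a), len(b)
    H = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    E = np.full((n1 + 1, n2 + 1), NEG, dtype=np.int64)
    F = np.full((n1 + 1, n2 + 1), NEG, dtype=np.int64)
    n_code = ord("N")
    ext = sc.gap_extend
    opn = sc.gap_open
    j_idx = np.arange(1, n2 + 1, dtype=np.int64)
    for i in range(1, n1 + 1):
        sub = np.where((b == a[i - 1]) & (b != n_code), sc.match, sc.mismatch)
        diag = H[i - 1, :-1] + sub
        F[i, 1:] = np.maximum(H[i - 1, 1:] - opn, F[i - 1, 1:] - ext)
        h0 = np.maximum(diag, F[i, 1:])
        np.maximum(h0, 0, out=h0)
        mrow = mask[i - 1]
        if mrow.any():
            h0[mrow] = 0
        # horizontal gaps: E[j] = max_{k<j} H[i,k] - opn - ext*(j-1-k),
        # computed as a prefix max of H0 + ext*k, reset at masked cells
        base = np.full(n2 + 1, NEG, dtype=np.int64)
        base[1:] = h0 + ext * j_idx
        if mrow.any():
            m_idx = np.flatnonzero(mrow)  # sequence columns; DP cols are +1
            base[m_idx + 1] = NEG
            # prefix max restarted after each masked run (gaps may not
            # cross masked cells); masked runs are few per row
            gap = np.diff(m_idx) > 1
            starts = m_idx[np.r_[True, gap]] + 1
            ends = m_idx[np.r_[gap, True]] + 1  # inclusive DP cols
            run_max = np.empty_like(base)
            prev = 0
            for s_, e_ in zip(starts, ends):
                if s_ > prev:
                    run_max[prev:s_] = np.maximum.accumulate(base[prev:s_])
                run_max[s_:e_ + 1] = NEG
                prev = e_ + 1
            if prev < n2 + 1:
                run_max[prev:] = np.maximum.accumulate(base[prev:])
        else:
            run_max = np.maximum.accumulate(base)
        e = run_max[:-1] - opn - ext * (j_idx - 1)
        np.maximum(e, NEG, out=e)
        E[i, 1:] = e
        H[i, 1:] = np.maximum(h0, np.maximum(e, 0))
        if mrow.any():
            H[i, 1:][mrow] = 0
            E[i, 1:][mrow] = NEG
            F[i, 1:][mrow] = NEG
    return H, E, F


def _traceback(a, b, H, E, F, sc: Scoring, i, j):
    """Recover one optimal path ending at DP cell (i, j) in state H."""
    n_code = ord("N")
    cells = []
    diag_cells = []  # 0-based (ref, qry) pairs, visited back-to-front
    n_matches = 0
    n_cols = 0
    i_lo, i_hi = i, i
    j_lo, j_hi = j, j
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h <= 0:
                break
            s = sc.match if (a[i - 1] == b[j - 1] and a[i - 1] != n_code) else sc.mismatch
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + s:
                cells.append((i, j))
                diag_cells.append((i - 1, j - 1))
                n_cols += 1
                if s == sc.match:
                    n_matches += 1
                i -= 1
                j -= 1
                i_lo, j_lo = min(i_lo, i + 1), min(j_lo, j + 1)
            elif h == E[i, j]:
                state = "E"
            elif h == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in state H")
        elif state == "E":
            cells.append((i, j))
            n_cols += 1
            if E[i, j] == H[i, j - 1] - sc.gap_open:
                j -= 1
                state = "H"
            elif E[i, j] == E[i, j - 1] - sc.gap_extend:
                j -= 1
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in state E")
            j_lo = min(j_lo, j + 1)
        else:  # state F
            cells.append((i, j))
            n_cols += 1
            if F[i, j] == H[i - 1, j] - sc.gap_open:
                i -= 1
                state = "H"
            elif F[i, j] == F[i - 1, j] - sc.gap_extend:
                i -= 1
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in state F")
            i_lo = min(i_lo, i + 1)
    diag_cells.reverse()
    runs = []
    for ci, cj in diag_cells:
        if runs and ci == runs[-1][0] + runs[-1][2] and cj == runs[-1][1] + runs[-1][2]:
            runs[-1][2] += 1
        else:
            runs.append([ci, cj, 1])
    aln = LocalAlignment(
        ref=(i_lo - 1, i_hi), qry=(j_lo - 1, j_hi),
        score=0,  # filled in by the caller from the DP cell value
        n_columns=n_cols, n_matches=n_matches,
        runs=tuple(tuple(r) for r in runs),
    )
    return aln, cells


def waterman_eggert(
    s1: str,
    s2: str,
    k: int = 25,
    scoring: Scoring | None = None,
    *,
    self_triangle: bool = False,
    min_score: int = 1,
) -> list[LocalAlignment]:
    """k best mutually non-overlapping local alignments of s1 vs s2.

    With ``self_triangle=True`` (self-comparison) only cells with
    j > i are searched.  Fewer than k alignments are returned when no
    positive-scoring alignment remains.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not s1 or not s2:
        raise ValueError("empty sequence")
    sc = scoring or Scoring()
    a, b = _encode(s1.upper()), _encode(s2.upper())
    n1, n2 = len(a), len(b)
    mask = np.zeros((n1, n2), dtype=bool)
    if self_triangle:
        if n1 != n2:
            raise ValueError("self_triangle requires s1 == s2")
        for i in range(n1):
            mask[i, : i + 1] = True  # forbid j <= i
    out: list[LocalAlignment] = []
    for _ in range(k):
        H, E, F = _fill(a, b, mask, sc)
        flat = int(np.argmax(H))
        i, j = divmod(flat, n2 + 1)
        best = int(H[i, j])
        if best < min_score:
            break
        aln, cells = _traceback(a, b, H, E, F, sc, i, j)
        aln = LocalAlignment(ref=aln.ref, qry=aln.qry, score=best,
                             n_columns=aln.n_columns, n_matches=aln.n_matches,
                             runs=aln.runs)
        out.append(aln)
        for ci, cj in cells:
            mask[ci - 1, cj - 1] = True
    return out


def kbest_self_alignments(seq: str, k: int = 25, scoring: Scoring | None = None,
                          min_score: int = 1) -> list[LocalAlignment]:
    """k best declumped local self-alignments (trivial identity excluded).

    `min_score` stops the declumping early once the best remaining
    alignment drops below it; sub-threshold alignments carry no usable
    repeat-boundary evidence.
    """
    return waterman_eggert(seq, seq, k=k, scoring=scoring, self_triangle=True,
                           min_score=min_score)
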