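"""Progressive multiple alignment and the gap-event indel encoding.

Condensed IGS sequences are aligned with a guide-tree progressive
scheme: a neighbor-joining tree is built on k-mer distances and
profiles are merged bottom-up with affine-gap global alignment
(match +5, mismatch -4, gap open -10, gap extend -0.5; a gap of
length L costs 10 + 0.5*(L-1)).  The procedure is deterministic for a
fixed input order; callers that want order-independence sort ids first.

Indels enter distance computations through a conservative encoding:
the first position of each maximal gap run is replaced by a symbol
unique to that alignment column, and the remaining gap positions become
missing data.  Rows whose deletion opens at the same column therefore
share the same symbol and match each other, and an indel contributes at
most one potential difference regardless of its length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix
from .nj import TreeNode, build_nj

__all__ = [
    "Alignment",
    "EncodedAlignment",
    "progressive_align",
    "pairwise_global",
    "encode_gap_events",
    "kmer_distance_matrix",
    "write_alignment",
    "read_alignment",
]

MATCH = 5.0
MISMATCH = -4.0
GAP_OPEN = 10.0  # cost of a length-1 gap
GAP_EXT = 0.5  # additional cost per extra gapped position
NEG = -1e18

_BASES = "ACGTN"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
# substitution matrix over ACGTN; N mismatches everything, including N
_S = np.full((5, 5), MISMATCH)
for _i in range(4):
    _S[_i, _i] = MATCH

GAP_EVENT_BASE = 5  # event code for column c is GAP_EVENT_BASE + c
MISSING = -1

_SYMBOL_POOL = list("abcdefghijklmnopqrstuvwxyz0123456789") + \
    list("!#$%&*+/:;<=>?@^_~")


@dataclass
class Alignment:
    """Gapped rows over {A,C,G,T,N,-}, all the same length."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        for r in self.rows:
            if set(r) - set("ACGTN-"):
                raise ValueError("invalid symbols in alignment row")
        cols = np.array([list(r) for r in self.rows]) if self.rows else None
        if cols is not None and cols.size and (cols == "-").all(axis=0).any():
            raise ValueError("alignment contains an all-gap column")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")


@dataclass
class EncodedAlignment:
    """Integer-coded alignment with gap events as column-unique states.

    Codes: 0-3 = A,C,G,T; ``GAP_EVENT_BASE + c`` = gap opening at
    column c; ``MISSING`` (-1) = interior gap positions and N.
    """

    ids: list[str]
    matrix: np.ndarray  # (n_rows, n_columns) int32
    event_columns: tuple[int, ...]  # columns where some gap opens

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def slice(self, lo: int, hi: int) -> "EncodedAlignment":
        ev = tuple(c for c in self.event_columns if lo <= c < hi)
        return EncodedAlignment(ids=list(self.ids),
                                matrix=self.matrix[:, lo:hi], event_columns=ev)

    def symbol_rows(self) -> tuple[list[str], dict[int, str]]:
        """Rows with gap events as printable symbols + column->symbol map."""
        ev_cols = list(self.event_columns)
        if len(ev_cols) > len(_SYMBOL_POOL):
            raise ValueError("more gap-event columns than printable symbols")
        sym = {c: _SYMBOL_POOL[k] for k, c in enumerate(ev_cols)}
        rows = []
        for r in self.matrix:
            chars = []
            for c, v in enumerate(r):
                if v == MISSING:
                    chars.append("-")
                elif v >= GAP_EVENT_BASE:
                    chars.append(sym[v - GAP_EVENT_BASE])
                else:
                    chars.append(_BASES[v])
            rows.append("".join(chars))
        return rows, sym


# ---------------------------------------------------------------------------
# profile-profile affine DP


def _profile_counts(rows: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    counts = np.zeros((arr.shape[1], 5), dtype=np.float64)
    for b, code in _BASE_CODE.items():
        counts[:, code] = (arr == ord(b)).sum(axis=0)
    return counts


def _align_profiles(xrows: list[str], yrows: list[str]):
    """Globally align two profiles; returns (merged ops, score).

    ops is a string over M (consume both), X (consume X column only),
    Y (consume Y column only).
    """
    PX = _profile_counts(xrows)
    PY = _profile_counts(yrows)
    nx, ny = len(xrows), len(yrows)
    L1, L2 = PX.shape[0], PY.shape[0]
    SY = _S @ PY.T / (nx * ny)  # (5, L2)
    H = np.full((L1 + 1, L2 + 1), NEG)
    E = np.full((L1 + 1, L2 + 1), NEG)
    F = np.full((L1 + 1, L2 + 1), NEG)
    j_idx = np.arange(1, L2 + 1, dtype=np.float64)
    H[0, 0] = 0.0
    H[0, 1:] = -(GAP_OPEN + (j_idx - 1) * GAP_EXT)
    E[0, 1:] = H[0, 1:]
    for i in range(1, L1 + 1):
        H[i, 0] = -(GAP_OPEN + (i - 1) * GAP_EXT)
        F[i, 0] = H[i, 0]
        srow = PX[i - 1] @ SY  # (L2,)
        diag = H[i - 1, :-1] + srow
        F[i, 1:] = np.maximum(H[i - 1, 1:] - GAP_OPEN, F[i - 1, 1:] - GAP_EXT)
        h0 = np.maximum(diag, F[i, 1:])
        base = np.empty(L2 + 1)
        base[0] = H[i, 0]
        base[1:] = h0 + GAP_EXT * j_idx
        run = np.maximum.accumulate(base)
        e = run[:-1] - GAP_OPEN - GAP_EXT * (j_idx - 1)
        E[i, 1:] = e
        H[i, 1:] = np.maximum(h0, e)
    score = float(H[L1, L2])

    ops = []
    i, j = L1, L2
    state = "H"
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + PX[i - 1] @ SY[:, j - 1])) < tol:
                ops.append("M")
                i -= 1
                j -= 1
            elif j > 0 and abs(H[i, j] - E[i, j]) < tol:
                state = "E"
            elif i > 0 and abs(H[i, j] - F[i, j]) < tol:
                state = "F"
            elif j > 0 and i == 0:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("Y")
            if j == 1 or abs(E[i, j] - (H[i, j - 1] - GAP_OPEN)) < tol:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:
            ops.append("X")
            if i == 1 or abs(F[i, j] - (H[i - 1, j] - GAP_OPEN)) < tol:
                i -= 1
                state = "H"
            else:
                i -= 1
    ops.reverse()
    return "".join(ops), score


def _merge(xrows: list[str], yrows: list[str], ops: str):
    out_x = [[] for _ in xrows]
    out_y = [[] for _ in yrows]
    i = j = 0
    for op in ops:
        if op in "MX":
            for r, row in zip(out_x, xrows):
                r.append(row[i])
            i += 1
        else:
            for r in out_x:
                r.append("-")
        if op in "MY":
            for r, row in zip(out_y, yrows):
                r.append(row[j])
            j += 1
        else:
            for r in out_y:
                r.append("-")
    return ["".join(r) for r in out_x] + ["".join(r) for r in out_y]


def pairwise_global(s1: str, s2: str) -> tuple[Alignment, float]:
    """Affine-gap global alignment of two sequences."""
    ops, score = _align_profiles([s1], [s2])
    r1, r2 = _merge([s1], [s2], ops)
    return Alignment(ids=["seq1", "seq2"], rows=[r1, r2]), score


# ---------------------------------------------------------------------------
# guide tree and progressive merge


def _kmer_profile(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_distance_matrix(seqs: list[str], ids: list[str], k: int = 6) -> DistanceMatrix:
    """1 - shared k-mer fraction; a fast guide-tree distance."""
    profs = [_kmer_profile(s, k) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(profs[i]), len(profs[j]))
            shared = len(profs[i] & profs[j]) if denom else 0
            d[i, j] = d[j, i] = 1.0 - (shared / denom if denom else 0.0)
    return DistanceMatrix(ids=list(ids), values=d)


def progressive_align(seqs: list[str], ids: list[str] | None = None) -> Alignment:
    """Progressive alignment over an NJ guide tree on k-mer distances.

    Deterministic for a fixed input order; row order matches input.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if ids is None:
        ids = [f"seq{i+1}" for i in range(len(seqs))]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    for s in seqs:
        if not s:
            raise ValueError("empty sequence in alignment input")
    if len(seqs) == 2:
        ops, _ = _align_profiles([seqs[0]], [seqs[1]])
        rows = _merge([seqs[0]], [seqs[1]], ops)
        return Alignment(ids=list(ids), rows=rows)

    by_id = dict(zip(ids, seqs))
    guide = build_nj(kmer_distance_matrix(seqs, ids))

    def merge_node(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            return [node.name], [by_id[node.name]]
        parts = [merge_node(c) for c, _ in node.children]
        cur_ids, cur_rows = parts[0]
        for nxt_ids, nxt_rows in parts[1:]:
            ops, _ = _align_profiles(cur_rows, nxt_rows)
            merged = _merge(cur_rows, nxt_rows, ops)
            cur_ids = cur_ids + nxt_ids
            cur_rows = merged
        return cur_ids, cur_rows

    got_ids, got_rows = merge_node(guide)
    order = [got_ids.index(i) for i in ids]
    return Alignment(ids=list(ids), rows=[got_rows[k] for k in order])


# ---------------------------------------------------------------------------
# indel encoding


def encode_gap_events(aln: Alignment) -> EncodedAlignment:
    """Replace the first position of each gap run with a column-unique
    state; keep the rest of the run (and N) as missing data.

    Rows whose gap opens at the same column receive the same state, so
    shared indels count as matches in downstream distances, and every
    indel contributes exactly one potential difference.
    """
    n, L = len(aln.rows), aln.n_columns
    mat = np.full((n, L), MISSING, dtype=np.int32)
    event_cols: set[int] = set()
    for r, row in enumerate(aln.rows):
        in_gap = False
        for c, ch in enumerate(row):
            if ch == "-":
                if not in_gap:
                    mat[r, c] = GAP_EVENT_BASE + c
                    event_cols.add(c)
                    in_gap = True
            else:
                in_gap = False
                if ch != "N":
                    mat[r, c] = _BASE_CODE[ch]
    return EncodedAlignment(ids=list(aln.ids), matrix=mat,
                            event_columns=tuple(sorted(event_cols)))


# ---------------------------------------------------------------------------
# i/o


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


def read_alignment(path) -> Alignment:
    ids, rows, cur = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                ids.append(line[1:].split()[0])
            else:
                cur.append(line.upper())
    if cur:
        rows.append("".join(cur))
    return Alignment(ids=ids, rows=rows)


def write_encoded(enc: EncodedAlignment, fasta_path, sidecar_path) -> None:
    rows, sym = enc.symbol_rows()
    with open(fasta_path, "w") as fh:
        for rid, row in zip(enc.ids, rows):
            fh.write(f">{rid}\n{row}\n")
    with open(sidecar_path, "w") as fh:
        json.dump({str(c): s for c, s in sym.items()}, fh, indent=2)
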