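"""Repeat-array dissection: unit boundaries and A/B/C family labels.

Unit boundaries are estimated from the endpoints of the k best local
self-alignments.  Each self-alignment pairs two homologous copies, so
its endpoints witness unit boundaries, and any boundary falling inside
one side of an alignment can be propagated through the alignment's
offset map to the other side.  Alignment ends are first snapped to the
point where sustained unit-to-unit identity begins, because local
alignments can over- or under-extend by a few nucleotides at repeat
junctions.  The witnessed and propagated endpoints are clustered with a
small tolerance and consecutive cluster representatives delimit units.

A boundary that no self-alignment endpoint can witness (e.g. the
internal junction of a strictly alternating super-unit that only ever
occurs as a block) is not recoverable by this procedure; see the
methods note.

Families are assigned by single-linkage clustering of unit sequences at
a pairwise-identity threshold, labelled A, B, C, ... in order of first
occurrence along the array.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .dotplot import DotplotHit, self_dotplot
from .local import LocalAlignment, kbest_self_alignments

__all__ = [
    "RepeatUnit",
    "RepeatAnnotation",
    "infer_repeat_units",
    "classify_repeats",
    "dissect",
    "annotation_to_json",
    "annotation_from_json",
    "annotation_to_bed",
]


@dataclass(frozen=True)
class RepeatUnit:
    type_label: str  # "" until classified
    interval: tuple[int, int]  # 0-based half-open on the record
    copy_index: int  # 1-based ordinal of this type along the array

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class RepeatAnnotation:
    record_id: str
    units: tuple[RepeatUnit, ...]

    def __post_init__(self):
        prev_end = -1
        for u in self.units:
            if u.interval[0] < prev_end:
                raise ValueError("repeat units overlap or are unsorted")
            prev_end = u.interval[1]

    @property
    def span(self) -> tuple[int, int] | None:
        if not self.units:
            return None
        return self.units[0].interval[0], self.units[-1].interval[1]


# ---------------------------------------------------------------------------
# boundary inference


def _agreement(s: np.ndarray, lo: int, hi: int, d: int) -> np.ndarray:
    """Per-position match vector between seq[x] and seq[x+d], x in [lo,hi)."""
    a = s[lo:hi]
    b = s[lo + d:hi + d]
    n_code = ord("N")
    return (a == b) & (a != n_code)


def _snap_ends(s: np.ndarray, ref: tuple[int, int], d: int,
               w: int = 10, min_id: float = 0.8) -> tuple[int, int] | None:
    """Trim an offset-d self-match to its sustained-identity core."""
    lo, hi = ref
    hi = min(hi, len(s) - d)
    if hi - lo < w:
        return None
    m = _agreement(s, lo, hi, d).astype(float)
    win = np.convolve(m, np.ones(w), mode="valid") / w
    good = np.flatnonzero(win >= min_id)
    if good.size == 0:
        return None
    new_lo = lo + int(good[0])
    new_hi = lo + int(good[-1]) + w
    return (new_lo, new_hi) if new_hi - new_lo >= w else None


def _cluster_positions(positions: list[int], tol: int) -> list[int]:
    """Single-linkage clustering on the line; representative = median
    (ties toward the earlier coordinate)."""
    if not positions:
        return []
    pos = sorted(positions)
    reps = []
    start = 0
    for k in range(1, len(pos) + 1):
        if k == len(pos) or pos[k] - pos[k - 1] > tol:
            group = pos[start:k]
            mid = group[(len(group) - 1) // 2]
            reps.append(mid)
            start = k
    return reps


def infer_repeat_units(
    seq: str,
    hits: list[DotplotHit] | None = None,
    alignments: list[LocalAlignment] | None = None,
    *,
    record_id: str = "",
    tol: int = 5,
    min_unit: int = 30,
    min_aln_len: int = 40,
    k: int = 25,
) -> RepeatAnnotation:
    """Delimit repeat units from self-comparison evidence.

    `hits` and `alignments` are computed from `seq` if not supplied.
    Returns an empty annotation when no repetitive region is found.
    """
    if alignments is None:
        alignments = kbest_self_alignments(seq, k=k)
    if hits is None:
        hits = self_dotplot(seq) if len(seq) >= 25 else []
    s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)

    # decompose each alignment into constant-offset diagonal runs and
    # snap every credible run to its sustained-identity core
    pairs: list[tuple[tuple[int, int], int]] = []  # (ref interval, offset)
    for a in alignments:
        # fall back to the whole-interval offset if the path is absent
        runs = a.runs or ((a.ref[0], a.qry[0],
                           min(a.ref[1] - a.ref[0], a.qry[1] - a.qry[0])),)
        for ri, rj, rl in runs:
            if rl < min_aln_len:
                continue
            d = rj - ri
            if d <= 0:
                continue
            snapped = _snap_ends(s, (ri, ri + rl), d)
            if snapped is not None and snapped[1] - snapped[0] >= min_aln_len:
                pairs.append((snapped, d))
    if not pairs:
        return RepeatAnnotation(record_id=record_id, units=())

    def endpoints() -> list[int]:
        out = []
        for (lo, hi), d in pairs:
            out.extend((lo, hi, lo + d, hi + d))
        return out

    bounds = set(endpoints())

    # propagate boundaries through each alignment's offset map
    for _ in range(3):
        added = set()
        for (lo, hi), d in pairs:
            for b in bounds:
                if lo + tol < b < hi - tol:
                    added.add(b + d)
                if lo + d + tol < b < hi + d - tol:
                    added.add(b - d)
        new = {b for b in added
               if all(abs(b - x) > tol for x in bounds)}
        if not new:
            break
        bounds |= new

    reps = _cluster_positions(sorted(bounds), tol)
    if len(reps) < 2:
        return RepeatAnnotation(record_id=record_id, units=())

    # consecutive boundaries delimit units; sub-minimum fragments are
    # absorbed into the following (or, at the array end, preceding) unit
    intervals: list[tuple[int, int]] = []
    cur_start: int | None = None
    for a_, b_ in zip(reps[:-1], reps[1:]):
        if cur_start is None:
            cur_start = a_
        if b_ - cur_start >= min_unit:
            intervals.append((cur_start, b_))
            cur_start = None
    if cur_start is not None and intervals:
        intervals[-1] = (intervals[-1][0], reps[-1])
    units = tuple(
        RepeatUnit(type_label="", interval=(lo, hi), copy_index=i + 1)
        for i, (lo, hi) in enumerate(intervals)
    )
    return RepeatAnnotation(record_id=record_id, units=units)


# ---------------------------------------------------------------------------
# family classification


def _levenshtein(a: str, b: str) -> int:
    """Banded-free edit distance, vectorized over rows."""
    pa = np.frombuffer(a.encode(), dtype=np.uint8)
    pb = np.frombuffer(b.encode(), dtype=np.uint8)
    idx = np.arange(len(pb) + 1, dtype=np.int32)
    prev = idx.copy()
    for i in range(1, len(pa) + 1):
        cur = np.empty_like(prev)
        cur[0] = i
        cur[1:] = np.minimum(prev[:-1] + (pb != pa[i - 1]), prev[1:] + 1)
        # in-row insertion dependency: cur[j] = min_k<=j (cur0[k] + j - k)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[-1])


def sequence_identity(a: str, b: str) -> float:
    """1 - edit distance / longer length; a cheap alignment-free identity."""
    if not a or not b:
        return 0.0
    return 1.0 - _levenshtein(a, b) / max(len(a), len(b))


def classify_repeats(
    annot: RepeatAnnotation,
    seq: str,
    identity_join: float = 0.70,
) -> RepeatAnnotation:
    """Assign family labels by single-linkage identity clustering.

    Clusters joined at pairwise identity >= `identity_join`; labels
    A, B, C, ... in order of first occurrence along the array; the
    partition does not depend on unit input order.
    """
    n = len(annot.units)
    if n == 0:
        return annot
    seqs = [seq[u.interval[0]:u.interval[1]] for u in annot.units]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sequence_identity(seqs[i], seqs[j]) >= identity_join:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    label_of_root: dict[int, str] = {}
    labels = []
    for r in roots:
        if r not in label_of_root:
            label_of_root[r] = chr(ord("A") + len(label_of_root))
        labels.append(label_of_root[r])
    counts: dict[str, int] = {}
    new_units = []
    for u, lab in zip(annot.units, labels):
        counts[lab] = counts.get(lab, 0) + 1
        new_units.append(replace(u, type_label=lab, copy_index=counts[lab]))
    return RepeatAnnotation(record_id=annot.record_id, units=tuple(new_units))


def dissect(seq: str, record_id: str = "", *, window: int = 25,
            threshold: int = 40, k: int = 25, min_score: int = 1,
            identity_join: float = 0.70, **kwargs) -> RepeatAnnotation:
    """Dot plot + k-best self-alignments + unit inference + classification."""
    hits = self_dotplot(seq, window=window, threshold=threshold) if len(seq) >= window else []
    alns = kbest_self_alignments(seq, k=k, min_score=min_score)
    annot = infer_repeat_units(seq, hits, alns, record_id=record_id, k=k, **kwargs)
    return classify_repeats(annot, seq, identity_join=identity_join)


# ---------------------------------------------------------------------------
# serialization


def annotation_to_json(annot: RepeatAnnotation) -> str:
    return json.dumps(
        {
            "record_id": annot.record_id,
            "units": [
                {"type": u.type_label, "start": u.interval[0],
                 "end": u.interval[1], "copy_index": u.copy_index}
                for u in annot.units
            ],
        },
        indent=2,
    )


def annotation_from_json(text: str) -> RepeatAnnotation:
    obj = json.loads(text)
    units = tuple(
        RepeatUnit(type_label=u["type"], interval=(u["start"], u["end"]),
                   copy_index=u["copy_index"])
        for u in obj["units"]
    )
    return RepeatAnnotation(record_id=obj["record_id"], units=units)


def annotation_to_bed(annot: RepeatAnnotation) -> str:
    lines = [
        f"{annot.record_id}\t{u.interval[0]}\t{u.interval[1]}\t{u.type_label}{u.copy_index}"
        for u in annot.units
    ]
    return "\n".join(lines) + ("\n" if lines else "")
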