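"""Consensus repeats and array condensation.

Because different IGS sequences carry different numbers and orders of
A/B/C repeats, their full-length sequences cannot be aligned
meaningfully across the array.  Each array is therefore condensed: all
copies of each repeat type within one IGS are aligned and collapsed to
a per-type consensus, and the array is replaced by one consensus copy
per type, in order of first occurrence.  The condensed sequence
N1 + consensus(A) + consensus(B) + ... + N2 is what enters the
multiple alignment and all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import Alignment, progressive_align
from .records import IGSRecord, partition_igs
from .repeats import RepeatAnnotation

__all__ = ["ConsensusRepeat", "repeat_consensus", "condense_igs"]


@dataclass(frozen=True)
class ConsensusRepeat:
    record_id: str
    type_label: str
    sequence: str
    n_copies: int


def repeat_consensus(copies: list[str], array_order: list[int] | None = None,
                     *, record_id: str = "", type_label: str = "") -> ConsensusRepeat:
    """Majority consensus of aligned repeat copies.

    Copies are aligned progressively; each column takes its majority
    base, with ties resolved to the base of the earliest copy in array
    order, and majority-gap columns dropped.
    """
    if not copies:
        raise ValueError("no repeat copies given")
    order = array_order if array_order is not None else list(range(len(copies)))
    if sorted(order) != list(range(len(copies))):
        raise ValueError("array_order must be a permutation of copy indices")
    if len(copies) == 1:
        return ConsensusRepeat(record_id, type_label, copies[0], 1)

    ranked = sorted(range(len(copies)), key=lambda i: order[i])
    aln = progressive_align([copies[i] for i in ranked])
    cols = np.array([list(r) for r in aln.rows])
    n = len(copies)
    out = []
    for c in range(cols.shape[1]):
        col = cols[:, c]
        n_gap = int((col == "-").sum())
        if n_gap > n / 2:
            continue
        bases, counts = np.unique(col[col != "-"], return_counts=True)
        top = counts.max()
        tied = set(bases[counts == top])
        # earliest copy in array order whose base is among the tied states
        for ch in col:
            if ch in tied:
                out.append(ch)
                break
    return ConsensusRepeat(record_id, type_label, "".join(out), n)


def condense_igs(rec: IGSRecord, annot: RepeatAnnotation) -> tuple[IGSRecord, dict]:
    """Replace the repeat array with one consensus copy per type.

    Returns the condensed record and a provenance map holding, for each
    region of the condensed sequence, its interval (0-based half-open)
    and the source unit intervals on the original record.
    """
    if not annot.units:
        raise ValueError(f"empty annotation for {rec.id!r}")
    part = partition_igs(rec, annot)
    n1 = rec.sequence[part.n1[0]:part.n1[1]]
    n2 = rec.sequence[part.n2[0]:part.n2[1]]

    type_order: list[str] = []
    copies: dict[str, list[tuple[int, tuple[int, int]]]] = {}
    for u in annot.units:
        if u.type_label not in copies:
            type_order.append(u.type_label)
            copies[u.type_label] = []
        copies[u.type_label].append((u.copy_index, u.interval))

    consensus_parts: list[str] = []
    provenance: dict = {"record_id": rec.id, "n1": (0, len(n1)), "types": {}}
    pos = len(n1)
    for t in type_order:
        seqs = [rec.sequence[lo:hi] for _, (lo, hi) in copies[t]]
        cons = repeat_consensus(seqs, record_id=rec.id, type_label=t)
        consensus_parts.append(cons.sequence)
        provenance["types"][t] = {
            "interval": (pos, pos + len(cons.sequence)),
            "n_copies": cons.n_copies,
            "source_units": [iv for _, iv in copies[t]],
        }
        pos += len(cons.sequence)
    provenance["n2"] = (pos, pos + len(n2))

    condensed = IGSRecord(
        id=rec.id, species=rec.species, individual=rec.individual,
        sequence=n1 + "".join(consensus_parts) + n2,
    )
    return condensed, provenance
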