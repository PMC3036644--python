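"""IGS sequence records, flank anchoring, and region partitioning.

The intergenic spacer (IGS) of the rDNA cistron lies between the 3' end of
the 28S rRNA gene and the 5' end of the 18S rRNA gene.  Each cloned rDNA
unit yields one IGS sequence, which is partitioned into three regions:

* ``N1`` — nonrepetitive, immediately downstream of the 28S gene;
* ``R``  — the repetitive midsection (interleaved A/B/C repeat arrays);
* ``N2`` — nonrepetitive, containing the ETS and core promoter, upstream
  of the 18S gene.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IGSRecord",
    "RegionPartition",
    "read_igs_fasta",
    "write_igs_fasta",
    "locate_flanking_genes",
    "partition_igs",
    "PRIMER_28S",
    "PRIMER_18S",
]

# Conserved PCR-primer regions at the 3' end of the 28S gene and the
# 5' end of the 18S gene; used as default anchors for flank location.
PRIMER_28S = "GTTTAGACCGTCGTGAGACAGGTTAG"
PRIMER_18S = "TCAGGCTCCCTCTCCGG"

_VALID = set("ACGTN")

# default header dialect: species|individual|id
_HEADER_RE = re.compile(r"^(?P<species>[^|\s]+)\|(?P<individual>[^|\s]+)\|(?P<id>\S+)$")


@dataclass(frozen=True)
class IGSRecord:
    """One complete IGS sequence from a cloned rDNA unit."""

    id: str
    species: str
    individual: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r} "
                "(allowed: A,C,G,T,N)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionPartition:
    """N1/R/N2 partition of one IGS; 0-based half-open intervals."""

    n1: tuple[int, int]
    r: tuple[int, int]
    n2: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.n1[0] == 0 and self.n1[1] == self.r[0] and self.r[1] == self.n2[0]):
            raise ValueError("regions must be contiguous: N1 < R < N2")
        for lo, hi in (self.n1, self.r, self.n2):
            if lo > hi:
                raise ValueError("interval start exceeds end")

    @property
    def length(self) -> int:
        return self.n2[1]


def _clean_seq(raw: str, rec_id: str) -> str:
    s = raw.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(
            f"record {rec_id!r}: non-IUPAC characters {sorted(bad)!r}"
        )
    return s


def read_igs_fasta(path, header_regex: re.Pattern | str | None = None) -> list[IGSRecord]:
    """Read IGS records from FASTA.

    Headers follow the ``species|individual|id`` dialect by default; an
    alternative regex with named groups ``species``, ``individual``, ``id``
    may be supplied for other defline styles.  Headers that do not match
    fall back to using the whole token as all three fields.
    """
    rx = _HEADER_RE if header_regex is None else (
        re.compile(header_regex) if isinstance(header_regex, str) else header_regex
    )
    records: list[IGSRecord] = []
    seen: set[str] = set()
    for sr in SeqIO.parse(str(path), "fasta"):
        m = rx.match(sr.description) or rx.match(sr.id)
        if m:
            species, individual, rid = m.group("species"), m.group("individual"), m.group("id")
        else:
            species = individual = rid = sr.id
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        records.append(
            IGSRecord(id=rid, species=species, individual=individual,
                      sequence=_clean_seq(str(sr.seq), rid))
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_igs_fasta(records: list[IGSRecord], path) -> None:
    """Write records in the ``species|individual|id`` header dialect."""
    out = [
        SeqRecord(Seq(r.sequence), id=f"{r.species}|{r.individual}|{r.id}", description="")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def _hamming_scan(seq: str, anchor: str) -> np.ndarray:
    """Mismatch count of `anchor` at every ungapped offset of `seq`.

    N counts as a mismatch on either side.
    """
    if len(anchor) > len(seq):
        return np.empty(0, dtype=np.int64)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    a = np.frombuffer(anchor.encode(), dtype=np.uint8)
    n_code = ord("N")
    m = len(anchor)
    n_pos = len(seq) - m + 1
    # sliding windows over seq
    win = np.lib.stride_tricks.sliding_window_view(s, m)
    match = (win == a) & (win != n_code) & (a != n_code)
    return m - match.sum(axis=1)


def locate_flanking_genes(
    rec: IGSRecord,
    anchor_28s: str = PRIMER_28S,
    anchor_18s: str = PRIMER_18S,
    max_mismatch: int = 3,
) -> tuple[int, int]:
    """Locate the flanking rRNA-gene termini by ungapped anchor scan.

    Returns ``(end_28s, start_18s)``: the 0-based position just past the
    28S terminus match, and the 0-based start of the 18S terminus match.
    The 28S anchor is expected near the sequence start (earliest best
    match wins), the 18S anchor near the end (latest best match wins).
    """
    for name, anchor in (("28S", anchor_28s), ("18S", anchor_18s)):
        if len(anchor) > rec.length:
            raise ValueError(f"{name} anchor longer than sequence {rec.id!r}")
    mm28 = _hamming_scan(rec.sequence, anchor_28s.upper())
    mm18 = _hamming_scan(rec.sequence, anchor_18s.upper())
    best28 = int(mm28.min())
    best18 = int(mm18.min())
    if best28 > max_mismatch:
        raise ValueError(
            f"28S anchor not found in {rec.id!r} within {max_mismatch} mismatches "
            f"(best has {best28})"
        )
    if best18 > max_mismatch:
        raise ValueError(
            f"18S anchor not found in {rec.id!r} within {max_mismatch} mismatches "
            f"(best has {best18})"
        )
    pos28 = int(np.flatnonzero(mm28 == best28)[0])
    pos18 = int(np.flatnonzero(mm18 == best18)[-1])
    return pos28 + len(anchor_28s), pos18


def partition_igs(rec: IGSRecord, annot) -> RegionPartition:
    """Partition a record into N1 / R / N2 from its repeat annotation.

    N1 runs from the start to the first repeat unit, R spans first repeat
    start to last repeat end, N2 runs to the end of the record.
    """
    units = list(annot.units)
    if not units:
        raise ValueError(f"no repeat array annotated for {rec.id!r}")
    if annot.record_id != rec.id:
        raise ValueError(
            f"annotation is for {annot.record_id!r}, not {rec.id!r}"
        )
    start = min(u.interval[0] for u in units)
    end = max(u.interval[1] for u in units)
    if end > rec.length:
        raise ValueError("annotation extends past end of record")
    return RegionPartition(n1=(0, start), r=(start, end), n2=(end, rec.length))


def partition_table(parts: dict[str, RegionPartition]):
    """Region table as a DataFrame with 1-based inclusive coordinates."""
    import pandas as pd

    rows = []
    for rid, p in parts.items():
        for name, (lo, hi) in (("N1", p.n1), ("R", p.r), ("N2", p.n2)):
            rows.append(
                {"id": rid, "region": name, "start_1based": lo + 1,
                 "end_1based": hi, "length": hi - lo}
            )
    return pd.DataFrame(rows)
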