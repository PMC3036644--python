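"""End-to-end orchestration of the IGS analysis stages.

Thin composition layer used by the analysis drivers, the CLI and the
acceptance checks: records -> repeat annotations -> condensed records
-> progressive alignment -> gap-event encoding -> distances / AMOVA /
breakpoint scan / gene-conversion screen.
"""

from __future__ import annotations

import numpy as np

from .condense import condense_igs
from .distance import pdistance_matrix
from .geneconv import fragment_pvalues, inner_fragments, polymorphic_projection
from .msa import Alignment, EncodedAlignment, encode_gap_events, progressive_align
from .records import IGSRecord
from .repeats import RepeatAnnotation, dissect
from .sim import SimTruth, truth_annotation

__all__ = [
    "dissect_records",
    "condense_records",
    "align_records",
    "align_and_encode",
    "region_column_spans",
    "detect_hybrid_transfer",
]


def dissect_records(records: list[IGSRecord], **kwargs) -> dict[str, RepeatAnnotation]:
    return {r.id: dissect(r.sequence, record_id=r.id, **kwargs) for r in records}


def condense_records(records: list[IGSRecord],
                     annots: dict[str, RepeatAnnotation]):
    condensed, provenances = [], {}
    for r in records:
        c, prov = condense_igs(r, annots[r.id])
        condensed.append(c)
        provenances[r.id] = prov
    return condensed, provenances


def align_records(records: list[IGSRecord]) -> Alignment:
    """Progressive alignment with ids canonicalized (sorted) first."""
    recs = sorted(records, key=lambda r: r.id)
    return progressive_align([r.sequence for r in recs], ids=[r.id for r in recs])


def align_and_encode(records: list[IGSRecord]) -> tuple[Alignment, EncodedAlignment]:
    aln = align_records(records)
    return aln, encode_gap_events(aln)


def _row_pos_to_col(row: str) -> np.ndarray:
    """Map ungapped position -> alignment column for one row."""
    return np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord("-"))


def region_column_spans(aln: Alignment, provenances: dict) -> dict[str, tuple[int, int]]:
    """Alignment-column span of each condensed region (N1, types, N2).

    A region's span is the per-row median of the columns holding that
    row's region (medians are robust to the occasional record whose
    automated dissection mis-places a boundary); regions are reported
    in condensed-sequence order.
    """
    spans: dict[str, tuple[int, int]] = {}
    prov0 = provenances[aln.ids[0]]
    names = ["n1", *prov0["types"].keys(), "n2"]
    for name in names:
        los, his = [], []
        for rid in aln.ids:
            prov = provenances[rid]
            if name not in ("n1", "n2") and name not in prov["types"]:
                continue
            iv = prov[name] if name in ("n1", "n2") else prov["types"][name]["interval"]
            cols = _row_pos_to_col(aln.row(rid))
            if iv[1] <= iv[0]:
                continue
            los.append(int(cols[iv[0]]))
            his.append(int(cols[iv[1] - 1]) + 1)
        if not los:
            continue
        spans[name.upper() if name in ("n1", "n2") else name] = (
            int(np.median(los)), int(np.median(his)))
    return spans


def detect_hybrid_transfer(records: list[IGSRecord], truth: SimTruth,
                           donor_species_leaves: list[str], recipient: str,
                           species_of, n_perm: int = 2000, seed: int = 0,
                           alpha: float = 0.05) -> float:
    """Fraction of a transferred N2 region flagged by the conversion screen.

    The complete IGS records are condensed with their true repeat
    annotations, aligned, and screened for inner fragments between the
    recipient and leaves of the donor species.  Detection needs the
    non-transferred background (N1 and the repeats) for contrast: the
    pair disagrees there but agrees across the transferred region, so
    the clustered agreement is permutation-significant.  Returns the
    fraction of N2 alignment columns covered by fragments significant
    at `alpha` after Bonferroni correction.
    """
    condensed, provenances = condense_records(
        records, {r.id: truth_annotation(truth, r.id) for r in records})
    aln, enc = align_and_encode(condensed)
    spans = region_column_spans(aln, provenances)
    n2_lo, n2_hi = spans["N2"]
    proj = polymorphic_projection(enc)
    if proj.n_sites == 0:
        return 0.0
    frags = inner_fragments(proj)
    pairset = {frozenset((recipient, d)) for d in donor_species_leaves}
    frags = [f for f in frags if frozenset((f.seq1, f.seq2)) in pairset]
    frags = fragment_pvalues(frags, proj, n_perm=n_perm, seed=seed)
    covered = np.zeros(enc.n_columns, dtype=bool)
    for f in frags:
        if f.global_p is not None and f.global_p < alpha:
            covered[f.aln_span[0]:f.aln_span[1] + 1] = True
    n2_cols = covered[n2_lo:n2_hi]
    return float(n2_cols.mean()) if n2_cols.size else 0.0
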