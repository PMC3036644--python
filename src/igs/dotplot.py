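"""Windowed self-comparison (dot plot) for locating repetitive regions.

A length-``window`` sliding window is scored at every pair of positions
(i, j), i < j, with match = +5 and mismatch = -4; pairs scoring at or
above ``threshold`` are reported.  With the defaults (window 25,
threshold 40) a hit requires at least 16 matching positions out of 25.
The main diagonal (j == i) is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DotplotHit", "self_dotplot", "offset_runs"]

MATCH = 5
MISMATCH = -4


@dataclass(frozen=True)
class DotplotHit:
    i: int
    j: int
    score: int


def self_dotplot(seq: str, window: int = 25, threshold: int = 40) -> list[DotplotHit]:
    """All upper-triangle window pairs of `seq` scoring >= `threshold`.

    Scores are computed per diagonal offset d = j - i with a sliding sum
    of per-position matches, so the cost is O(len(seq)^2 / window)
    vector operations.  N never matches anything, including N.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_code = ord("N")
    hits: list[DotplotHit] = []
    kernel = np.ones(window, dtype=np.int32)
    for d in range(1, n - window + 1):
        a, b = s[:-d], s[d:]
        match = ((a == b) & (a != n_code)).astype(np.int32)
        if len(match) < window:
            break
        wins = np.convolve(match, kernel, mode="valid")
        scores = MATCH * wins + MISMATCH * (window - wins)
        idx = np.flatnonzero(scores >= threshold)
        for i in idx:
            hits.append(DotplotHit(int(i), int(i) + d, int(scores[i])))
    return hits


def offset_runs(hits: list[DotplotHit], min_run: int = 1) -> dict[int, list[tuple[int, int]]]:
    """Group hits by diagonal offset into maximal runs of consecutive i.

    Returns offset -> list of (i_start, i_end) half-open runs, keeping
    runs of at least `min_run` windows.  Useful for summarizing the
    periodic structure of a repeat array.
    """
    by_offset: dict[int, list[int]] = {}
    for h in hits:
        by_offset.setdefault(h.j - h.i, []).append(h.i)
    runs: dict[int, list[tuple[int, int]]] = {}
    for d, positions in by_offset.items():
        positions.sort()
        out = []
        start = prev = positions[0]
        for p in positions[1:]:
            if p == prev + 1:
                prev = p
                continue
            if prev - start + 1 >= min_run:
                out.append((start, prev + 1))
            start = prev = p
        if prev - start + 1 >= min_run:
            out.append((start, prev + 1))
        if out:
            runs[d] = out
    return runs
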