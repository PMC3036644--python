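"""Gene-conversion detection from polymorphic-site fragments.

A gene-conversion tract copied between the ancestors of two sequences
leaves an unusually long stretch of polymorphic sites at which the two
sequences agree.  Working on the projection of the alignment onto its
polymorphic columns, the detector scores, for every sequence pair,
maximal runs of identical polymorphic sites ("inner" fragments), and,
for every single sequence, maximal runs of sites at which it differs
from all other rows ("outer" fragments, evidence of conversion from
outside the alignment or from a source later erased).

With the default mismatch penalty g = 0 a fragment may not contain a
mismatched site, so fragments are the maximal identical (or unique)
stretches; with g > 0 fragments are maximal-scoring segments with
score = matches - g * mismatches and no negative-scoring prefix or
suffix.  Significance comes from permuting polymorphic-site columns:
the permutation preserves each pair's number of agreements while
destroying their spatial clustering.  Reported p-values are the
per-pair permutation tail with the +1 correction, and a Bonferroni
global correction over ordered pairs (inner) or rows (outer).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .msa import EncodedAlignment

__all__ = [
    "PolymorphicProjection",
    "ConversionFragment",
    "polymorphic_projection",
    "inner_fragments",
    "outer_fragments",
    "fragment_pvalues",
]


@dataclass(frozen=True)
class PolymorphicProjection:
    """Alignment restricted to its polymorphic columns."""

    ids: tuple[str, ...]
    matrix: np.ndarray  # (n_rows, n_poly) int32, negatives missing
    columns: np.ndarray  # projection index -> alignment column

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ConversionFragment:
    kind: str  # "inner" | "outer"
    seq1: str
    seq2: str | None  # None for outer fragments
    proj_span: tuple[int, int]  # inclusive, polymorphic-site indices
    aln_span: tuple[int, int]  # inclusive, 0-based alignment columns
    score: float
    sim_p: float | None = None
    global_p: float | None = None


def polymorphic_projection(enc: EncodedAlignment) -> PolymorphicProjection:
    """Drop monomorphic and all-missing columns, keeping the coordinate map."""
    m = enc.matrix
    keep = []
    for c in range(m.shape[1]):
        obs = m[:, c][m[:, c] >= 0]
        if obs.size and np.unique(obs).size >= 2:
            keep.append(c)
    cols = np.array(keep, dtype=np.int64)
    return PolymorphicProjection(ids=tuple(enc.ids), matrix=m[:, cols].copy()
                                 if cols.size else m[:, :0].copy(), columns=cols)


def _runs_g0(informative: np.ndarray, barrier: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of informative sites not interrupted by barriers.

    Sites that are neither informative nor barriers (missing data) are
    transparent.  Returns (start, end inclusive, score) in site indices.
    """
    out = []
    start = None
    last = None
    count = 0
    for k in range(len(informative)):
        if informative[k]:
            if start is None:
                start = k
            last = k
            count += 1
        elif barrier[k]:
            if start is not None:
                out.append((start, last, count))
            start, last, count = None, None, 0
    if start is not None:
        out.append((start, last, count))
    return out


def _segments_penalized(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Disjoint maximal-scoring segments of a site score series.

    Greedy linear scan: a segment opens at a positive site, closes when
    the running score goes negative, and is trimmed to its best end, so
    no reported segment has a negative-scoring prefix or suffix.
    """
    out = []
    k = 0
    n = len(values)
    while k < n:
        if values[k] <= 0:
            k += 1
            continue
        start = k
        acc = 0.0
        best = 0.0
        best_end = k
        while k < n:
            acc += values[k]
            if acc > best:
                best = acc
                best_end = k
            if acc < 0:
                break
            k += 1
        out.append((start, best_end, best))
        k += 1
    return out


def _pair_fragments(a: np.ndarray, b: np.ndarray, g: float) -> list[tuple[int, int, float]]:
    obs = (a >= 0) & (b >= 0)
    agree = obs & (a == b)
    disagree = obs & (a != b)
    if g == 0:
        return _runs_g0(agree, disagree)
    values = np.where(agree, 1.0, np.where(disagree, -float(g), 0.0))
    return _segments_penalized(values)


def inner_fragments(proj: PolymorphicProjection, g: float = 0) -> list[ConversionFragment]:
    """Candidate conversion tracts between every pair of rows."""
    n = len(proj.ids)
    if n < 2:
        raise ValueError("need at least two rows")
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            for s, e, score in _pair_fragments(proj.matrix[i], proj.matrix[j], g):
                out.append(ConversionFragment(
                    kind="inner", seq1=proj.ids[i], seq2=proj.ids[j],
                    proj_span=(s, e),
                    aln_span=(int(proj.columns[s]), int(proj.columns[e])),
                    score=float(score),
                ))
    out.sort(key=lambda f: -f.score)
    return out


def _unique_states(matrix: np.ndarray) -> np.ndarray:
    """unique[r, k] is True when row r's state at site k is observed and
    shared with no other observed row."""
    n, S = matrix.shape
    unique = np.zeros((n, S), dtype=bool)
    for k in range(S):
        col = matrix[:, k]
        obs = col >= 0
        if obs.sum() < 2:
            continue
        vals, counts = np.unique(col[obs], return_counts=True)
        singles = set(vals[counts == 1])
        if singles:
            unique[:, k] = obs & np.isin(col, list(singles))
    return unique


def outer_fragments(proj: PolymorphicProjection, g: float = 0) -> list[ConversionFragment]:
    """Candidate conversion tracts from outside the alignment: per-row
    maximal runs of sites where the row differs from every other row."""
    n = len(proj.ids)
    if n < 3:
        raise ValueError("outer fragments need at least three rows")
    uniq = _unique_states(proj.matrix)
    out = []
    for r in range(n):
        obs = proj.matrix[r] >= 0
        informative = uniq[r]
        barrier = obs & ~uniq[r]
        if g == 0:
            frs = _runs_g0(informative, barrier)
        else:
            values = np.where(informative, 1.0, np.where(barrier, -float(g), 0.0))
            frs = _segments_penalized(values)
        for s, e, score in frs:
            out.append(ConversionFragment(
                kind="outer", seq1=proj.ids[r], seq2=None,
                proj_span=(s, e),
                aln_span=(int(proj.columns[s]), int(proj.columns[e])),
                score=float(score),
            ))
    out.sort(key=lambda f: -f.score)
    return out


# ---------------------------------------------------------------------------
# permutation significance


def _max_scores_null(values01: np.ndarray, perm_idx: np.ndarray, g: float) -> np.ndarray:
    """Null distribution of the best fragment score under column shuffles.

    `values01` holds +1 (informative), 0 (barrier), -1 (missing).
    """
    B = values01[perm_idx]  # (n_perm, S)
    inf_ = B == 1
    bar = B == 0
    c = inf_.cumsum(axis=1)
    if g == 0:
        z = np.where(bar, c, 0)
        running = np.maximum.accumulate(z, axis=1)
        return (c - running).max(axis=1)
    s = np.where(inf_, 1.0, np.where(bar, -float(g), 0.0))
    p = s.cumsum(axis=1)
    cummin = np.minimum.accumulate(np.hstack([np.zeros((p.shape[0], 1)), p[:, :-1]]), axis=1)
    return (p - cummin).max(axis=1)


def fragment_pvalues(
    fragments: list[ConversionFragment],
    proj: PolymorphicProjection,
    n_perm: int = 10000,
    seed: int = 0,
    g: float = 0,
) -> list[ConversionFragment]:
    """Attach permutation sim p-values and Bonferroni global p-values.

    sim p = (permutations whose best score for that pair/row >= the
    fragment's score, +1) / (n_perm + 1); global p multiplies by the
    number of ordered pairs (inner) or rows (outer), capped at 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    S = proj.n_sites
    if S == 0:
        return list(fragments)
    perm_idx = np.argsort(rng.random((n_perm, S)), axis=1)
    n = len(proj.ids)
    n_inner_tests = n * (n - 1)
    n_outer_tests = n
    null_cache: dict[tuple, np.ndarray] = {}
    uniq = None
    out = []
    for f in fragments:
        if f.kind == "inner":
            i, j = proj.ids.index(f.seq1), proj.ids.index(f.seq2)
            key = ("inner", min(i, j), max(i, j))
            if key not in null_cache:
                a, b = proj.matrix[i], proj.matrix[j]
                obs = (a >= 0) & (b >= 0)
                v = np.where(obs & (a == b), 1, np.where(obs, 0, -1)).astype(np.int8)
                null_cache[key] = _max_scores_null(v, perm_idx, g)
            mult = n_inner_tests
        else:
            r = proj.ids.index(f.seq1)
            key = ("outer", r)
            if key not in null_cache:
                if uniq is None:
                    uniq = _unique_states(proj.matrix)
                obs = proj.matrix[r] >= 0
                v = np.where(uniq[r], 1, np.where(obs, 0, -1)).astype(np.int8)
                null_cache[key] = _max_scores_null(v, perm_idx, g)
            mult = n_outer_tests
        null = null_cache[key]
        hits = int((null >= f.score - 1e-12).sum())
        sim_p = (hits + 1) / (n_perm + 1)
        out.append(_dc_replace(f, sim_p=sim_p, global_p=min(1.0, sim_p * mult)))
    return out
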