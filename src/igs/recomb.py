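"""Recombination breakpoint scanning by segment-wise phylogenetic fit.

Recombination leaves adjacent alignment segments supporting different
topologies.  The scan places 0..K_max breakpoints at variable sites
(breakpoints are only resolvable to the nearest variable site), fits an
NJ tree with JC69 branch lengths to every segment, and selects the
number and placement of breakpoints by the small-sample Akaike
information criterion (AICc).  Placement for each K is exact: a dynamic
program over candidate breakpoints maximizes the summed per-segment
log-likelihood.

The substitution model is JC69 with equal rates across sites; branch
lengths start from the NJ estimates and are refined by per-edge Newton
updates, which for JC have a closed per-site likelihood of the form
a + b*exp(-4t/3) so each edge update needs no extra tree traversals.
Missing data (gaps, N, gap-event symbols) are marginalized in the
standard pruning fashion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import pdistance_matrix
from .msa import EncodedAlignment
from .nj import TreeNode, build_nj

__all__ = [
    "SegmentFit",
    "BreakpointPartition",
    "candidate_breakpoints",
    "segment_fit",
    "breakpoint_search",
    "jc_alignment",
]

_TMIN, _TMAX = 1e-8, 10.0


def candidate_breakpoints(enc: EncodedAlignment) -> list[int]:
    """Columns with at least two distinct observed states.

    Gap-event symbols are ordinary states, so a column where a deletion
    opens in some rows is variable.
    """
    m = enc.matrix
    out = []
    for c in range(m.shape[1]):
        col = m[:, c]
        obs = col[col >= 0]
        if obs.size and np.unique(obs).size >= 2:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# JC69 likelihood on a tree


class _Phylo:
    """Flattened rooted view of an unrooted NJ tree for pruning."""

    def __init__(self, tree: TreeNode):
        self.children: list[list[int]] = []
        self.parent: list[int] = []
        self.blen: list[float] = []
        self.names: list[str | None] = []
        self._build(tree, -1, 0.0)
        self.postorder = self._postorder(0)

    def _build(self, node: TreeNode, parent: int, bl: float) -> int:
        idx = len(self.children)
        self.children.append([])
        self.parent.append(parent)
        self.blen.append(max(bl, _TMIN))
        self.names.append(node.name)
        for c, l in node.children:
            cidx = self._build(c, idx, l)
            self.children[idx].append(cidx)
        return idx

    def _postorder(self, root: int) -> list[int]:
        order, stack = [], [root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(self.children[n])
        return order[::-1]


def _jc_p(t: float) -> np.ndarray:
    e = np.exp(-4.0 * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def _leaf_partials(ph: _Phylo, m: np.ndarray, ids: list[str]) -> dict[int, np.ndarray]:
    """(L, 4) indicator partials; missing/ambiguous sites are all-ones."""
    L = m.shape[1]
    row_of = {rid: k for k, rid in enumerate(ids)}
    parts = {}
    for n, name in enumerate(ph.names):
        if name is None:
            continue
        col = m[row_of[name]]
        p = np.ones((L, 4))
        valid = (col >= 0) & (col < 4)
        p[valid] = 0.0
        p[valid, col[valid]] = 1.0
        parts[n] = p
    return parts


def _down_pass(ph: _Phylo, leafp: dict[int, np.ndarray], L: int):
    """Conditional likelihoods below each node, with per-site scaling."""
    down = [None] * len(ph.children)
    logscale = [np.zeros(L) for _ in ph.children]
    for n in ph.postorder:
        if not ph.children[n]:
            down[n] = leafp[n]
            continue
        acc = np.ones((L, 4))
        scale = np.zeros(L)
        for c in ph.children[n]:
            acc = acc * (down[c] @ _jc_p(ph.blen[c]))
            scale = scale + logscale[c]
        mx = acc.max(axis=1)
        mx[mx == 0] = 1.0
        acc = acc / mx[:, None]
        down[n] = acc
        logscale[n] = scale + np.log(mx)
    return down, logscale


def _loglik(ph: _Phylo, down, logscale, L: int) -> float:
    site = 0.25 * down[0].sum(axis=1)
    return float(np.log(site).sum() + logscale[0].sum())


def _optimize_edges(ph: _Phylo, m: np.ndarray, ids: list[str], sweeps: int = 2):
    """Per-edge Newton refinement of branch lengths under JC69."""
    L = m.shape[1]
    leafp = _leaf_partials(ph, m, ids)
    n_nodes = len(ph.children)
    for _ in range(sweeps):
        down, logscale = _down_pass(ph, leafp, L)
        # up partials: contribution from everything on the parent side
        up = [None] * n_nodes
        up[0] = np.ones((L, 4)) * 0.25
        for n in ph.postorder[::-1]:
            for c in ph.children[n]:
                acc = up[n].copy()
                for s in ph.children[n]:
                    if s != c:
                        acc = acc * (down[s] @ _jc_p(ph.blen[s]))
                mx = acc.max(axis=1)
                mx[mx == 0] = 1.0
                up[c] = acc / mx[:, None]
        for c in range(1, n_nodes):
            U, V = up[c], down[c]
            SU = U.sum(axis=1)
            SV = V.sum(axis=1)
            C = (U * V).sum(axis=1)
            a = SU * SV / 4.0
            b = C - SU * SV / 4.0
            # maximize sum log(a + b z) for z in (0, 1]
            z = np.exp(-4.0 * ph.blen[c] / 3.0)
            lo, hi = np.exp(-4.0 * _TMAX / 3.0), 1.0 - 1e-12
            for _ in range(12):
                denom = a + b * z
                denom[denom <= 0] = 1e-300
                g = (b / denom).sum()
                h = -(b * b / (denom * denom)).sum()
                if h >= 0:
                    break
                step = -g / h
                z = float(np.clip(z + step, lo, hi))
                if abs(step) < 1e-10:
                    break
            ph.blen[c] = float(np.clip(-0.75 * np.log(z), _TMIN, _TMAX))
    down, logscale = _down_pass(ph, leafp, L)
    return _loglik(ph, down, logscale, L)


@dataclass(frozen=True)
class SegmentFit:
    span: tuple[int, int]  # half-open column interval
    newick: str
    loglik: float
    n_params: int


def segment_fit(enc: EncodedAlignment, span: tuple[int, int] | None = None,
                sweeps: int = 2) -> SegmentFit:
    """NJ topology + JC69 branch lengths + log-likelihood for one slice."""
    sl = enc if span is None else enc.slice(*span)
    span = span or (0, enc.n_columns)
    m = sl.matrix
    if m.shape[0] < 3:
        raise ValueError("segment fit needs at least 3 rows")
    if m.shape[1] < 1:
        raise ValueError("empty segment")
    if (m < 0).all():
        raise ValueError("segment has no observed data")
    dm = pdistance_matrix(sl)
    vals = dm.values.copy()
    vals[np.isnan(vals)] = 0.0
    dm.values = vals
    tree = build_nj(dm)
    ph = _Phylo(tree)
    ll = _optimize_edges(ph, m, list(sl.ids), sweeps=sweeps)
    n = m.shape[0]
    fitted = _to_newick(ph)
    return SegmentFit(span=span, newick=fitted, loglik=ll, n_params=2 * n - 3)


def _to_newick(ph: _Phylo) -> str:
    def rec(n: int) -> str:
        if not ph.children[n]:
            return str(ph.names[n])
        inner = ",".join(f"{rec(c)}:{ph.blen[c]:.6f}" for c in ph.children[n])
        return f"({inner})"

    return rec(0) + ";"


# ---------------------------------------------------------------------------
# breakpoint search


@dataclass(frozen=True)
class BreakpointPartition:
    breakpoints: tuple[int, ...]  # alignment columns (variable sites)
    segments: tuple[SegmentFit, ...]
    k: int
    aicc: float
    aicc_by_k: dict[int, float]
    loglik_by_k: dict[int, float]  # DP optimum of summed segment loglik
    breakpoints_by_k: dict[int, tuple[int, ...]]


def _aicc(loglik: float, k_params: int, n_obs: int) -> float:
    aic = 2.0 * k_params - 2.0 * loglik
    denom = n_obs - k_params - 1
    if denom <= 0:
        return float("inf")
    return aic + 2.0 * k_params * (k_params + 1) / denom


def breakpoint_search(
    enc: EncodedAlignment,
    k_max: int = 5,
    min_segment: int = 50,
    stride: int = 1,
    sweeps: int = 2,
) -> BreakpointPartition:
    """Exact DP placement of 0..k_max breakpoints, chosen by AICc.

    Breakpoints sit at variable sites (every `stride`-th candidate is
    considered); each segment must contain at least `min_segment`
    variable sites.  Model parameters are the per-segment branch
    lengths plus one parameter per breakpoint; per-segment AICc uses
    the segment's column count as sample size.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    cands = candidate_breakpoints(enc)
    L = enc.n_columns
    points = cands[::stride] if stride > 1 else list(cands)
    n_var_before = {}
    cnt = 0
    ci = 0
    for c in points:
        while ci < len(cands) and cands[ci] < c:
            cnt += 1
            ci += 1
        n_var_before[c] = cnt
    total_var = len(cands)

    # boundaries: 0, candidate columns..., L
    bounds = [0] + points + [L]
    var_at = {0: 0, L: total_var}
    var_at.update(n_var_before)

    cache: dict[tuple[int, int], SegmentFit] = {}

    def fit(lo: int, hi: int) -> SegmentFit:
        key = (lo, hi)
        if key not in cache:
            cache[key] = segment_fit(enc, (lo, hi), sweeps=sweeps)
        return cache[key]

    def ok(lo: int, hi: int) -> bool:
        return var_at[hi] - var_at[lo] >= min_segment

    nb = len(bounds)
    # best[k][j]: max summed loglik over segments covering bounds[0..j]
    # using exactly k breakpoints, ending a segment at bounds[j]
    best = [[-np.inf] * nb for _ in range(k_max + 1)]
    back = [[-1] * nb for _ in range(k_max + 1)]
    for j in range(1, nb):
        if ok(bounds[0], bounds[j]):
            best[0][j] = fit(bounds[0], bounds[j]).loglik
    for k in range(1, k_max + 1):
        for j in range(1, nb):
            b_hi = bounds[j]
            cur = -np.inf
            arg = -1
            for i in range(1, j):
                if best[k - 1][i] == -np.inf or not ok(bounds[i], b_hi):
                    continue
                val = best[k - 1][i] + fit(bounds[i], b_hi).loglik
                if val > cur:
                    cur = val
                    arg = i
            best[k][j] = cur
            back[k][j] = arg

    aicc_by_k: dict[int, float] = {}
    loglik_by_k: dict[int, float] = {}
    partitions: dict[int, list[tuple[int, int]]] = {}
    for k in range(0, k_max + 1):
        if best[k][nb - 1] == -np.inf:
            continue
        # recover segmentation
        segs = []
        j = nb - 1
        kk = k
        while kk > 0:
            i = back[kk][j]
            segs.append((bounds[i], bounds[j]))
            j = i
            kk -= 1
        segs.append((bounds[0], bounds[j]))
        segs.reverse()
        total = 0.0
        for lo, hi in segs:
            f = fit(lo, hi)
            total += _aicc(f.loglik, f.n_params, hi - lo)
        total += 2.0 * k
        aicc_by_k[k] = total
        loglik_by_k[k] = float(best[k][nb - 1])
        partitions[k] = segs
    if not aicc_by_k:
        raise ValueError(
            "no admissible segmentation: fewer variable sites than min_segment"
        )
    k_best = min(aicc_by_k, key=lambda k: (aicc_by_k[k], k))
    segs = partitions[k_best]
    fits = tuple(fit(lo, hi) for lo, hi in segs)
    bps = tuple(lo for lo, _ in segs[1:])
    return BreakpointPartition(
        breakpoints=bps, segments=fits, k=k_best,
        aicc=aicc_by_k[k_best], aicc_by_k=aicc_by_k,
        loglik_by_k=loglik_by_k,
        breakpoints_by_k={k: tuple(lo for lo, _ in p[1:])
                          for k, p in partitions.items()})


# ---------------------------------------------------------------------------
# JC simulation on a tree (testing / calibration utility)


def jc_alignment(tree: TreeNode, n_cols: int, seed: int = 0) -> EncodedAlignment:
    """Simulate a JC69 alignment of `n_cols` sites down a TreeNode tree."""
    rng = np.random.default_rng(seed)
    ph = _Phylo(tree)
    states = {0: rng.integers(0, 4, size=n_cols)}
    order = ph.postorder[::-1]  # root first
    for n in order:
        for c in ph.children[n]:
            t = ph.blen[c]
            p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            s = states[n].copy()
            flip = rng.random(n_cols) < p_change
            # a change goes to one of the three other states uniformly
            s[flip] = (s[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4
            states[c] = s
    ids, rows = [], []
    for n, name in enumerate(ph.names):
        if name is not None:
            ids.append(name)
            rows.append(states[n].astype(np.int32))
    return EncodedAlignment(ids=ids, matrix=np.vstack(rows), event_columns=())
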