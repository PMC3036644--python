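"""Analysis of molecular variance (AMOVA) from pairwise distances.

Genetic variance is partitioned hierarchically from pairwise squared
distances (here: difference counts on the gap-encoded condensed
alignment), following the classical sum-of-squared-deviations
decomposition: the total SS computed from all pairs equals the sum of
the SS within and among groups, variance components follow by the
method of moments, and significance comes from random permutation of
sequences (or individuals) across the hierarchy.  Negative variance
components are reported as estimated, not truncated.

Supported designs: two-level (among species / within species) and
three-level (among species / among individuals within species /
within individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix

__all__ = ["AMOVALevel", "AMOVAResult", "amova", "permutation_test"]


@dataclass(frozen=True)
class AMOVALevel:
    source: str
    df: int
    ss: float
    variance: float
    percent: float


@dataclass
class AMOVAResult:
    levels: list[AMOVALevel]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)

    @property
    def total_ss(self) -> float:
        return sum(l.ss for l in self.levels)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"source": l.source, "df": l.df, "ss": l.ss,
             "variance": l.variance, "percent": l.percent,
             "p": self.p_values.get(l.source, float("nan"))}
            for l in self.levels
        ]
        return pd.DataFrame(rows)


def _pair_ss(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations of a group from its centroid:
    (1/n) * sum of pairwise squared distances."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def _components_2level(d2: np.ndarray, groups: list[np.ndarray]):
    N = sum(len(g) for g in groups)
    a = len(groups)
    ss_t = float(d2.sum() / (2 * N))
    ss_w = sum(_pair_ss(d2, g) for g in groups)
    ss_a = ss_t - ss_w
    df_a, df_w = a - 1, N - a
    if df_a == 0 or df_w == 0:
        raise ValueError("zero degrees of freedom at one level")
    ms_a, ms_w = ss_a / df_a, ss_w / df_w
    n_prime = (N - sum(len(g) ** 2 for g in groups) / N) / df_a
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_prime
    return ss_a, ss_w, df_a, df_w, sigma_a, sigma_w


def _components_3level(d2: np.ndarray, species: list[list[np.ndarray]]):
    """`species` is a nested list: per species, per individual, indices."""
    all_idx = np.concatenate([i for s in species for i in s])
    N = len(all_idx)
    a = len(species)
    b = sum(len(s) for s in species)
    ss_t = float(d2[np.ix_(all_idx, all_idx)].sum() / (2 * N))
    ss_wi = sum(_pair_ss(d2, ind) for s in species for ind in s)
    ss_ws = sum(_pair_ss(d2, np.concatenate(s)) for s in species)
    ss_ai = ss_ws - ss_wi
    ss_as = ss_t - ss_ws
    df_as, df_ai, df_wi = a - 1, b - a, N - b
    if 0 in (df_as, df_ai, df_wi):
        raise ValueError("zero degrees of freedom at one level")
    ms_as, ms_ai, ms_wi = ss_as / df_as, ss_ai / df_ai, ss_wi / df_wi
    n_s = [sum(len(i) for i in s) for s in species]
    sq_si = [sum(len(i) ** 2 for i in s) for s in species]
    n1 = (N - sum(q / n for q, n in zip(sq_si, n_s))) / df_ai
    n2 = (sum(q / n for q, n in zip(sq_si, n_s)) - sum(sq_si) / N) / df_as
    n3 = (N - sum(n ** 2 for n in n_s) / N) / df_as
    sigma_c = ms_wi
    sigma_b = (ms_ai - sigma_c) / n1
    sigma_a = (ms_as - sigma_c - n2 * sigma_b) / n3
    return (ss_as, ss_ai, ss_wi, df_as, df_ai, df_wi, sigma_a, sigma_b, sigma_c)


def _percents(*sigmas: float) -> list[float]:
    tot = sum(sigmas)
    if tot == 0:
        return [0.0 for _ in sigmas]
    return [100.0 * s / tot for s in sigmas]


def _structure_arrays(dm: DistanceMatrix, structure: dict):
    vals = list(structure.values())
    three = isinstance(vals[0], (tuple, list))
    idx_of = {lab: k for k, lab in enumerate(dm.ids)}
    if not three:
        by_sp: dict[str, list[int]] = {}
        for lab in dm.ids:
            by_sp.setdefault(structure[lab], []).append(idx_of[lab])
        return False, [np.array(v) for v in by_sp.values()]
    by_sp_ind: dict[str, dict[str, list[int]]] = {}
    for lab in dm.ids:
        sp, ind = structure[lab]
        by_sp_ind.setdefault(sp, {}).setdefault(ind, []).append(idx_of[lab])
    nested = [[np.array(v) for v in inds.values()] for inds in by_sp_ind.values()]
    return True, nested


def amova(dm: DistanceMatrix, structure: dict) -> AMOVAResult:
    """AMOVA from a squared-distance matrix and a label->group map.

    `structure` maps each label to a species (two-level design) or to a
    (species, individual) pair (three-level design).
    """
    if set(structure) != set(dm.ids):
        raise ValueError("structure labels do not match matrix labels")
    d2 = dm.values
    three, groups = _structure_arrays(dm, structure)
    if not three:
        ss_a, ss_w, df_a, df_w, sig_a, sig_w = _components_2level(d2, groups)
        pct = _percents(sig_a, sig_w)
        levels = [
            AMOVALevel("among_species", df_a, ss_a, sig_a, pct[0]),
            AMOVALevel("within_species", df_w, ss_w, sig_w, pct[1]),
        ]
        tot = sig_a + sig_w
        phi = {"Phi_ST": sig_a / tot if tot != 0 else 0.0}
        return AMOVAResult(levels=levels, phi=phi)
    (ss_as, ss_ai, ss_wi, df_as, df_ai, df_wi,
     sig_a, sig_b, sig_c) = _components_3level(d2, groups)
    pct = _percents(sig_a, sig_b, sig_c)
    levels = [
        AMOVALevel("among_species", df_as, ss_as, sig_a, pct[0]),
        AMOVALevel("among_individuals", df_ai, ss_ai, sig_b, pct[1]),
        AMOVALevel("within_individuals", df_wi, ss_wi, sig_c, pct[2]),
    ]
    tot = sig_a + sig_b + sig_c
    phi = {
        "Phi_ST": (sig_a + sig_b) / tot if tot != 0 else 0.0,
        "Phi_SC": sig_b / (sig_b + sig_c) if (sig_b + sig_c) != 0 else 0.0,
        "Phi_CT": sig_a / tot if tot != 0 else 0.0,
    }
    return AMOVAResult(levels=levels, phi=phi)


def permutation_test(dm: DistanceMatrix, structure: dict,
                     n_perm: int = 1023, seed: int = 0) -> dict[str, float]:
    """Permutation p-values with the +1 correction p = (b+1)/(n_perm+1).

    Two-level: sequences are permuted among species and the among-species
    component is recomputed.  Three-level: whole individuals are permuted
    among species (among-species p) and sequences are permuted among
    individuals within species (among-individuals p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    d2 = dm.values
    three, groups = _structure_arrays(dm, structure)
    out: dict[str, float] = {}
    if not three:
        sizes = [len(g) for g in groups]
        obs = _components_2level(d2, groups)[4]
        all_idx = np.concatenate(groups)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(all_idx)
            newg, pos = [], 0
            for s in sizes:
                newg.append(perm[pos:pos + s])
                pos += s
            if _components_2level(d2, newg)[4] >= obs - 1e-12:
                hits += 1
        out["among_species"] = (hits + 1) / (n_perm + 1)
        return out

    comp = _components_3level(d2, groups)
    obs_a, obs_b = comp[6], comp[7]
    # among species: permute whole individuals across species
    inds = [ind for s in groups for ind in s]
    sp_sizes = [len(s) for s in groups]
    hits_a = 0
    for _ in range(n_perm):
        order = rng.permutation(len(inds))
        newsp, pos = [], 0
        for s in sp_sizes:
            newsp.append([inds[k] for k in order[pos:pos + s]])
            pos += s
        if _components_3level(d2, newsp)[6] >= obs_a - 1e-12:
            hits_a += 1
    out["among_species"] = (hits_a + 1) / (n_perm + 1)
    # among individuals within species: reshuffle sequences among
    # individuals inside each species
    hits_b = 0
    for _ in range(n_perm):
        newsp = []
        for s in groups:
            seqs = np.concatenate(s)
            perm = rng.permutation(seqs)
            newinds, pos = [], 0
            for ind in s:
                newinds.append(perm[pos:pos + len(ind)])
                pos += len(ind)
            newsp.append(newinds)
        if _components_3level(d2, newsp)[7] >= obs_b - 1e-12:
            hits_b += 1
    out["among_individuals"] = (hits_b + 1) / (n_perm + 1)
    return out
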