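"""Divergence summaries: within/between clusters and per-segment
intra-/interspecific means.

Two summary shapes are produced.  For repeat copies, pairwise
p-distances are averaged within and between clusters (clusters usually
being NJ-tree groups of array positions).  For alignment segments, the
overall mean (OAM), mean intraspecific (MIA, x), and mean interspecific
(MIR, y) p-distances are reported with the ratio x/y; under concerted
evolution x/y falls below one and decreases with divergence time, while
a ratio pinned near one indicates shared constraint rather than
homogenization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix, pdistance_matrix

__all__ = [
    "ClusterDivergence",
    "DivergenceSummary",
    "cluster_divergence",
    "segment_divergence_profile",
    "divergence_summary",
    "pdistance_ratio",
]


@dataclass(frozen=True)
class ClusterDivergence:
    within_mean: float  # NaN when no intra-cluster pair exists
    between_mean: float  # NaN when no inter-cluster pair exists
    within_range: tuple[float, float] | None
    between_range: tuple[float, float] | None


@dataclass(frozen=True)
class DivergenceSummary:
    """OAM / MIA (x) / MIR (y) p-distances for one alignment segment."""

    segment: tuple[int, int]
    oam: float
    mia: float
    mir: float
    se_oam: float
    n_pairs: int

    @property
    def ratio(self) -> float:
        """MIA/MIR, NaN when MIR is undefined or zero."""
        if not np.isfinite(self.mir) or self.mir == 0:
            return float("nan")
        return self.mia / self.mir

    @property
    def ratio_3dp(self) -> float:
        return pdistance_ratio(self.mia, self.mir)


def pdistance_ratio(x: float, y: float) -> float:
    """Intra/inter p-distance ratio as reported: x/y to 3 decimals."""
    if not np.isfinite(y) or y == 0:
        return float("nan")
    return round(x / y, 3)


def cluster_divergence(dm: DistanceMatrix, clusters: list[set[str]]) -> ClusterDivergence:
    """Mean p-distance within and between clusters of labels.

    `clusters` must partition dm's labels.  Singleton clusters
    contribute no within-cluster pair.
    """
    flat = [l for c in clusters for l in c]
    if sorted(flat) != sorted(dm.ids):
        raise ValueError("clusters do not partition the labels")
    of = {lab: k for k, c in enumerate(clusters) for lab in c}
    within, between = [], []
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            v = dm.values[i, j]
            if np.isnan(v):
                continue
            (within if of[dm.ids[i]] == of[dm.ids[j]] else between).append(v)
    return ClusterDivergence(
        within_mean=float(np.mean(within)) if within else float("nan"),
        between_mean=float(np.mean(between)) if between else float("nan"),
        within_range=(min(within), max(within)) if within else None,
        between_range=(min(between), max(between)) if between else None,
    )


def divergence_summary(dm: DistanceMatrix, species_map: dict[str, str],
                       segment: tuple[int, int] = (0, 0)) -> DivergenceSummary:
    """OAM/MIA/MIR from a distance matrix and a label->species map."""
    intra, inter, allp, weights = [], [], [], []
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            v = dm.values[i, j]
            if np.isnan(v):
                continue
            allp.append(v)
            weights.append(dm.counts[i, j])
            if species_map[dm.ids[i]] == species_map[dm.ids[j]]:
                intra.append(v)
            else:
                inter.append(v)
    oam = float(np.mean(allp)) if allp else float("nan")
    # analytical binomial SE on the pooled proportion
    mean_sites = float(np.mean(weights)) if weights else 0.0
    se = float(np.sqrt(oam * (1 - oam) / mean_sites)) if mean_sites > 0 and 0 <= oam <= 1 else float("nan")
    return DivergenceSummary(
        segment=segment,
        oam=oam,
        mia=float(np.mean(intra)) if intra else float("nan"),
        mir=float(np.mean(inter)) if inter else float("nan"),
        se_oam=se,
        n_pairs=len(allp),
    )


def segment_divergence_profile(enc, species_map: dict[str, str],
                               segments: list[tuple[int, int]]) -> list[DivergenceSummary]:
    """Per-segment OAM/MIA/MIR profile over an encoded alignment.

    p-distances are recomputed on each column slice; species with a
    single sequence contribute only to MIR.  At least two species must
    be present for MIR to be defined.
    """
    if len(set(species_map[i] for i in enc.ids)) < 2:
        raise ValueError("need sequences from at least two species")
    out = []
    for lo, hi in segments:
        if not (0 <= lo < hi <= enc.n_columns):
            raise ValueError(f"segment ({lo}, {hi}) out of bounds")
        dm = pdistance_matrix(enc.slice(lo, hi))
        out.append(divergence_summary(dm, species_map, segment=(lo, hi)))
    return out
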