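"""Uncorrected p-distances with pairwise deletion of missing data.

p = (number of differing sites) / (number of compared sites), where a
site is compared for a pair only if both rows carry an observed state
there.  Gap-event symbols introduced by the indel encoding are ordinary
states: two rows sharing the same event symbol match, an event symbol
against a base is a difference.  Interior gap positions and N are
missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistanceMatrix", "pdistance_matrix", "difference_matrix"]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise values with compared-site counts.

    ``values[i, j]`` is NaN where no site could be compared.
    """

    ids: list[str]
    values: np.ndarray
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match label count")
        with np.errstate(invalid="ignore"):
            if not np.allclose(v, v.T, equal_nan=True):
                raise ValueError("matrix is not symmetric")
        self.values = v
        if self.counts is None:
            self.counts = np.ones_like(v, dtype=np.int64)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_complete(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return not np.isnan(self.values[off]).any()

    def to_phylip(self) -> str:
        lines = [f"{self.n}"]
        for i, lab in enumerate(self.ids):
            vals = " ".join(f"{v:.6f}" for v in np.nan_to_num(self.values[i]))
            lines.append(f"{lab:<12}{vals}")
        return "\n".join(lines) + "\n"


def _pair_stats(matrix: np.ndarray):
    """(differences, compared-site counts) for all row pairs.

    `matrix` is integer-coded with negative values meaning missing.
    """
    n = matrix.shape[0]
    diffs = np.zeros((n, n), dtype=np.int64)
    comps = np.zeros((n, n), dtype=np.int64)
    obs = matrix >= 0
    for i in range(n):
        both = obs[i] & obs[i + 1:]
        ne = (matrix[i] != matrix[i + 1:]) & both
        d = ne.sum(axis=1)
        c = both.sum(axis=1)
        diffs[i, i + 1:] = d
        diffs[i + 1:, i] = d
        comps[i, i + 1:] = c
        comps[i + 1:, i] = c
    np.fill_diagonal(comps, matrix.shape[1])
    return diffs, comps


def pdistance_matrix(enc) -> DistanceMatrix:
    """p-distance matrix from an encoded alignment (pairwise deletion).

    `enc` provides ``ids`` and an integer ``matrix`` with negative
    codes for missing data (see :mod:`igs.msa`).
    """
    m = np.asarray(enc.matrix)
    if m.shape[0] < 2:
        raise ValueError("need at least two rows")
    diffs, comps = _pair_stats(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(comps > 0, diffs / np.maximum(comps, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids=list(enc.ids), values=values, counts=comps)


def difference_matrix(enc) -> DistanceMatrix:
    """Pairwise difference counts (the AMOVA squared-distance input)."""
    m = np.asarray(enc.matrix)
    diffs, comps = _pair_stats(m)
    return DistanceMatrix(ids=list(enc.ids), values=diffs.astype(float), counts=comps)
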