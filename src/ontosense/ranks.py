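"""Rank-order stability of phenotypes across ontogeny.

A population developing under the same policy is ranked at every time
point -- birth (all counters zero) through maturity -- by its count of
specializations towards ``P1`` (the ``y1`` counter).  Ranking is dense:
organisms sharing a trait value share a rank, and ranks are consecutive
integers.  The proportion of organisms whose rank differs between two
time points measures (the inverse of) trait repeatability; its decline
across ontogeny indicates stabilizing individual differences.

Cross-period comparisons label ranks from the top (rank 1 = most
specialized).  The direction matters: when the population piles up at
the maximum trait value -- the typical outcome with the environment
fixed to ``E1`` -- top-anchored labels keep that stable majority's rank
constant, whereas bottom-anchored labels would relabel it every time a
new distinct value appears below, flooding the measure with spurious
switches.  The complementary caveat (instability when the population
piles at zero) is the price of the convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Population

__all__ = [
    "RankSwitchMatrix",
    "rank_population",
    "rank_switch_matrix",
    "consecutive_switch_series",
]


def rank_population(phenotype_values) -> np.ndarray:
    """Dense ranks (1 = lowest value) of a vector of trait values.

    Equal values share a rank and ranks are consecutive integers.
    """
    values = np.asarray(phenotype_values)
    if values.size == 0:
        raise ValueError("cannot rank an empty population")
    if values.ndim != 1:
        raise ValueError("expected a 1-D vector of trait values")
    _, inverse = np.unique(values, return_inverse=True)
    return inverse + 1


@dataclass(frozen=True)
class RankSwitchMatrix:
    """``(T+1) x (T+1)`` table of rank-switch proportions.

    Entry ``(i, j)`` is the fraction of the population whose dense rank
    on ``y1`` differs between time points ``i`` and ``j`` (time point 0
    is birth, where every organism shares one rank).  The matrix is
    symmetric with a zero diagonal; the superdiagonal gives one
    switch proportion per ontogenetic period.
    """

    matrix: np.ndarray
    n: int

    @property
    def T(self) -> int:
        return self.matrix.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        points = np.arange(self.T + 1)
        return pd.DataFrame(self.matrix, index=points, columns=points)

    def to_csv(self, path, config_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if config_comment:
                fh.write(f"# {config_comment}\n")
            self.to_frame().to_csv(fh, index_label="time_point")


def rank_switch_matrix(population: Population | np.ndarray) -> RankSwitchMatrix:
    """Rank-switch proportions between every pair of time points.

    Accepts a :class:`~ontosense.simulate.Population` or a raw ``(n, T)``
    matrix of per-period ``y1`` values; a zero column for the natal time
    point is prepended internally.
    """
    y1 = population.y1 if isinstance(population, Population) else np.asarray(population)
    if y1.ndim != 2:
        raise ValueError("expected an (n, T) matrix of y1 values")
    n, T = y1.shape
    full = np.concatenate([np.zeros((n, 1), dtype=y1.dtype), y1], axis=1)
    ranks = np.empty((n, T + 1), dtype=np.int64)
    for t in range(T + 1):
        u, inverse = np.unique(full[:, t], return_inverse=True)
        ranks[:, t] = u.size - inverse  # top-anchored: highest y1 -> rank 1
    out = np.zeros((T + 1, T + 1))
    for i in range(T + 1):
        for j in range(i + 1, T + 1):
            prop = float(np.mean(ranks[:, i] != ranks[:, j]))
            out[i, j] = out[j, i] = prop
    return RankSwitchMatrix(matrix=out, n=n)


def consecutive_switch_series(matrix: RankSwitchMatrix) -> np.ndarray:
    """Switch proportions between consecutive time points (the
    superdiagonal): one value per period, the first covering the
    transition from birth into period 1."""
    return np.diagonal(matrix.matrix, offset=1).copy()
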