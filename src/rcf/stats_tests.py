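"""Friedman omnibus test and Nemenyi post-hoc analysis for comparing k
scoring methods over N testing cases.

Given per-case ranks r_i^j (1 = best) and average ranks R_j, the Friedman
statistic is

    chi2_F = 12 N / (k (k+1)) * ( sum_j R_j^2  -  k (k+1)^2 / 4 ),

and the less conservative F-form (Iman–Davenport)

    F_F = (N - 1) chi2_F / ( N (k - 1) - chi2_F ),

distributed as F(k-1, (k-1)(N-1)) under the null of equivalent methods.
When the omnibus null is rejected, the Nemenyi critical difference

    CD = q_alpha * sqrt( k (k+1) / (6 N) )

declares two methods different when their average ranks differ by more than
CD; q_alpha is the Studentized-range upper quantile for k groups at infinite
degrees of freedom, divided by sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankTable",
    "rank_table_from_scores",
    "average_ranks",
    "friedman_chi2",
    "friedman_F",
    "f_critical",
    "q_alpha",
    "nemenyi_cd",
    "nemenyi_matrix",
]

#: Studentized-range-based q_alpha table (infinite df, already divided by
#: sqrt(2)) for k = 2..10 methods, as conventionally tabulated for the
#: Nemenyi test.  Authoritative for matching published critical differences;
#: ``q_alpha(..., source="distribution")`` recomputes the same values from
#: the Studentized-range quantile function.
_Q_TABLE = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclass(frozen=True)
class RankTable:
    """N×k matrix of per-case method ranks (1 = best; ties fractional)."""

    ranks: np.ndarray

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks, dtype=float)
        if ranks.ndim != 2 or ranks.shape[0] < 1 or ranks.shape[1] < 2:
            raise ValueError("rank table must be N x k with k >= 2")
        object.__setattr__(self, "ranks", ranks)
        k = ranks.shape[1]
        expected = k * (k + 1) / 2
        if not np.allclose(ranks.sum(axis=1), expected):
            raise ValueError(f"each row of ranks must sum to k(k+1)/2 = {expected}")
        if ranks.min() < 1 or ranks.max() > k:
            raise ValueError("ranks must lie in [1, k]")

    @property
    def n_cases(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_methods(self) -> int:
        return self.ranks.shape[1]


def rank_table_from_scores(performance: np.ndarray,
                           higher_is_better: bool = True) -> RankTable:
    """Rank methods (columns) within each case (row) of a performance matrix.

    Ties receive average (fractional) ranks, the standard Friedman
    convention.
    """
    perf = np.asarray(performance, dtype=float)
    signed = -perf if higher_is_better else perf
    ranks = np.apply_along_axis(sps.rankdata, 1, signed)
    return RankTable(ranks)


def average_ranks(table: RankTable) -> np.ndarray:
    """Average rank R_j of each method across cases."""
    return table.ranks.mean(axis=0)


def friedman_chi2(R: np.ndarray, k: int, N: int) -> float:
    """Friedman chi-square statistic from average ranks."""
    if k < 2 or N < 2:
        raise ValueError("need k >= 2 methods and N >= 2 cases")
    R = np.asarray(R, dtype=float)
    if R.size != k:
        raise ValueError(f"expected {k} average ranks, got {R.size}")
    return 12.0 * N / (k * (k + 1)) * (float(np.sum(R ** 2)) - k * (k + 1) ** 2 / 4.0)


def friedman_F(chi2: float, k: int, N: int) -> float:
    """Iman–Davenport F-form of the Friedman statistic.

    Undefined (singular) when chi2 reaches its maximum N(k-1) — perfect
    separation of the methods on every case.
    """
    denom = N * (k - 1) - chi2
    if denom <= 0:
        raise ValueError(
            f"chi2 = {chi2} >= N(k-1) = {N * (k - 1)}: perfect separation, "
            "F statistic is singular")
    return (N - 1) * chi2 / denom


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-alpha critical value of the F(df1, df2) distribution."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(sps.f.ppf(1.0 - alpha, df1, df2))


def q_alpha(k: int, alpha: float = 0.10, source: str = "table") -> float:
    """Nemenyi critical value q_alpha for k methods.

    ``source="table"`` reads the embedded conventional table (alpha in
    {0.05, 0.10}, k in 2..10); ``source="distribution"`` evaluates the
    Studentized-range quantile at infinite df divided by sqrt(2).
    """
    if k < 2:
        raise ValueError("need k >= 2 methods")
    if source == "table":
        try:
            return _Q_TABLE[round(alpha, 2)][k]
        except KeyError:
            raise ValueError(
                f"tabulated q_alpha unavailable for alpha={alpha}, k={k}; "
                f"supported alpha levels: {sorted(_Q_TABLE)} with k in 2..10 "
                "(or use source='distribution')") from None
    if source == "distribution":
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        return float(sps.studentized_range.ppf(1.0 - alpha, k, np.inf)
                     / math.sqrt(2.0))
    raise ValueError(f"unknown q_alpha source {source!r}")


def nemenyi_cd(k: int, N: int, alpha: float = 0.10,
               source: str = "table") -> float:
    """Nemenyi critical difference CD = q_alpha * sqrt(k(k+1)/(6N))."""
    if N < 1:
        raise ValueError("need N >= 1 cases")
    return q_alpha(k, alpha, source) * math.sqrt(k * (k + 1) / (6.0 * N))


def nemenyi_matrix(R: np.ndarray, k: int, N: int,
                   alpha: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise average-rank differences and their significance flags."""
    R = np.asarray(R, dtype=float)
    cd = nemenyi_cd(k, N, alpha)
    diff = np.abs(R[:, None] - R[None, :])
    return diff, diff > cd
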