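"""Inter-neighborhood similarity (I-Sim) metrics and the rescaled cosine
coefficient (RCC).

The mapping indicator between proteins i and j is a vector similarity over
their IW feature vectors y_i, y_j.  The benchmark is plain cosine similarity

    cos(i, j) = <y_i, y_j> / (||y_i|| * ||y_j||),

which is unstable on noisy sparse networks: one hub endpoint crushes the
score.  RCC applies two saturation devices:

1. A saturated denominator g(||y_i||, ||y_j||; C_Y) replaces the norm
   product.  g must be monotonously non-decreasing in each norm (so ranks
   among equally-supported pairs are preserved) and bounded above (so the
   numerical gap caused by extreme norms is shrunk).  The form used here is

       g(x1, x2; C_Y) = C_Y * (1 - exp(-x1 * x2 / C_Y)),

   which saturates at C_Y.

2. A rescaling coefficient r_ij in (0, 1): the probability, under a normal
   distribution fitted to all nonzero I-Sim supports n_ij = <y_i, y_j>, that
   a pair's support is at least as large as a typical one.  Raising r_ij to
   a power d sharpens the separation between frequently- and
   rarely-supported pairs; d = 0 switches rescaling off.

Final score:  rcc_ij = r_ij**d * <y_i, y_j> / g(||y_i||, ||y_j||; C_Y).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm

from .network import IWMatrix, Pair, pair_key

logger = logging.getLogger(__name__)

__all__ = [
    "RCCParams",
    "SupportStats",
    "MappingIndicatorSet",
    "support",
    "cosine_similarity",
    "saturated_denominator",
    "support_stats",
    "rescaling_coefficient",
    "rcc_score",
    "score_all_pairs",
    "CANDIDATE_STRATEGIES",
]

CANDIDATE_STRATEGIES = ("observed-edges", "common-neighbor-pairs", "all-pairs")

#: Default ceiling on the number of enumerated pairs for the all-pairs
#: candidate strategy (quadratic blow-up guard).
DEFAULT_PAIR_CAP = 2_000_000


@dataclass(frozen=True)
class RCCParams:
    """RCC hyper-parameters.

    c_y : saturation constant of the denominator (> 0).  Larger values move
        the metric back toward plain cosine behaviour.
    d : rescaling exponent (>= 0).  d = 0 disables the rescaling coefficient.

    Defaults (c_y=30, d=5) are the settings used for all benchmark cases.
    """

    c_y: float = 30.0
    d: float = 5.0

    def __post_init__(self) -> None:
        if not self.c_y > 0:
            raise ValueError(f"C_Y must be positive, got {self.c_y}")
        if self.d < 0:
            raise ValueError(f"d must be non-negative, got {self.d}")


@dataclass(frozen=True)
class SupportStats:
    """Normal fit to the nonzero I-Sim supports of one IW matrix.

    mu, sigma2 are the maximum-likelihood (population) mean and variance of
    {n_ij : i < j, n_ij > 0}; n_y is the size of that set.
    """

    mu: float
    sigma2: float
    n_y: int

    def __post_init__(self) -> None:
        if self.n_y < 1:
            raise ValueError("n_y must be >= 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


@dataclass
class MappingIndicatorSet:
    """Per-pair likelihood scores (the mapping-indicator matrix).

    Keys are canonical unordered pairs; lookup is symmetric.  Pairs absent
    from the map have zero support and score 0.
    """

    scores: dict[Pair, float]
    supports: dict[Pair, int] = field(default_factory=dict)
    method: str = ""

    def score(self, a: str, b: str) -> float:
        return self.scores.get(pair_key(a, b), 0.0)

    def support(self, a: str, b: str) -> int:
        return self.supports.get(pair_key(a, b), 0)

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, pair: Pair) -> bool:
        return pair_key(*pair) in self.scores


def _check_vectors(y_i: np.ndarray, y_j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_i = np.asarray(y_i).ravel()
    y_j = np.asarray(y_j).ravel()
    if y_i.shape != y_j.shape:
        raise ValueError(
            f"feature vectors have different lengths: {y_i.size} vs {y_j.size}")
    return y_i, y_j


def support(y_i: np.ndarray, y_j: np.ndarray) -> int:
    """I-Sim support n_ij = <y_i, y_j>: the number of common closed-neighborhood
    members backing the similarity between i and j."""
    y_i, y_j = _check_vectors(y_i, y_j)
    return int(np.dot(y_i, y_j))


def cosine_similarity(y_i: np.ndarray, y_j: np.ndarray) -> float:
    """Plain cosine I-Sim (the benchmark metric), in [0, 1] for IW rows."""
    y_i, y_j = _check_vectors(y_i, y_j)
    num = float(np.dot(y_i, y_j))
    if num == 0.0:
        return 0.0
    return num / (float(np.linalg.norm(y_i)) * float(np.linalg.norm(y_j)))


def saturated_denominator(norm_i, norm_j, c_y: float):
    """Saturation transform of the cosine denominator.

    g(x1, x2; C_Y) = C_Y * (1 - exp(-x1*x2/C_Y)).  Monotonously non-decreasing
    in each norm and bounded above by C_Y, so scores keep their relative order
    at equal support while the gap caused by extreme norms is shrunk.
    Accepts scalars or arrays.
    """
    if not c_y > 0:
        raise ValueError(f"C_Y must be positive, got {c_y}")
    prod = np.asarray(norm_i, dtype=float) * np.asarray(norm_j, dtype=float)
    out = c_y * -np.expm1(-prod / c_y)
    if out.ndim == 0:
        return float(out)
    return out


def _nonzero_supports(iw: IWMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row, col, support arrays for all unordered pairs i<j with n_ij > 0."""
    gram = (iw.matrix @ iw.matrix.T).tocoo()
    mask = gram.row < gram.col
    return gram.row[mask], gram.col[mask], gram.data[mask]


def support_stats(iw: IWMatrix) -> SupportStats:
    """Fit a normal distribution to all nonzero off-diagonal supports.

    Self-pairs are excluded: a protein's support with itself is just its
    degree plus one, an artifact of the unit diagonal rather than an
    interactome signal.  Variance is the population (ML) variance.
    """
    _, _, data = _nonzero_supports(iw)
    if data.size == 0:
        raise ValueError(
            "no protein pair shares a closed-neighborhood member; "
            "support statistics are undefined")
    vals = data.astype(float)
    return SupportStats(mu=float(vals.mean()),
                        sigma2=float(vals.var()),
                        n_y=int(vals.size))


#: coefficients of the Maclaurin series of the standard normal CDF,
#: Phi(z) = 1/2 + (1/sqrt(2*pi)) * sum_k (-1)^k z^(2k+1) / (2^k k! (2k+1))
_SERIES_TERMS = 24


def _normal_cdf_series(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    acc = np.zeros_like(z)
    for k in range(_SERIES_TERMS):
        coef = (-1.0) ** k / (2.0 ** k * math.factorial(k) * (2 * k + 1))
        acc = acc + coef * z ** (2 * k + 1)
    return np.clip(0.5 + acc / math.sqrt(2.0 * math.pi), 0.0, 1.0)


def rescaling_coefficient(n_ij, stats: SupportStats, method: str = "exact"):
    """Rescaling coefficient r_ij: Phi((n_ij - mu) / sigma) under the fitted
    normal — the estimated probability that a support of size n_ij is at
    least as large as a typical one.

    ``method="exact"`` evaluates the normal CDF through the error function;
    ``method="series"`` uses a truncated Maclaurin expansion, shipped only as
    a cross-check of the exact route.

    Coefficients are clipped to the open unit interval at machine precision:
    mathematically r lies strictly in (0, 1) for every finite support, but
    the float64 CDF rounds to exactly 0 or 1 once the tail mass drops below
    machine epsilon (|z| beyond about 8), and downstream contracts (zero
    score iff zero support) rely on strict openness.

    Degenerate fit (sigma2 = 0) falls back to the limiting step-function CDF:
    0 below mu, 1 above, 0.5 at mu (logged).
    """
    n = np.asarray(n_ij, dtype=float)
    if stats.sigma2 == 0.0:
        logger.warning(
            "degenerate support distribution (sigma2=0); using step-function CDF")
        out = np.where(n < stats.mu, 0.0, np.where(n > stats.mu, 1.0, 0.5))
        return float(out) if out.ndim == 0 else out
    z = (n - stats.mu) / math.sqrt(stats.sigma2)
    if method == "exact":
        out = norm.cdf(z)
    elif method == "series":
        out = _normal_cdf_series(z)
    else:
        raise ValueError(f"unknown CDF method {method!r}")
    tiny = np.finfo(float).tiny
    out = np.clip(out, tiny, 1.0 - np.finfo(float).eps / 2)
    return float(out) if np.ndim(out) == 0 else out


def rcc_score(y_i: np.ndarray, y_j: np.ndarray, params: RCCParams,
              stats: SupportStats) -> float:
    """Rescaled cosine coefficient for one pair of IW feature vectors.

    Zero iff the support is zero; with d = 0 it equals the saturated cosine
    exactly.
    """
    y_i, y_j = _check_vectors(y_i, y_j)
    n_ij = float(np.dot(y_i, y_j))
    if n_ij == 0.0:
        return 0.0
    g = saturated_denominator(np.linalg.norm(y_i), np.linalg.norm(y_j),
                              params.c_y)
    r = rescaling_coefficient(n_ij, stats)
    return float(r ** params.d * n_ij / g)


def _candidate_pairs(iw: IWMatrix, candidates: str,
                     pair_cap: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index pairs (i<j) and their supports for a candidate strategy."""
    n = iw.n_proteins
    if candidates == "observed-edges":
        adj = iw.matrix.tocoo()
        mask = adj.row < adj.col  # off-diagonal upper triangle = edges
        rows, cols = adj.row[mask], adj.col[mask]
        gram = iw.matrix @ iw.matrix.T
        supports = np.asarray(gram[rows, cols]).ravel()
        return rows, cols, supports
    if candidates == "common-neighbor-pairs":
        return _nonzero_supports(iw)
    if candidates == "all-pairs":
        total = n * (n - 1) // 2
        if total > pair_cap:
            raise ValueError(
                f"all-pairs enumeration would score {total} pairs "
                f"(cap {pair_cap}); use candidates='common-neighbor-pairs' — "
                "zero-support pairs score 0 and are omitted losslessly")
        rows, cols = np.triu_indices(n, k=1)
        gram = (iw.matrix @ iw.matrix.T).toarray()
        supports = gram[rows, cols]
        return rows, cols, supports
    raise ValueError(
        f"unknown candidate strategy {candidates!r}; "
        f"choose one of {CANDIDATE_STRATEGIES}")


def score_all_pairs(iw: IWMatrix, params: RCCParams | None = None,
                    candidates: str = "common-neighbor-pairs",
                    metric: str = "rcc",
                    stats: SupportStats | None = None,
                    pair_cap: int = DEFAULT_PAIR_CAP) -> MappingIndicatorSet:
    """Score a candidate set of protein pairs with an I-Sim metric.

    Parameters
    ----------
    candidates
        ``"observed-edges"`` (assessment universe),
        ``"common-neighbor-pairs"`` (all pairs with nonzero support; the
        default — zero-support pairs score 0 by construction so omitting
        them is lossless), or ``"all-pairs"`` (guarded by ``pair_cap``).
    metric
        ``"rcc"`` (default) or ``"cosine"`` (the plain benchmark).
    stats
        Pre-computed support statistics; computed from ``iw`` if omitted.

    Scoring is fully vectorized over the sparse Gram matrix Y @ Y.T.
    """
    params = params or RCCParams()
    rows, cols, supports = _candidate_pairs(iw, candidates, pair_cap)
    norms = iw.row_norms()
    n_vals = supports.astype(float)
    with np.errstate(invalid="ignore"):
        if metric == "cosine":
            scores = np.where(n_vals > 0,
                              n_vals / (norms[rows] * norms[cols]), 0.0)
        elif metric == "rcc":
            if stats is None:
                stats = support_stats(iw)
            g = saturated_denominator(norms[rows], norms[cols], params.c_y)
            r = rescaling_coefficient(n_vals, stats)
            scores = np.where(n_vals > 0, np.asarray(r) ** params.d * n_vals / g,
                              0.0)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    proteins = iw.proteins
    score_map: dict[Pair, float] = {}
    support_map: dict[Pair, int] = {}
    for i, j, n_ij, s in zip(rows.tolist(), cols.tolist(),
                             supports.tolist(), scores.tolist()):
        key = pair_key(proteins[i], proteins[j])
        score_map[key] = s
        support_map[key] = int(n_ij)
    return MappingIndicatorSet(score_map, support_map, method=metric)
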