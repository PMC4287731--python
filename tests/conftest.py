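"""Shared fixtures and naive dense oracles.

The oracles deliberately avoid the package's sparse code paths: they build a
dense IW matrix entry by entry from the edge set and evaluate every formula
by direct arithmetic over all pairs, so they can certify the vectorized
sparse implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from rcf.network import InteractomeNetwork, pair_key
from rcf.rcc import RCCParams


def random_network(rng: np.random.Generator, n: int,
                   p: float) -> InteractomeNetwork:
    """Erdos-Renyi network on n named proteins."""
    proteins = tuple(f"n{i:03d}" for i in range(n))
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((proteins[i], proteins[j]))
    return InteractomeNetwork(proteins, frozenset(edges))


def dense_iw(net: InteractomeNetwork) -> np.ndarray:
    """Entry-by-entry dense IW matrix: 1 on the diagonal and on edges."""
    n = net.n_proteins
    idx = net.index
    y = np.zeros((n, n))
    for i in range(n):
        y[i, i] = 1.0
    for a, b in net.edges:
        y[idx[a], idx[b]] = 1.0
        y[idx[b], idx[a]] = 1.0
    return y


def dense_supports(y: np.ndarray) -> np.ndarray:
    """All-pairs support matrix by explicit loops over inner products."""
    n = y.shape[0]
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s[i, j] = float(np.dot(y[i], y[j]))
    return s


def dense_support_stats(y: np.ndarray) -> tuple[float, float, int]:
    """(mu, sigma2, N_Y) over nonzero off-diagonal supports, brute force."""
    s = dense_supports(y)
    vals = [s[i, j] for i in range(y.shape[0]) for j in range(i + 1, y.shape[0])
            if s[i, j] > 0]
    mu = sum(vals) / len(vals)
    sigma2 = sum((v - mu) ** 2 for v in vals) / len(vals)
    return mu, sigma2, len(vals)


def dense_rcc_scores(net: InteractomeNetwork,
                     params: RCCParams) -> dict[tuple[str, str], float]:
    """All nonzero-support pair scores by the direct RCC formula, using
    math.erf for the normal CDF (independent of scipy)."""
    y = dense_iw(net)
    s = dense_supports(y)
    mu, sigma2, _ = dense_support_stats(y)
    sigma = math.sqrt(sigma2)
    norms = [math.sqrt(float(np.dot(row, row))) for row in y]
    out = {}
    proteins = net.proteins
    n = len(proteins)
    for i in range(n):
        for j in range(i + 1, n):
            n_ij = s[i, j]
            if n_ij == 0:
                continue
            g = params.c_y * (1.0 - math.exp(-norms[i] * norms[j] / params.c_y))
            if sigma == 0.0:
                r = 0.5 if n_ij == mu else (0.0 if n_ij < mu else 1.0)
            else:
                r = 0.5 * (1.0 + math.erf((n_ij - mu) / (sigma * math.sqrt(2.0))))
            out[pair_key(proteins[i], proteins[j])] = r ** params.d * n_ij / g
    return out


def dense_cosine_scores(net: InteractomeNetwork) -> dict[tuple[str, str], float]:
    y = dense_iw(net)
    s = dense_supports(y)
    norms = [math.sqrt(float(np.dot(row, row))) for row in y]
    out = {}
    proteins = net.proteins
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if s[i, j] > 0:
                out[pair_key(proteins[i], proteins[j])] = (
                    s[i, j] / (norms[i] * norms[j]))
    return out


@pytest.fixture
def path_network() -> InteractomeNetwork:
    """a - b - c path: one common-neighbor missing pair (a, c)."""
    return InteractomeNetwork(("a", "b", "c"),
                              frozenset({("a", "b"), ("b", "c")}))


@pytest.fixture
def toy6_network() -> InteractomeNetwork:
    """Six-node graph: i and j adjacent, sharing neighbors x and w; plus a
    pendant leaf z on j and an isolated protein q."""
    edges = {("i", "j"), ("i", "x"), ("j", "x"), ("i", "w"), ("j", "w"),
             ("j", "z")}
    return InteractomeNetwork(("i", "j", "x", "w", "z", "q"),
                              frozenset(pair_key(*e) for e in edges))
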