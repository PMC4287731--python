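"""Topology-based comparison metrics: IG, CD and FW.

These are the established neighborhood-topology reliability indices the
collaborative-filtering approach is benchmarked against.  All use the same
undirected binary network; CD and FW operate on closed neighborhoods
N_x = Int(x) ∪ {x}.

IG (interaction generality, Saito et al.):  1 + the number of third-party
proteins that interact with either endpoint and have no interaction beyond
that single one (degree-1 neighbors).  Lower is more reliable, so for
ranking the score is negated.

CD (Czekanowski-Dice):  distance D(i,j) = |N_i Δ N_j| / (|N_i| + |N_j|);
reported here as the similarity 1 - D, in [0, 1].

FW (functional similarity weight, Chua et al.):  product of two asymmetric
overlap ratios with an optional pseudo-count λ_{u,v} = max(0, n_avg - |N_u|)
where n_avg is the average closed-neighborhood size.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .network import InteractomeNetwork, Pair, pair_key, build_iw_matrix
from .rcc import MappingIndicatorSet, _candidate_pairs, DEFAULT_PAIR_CAP

__all__ = ["ig_score", "cd_score", "fw_score", "score_all_pairs",
           "BASELINE_METHODS"]

BASELINE_METHODS = ("ig", "cd", "fw")


def _closed(net: InteractomeNetwork, p: str) -> frozenset[str]:
    return net.neighbors(p) | {p}


def ig_score(net: InteractomeNetwork, pair: tuple[str, str]) -> int:
    """Interaction generality of an observed edge (lower = more reliable).

    Counts degree-1 proteins hanging off either endpoint: spoke-like
    neighborhoods are the signature of promiscuous bait/prey artifacts.
    Defined on observed edges only.
    """
    a, b = pair
    if not net.has_edge(a, b):
        raise ValueError(f"IG is defined on observed edges only; "
                         f"({a},{b}) is not in the network")
    adj = net.adjacency()
    count = 0
    for v in (adj[a] | adj[b]) - {a, b}:
        if len(adj[v]) == 1:
            count += 1
    return 1 + count


def cd_score(net: InteractomeNetwork, pair: tuple[str, str]) -> float:
    """Czekanowski-Dice similarity 1 - |N_iΔN_j|/(|N_i|+|N_j|), closed
    neighborhoods; 1 for identical neighborhoods, 0 for disjoint ones."""
    a, b = pair
    na, nb = _closed(net, a), _closed(net, b)
    return 1.0 - len(na ^ nb) / (len(na) + len(nb))


def _avg_closed_size(net: InteractomeNetwork) -> float:
    return 2.0 * net.n_edges / net.n_proteins + 1.0


def fw_score(net: InteractomeNetwork, pair: tuple[str, str],
             lam: str | float = "auto") -> float:
    """Functional similarity weight, in [0, 1].

    FW(u,v) = [2|N_u∩N_v| / (|N_u\\N_v| + 2|N_u∩N_v| + λ_uv)]
            * [2|N_u∩N_v| / (|N_v\\N_u| + 2|N_u∩N_v| + λ_vu)]

    ``lam="auto"`` uses the pseudo-count λ_uv = max(0, n_avg - |N_u|)
    penalizing proteins with fewer partners than average; ``lam=0`` gives
    the simplified (hand-checkable) form.
    """
    u, v = pair
    nu, nv = _closed(net, u), _closed(net, v)
    inter = len(nu & nv)
    if inter == 0:
        return 0.0
    if lam == "auto":
        n_avg = _avg_closed_size(net)
        lam_uv = max(0.0, n_avg - len(nu))
        lam_vu = max(0.0, n_avg - len(nv))
    else:
        lam_uv = lam_vu = float(lam)
    left = 2 * inter / (len(nu - nv) + 2 * inter + lam_uv)
    right = 2 * inter / (len(nv - nu) + 2 * inter + lam_vu)
    return left * right


def score_all_pairs(net: InteractomeNetwork, method: str,
                    candidates: str = "common-neighbor-pairs",
                    lam: str | float = "auto",
                    pair_cap: int = DEFAULT_PAIR_CAP) -> MappingIndicatorSet:
    """Vectorized baseline scoring over a candidate pair set.

    The closed-neighborhood set sizes reduce to IW-matrix quantities
    (|N_u∩N_v| = n_uv, |N_u| = deg(u)+1), so CD and FW are computed from the
    same sparse Gram products as RCC.  IG only ranks observed edges, where
    the spoke count vectorizes through the adjacency matrix; scores are
    negated so that higher-is-better matches the shared convention.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline {method!r}; choose from "
                         f"{BASELINE_METHODS}")
    iw = build_iw_matrix(net)
    if method == "ig":
        if candidates != "observed-edges":
            raise ValueError("IG is defined on observed edges only; "
                             "use candidates='observed-edges'")
        adj = iw.matrix - sp.eye(iw.n_proteins, dtype=np.int32, format="csr")
        deg = np.asarray(adj.sum(axis=1)).ravel()
        spoke = (deg == 1).astype(np.int64)
        c1 = adj @ spoke  # degree-1 neighbors of each protein
        coo = adj.tocoo()
        mask = coo.row < coo.col
        rows, cols = coo.row[mask], coo.col[mask]
        # subtract the endpoints themselves when they are degree-1
        counts = c1[rows] + c1[cols] - spoke[cols] - spoke[rows]
        ig = 1 + counts
        proteins = iw.proteins
        scores: dict[Pair, float] = {}
        supports: dict[Pair, int] = {}
        for i, j, g in zip(rows.tolist(), cols.tolist(), ig.tolist()):
            key = pair_key(proteins[i], proteins[j])
            scores[key] = -float(g)
            supports[key] = int(g)
        return MappingIndicatorSet(scores, supports, method="ig")

    rows, cols, n_uv = _candidate_pairs(iw, candidates, pair_cap)
    sizes = np.asarray(iw.matrix.sum(axis=1)).ravel().astype(float)
    su, sv = sizes[rows], sizes[cols]
    n_uv = n_uv.astype(float)
    if method == "cd":
        vals = 2.0 * n_uv / (su + sv)
    else:  # fw
        if lam == "auto":
            n_avg = _avg_closed_size(net)
            lam_u = np.maximum(0.0, n_avg - su)
            lam_v = np.maximum(0.0, n_avg - sv)
        else:
            lam_u = lam_v = float(lam)
        vals = (2 * n_uv / (su + n_uv + lam_u)) * (2 * n_uv / (sv + n_uv + lam_v))
    proteins = iw.proteins
    scores = {}
    supports = {}
    for i, j, n_ij, s in zip(rows.tolist(), cols.tolist(),
                             n_uv.tolist(), vals.tolist()):
        key = pair_key(proteins[i], proteins[j])
        scores[key] = s
        supports[key] = int(n_ij)
    return MappingIndicatorSet(scores, supports, method=method)
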