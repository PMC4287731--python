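"""Binary PPI network parsing and the interactome weight (IW) matrix.

A high-throughput PPI screen yields a binary, undirected network G = (V, E).
The IW matrix Y encodes each protein's *closed* neighborhood: y_ij = 1 when
(i, j) is an observed interaction or i = j, else 0.  Row i of Y is protein i's
feature vector; all downstream similarity scoring operates on these rows.
Real HTS networks are very sparse (densities around 0.1%), so only nonzero
entries are materialized.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

__all__ = [
    "InteractomeNetwork",
    "IWMatrix",
    "ParseError",
    "pair_key",
    "read_edge_list",
    "write_edge_list",
    "build_iw_matrix",
    "feature_vector",
]


class ParseError(ValueError):
    """Raised when an edge-list line cannot be interpreted."""


def pair_key(a: str, b: str) -> Pair:
    """Canonical unordered-pair key (lexicographic)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractomeNetwork:
    """An undirected binary PPI network.

    Parameters
    ----------
    proteins
        Protein identifiers in first-appearance order.  Identifiers are
        opaque, case-sensitive strings; no symbol normalization is applied.
    edges
        Unordered interaction pairs, each stored once under its canonical
        (lexicographic) key.  No self-loops.
    """

    proteins: tuple[str, ...]
    edges: frozenset[Pair]

    def __post_init__(self) -> None:
        known = set(self.proteins)
        if len(known) != len(self.proteins):
            raise ValueError("duplicate protein identifiers")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop ({a},{b}) not allowed")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a},{b}) references unknown protein")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.proteins)}

    def density(self) -> float:
        """Edge density |E| / C(|V|, 2)."""
        n = self.n_proteins
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)

    def mean_degree(self) -> float:
        """Mean interactions per protein, |E| / |V|."""
        return self.n_edges / self.n_proteins if self.proteins else 0.0

    def has_edge(self, a: str, b: str) -> bool:
        return pair_key(a, b) in self.edges

    def neighbors(self, p: str) -> frozenset[str]:
        return self.adjacency()[p]

    def adjacency(self) -> dict[str, frozenset[str]]:
        """Open neighbor sets; cached after first call."""
        cached = getattr(self, "_adjacency", None)
        if cached is None:
            adj: dict[str, set[str]] = {p: set() for p in self.proteins}
            for a, b in self.edges:
                adj[a].add(b)
                adj[b].add(a)
            cached = {p: frozenset(s) for p, s in adj.items()}
            object.__setattr__(self, "_adjacency", cached)
        return cached


def from_pairs(pairs: Iterable[tuple[str, str]],
               extra_proteins: Iterable[str] = ()) -> InteractomeNetwork:
    """Build a network from iterable pairs, deduplicating and dropping loops."""
    order: dict[str, None] = {}
    edges: set[Pair] = set()
    for a, b in pairs:
        order.setdefault(a, None)
        order.setdefault(b, None)
        if a == b:
            logger.warning("dropping self-loop on %r", a)
            continue
        edges.add(pair_key(a, b))
    for p in extra_proteins:
        order.setdefault(p, None)
    return InteractomeNetwork(tuple(order), frozenset(edges))


def _open(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_edge_list(source: str | Path | TextIO,
                   dialect: str = "tsv-pairs") -> InteractomeNetwork:
    """Parse a binary PPI edge list into an :class:`InteractomeNetwork`.

    Parameters
    ----------
    source
        Path or open text stream.
    dialect
        ``"tsv-pairs"`` — two identifier columns, tab- or whitespace-separated,
        ``#`` comment lines skipped.
        ``"mitab-ids"`` — PSI-MITAB 2.5; only interactor-ID columns 1–2 are
        read, all evidence columns are ignored.

    Duplicate pairs (in either orientation) are stored once; self-loops are
    dropped with a warning.  Raises :class:`ParseError` naming the offending
    line, or on empty input.
    """
    if dialect not in ("tsv-pairs", "mitab-ids"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fh, should_close = _open(source)
    try:
        pairs: list[tuple[str, str]] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                continue
            if dialect == "tsv-pairs":
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError(
                        f"line {lineno}: expected two identifiers, got {line!r}")
                a, b = fields[0], fields[1]
            else:
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(
                        f"line {lineno}: expected >=2 MITAB columns, got {line!r}")
                a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ParseError(f"line {lineno}: empty identifier in {line!r}")
            pairs.append((a, b))
    finally:
        if should_close:
            fh.close()
    if not pairs:
        raise ParseError("no interaction records found in input")
    return from_pairs(pairs)


def write_edge_list(net: InteractomeNetwork,
                    dest: str | Path | TextIO) -> None:
    """Write the network as a two-column TSV (canonical pair order)."""
    fh: TextIO
    if isinstance(dest, (str, Path)):
        fh = open(dest, "w", encoding="utf-8")
        close = True
    else:
        fh, close = dest, False
    try:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
    finally:
        if close:
            fh.close()


@dataclass(frozen=True)
class IWMatrix:
    """Interactome weight matrix: symmetric binary |P|x|P| with unit diagonal.

    ``matrix`` is a CSR sparse matrix; only nonzeros are materialized.  Row i,
    read as a vector, is protein i's IW feature vector: ones at itself and at
    every observed interaction partner.
    """

    proteins: tuple[str, ...]
    matrix: sp.csr_matrix = field(repr=False)

    @property
    def index(self) -> dict[str, int]:
        cached = getattr(self, "_index", None)
        if cached is None:
            cached = {p: i for i, p in enumerate(self.proteins)}
            object.__setattr__(self, "_index", cached)
        return cached

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def row_norms(self) -> np.ndarray:
        """Euclidean norm of every feature vector: sqrt(degree + 1)."""
        counts = np.asarray(self.matrix.sum(axis=1)).ravel()
        return np.sqrt(counts.astype(float))


def build_iw_matrix(net: InteractomeNetwork) -> IWMatrix:
    """Construct the IW matrix from a network.

    y_ij = 1 iff (i, j) is an observed edge or i = j; 0 otherwise.  The unit
    diagonal makes each row the protein's closed neighborhood, which is what
    lets adjacent proteins share support even without third-party neighbors.
    nnz = 2|E| + |V|.
    """
    n = net.n_proteins
    idx = net.index
    rows = np.empty(2 * net.n_edges + n, dtype=np.int64)
    cols = np.empty_like(rows)
    k = 0
    for a, b in net.edges:
        ia, ib = idx[a], idx[b]
        rows[k], cols[k] = ia, ib
        rows[k + 1], cols[k + 1] = ib, ia
        k += 2
    rows[k:] = np.arange(n)
    cols[k:] = np.arange(n)
    data = np.ones(rows.shape[0], dtype=np.int32)
    mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    mat.sum_duplicates()
    return IWMatrix(net.proteins, mat)


def feature_vector(iw: IWMatrix, protein: str) -> np.ndarray:
    """Dense binary feature vector (row of Y) for ``protein``.

    Raises KeyError for an identifier not present in the matrix index.
    """
    try:
        i = iw.index[protein]
    except KeyError:
        raise KeyError(f"unknown protein identifier {protein!r}") from None
    return np.asarray(iw.matrix.getrow(i).todense()).ravel()
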