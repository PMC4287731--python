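"""GO-annotation evaluation of ranked interactome lists.

The validation convention is "guilt by association": truly interacting
proteins tend to share function and cellular localization.  A ranked pair
list is scored by its coherence rate — among the top fraction of pairs in
which *both* proteins carry at least one term of the relevant GO branch,
the fraction sharing at least one common term.  Localization coherence uses
the cellular-component branch; functional homogeneity uses the union of
biological process and molecular function.

To avoid trivially shared high-level terms, the most frequent 1% of terms
(those annotating the most proteins) are removed per branch before rating.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

from .mapping import RankedInteractomeList

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "CoherenceCurve",
    "read_gaf",
    "filter_frequent_terms",
    "coherence_rate",
    "coherence_curve",
    "BRANCHES",
]

BRANCHES = ("cellular_component", "biological_process", "molecular_function")

_ASPECT_TO_BRANCH = {"C": "cellular_component",
                     "P": "biological_process",
                     "F": "molecular_function"}


@dataclass(frozen=True)
class AnnotationMap:
    """Protein → GO-term sets, split by ontology branch."""

    cellular_component: dict[str, frozenset[str]]
    biological_process: dict[str, frozenset[str]]
    molecular_function: dict[str, frozenset[str]]

    def branch(self, name: str) -> dict[str, frozenset[str]]:
        if name not in BRANCHES:
            raise ValueError(f"unknown branch {name!r}")
        return getattr(self, name)

    def terms_for(self, protein: str, branch_mode: str) -> frozenset[str]:
        """Relevant term set for one protein under an evaluation mode.

        ``"localization"`` → cellular component;
        ``"function"`` → biological process ∪ molecular function.
        """
        if branch_mode == "localization":
            return self.cellular_component.get(protein, frozenset())
        if branch_mode == "function":
            return (self.biological_process.get(protein, frozenset())
                    | self.molecular_function.get(protein, frozenset()))
        raise ValueError(f"unknown branch_mode {branch_mode!r}")


@dataclass(frozen=True)
class CoherenceCurve:
    """Coherence rate as a function of the top-list fraction."""

    points: tuple[tuple[float, float, int], ...]  # (fraction, rate, n_evaluable)
    branch_mode: str = ""

    def fractions(self) -> list[float]:
        return [f for f, _, _ in self.points]

    def rates(self) -> list[float]:
        return [r for _, r, _ in self.points]


def read_gaf(source: str | Path | TextIO) -> AnnotationMap:
    """Parse GAF 2.x annotation lines into an :class:`AnnotationMap`.

    Uses the DB-object-ID column as the protein identifier, the aspect
    column (C/P/F) to choose the branch, and skips NOT-qualified rows.
    Malformed lines are skipped with a warning; zero usable rows is an error.
    """
    if isinstance(source, (str, Path)):
        fh: TextIO = open(source, "r", encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    maps: dict[str, dict[str, set[str]]] = {b: {} for b in BRANCHES}
    usable = 0
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                logger.warning("GAF line %d: expected >=9 columns, got %d; "
                               "skipped", lineno, len(fields))
                continue
            protein, qualifier, term, aspect = (fields[1], fields[3],
                                                fields[4], fields[8])
            if not protein or not term or aspect not in _ASPECT_TO_BRANCH:
                logger.warning("GAF line %d: missing identifier/term or bad "
                               "aspect %r; skipped", lineno, aspect)
                continue
            if "NOT" in qualifier.split("|"):
                continue
            maps[_ASPECT_TO_BRANCH[aspect]].setdefault(protein, set()).add(term)
            usable += 1
    finally:
        if close:
            fh.close()
    if usable == 0:
        raise ValueError("no usable GAF annotation rows found")
    frozen = {b: {p: frozenset(s) for p, s in m.items()}
              for b, m in maps.items()}
    return AnnotationMap(**frozen)


def _filter_branch(branch: dict[str, frozenset[str]],
                   fraction: float) -> dict[str, frozenset[str]]:
    counts: dict[str, int] = {}
    for terms in branch.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    n_terms = len(counts)
    if n_terms == 0:
        return dict(branch)
    n_remove = math.ceil(fraction * n_terms)
    # most-annotating terms first; frequency ties broken by term identifier
    ordered = sorted(counts, key=lambda t: (-counts[t], t))
    removed = set(ordered[:n_remove])
    return {p: terms - removed for p, terms in branch.items()}


def filter_frequent_terms(ann: AnnotationMap,
                          fraction: float = 0.01) -> AnnotationMap:
    """Remove, per branch, the top ``fraction`` of terms annotating the most
    proteins (ceil(fraction * T) terms out of T distinct terms).

    This is the operational stand-in for "middle-level" GO terms: the
    near-root terms that annotate huge protein sets carry no discriminating
    signal and would inflate coherence rates.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    return AnnotationMap(**{b: _filter_branch(ann.branch(b), fraction)
                            for b in BRANCHES})


def coherence_rate(ranked: RankedInteractomeList, ann: AnnotationMap,
                   branch_mode: str,
                   top_fraction: float = 1.0) -> tuple[float, int]:
    """Coherence rate of the top fraction of a ranked pair list.

    Returns ``(rate, n_evaluable)``.  A pair is evaluable when both proteins
    carry at least one term in the relevant branch set; unannotated proteins
    are excluded from the denominator (missing annotation is not evidence of
    incoherence).  With zero evaluable pairs the rate is undefined and
    returned as NaN.
    """
    if len(ranked) == 0:
        raise ValueError("ranked list is empty")
    top = ranked.top_fraction(top_fraction)
    n_eval = 0
    n_shared = 0
    for (a, b), _, _ in top.entries:
        ta = ann.terms_for(a, branch_mode)
        tb = ann.terms_for(b, branch_mode)
        if not ta or not tb:
            continue
        n_eval += 1
        if ta & tb:
            n_shared += 1
    if n_eval == 0:
        logger.warning("no evaluable pairs at fraction %s (%s); rate undefined",
                       top_fraction, branch_mode)
        return math.nan, 0
    return n_shared / n_eval, n_eval


def coherence_curve(ranked: RankedInteractomeList, ann: AnnotationMap,
                    branch_mode: str,
                    fractions: Iterable[float]) -> CoherenceCurve:
    """Coherence rate at each top-list fraction (the x-axis sweep of the
    benchmark figures).  Fractions must be strictly increasing in (0, 1]."""
    fracs = list(fractions)
    if not fracs:
        raise ValueError("fractions must be nonempty")
    if any(not 0 < f <= 1 for f in fracs):
        raise ValueError("fractions must lie in (0, 1]")
    if any(b <= a for a, b in zip(fracs, fracs[1:])):
        raise ValueError("fractions must be strictly increasing")
    points = []
    for f in fracs:
        rate, n_eval = coherence_rate(ranked, ann, branch_mode, f)
        points.append((f, rate, n_eval))
    return CoherenceCurve(tuple(points), branch_mode)
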