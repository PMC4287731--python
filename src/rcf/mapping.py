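"""The two binary interactome mapping (BIM) tasks.

Assessment ranks the *observed* interactions by mapping indicator: high
scores mark reliable PPIs, low scores mark likely false positives.
Prediction ranks the scored *missing* pairs and keeps the top K as probable
undetected interactions (K = 20,000 in the benchmark protocol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

from .network import InteractomeNetwork, Pair
from .rcc import MappingIndicatorSet

logger = logging.getLogger(__name__)

__all__ = ["RankedInteractomeList", "assess", "predict", "DEFAULT_K"]

DEFAULT_K = 20_000


@dataclass(frozen=True)
class RankedInteractomeList:
    """Protein pairs ordered by mapping indicator.

    entries: (pair, score, rank) with scores non-increasing and ranks 1..n.
    task: "assessment" (entries are observed edges) or "prediction"
    (entries are missing pairs).
    """

    entries: tuple[tuple[Pair, float, int], ...]
    task: str

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> list[Pair]:
        return [pair for pair, _, _ in self.entries]

    def top_fraction(self, fraction: float) -> "RankedInteractomeList":
        """Prefix containing the top ceil(fraction * n) entries."""
        import math
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        m = math.ceil(fraction * len(self.entries))
        return RankedInteractomeList(self.entries[:m], self.task)

    def write_tsv(self, dest: str | Path | TextIO) -> None:
        fh: TextIO
        if isinstance(dest, (str, Path)):
            fh = open(dest, "w", encoding="utf-8")
            close = True
        else:
            fh, close = dest, False
        try:
            fh.write("rank\tprotein_a\tprotein_b\tscore\n")
            for (a, b), score, rank in self.entries:
                fh.write(f"{rank}\t{a}\t{b}\t{score:.10g}\n")
        finally:
            if close:
                fh.close()


def _ranked(pairs_scores: list[tuple[Pair, float]], task: str) -> RankedInteractomeList:
    # descending score; ties broken by lexicographic pair order for determinism
    pairs_scores.sort(key=lambda item: (-item[1], item[0]))
    entries = tuple((pair, score, rank)
                    for rank, (pair, score) in enumerate(pairs_scores, start=1))
    return RankedInteractomeList(entries, task)


def assess(net: InteractomeNetwork,
           scores: MappingIndicatorSet) -> RankedInteractomeList:
    """Rank every observed interaction by its mapping indicator (descending).

    Edges absent from the score map have zero support and score 0.
    """
    items = [(pair, scores.score(*pair)) for pair in net.edges]
    return _ranked(items, "assessment")


def predict(net: InteractomeNetwork, scores: MappingIndicatorSet,
            k: int = DEFAULT_K) -> RankedInteractomeList:
    """Top-k missing interactomes by mapping indicator.

    Candidates are the scored pairs that are not observed edges; pairs with
    zero support are never scored (the metric assigns them 0 uniformly, so
    they carry no ranking information).  If fewer than ``k`` candidates
    exist, all are returned and the shortfall is logged.
    """
    if k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    items = [(pair, score) for pair, score in scores.scores.items()
             if pair not in net.edges]
    ranked = _ranked(items, "prediction")
    if len(ranked) < k:
        logger.warning("only %d missing-pair candidates available (k=%d)",
                       len(ranked), k)
        return ranked
    return RankedInteractomeList(ranked.entries[:k], "prediction")
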