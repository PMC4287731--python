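"""Tabular report writers (TSV) for scores and evaluation curves."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .evaluation import CoherenceCurve
from .network import InteractomeNetwork
from .rcc import MappingIndicatorSet

__all__ = ["scores_frame", "write_scores_tsv", "curves_frame",
           "write_curves_tsv"]


def scores_frame(scores: MappingIndicatorSet,
                 net: InteractomeNetwork) -> pd.DataFrame:
    """Score table: protein_a, protein_b, support, score, candidate_class."""
    rows = []
    for (a, b), s in sorted(scores.scores.items()):
        rows.append({
            "protein_a": a,
            "protein_b": b,
            "support": scores.support(a, b),
            "score": s,
            "candidate_class": "observed" if net.has_edge(a, b) else "missing",
        })
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "support",
                                       "score", "candidate_class"])


def write_scores_tsv(scores: MappingIndicatorSet, net: InteractomeNetwork,
                     dest: str | Path) -> None:
    scores_frame(scores, net).to_csv(dest, sep="\t", index=False)


def curves_frame(curves: dict[str, CoherenceCurve]) -> pd.DataFrame:
    """Long-format table of coherence curves keyed by a label (method or
    method×mode)."""
    rows = []
    for label, curve in curves.items():
        for fraction, rate, n_eval in curve.points:
            rows.append({"label": label, "branch_mode": curve.branch_mode,
                         "fraction": fraction, "rate": rate,
                         "n_evaluable": n_eval})
    return pd.DataFrame(rows, columns=["label", "branch_mode", "fraction",
                                       "rate", "n_evaluable"])


def write_curves_tsv(curves: dict[str, CoherenceCurve],
                     dest: str | Path) -> None:
    curves_frame(curves).to_csv(dest, sep="\t", index=False)
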