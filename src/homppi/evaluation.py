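"""Performance measures for interface residue prediction.

Per-protein confusion counts yield sensitivity (recall), specificity --
used here, as is common in the interface-prediction literature, to mean
*precision* TP/(TP+FP), not the true-negative rate -- accuracy and the
Matthews correlation coefficient (CC).  Protein-based overall measures are
unweighted means over proteins; residue-based overall measures pool the
counts first.  Ratios with a zero denominator are undefined: they are
reported as None and excluded from averages, with the exclusion count kept.

The interface-conservation (IC) score of a template against a query is the
CC between the transferred template labels and the query's true labels,
with ``?`` positions excluded pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from homppi.structure_interface import LabelTrack

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "OverallSummary",
    "metrics",
    "protein_level_summary",
    "ic_score",
    "confusion_from_tracks",
    "pr_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    """Per-protein measures; None marks an undefined (0/0) ratio."""

    sensitivity: Optional[float]
    specificity: Optional[float]  # precision TP/(TP+FP)
    accuracy: Optional[float]
    cc: Optional[float]


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity (precision), accuracy and Matthews CC."""
    mcc_den = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    cc = None if mcc_den == 0 else \
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_den)
    return Metrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tp, c.tp + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        cc=cc,
    )


@dataclass(frozen=True)
class OverallSummary:
    """Protein-based (averaged) and residue-based (pooled) overall measures."""

    protein_based: Metrics
    residue_based: Metrics
    n_proteins: int
    n_excluded: dict[str, int]  # per measure: proteins with undefined value


def protein_level_summary(counts: Sequence[ConfusionCounts]) -> OverallSummary:
    """Overall measures over a set of test proteins.

    Protein-based values are unweighted means of the per-protein measures,
    skipping proteins where a measure is undefined; residue-based values
    are computed once on the pooled counts.
    """
    if not counts:
        raise ValueError("no proteins to summarise")
    per = [metrics(c) for c in counts]
    fields = ("sensitivity", "specificity", "accuracy", "cc")
    averaged = {}
    excluded = {}
    for name in fields:
        values = [getattr(m, name) for m in per if getattr(m, name) is not None]
        excluded[name] = len(per) - len(values)
        averaged[name] = sum(values) / len(values) if values else None
    pooled = metrics(sum(counts[1:], counts[0]))
    return OverallSummary(protein_based=Metrics(**averaged),
                          residue_based=pooled,
                          n_proteins=len(counts),
                          n_excluded=excluded)


def confusion_from_tracks(predicted: LabelTrack, actual: LabelTrack) -> ConfusionCounts:
    """Counts over positions where both tracks are 0/1 ('?' excluded pairwise)."""
    if len(predicted) != len(actual):
        raise ValueError("tracks must have equal length")
    tp = fp = tn = fn = 0
    for p, a in zip(predicted.labels, actual.labels):
        if p == "?" or a == "?":
            continue
        if p == "1" and a == "1":
            tp += 1
        elif p == "1" and a == "0":
            fp += 1
        elif p == "0" and a == "0":
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def ic_score(predicted: LabelTrack, actual: LabelTrack) -> Optional[float]:
    """Interface conservation: Matthews CC between two label tracks."""
    return metrics(confusion_from_tracks(predicted, actual)).cc


def pr_sweep(
    predictions: Sequence[Sequence[Optional[float]]],
    truths: Sequence[LabelTrack],
    thresholds: Optional[Sequence[float]] = None,
) -> list[tuple[float, Optional[float], Optional[float]]]:
    """(threshold, pooled sensitivity, pooled precision) per distinct score.

    Majority-vote scores take only a few distinct values, so thresholds are
    exactly the scores present in the predictions (plus 0.0 so the sweep
    includes the call-everything point).  At threshold t a position scores
    positive when its vote score >= t; no-vote positions are negative at
    every threshold.
    """
    if thresholds is None:
        distinct = {0.0}
        for scores in predictions:
            distinct.update(s for s in scores if s is not None)
        thresholds = sorted(distinct)
    out = []
    for threshold in thresholds:
        tp = fp = fn = tn = 0
        for scores, truth in zip(predictions, truths):
            for s, a in zip(scores, truth.labels):
                if a == "?":
                    continue
                call = s is not None and s >= threshold
                if call and a == "1":
                    tp += 1
                elif call and a == "0":
                    fp += 1
                elif not call and a == "1":
                    fn += 1
                else:
                    tn += 1
        out.append((threshold, _ratio(tp, tp + fn), _ratio(tp, tp + fp)))
    return out
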