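"""Binary-classification evaluation for depression detection.

The reported quantities, with class 1 = depression:

* ``acc``   = (TP + TN) / N x 100 -- overall percent correct.
* ``pre``   = TP / (TP + FP) x 100 -- percent of depression calls that are
  correct (precision on the depressed class).
* ``error`` = FP / (TP + FP) x 100 -- percent of depression calls that are
  wrong; by construction ``pre`` and ``error`` are complementary and sum
  to 100.
* ``f1``    = harmonic mean of precision and recall on the depressed class,
  as a fraction in [0, 1].

Percentages are rounded half-up to two decimals and F1 to three, matching
the precision such results are conventionally printed at.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "accuracy",
    "precision_pct",
    "error_pct",
    "f1_score",
    "relative_improvement",
    "participant_majority",
    "evaluate",
    "format_table",
]


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN with class 1 = depression."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def cs(self) -> int:  # correctly detected samples
        return self.tp + self.tn

    @property
    def ts(self) -> int:  # total samples
        return self.tp + self.fp + self.fn + self.tn

    @property
    def csd(self) -> int:  # correctly detected as depression
        return self.tp

    @property
    def tsd(self) -> int:  # total detected as depression
        return self.tp + self.fp

    @property
    def msd(self) -> int:  # misjudged as depression
        return self.fp


def confusion(predicted, truth) -> ConfusionCounts:
    """Tabulate binary predictions against truth."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    for arr, name in ((predicted, "predicted"), (truth, "truth")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be 0 or 1")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    return ConfusionCounts(tp, fp, fn, tn)


def accuracy(c: ConfusionCounts) -> float:
    if c.ts == 0:
        raise ValueError("accuracy undefined with no samples")
    return _round_half_up(c.cs / c.ts * 100.0, 2)


def precision_pct(c: ConfusionCounts) -> float:
    if c.tsd == 0:
        raise ValueError("precision undefined with no depression calls")
    return _round_half_up(c.csd / c.tsd * 100.0, 2)


def error_pct(c: ConfusionCounts) -> float:
    """FP share of depression calls, reported as the exact complement of
    the rounded precision so that pre + error == 100.00 always holds
    (direct rounding of FP/(TP+FP) x 100 would differ by 0.01 when both
    quantities sit exactly on a half-cent boundary)."""
    if c.tsd == 0:
        raise ValueError("error undefined with no depression calls")
    return _round_half_up(100.0 - precision_pct(c), 2)


def f1_score(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0 or c.tp + c.fn == 0:
        raise ValueError("F1 undefined: no positive calls or no positive truth")
    p = c.tp / (c.tp + c.fp)
    r = c.tp / (c.tp + c.fn)
    if p + r == 0:
        return 0.0
    return _round_half_up(2 * p * r / (p + r), 3)


def relative_improvement(a: float, b: float) -> float:
    """Percent improvement of a over baseline b, one decimal."""
    if b <= 0:
        raise ValueError(f"baseline must be positive, got {b}")
    return _round_half_up((a - b) / b * 100.0, 1)


@dataclass
class MetricsReport:
    acc: float
    pre: float
    error: float
    f1: float
    footnotes: tuple = ()

    @classmethod
    def from_counts(cls, c: ConfusionCounts, footnotes=()) -> "MetricsReport":
        """Build a report, degrading gracefully when a metric is undefined
        (no depression calls, or no depressed truth): the strict metric
        functions raise, the report records NaN plus a footnote."""
        notes = list(footnotes)
        try:
            pre, err = precision_pct(c), error_pct(c)
        except ValueError:
            pre = err = float("nan")
            notes.append("precision/error undefined: no samples were "
                         "detected as depression")
        try:
            f1 = f1_score(c)
        except ValueError:
            f1 = float("nan")
            notes.append("F1 undefined: no depression calls or no depressed truth")
        return cls(acc=accuracy(c), pre=pre, error=err, f1=f1,
                   footnotes=tuple(notes))

    def to_json(self) -> str:
        d = asdict(self)
        d["footnotes"] = list(self.footnotes)
        return json.dumps(d, indent=2)


def evaluate(predicted, truth) -> MetricsReport:
    return MetricsReport.from_counts(confusion(predicted, truth))


def participant_majority(predicted, participant_ids):
    """Majority vote over each participant's segment predictions.

    Ties break toward class 0.  Returns (participant_id list, label array)
    in first-appearance order.
    """
    predicted = np.asarray(predicted)
    ids = list(participant_ids)
    if len(ids) != predicted.size:
        raise ValueError("one participant id per prediction required")
    order, votes = [], {}
    for pid, p in zip(ids, predicted):
        if pid not in votes:
            votes[pid] = []
            order.append(pid)
        votes[pid].append(int(p))
    labels = np.array(
        [1 if sum(votes[pid]) * 2 > len(votes[pid]) else 0 for pid in order]
    )
    return order, labels


def format_table(rows: dict) -> str:
    """Aligned text table of model -> MetricsReport, one model per row."""
    header = f"{'Model':<12}{'Acc (%)':>10}{'Pre (%)':>10}{'Error (%)':>11}{'F1':>8}"
    lines = [header, "-" * len(header)]
    notes = []
    for name, rep in rows.items():
        lines.append(
            f"{name:<12}{rep.acc:>10.2f}{rep.pre:>10.2f}{rep.error:>11.2f}"
            f"{rep.f1:>8.3f}"
        )
        notes.extend(rep.footnotes)
    for note in notes:
        lines.append(f"  note: {note}")
    return "\n".join(lines)
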