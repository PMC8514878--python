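"""PHQ-8 questionnaire scoring, binary depression labels, and manifest I/O.

The PHQ-8 instrument sums eight item scores (each 0-3) to a total of 0-24;
a total of 10 or more defines the depressed class.  Manifests are CSV files
with one participant per row carrying the item scores and, optionally, a
stated total and label.  Stated values that disagree with recomputation are
flagged with a warning rather than rejected -- published example tables
contain such inconsistencies -- and downstream code always uses the
recomputed score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ITEM_FIELDS",
    "PHQ8Record",
    "score_phq8",
    "binarize",
    "load_manifest",
    "save_manifest",
    "PHQ_THRESHOLD",
]

ITEM_FIELDS = (
    "no_interest",
    "depressed",
    "sleep",
    "tired",
    "appetite",
    "failure",
    "concentrating",
    "moving",
)

PHQ_THRESHOLD = 10  # total score >= 10 -> depressed class


def score_phq8(items) -> int:
    """Sum the eight item scores after validating count and range."""
    items = list(items)
    if len(items) != len(ITEM_FIELDS):
        raise ValueError(f"expected {len(ITEM_FIELDS)} items, got {len(items)}")
    for name, value in zip(ITEM_FIELDS, items):
        if int(value) != value or not 0 <= int(value) <= 3:
            raise ValueError(f"item {name!r} must be an integer in 0-3, got {value}")
    return int(sum(int(v) for v in items))


def binarize(score: int) -> int:
    """1 iff the total score reaches the depression threshold (>= 10)."""
    if int(score) != score or not 0 <= int(score) <= 24:
        raise ValueError(f"PHQ-8 total must be an integer in 0-24, got {score}")
    return int(int(score) >= PHQ_THRESHOLD)


@dataclass
class PHQ8Record:
    """One participant's questionnaire outcome."""

    participant_id: str
    gender: int
    items: tuple
    score: int = None
    label: int = None
    consistent: bool = True
    stated_score: int = None

    def __post_init__(self):
        self.items = tuple(int(v) for v in self.items)
        computed = score_phq8(self.items)
        if self.score is None:
            self.score = computed
        elif self.score != computed:
            raise ValueError(
                f"participant {self.participant_id}: stated score {self.score} "
                f"!= item sum {computed}"
            )
        self.label = binarize(self.score) if self.label is None else int(self.label)
        if self.label != binarize(self.score):
            raise ValueError(
                f"participant {self.participant_id}: label {self.label} "
                f"inconsistent with score {self.score}"
            )
        if self.gender not in (0, 1):
            raise ValueError(f"gender must be 0 or 1, got {self.gender}")


def load_manifest(path) -> list:
    """Read a participant manifest CSV into validated :class:`PHQ8Record`s.

    Required columns: ``participant_id``, ``gender`` and the eight item
    columns.  Optional ``score``/``label`` columns are checked against the
    recomputed values; a disagreement produces a warning and a record with
    ``consistent=False`` (the recomputed score and label are kept).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["participant_id", "gender", *ITEM_FIELDS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        items = [row[c] for c in ITEM_FIELDS]
        computed = score_phq8(items)
        consistent = True
        stated = None
        if "score" in df.columns and not pd.isna(row["score"]):
            stated = int(row["score"])
            if stated != computed:
                consistent = False
                warnings.warn(
                    f"participant {row['participant_id']}: stated PHQ-8 score "
                    f"{stated} disagrees with item sum {computed}; using the sum",
                    stacklevel=2,
                )
        if "label" in df.columns and not pd.isna(row["label"]):
            # the stated label may follow the stated score; recomputation wins
            if int(row["label"]) != binarize(computed) and consistent:
                consistent = False
                warnings.warn(
                    f"participant {row['participant_id']}: stated label "
                    f"{int(row['label'])} disagrees with recomputed label "
                    f"{binarize(computed)}",
                    stacklevel=2,
                )
        records.append(
            PHQ8Record(
                participant_id=str(row["participant_id"]),
                gender=int(row["gender"]),
                items=items,
                consistent=consistent,
                stated_score=stated,
            )
        )
    return records


def save_manifest(records, path) -> None:
    """Write records back to the CSV schema accepted by :func:`load_manifest`."""
    rows = []
    for r in records:
        row = {"participant_id": r.participant_id, "gender": r.gender}
        row.update({name: v for name, v in zip(ITEM_FIELDS, r.items)})
        row["score"] = r.score
        row["label"] = r.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
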