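"""Training/evaluation protocols and classification metrics.

Two protocols probe the classifier:

* **All-vs-All** — a uniform random 80/20 split of all usable cages; the
  same precursor may appear on both sides, so this mostly measures how
  well the model memorises per-precursor collapse propensity.
* **All-vs-One** — one entire reaction family is held out as the test set,
  probing transferability to precursors functionalised for an unseen
  chemistry.

"Collapsed" is the positive class throughout.  Records labelled
"undetermined" are excluded from both training and evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import train_test_split

from .model import COLLAPSED, NOT_COLLAPSED, CageCollapseClassifier

__all__ = [
    "REACTION_FAMILIES",
    "CageRecord",
    "ConfusionCounts",
    "MetricsReport",
    "determinate",
    "records_to_xy",
    "split_all_vs_all",
    "split_all_vs_one",
    "train",
    "evaluate",
    "confusion",
    "metrics",
    "aggregate_accuracy",
]

#: The six reaction chemistries pairing a tritopic building block with a
#: ditopic linker (functional group name + topicity).
REACTION_FAMILIES: tuple[str, ...] = (
    "aldehyde3amine2",
    "amine3aldehyde2",
    "alkene3alkene2",
    "alkyne3alkyne2",
    "acid3amine2",
    "amine3acid2",
)

LABELS = (COLLAPSED, NOT_COLLAPSED, "undetermined")


@dataclass(frozen=True)
class CageRecord:
    """One dataset row: a precursor pair, its reaction family and label."""

    bb_smiles: str
    linker_smiles: str
    reaction: str
    label: str | None = None
    cage_id: str = ""

    def __post_init__(self) -> None:
        if self.reaction not in REACTION_FAMILIES:
            raise ValueError(
                f"unknown reaction {self.reaction!r}; expected one of "
                f"{list(REACTION_FAMILIES)}"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {list(LABELS)}"
            )

    def with_label(self, label: str) -> "CageRecord":
        return replace(self, label=label)


def determinate(records: Sequence[CageRecord]) -> list[CageRecord]:
    """Drop "undetermined" (and unlabelled) records."""
    return [r for r in records if r.label in (COLLAPSED, NOT_COLLAPSED)]


def records_to_xy(records: Sequence[CageRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(building block, linker) pairs and labels as estimator inputs."""
    X = np.array(
        [(r.bb_smiles, r.linker_smiles) for r in records], dtype=object
    ).reshape(-1, 2)
    y = np.array([r.label for r in records], dtype=object)
    return X, y


def split_all_vs_all(
    records: Sequence[CageRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[CageRecord], list[CageRecord]]:
    """Uniform random split of the determinate records."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    usable = determinate(records)
    if not usable:
        raise ValueError("no determinate records to split")
    tr, te = train_test_split(
        usable, train_size=train_fraction, random_state=seed, shuffle=True
    )
    return list(tr), list(te)


def split_all_vs_one(
    records: Sequence[CageRecord], held_out_reaction: str
) -> tuple[list[CageRecord], list[CageRecord]]:
    """Hold one reaction family out entirely as the test set."""
    if held_out_reaction not in REACTION_FAMILIES:
        raise ValueError(
            f"unknown reaction {held_out_reaction!r}; valid families: "
            f"{list(REACTION_FAMILIES)}"
        )
    usable = determinate(records)
    test = [r for r in usable if r.reaction == held_out_reaction]
    train_ = [r for r in usable if r.reaction != held_out_reaction]
    if not test:
        raise ValueError(f"no records for held-out reaction {held_out_reaction!r}")
    return train_, test


def train(
    train_records: Sequence[CageRecord],
    seed: int = 0,
    **model_params,
) -> CageCollapseClassifier:
    """Fit a :class:`CageCollapseClassifier` on determinate records."""
    usable = determinate(train_records)
    if not usable:
        raise ValueError("empty training set")
    X, y = records_to_xy(usable)
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    est = CageCollapseClassifier(random_state=seed, **model_params)
    return est.fit(X, y)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with "collapsed" as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    predictions: Sequence[str], labels: Sequence[str]
) -> ConfusionCounts:
    """Count TP/FP/TN/FN; positive = "collapsed"."""
    if len(predictions) != len(labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(labels)} labels"
        )
    preds = np.asarray(predictions, dtype=object)
    labs = np.asarray(labels, dtype=object)
    bad = set(preds) | set(labs)
    if not bad <= {COLLAPSED, NOT_COLLAPSED}:
        raise ValueError(f"non-binary labels present: {bad}")
    pos_p = preds == COLLAPSED
    pos_l = labs == COLLAPSED
    return ConfusionCounts(
        tp=int(np.sum(pos_p & pos_l)),
        fp=int(np.sum(pos_p & ~pos_l)),
        tn=int(np.sum(~pos_p & ~pos_l)),
        fn=int(np.sum(~pos_p & pos_l)),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision, recall, specificity; NaN marks an undefined ratio."""

    accuracy: float
    precision: float
    recall: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Standard binary metrics from confusion counts.

    A ratio with zero denominator is reported as NaN, never silently as 0.
    """
    if counts.total == 0:
        raise ValueError("no evaluated records")
    return MetricsReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=_ratio(counts.tp, counts.tp + counts.fp),
        recall=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
    )


def evaluate(
    model: CageCollapseClassifier, test_records: Sequence[CageRecord]
) -> tuple[MetricsReport, ConfusionCounts]:
    """Predict on determinate test records and score."""
    usable = determinate(test_records)
    if not usable:
        raise ValueError("empty test set")
    X, y = records_to_xy(usable)
    counts = confusion(model.predict(X), y)
    return metrics(counts), counts


def aggregate_accuracy(
    task_accuracies: Sequence[float],
) -> tuple[float, float]:
    """Mean and Student-t 95% confidence half-width over per-task scores."""
    vals = np.asarray(task_accuracies, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 task accuracies to aggregate")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(len(vals)))
    half = float(stats.t.ppf(0.975, df=len(vals) - 1) * se)
    return mean, half
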