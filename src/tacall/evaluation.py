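"""Scoring calls against the gold standard.

Positive class is amplification throughout.  Classification is summarized by
the confusion matrix and accuracy, sensitivity, specificity, PPV and NPV; a
metric whose denominator is zero is reported as absent (``None``), never as
zero.

Ct error is the mean absolute difference between predicted and gold Ct over
the reactions the model *called* amplified.  For false positives — calls with
no gold Ct — the gold value is taken as the run length (Ct = 40 by default),
the convention for "no amplification within the run".  A second variant drops
the false positives entirely.  False negatives carry no predicted Ct and are
not part of the MAE denominator by default; an optional symmetric mode counts
them with a predicted Ct of 40.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .curve_io import CallRecord, ReactionLabel
from .errors import AlignmentError

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "metrics",
    "ct_mae",
    "flag_counts",
    "evaluate",
    "compare_analysts",
    "calls_to_labels",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with amplification as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_misclassified(self) -> int:
        return self.fp + self.fn


@dataclass
class EvalReport:
    """Classification metrics, Ct error, and flag counts for one call set."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    mae: float | None = None
    mae_excluding_misclassified: float | None = None
    n_misclassified: int | None = None
    n_flagged_misclassified: int | None = None
    n_flagged_correct: int | None = None
    confusion_matrix: ConfusionMatrix | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "mae": self.mae,
            "mae_excluding_misclassified": self.mae_excluding_misclassified,
            "n_misclassified": self.n_misclassified,
            "n_flagged_misclassified": self.n_flagged_misclassified,
            "n_flagged_correct": self.n_flagged_correct,
            "notes": self.notes,
        }
        if self.confusion_matrix is not None:
            cm = self.confusion_matrix
            d["confusion_matrix"] = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        return d


def _align(
    calls: Sequence[CallRecord], labels: Sequence[ReactionLabel]
) -> list[tuple[CallRecord, ReactionLabel]]:
    by_id = {lab.reaction_id: lab for lab in labels}
    if len(by_id) != len(labels):
        raise AlignmentError("duplicate reaction ids among labels")
    call_ids = {c.reaction_id for c in calls}
    if len(call_ids) != len(calls):
        raise AlignmentError("duplicate reaction ids among calls")
    missing = sorted(call_ids ^ set(by_id))
    if missing:
        raise AlignmentError(f"calls and labels do not align; mismatched ids: {missing}")
    return [(c, by_id[c.reaction_id]) for c in calls]


def confusion(
    calls: Sequence[CallRecord], labels: Sequence[ReactionLabel]
) -> ConfusionMatrix:
    """Cross-tabulate model calls against gold labels by reaction_id."""
    tp = fp = fn = tn = 0
    for call, lab in _align(calls, labels):
        if call.amplified and lab.amplified:
            tp += 1
        elif call.amplified and not lab.amplified:
            fp += 1
        elif not call.amplified and lab.amplified:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy, Se, Sp, PPV, NPV from a confusion matrix.

    Fields with a zero denominator are left absent, with a note.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    report = EvalReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        n_misclassified=cm.n_misclassified,
        confusion_matrix=cm,
    )
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        if getattr(report, name) is None:
            report.notes.append(f"{name} undefined: zero denominator")
    return report


def ct_mae(
    calls: Sequence[CallRecord],
    labels: Sequence[ReactionLabel],
    no_amp_ct: float = 40.0,
    include_false_negatives: bool = False,
) -> tuple[float | None, float | None]:
    """Mean absolute Ct error over model-called-amplified reactions.

    Returns ``(mae, mae_excluding_misclassified)``.  For false positives the
    gold Ct is substituted with ``no_amp_ct``; the excluding variant drops
    them.  With ``include_false_negatives`` the symmetric convention is used:
    missed amplifications enter with a predicted Ct of ``no_amp_ct`` (off by
    default).  Both values are ``None`` when no reactions qualify.
    """
    errors_all: list[float] = []
    errors_correct: list[float] = []
    for call, lab in _align(calls, labels):
        if call.amplified:
            gold = lab.ct if lab.amplified else no_amp_ct
            err = abs(call.ct - gold)
            errors_all.append(err)
            if lab.amplified:
                errors_correct.append(err)
        elif include_false_negatives and lab.amplified:
            errors_all.append(abs(no_amp_ct - lab.ct))
    mae = sum(errors_all) / len(errors_all) if errors_all else None
    mae_excl = sum(errors_correct) / len(errors_correct) if errors_correct else None
    return mae, mae_excl


def flag_counts(
    calls: Sequence[CallRecord], labels: Sequence[ReactionLabel]
) -> tuple[int, int]:
    """(flagged among misclassified, flagged among correctly classified)."""
    flagged_mis = flagged_ok = 0
    for call, lab in _align(calls, labels):
        if call.amplified != lab.amplified:
            flagged_mis += call.flagged
        else:
            flagged_ok += call.flagged
    return flagged_mis, flagged_ok


def evaluate(
    calls: Sequence[CallRecord],
    labels: Sequence[ReactionLabel],
    no_amp_ct: float = 40.0,
) -> EvalReport:
    """Full report: confusion metrics, Ct MAE variants, and flag counts."""
    cm = confusion(calls, labels)
    report = metrics(cm)
    mae, mae_excl = ct_mae(calls, labels, no_amp_ct=no_amp_ct)
    report.mae = mae
    report.mae_excluding_misclassified = mae_excl
    if mae is None:
        report.notes.append("mae undefined: no amplified calls")
    report.n_flagged_misclassified, report.n_flagged_correct = flag_counts(calls, labels)
    return report


def calls_to_labels(calls: Sequence[CallRecord]) -> list[ReactionLabel]:
    """View model calls as an analyst-style call table (amplified + Ct)."""
    return [
        ReactionLabel(c.reaction_id, c.amplified, c.ct if c.amplified else None)
        for c in calls
    ]


def compare_analysts(
    analysts: Mapping[str, Sequence[ReactionLabel]],
    gold: Sequence[ReactionLabel],
    automated: Sequence[CallRecord] | None = None,
    automated_name: str = "Automated Analysis",
    no_amp_ct: float = 40.0,
) -> pd.DataFrame:
    """Score each analyst's calls against gold, ordered worst to best.

    Each analyst table is a full set of amplified/Ct calls for the same
    reactions as ``gold``; missing or extra reactions raise
    :class:`AlignmentError` listing the ids.  The returned frame has one row
    per analyst (plus one for the automated model when given) with columns
    ``accuracy``, ``mae``, ``mae_excluding_misclassified``, sorted ascending
    by accuracy, ties broken by MAE (lower first).
    """
    gold_by_id = {lab.reaction_id: lab for lab in gold}
    rows = []

    def score(name: str, table: Sequence[ReactionLabel]) -> None:
        ids = {t.reaction_id for t in table}
        missing = sorted(set(gold_by_id) - ids)
        extra = sorted(ids - set(gold_by_id))
        if missing or extra:
            raise AlignmentError(
                f"analyst {name!r}: missing reactions {missing}, unknown {extra}"
            )
        n_correct = 0
        errors_all: list[float] = []
        errors_correct: list[float] = []
        for t in table:
            lab = gold_by_id[t.reaction_id]
            if t.amplified == lab.amplified:
                n_correct += 1
            if t.amplified:
                goldct = lab.ct if lab.amplified else no_amp_ct
                err = abs(t.ct - goldct)
                errors_all.append(err)
                if lab.amplified:
                    errors_correct.append(err)
        rows.append(
            {
                "analyst": name,
                "accuracy": n_correct / len(gold_by_id),
                "mae": sum(errors_all) / len(errors_all) if errors_all else None,
                "mae_excluding_misclassified": (
                    sum(errors_correct) / len(errors_correct) if errors_correct else None
                ),
            }
        )

    for name, table in analysts.items():
        score(name, table)
    if automated is not None:
        score(automated_name, calls_to_labels(automated))

    df = pd.DataFrame(rows, columns=["analyst", "accuracy", "mae",
                                     "mae_excluding_misclassified"])
    df = df.sort_values(
        ["accuracy", "mae"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
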