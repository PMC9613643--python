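"""Patient-level decision rule and onset-stratified evaluation reports.

The screening rule is *any-slice*: a subject is called ischemic as soon as
at least one of their slices is predicted ischemic, otherwise normal.
Reports stratify by stroke-onset group (≤6h, 6–12h) for ischemic subjects
and a separate stratum for normal subjects, mirroring the patient-wise
evaluation layout of the clinical study this pipeline models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .cnnmodel import SlicePrediction
from .ctio import SubjectSeries
from .evalmetrics import ConfusionCounts, confusion

__all__ = [
    "SubjectDecision",
    "StratumReport",
    "StratifiedReport",
    "decide_subject",
    "subject_accuracy",
    "build_report",
]

STRATA = ("≤6h", "6–12h", "normal")


@dataclass(frozen=True)
class SubjectDecision:
    subject_id: str
    predicted_class: str
    n_slices: int
    n_predicted_ischemic: int

    def __post_init__(self) -> None:
        want = "ischemic" if self.n_predicted_ischemic >= 1 else "normal"
        if self.predicted_class != want:
            raise ValueError("predicted_class inconsistent with the any-slice rule")


def decide_subject(preds: list[SlicePrediction]) -> SubjectDecision:
    """Any-slice rule: ischemic iff ≥1 slice is predicted ischemic."""
    if not preds:
        raise ValueError("no predictions for subject")
    sids = {p.subject_id for p in preds}
    if len(sids) > 1:
        raise ValueError(f"mixed subject ids in one decision: {sorted(sids)}")
    n_isch = sum(p.predicted_label == "ischemic" for p in preds)
    return SubjectDecision(
        subject_id=preds[0].subject_id,
        predicted_class="ischemic" if n_isch >= 1 else "normal",
        n_slices=len(preds),
        n_predicted_ischemic=n_isch,
    )


def subject_accuracy(decisions: list[SubjectDecision],
                     subject_truths: dict[str, str]) -> dict:
    """Fraction of subjects classified correctly, with per-class counts."""
    seen = set()
    for d in decisions:
        if d.subject_id in seen:
            raise ValueError(f"duplicate subject {d.subject_id}")
        seen.add(d.subject_id)
    n_correct = 0
    by_class = {"ischemic": [0, 0], "normal": [0, 0]}  # [correct, total]
    for d in decisions:
        truth = subject_truths[d.subject_id]
        by_class[truth][1] += 1
        if d.predicted_class == truth:
            n_correct += 1
            by_class[truth][0] += 1
    n = len(decisions)
    return {
        "n_subjects": n,
        "n_correct": n_correct,
        "accuracy": n_correct / n,
        "ischemic_correct": by_class["ischemic"][0],
        "ischemic_total": by_class["ischemic"][1],
        "normal_correct": by_class["normal"][0],
        "normal_total": by_class["normal"][1],
    }


@dataclass
class StratumReport:
    stratum: str
    n_subjects: int = 0
    n_slices: int = 0
    counts: ConfusionCounts = field(default_factory=ConfusionCounts)
    n_correct_subjects: int = 0

    @property
    def slice_accuracy(self) -> float | None:
        t = self.counts.total
        return None if t == 0 else (self.counts.tp + self.counts.tn) / t


@dataclass
class StratifiedReport:
    strata: list[StratumReport]
    overall_subject_accuracy: float
    n_subjects: int
    n_correct_subjects: int
    notes: list[str] = field(default_factory=list)

    def total_counts(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for s in self.strata:
            total = total + s.counts
        return total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            rows.append(
                {
                    "stroke_onset": s.stratum,
                    "n_patients": s.n_subjects,
                    "n_ncct_slices": s.n_slices,
                    "TP": s.counts.tp,
                    "FP": s.counts.fp,
                    "TN": s.counts.tn,
                    "FN": s.counts.fn,
                    "accuracy": s.slice_accuracy,
                    "n_correct_prediction": s.n_correct_subjects,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str) -> None:
        payload = {
            "strata": self.to_frame().to_dict(orient="records"),
            "overall_subject_accuracy": self.overall_subject_accuracy,
            "n_subjects": self.n_subjects,
            "n_correct_subjects": self.n_correct_subjects,
            "notes": self.notes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=2)


def build_report(series: list[SubjectSeries],
                 preds: list[SlicePrediction]) -> StratifiedReport:
    """Assemble the onset-stratified patient-wise evaluation report.

    Every prediction must belong to a listed subject; each subject's
    predictions feed both the stratum confusion table (slice level) and the
    any-slice subject decision.  Empty strata are omitted with a note.
    """
    by_subject: dict[str, list[SlicePrediction]] = {}
    known = {s.subject_id for s in series}
    orphans = sorted({p.subject_id for p in preds} - known)
    if orphans:
        raise ValueError(f"predictions for unknown subject(s): {orphans}")
    for p in preds:
        by_subject.setdefault(p.subject_id, []).append(p)

    strata = {name: StratumReport(stratum=name) for name in STRATA}
    n_correct_total = 0
    for subj in series:
        stratum = "normal" if subj.subject_label == "normal" else subj.onset_group
        if stratum not in strata:
            raise ValueError(f"subject {subj.subject_id}: unknown onset group {stratum!r}")
        rep = strata[stratum]
        sp = sorted(by_subject.get(subj.subject_id, []), key=lambda p: p.slice_index)
        if len(sp) != len(subj.slice_labels):
            raise ValueError(
                f"subject {subj.subject_id}: {len(sp)} predictions for "
                f"{len(subj.slice_labels)} slices"
            )
        rep.n_subjects += 1
        rep.n_slices += len(sp)
        rep.counts = rep.counts + confusion([p.predicted_label for p in sp], subj.slice_labels)
        decision = decide_subject(sp)
        if decision.predicted_class == subj.subject_label:
            rep.n_correct_subjects += 1
            n_correct_total += 1

    notes = [f"stratum {name} empty, omitted" for name, rep in strata.items()
             if rep.n_subjects == 0]
    kept = [rep for rep in strata.values() if rep.n_subjects > 0]
    n_subjects = sum(r.n_subjects for r in kept)
    return StratifiedReport(
        strata=kept,
        overall_subject_accuracy=n_correct_total / n_subjects if n_subjects else 0.0,
        n_subjects=n_subjects,
        n_correct_subjects=n_correct_total,
        notes=notes,
    )
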