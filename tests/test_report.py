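"""Any-slice subject rule, subject accuracy and the stratified report."""

import numpy as np
import pytest

from ncctscreen.cnnmodel import SlicePrediction
from ncctscreen.ctio import SubjectSeries
from ncctscreen.evalmetrics import compute_metrics, confusion
from ncctscreen.reference import EVAL_CONFUSION, EVAL_PATIENTS
from ncctscreen.report import (SubjectDecision, build_report, decide_subject,
                               subject_accuracy)


def _preds(subject_id, labels, start=0):
    return [
        SlicePrediction(subject_id=subject_id, slice_index=start + i,
                        score=1.0 if lab == "ischemic" else 0.0, predicted_label=lab)
        for i, lab in enumerate(labels)
    ]


class TestDecideSubject:
    def test_four_of_twenty_slices_flags_subject(self):
        preds = _preds("p1", ["ischemic"] * 4 + ["normal"] * 16)
        d = decide_subject(preds)
        assert d.predicted_class == "ischemic"
        assert d.n_slices == 20 and d.n_predicted_ischemic == 4

    def test_all_normal_slices_gives_normal(self):
        d = decide_subject(_preds("p2", ["normal"] * 12))
        assert d.predicted_class == "normal"

    def test_single_ischemic_slice_among_thirty_suffices(self):
        preds = _preds("p3", ["normal"] * 29 + ["ischemic"])
        assert decide_subject(preds).predicted_class == "ischemic"

    def test_monotone_in_added_ischemic_slice(self):
        base = _preds("p4", ["ischemic"] + ["normal"] * 5)
        more = base + _preds("p4", ["ischemic"], start=6)
        assert decide_subject(base).predicted_class == "ischemic"
        assert decide_subject(more).predicted_class == "ischemic"

    def test_mixed_subjects_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            decide_subject(_preds("a", ["normal"]) + _preds("b", ["normal"]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            decide_subject([])


class TestSubjectAccuracy:
    def test_evaluation_cohort_accuracy(self):
        """29/29 ischemic + 24/29 normal correct -> 53/58 = 91.37%."""
        decisions, truths = [], {}
        k = 0
        for n_subj, n_correct, label in ((29, 29, "ischemic"), (29, 24, "normal")):
            for j in range(n_subj):
                sid = f"{label}{j}"
                truths[sid] = label
                correct = j < n_correct
                if label == "ischemic":
                    pred = "ischemic" if correct else "normal"
                    n_isch = 1 if correct else 0
                else:
                    pred = "normal" if correct else "ischemic"
                    n_isch = 0 if correct else 1
                decisions.append(SubjectDecision(sid, pred, 20, n_isch))
        res = subject_accuracy(decisions, truths)
        assert res["n_correct"] == 53 and res["n_subjects"] == 58
        assert 100 * res["accuracy"] == pytest.approx(91.379, abs=0.01)
        assert res["ischemic_correct"] == 29 and res["normal_correct"] == 24

    def test_all_correct_is_100pct(self):
        d = [SubjectDecision("a", "ischemic", 5, 2)]
        assert subject_accuracy(d, {"a": "ischemic"})["accuracy"] == 1.0

    def test_none_correct_is_0pct(self):
        ds = [SubjectDecision(f"s{i}", "normal", 3, 0) for i in range(4)]
        truths = {f"s{i}": "ischemic" for i in range(4)}
        assert subject_accuracy(ds, truths)["accuracy"] == 0.0

    def test_duplicate_subject_rejected(self):
        ds = [SubjectDecision("a", "normal", 1, 0)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            subject_accuracy(ds, {"a": "normal"})


def _series(sid, subject_label, onset, slice_labels):
    return SubjectSeries(subject_id=sid, subject_label=subject_label,
                         onset_group=onset, slices=[None] * len(slice_labels),
                         slice_labels=slice_labels)


class TestBuildReport:
    def test_single_correct_subject(self):
        series = [_series("s1", "ischemic", "≤6h", ["ischemic"])]
        preds = _preds("s1", ["ischemic"])
        rep = build_report(series, preds)
        assert rep.overall_subject_accuracy == 1.0
        assert rep.strata[0].slice_accuracy == 1.0

    def test_empty_stratum_omitted_with_note(self):
        series = [_series("s1", "ischemic", "≤6h", ["ischemic", "normal"])]
        rep = build_report(series, _preds("s1", ["ischemic", "normal"]))
        assert all(s.stratum != "6–12h" for s in rep.strata)
        assert any("6–12h" in n for n in rep.notes)

    def test_orphan_predictions_rejected(self):
        series = [_series("s1", "normal", "n/a", ["normal"])]
        with pytest.raises(ValueError, match="unknown subject"):
            build_report(series, _preds("ghost", ["normal"]))

    def test_stratum_counts_conserve_cohort_confusion(self):
        rng = np.random.default_rng(4)
        series, preds, all_pred, all_truth = [], [], [], []
        for i in range(8):
            label = "ischemic" if i % 2 else "normal"
            onset = "≤6h" if i in (1, 3) else ("6–12h" if label == "ischemic" else "n/a")
            n = int(rng.integers(3, 8))
            truth = ["ischemic" if (label == "ischemic" and (j == 0 or rng.random() < 0.4))
                     else "normal" for j in range(n)]
            guess = ["ischemic" if rng.random() < 0.3 else "normal" for _ in range(n)]
            series.append(_series(f"s{i}", label, onset, truth))
            preds += _preds(f"s{i}", guess)
            all_pred += guess
            all_truth += truth
        rep = build_report(series, preds)
        assert rep.total_counts() == confusion(all_pred, all_truth)
        assert sum(s.n_slices for s in rep.strata) == len(all_truth)


class TestPublishedEvaluationTables:
    """The shipped evaluation fixtures reproduce every published rate."""

    def test_model_stratum_slice_accuracies(self):
        m = {k: compute_metrics(v) for k, v in EVAL_CONFUSION["cnn"].items()}
        assert round(m["≤6h"].accuracy, 2) == 0.75      # 320/425
        assert round(m["6–12h"].accuracy, 2) == 0.64    # 86/135
        assert round(m["normal"].accuracy, 2) == 0.95   # 582/610
        assert round(m["normal"].fp_rate, 2) == 0.05    # 28/610

    def test_radiologist_stratum_slice_accuracies(self):
        m = {k: compute_metrics(v) for k, v in EVAL_CONFUSION["radiologist"].items()}
        assert round(m["≤6h"].accuracy, 2) == 0.69      # 292/425
        assert round(m["6–12h"].accuracy, 2) == 0.62    # 84/135
        # 546/610 = 0.89508, printed truncated as 0.89
        assert m["normal"].accuracy == pytest.approx(0.89, abs=0.006)
        assert round(m["normal"].fp_rate, 2) == 0.10    # 64/610

    def test_pooled_ischemic_slice_sensitivity(self):
        # sensitivity and FN rate pool all ischemic slices (230, all from
        # ischemic patients); the published TN rate 206/330 pools only the
        # ischemic-patient strata
        pooled = EVAL_CONFUSION["cnn"]["≤6h"] + EVAL_CONFUSION["cnn"]["6–12h"]
        m = compute_metrics(pooled)
        assert round(100 * m.sensitivity, 2) == 86.96   # 200/230 slices
        assert round(m.fn_rate, 2) == 0.13              # 30/230
        assert round(m.tn_rate, 2) == 0.62              # 206/330

    def test_subject_correctness_columns_give_53_of_58(self):
        n = sum(v[0] for v in EVAL_PATIENTS["cnn"].values())
        correct = sum(v[1] for v in EVAL_PATIENTS["cnn"].values())
        assert (n, correct) == (58, 53)
        assert round(100 * correct / n, 2) == 91.38
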