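"""Published evaluation tables of the clinical screening study, as inputs.

The clinical NCCT data behind the original model are private, but the
study's printed evaluation tables — patient-wise confusion counts per
onset stratum (model and radiologist arms) and the per-fold derivation
metrics — are public numbers.  They are shipped here as structured inputs
so the metric suite can recompute every published rate from its published
counts, serving as exact worked examples and regression fixtures.
"""

from __future__ import annotations

import pandas as pd

from .evalmetrics import ConfusionCounts, MetricSet

__all__ = [
    "EVAL_CONFUSION",
    "EVAL_PATIENTS",
    "derivation_fold_table",
    "derivation_fold_metricsets",
    "MODEL_SELECTION_TABLE",
]

#: Patient-wise evaluation: slice-level confusion counts per onset stratum,
#: for the customized-VGG16 model arm and the radiologist reading arm.
EVAL_CONFUSION: dict[str, dict[str, ConfusionCounts]] = {
    "cnn": {
        "≤6h": ConfusionCounts(tp=161, fp=79, tn=159, fn=26),
        "6–12h": ConfusionCounts(tp=39, fp=45, tn=47, fn=4),
        "normal": ConfusionCounts(tp=0, fp=28, tn=582, fn=0),
    },
    "radiologist": {
        "≤6h": ConfusionCounts(tp=117, fp=63, tn=175, fn=70),
        "6–12h": ConfusionCounts(tp=26, fp=34, tn=58, fn=17),
        "normal": ConfusionCounts(tp=0, fp=64, tn=546, fn=0),
    },
}

#: Patient-wise evaluation: subjects per stratum and the number the
#: model/radiologists classified correctly under the any-slice rule.
EVAL_PATIENTS: dict[str, dict[str, tuple[int, int]]] = {
    # stratum: (n_subjects, n_correct)
    "cnn": {"≤6h": (22, 22), "6–12h": (7, 7), "normal": (29, 24)},
    "radiologist": {"≤6h": (22, 19), "6–12h": (7, 6), "normal": (29, 20)},
}

#: Tenfold derivation metrics of the customized model, one row per fold.
_FOLD_ROWS = [
    # fold, accuracy, precision, sensitivity, f_score, specificity, auc, ap
    (1, 0.85, 0.76, 0.93, 0.83, 0.79, 0.86, 0.87),
    (2, 0.79, 0.84, 0.66, 0.82, 0.90, 0.77, 0.75),
    (3, 0.84, 0.78, 0.87, 0.82, 0.81, 0.85, 0.84),
    (4, 0.82, 0.75, 0.85, 0.79, 0.79, 0.82, 0.83),
    (5, 0.81, 0.75, 0.79, 0.76, 0.82, 0.78, 0.80),
    (6, 0.89, 0.81, 0.96, 0.87, 0.84, 0.92, 0.92),
    (7, 0.92, 0.88, 0.95, 0.91, 0.90, 0.90, 0.87),
    (8, 0.83, 0.79, 0.80, 0.79, 0.85, 0.82, 0.80),
    (9, 0.84, 0.77, 0.88, 0.82, 0.81, 0.82, 0.81),
    (10, 0.79, 0.70, 0.86, 0.77, 0.74, 0.77, 0.77),
]

#: Single-fold model-selection comparison of the five candidate backbones.
MODEL_SELECTION_TABLE = pd.DataFrame(
    [
        ("VGG16", 0.80, 0.87, 0.71, 0.78, 0.89, 0.81, 0.75),
        ("Inception-v3", 0.79, 0.77, 0.74, 0.75, 0.83, 0.77, 0.77),
        ("Inception-v4", 0.75, 0.46, 0.60, 0.88, 0.71, 0.78, 0.61),
        ("IR-v2", 0.74, 0.92, 0.63, 0.74, 0.91, 0.78, 0.60),
        ("ResNet 50", 0.77, 0.66, 0.76, 0.70, 0.77, 0.78, 0.71),
    ],
    columns=["architecture", "accuracy", "precision", "sensitivity",
             "f_score", "specificity", "auc", "ap"],
)


def derivation_fold_table() -> pd.DataFrame:
    return pd.DataFrame(
        _FOLD_ROWS,
        columns=["fold", "accuracy", "precision", "sensitivity", "f_score",
                 "specificity", "auc", "ap"],
    )


def derivation_fold_metricsets() -> list[MetricSet]:
    """The ten published fold rows as MetricSet objects for aggregation."""
    return [
        MetricSet(accuracy=acc, precision=pre, sensitivity=sen, f_score=f,
                  specificity=spe, auc=auc, ap=ap,
                  fp_rate=round(1 - spe, 2), fn_rate=round(1 - sen, 2), tn_rate=spe)
        for _, acc, pre, sen, f, spe, auc, ap in _FOLD_ROWS
    ]
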