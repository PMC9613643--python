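"""Augmentation, tenfold slice-wise cross-validation, random hyper-search.

The cross-validation protocol: slices are shuffled into k=10 folds of
near-equal size; in iteration i, fold i is the test set and a fresh random
10% of the remaining slices becomes the validation set for early stopping,
the rest the training set.  Folding is slice-wise (the derivation protocol
of the study), which permits within-subject leakage across folds; a
subject-wise mode is available as an explicit deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .cnnmodel import HyperParams, ModelSpec, SliceClassifier, encode_labels
from .evalmetrics import (MetricSet, aggregate_folds, average_precision,
                          compute_metrics, confusion, roc_auc)

__all__ = [
    "AugmentSpec",
    "augment_slice",
    "augment_batch",
    "FoldAssignment",
    "make_folds",
    "SearchSpace",
    "random_search",
    "cross_validate",
    "CrossValidationResult",
]


@dataclass(frozen=True)
class AugmentSpec:
    """Stochastic augmentation applied to every training batch.

    Magnitudes follow the tuned configuration: intensity rescale to [0,1],
    uniform intensity ('channel') shift within ±8 gray levels, horizontal
    flip with probability ½, rotation within ±3°, zoom factor in [0.7, 1].
    """

    rescale: float = 1.0 / 255.0
    channel_shift: float = 8.0
    horizontal_flip: bool = True
    rotation_degrees: float = 3.0
    zoom_range: tuple[float, float] = (0.7, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.zoom_range
        if not (0.0 < lo <= hi <= 2.0):
            raise ValueError("zoom_range must satisfy 0 < lo <= hi <= 2")
        if self.rotation_degrees < 0 or self.channel_shift < 0:
            raise ValueError("rotation and channel shift must be non-negative")


def _zoom_about_center(img: np.ndarray, factor: float) -> np.ndarray:
    """Zoom keeping shape: <1 shrinks onto a zero canvas, >1 crops the center."""
    if factor == 1.0:
        return img
    h, w = img.shape
    zoomed = ndimage.zoom(img, factor, order=1, prefilter=False)
    zh, zw = zoomed.shape
    out = np.zeros_like(img)
    if factor < 1.0:
        r0, c0 = (h - zh) // 2, (w - zw) // 2
        out[r0 : r0 + zh, c0 : c0 + zw] = zoomed
    else:
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        out = zoomed[r0 : r0 + h, c0 : c0 + w]
    return out


def augment_slice(pixels: np.ndarray, aug: AugmentSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Augment one 8-bit slice; returns a float array in [0, 1].

    Order: rescale -> intensity shift -> horizontal flip -> rotation -> zoom,
    each magnitude sampled from ``rng``; the result is clipped to [0, 1].
    """
    x = pixels.astype(np.float32) * aug.rescale
    if aug.channel_shift > 0:
        x = x + rng.uniform(-aug.channel_shift, aug.channel_shift) * aug.rescale
    if aug.horizontal_flip and rng.random() < 0.5:
        x = x[:, ::-1]
    if aug.rotation_degrees > 0:
        angle = rng.uniform(-aug.rotation_degrees, aug.rotation_degrees)
        x = ndimage.rotate(x, angle, reshape=False, order=1, prefilter=False)
    lo, hi = aug.zoom_range
    if (lo, hi) != (1.0, 1.0):
        x = _zoom_about_center(x, float(rng.uniform(lo, hi)))
    return np.clip(x, 0.0, 1.0)


def augment_batch(batch01: np.ndarray, aug: AugmentSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Batch version for the training loop; input already rescaled to [0,1]."""
    shift_scale = 1.0 / 255.0  # shift magnitude is quoted in 8-bit gray levels
    out = np.empty_like(batch01)
    for i, img in enumerate(batch01):
        x = img.astype(np.float32)
        if aug.channel_shift > 0:
            x = x + rng.uniform(-aug.channel_shift, aug.channel_shift) * shift_scale
        if aug.horizontal_flip and rng.random() < 0.5:
            x = x[:, ::-1]
        if aug.rotation_degrees > 0:
            angle = rng.uniform(-aug.rotation_degrees, aug.rotation_degrees)
            x = ndimage.rotate(x, angle, reshape=False, order=1, prefilter=False)
        lo, hi = aug.zoom_range
        if (lo, hi) != (1.0, 1.0):
            x = _zoom_about_center(x, float(rng.uniform(lo, hi)))
        out[i] = np.clip(x, 0.0, 1.0)
    return out


@dataclass(frozen=True)
class FoldAssignment:
    """Slice -> fold map plus per-iteration train/validation/test roles."""

    k: int
    fold_of_slice: dict
    seed: int = 0

    def fold_members(self, fold: int) -> list:
        return [s for s, f in self.fold_of_slice.items() if f == fold]

    def iteration(self, i: int) -> tuple[list, list, list]:
        """(train_ids, val_ids, test_ids) for iteration i (folds numbered 1..k).

        The validation set is a fresh random 10% of the non-test slices,
        drawn with seed ``base_seed + i``.
        """
        if not 1 <= i <= self.k:
            raise ValueError(f"iteration must lie in 1..{self.k}")
        test = self.fold_members(i)
        rest = [s for s, f in self.fold_of_slice.items() if f != i]
        rng = np.random.default_rng(self.seed + i)
        n_val = int(round(0.10 * len(rest)))
        val_idx = set(rng.choice(len(rest), size=n_val, replace=False).tolist())
        val = [s for j, s in enumerate(rest) if j in val_idx]
        train = [s for j, s in enumerate(rest) if j not in val_idx]
        return train, val, test


def make_folds(slice_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Shuffle slices into k folds whose sizes differ by at most one."""
    ids = list(slice_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} slices, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("slice ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_of = {ids[j]: (pos % k) + 1 for pos, j in enumerate(order)}
    return FoldAssignment(k=k, fold_of_slice=fold_of, seed=seed)


@dataclass(frozen=True)
class SearchSpace:
    """Candidate ranges for random hyper-parameter search.

    ``ranges`` maps a HyperParams field to either a (low, high) tuple
    (log-uniform for learning_rate, uniform otherwise) or a list of
    discrete choices.
    """

    ranges: dict
    n_draws: int = 10
    seed: int = 0

    def draw(self) -> list[HyperParams]:
        rng = np.random.default_rng(self.seed)
        out = []
        for _ in range(self.n_draws):
            kw = {}
            for name, rng_spec in self.ranges.items():
                # tuple = continuous/integer range, list = discrete choices
                if isinstance(rng_spec, tuple) and len(rng_spec) == 2:
                    lo, hi = rng_spec
                    if name == "learning_rate":
                        kw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                    elif isinstance(lo, int) and isinstance(hi, int):
                        kw[name] = int(rng.integers(lo, hi + 1))
                    else:
                        kw[name] = float(rng.uniform(lo, hi))
                else:
                    kw[name] = rng_spec[int(rng.integers(len(rng_spec)))]
            out.append(replace(HyperParams(), **kw))
        return out


def random_search(space: SearchSpace, evaluate_fn) -> tuple[HyperParams, list[dict]]:
    """Draw configurations, evaluate each, pick the best.

    ``evaluate_fn(hp) -> (mean_val_loss, mean_accuracy)``; selection is
    lexicographic — smallest mean validation loss, ties broken by highest
    mean accuracy.  Failed draws are recorded and skipped.
    """
    if space.n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    leaderboard = []
    for i, hp in enumerate(space.draw()):
        try:
            val_loss, acc = evaluate_fn(hp)
            leaderboard.append({"draw": i, "hp": hp, "val_loss": float(val_loss),
                                "accuracy": float(acc), "failed": False})
        except Exception as exc:  # noqa: BLE001 - a failed draw must not kill the search
            leaderboard.append({"draw": i, "hp": hp, "val_loss": math.inf,
                                "accuracy": -math.inf, "failed": True, "error": str(exc)})
    ok = [row for row in leaderboard if not row["failed"]]
    if not ok:
        raise RuntimeError("every hyper-parameter draw failed")
    best = min(ok, key=lambda r: (r["val_loss"], -r["accuracy"]))
    return best["hp"], leaderboard


class CrossValidationResult:
    """Per-fold metrics plus the mean ± SD summary across folds."""

    def __init__(self, per_fold: list[MetricSet], fold_assignment: FoldAssignment | None = None):
        self.per_fold = per_fold
        self.fold_assignment = fold_assignment
        self.mean_sd = aggregate_folds(per_fold) if len(per_fold) > 1 else {}

    def summary(self):
        """DataFrame with one row per fold and a trailing mean ± SD row."""
        import pandas as pd

        rows = [{"fold": i + 1, **m.as_dict()} for i, m in enumerate(self.per_fold)]
        df = pd.DataFrame(rows)
        if self.mean_sd:
            avg = {"fold": "mean"}
            sd = {"fold": "sd"}
            for name, (m, s) in self.mean_sd.items():
                avg[name] = m
                sd[name] = s
            df = pd.concat([df, pd.DataFrame([avg, sd])], ignore_index=True)
        return df


def cross_validate(x: np.ndarray, labels, spec: ModelSpec, hp: HyperParams,
                   aug: "AugmentSpec | None" = None, k: int = 10, seed: int = 0,
                   slice_ids=None, early_stopping_patience: int = 3,
                   classifier_factory=None, warn=None) -> CrossValidationResult:
    """k-fold slice-wise cross-validation of the classifier.

    ``x`` is (N, H, W) in [0, 1]; ``labels`` are 'ischemic'/'normal'
    strings.  Per iteration a fresh model is trained on the train split
    with early stopping on the validation split and scored on the test
    fold with the full metric suite.  Folds whose test split contains a
    single class get AUC/AP recorded as undefined and excluded from the
    mean with a warning.
    """
    labels = list(labels)
    ids = list(slice_ids) if slice_ids is not None else list(range(len(labels)))
    folds = make_folds(ids, k=k, seed=seed)
    pos = {sid: j for j, sid in enumerate(ids)}
    y = encode_labels(labels)
    aug_fn = (lambda b, rng: augment_batch(b, aug, rng)) if aug is not None else None

    per_fold = []
    for i in range(1, k + 1):
        train_ids, val_ids, test_ids = folds.iteration(i)
        tr = np.array([pos[s] for s in train_ids])
        va = np.array([pos[s] for s in val_ids])
        te = np.array([pos[s] for s in test_ids])
        if classifier_factory is not None:
            model = classifier_factory(seed + i)
        else:
            model = SliceClassifier(spec, hp, seed=seed + i)
        if hasattr(model, "fit"):
            model.fit(x[tr], y[tr], x[va], y[va], augment_fn=aug_fn,
                      early_stopping_patience=early_stopping_patience)
        scores = model.scores(x[te])
        preds = ["ischemic" if s >= 0.5 else "normal" for s in scores]
        truth = [labels[j] for j in te]
        ms = compute_metrics(confusion(preds, truth))
        ms = replace(ms, auc=roc_auc(scores, truth), ap=average_precision(scores, truth))
        if (ms.auc is None or ms.ap is None) and warn is not None:
            warn(f"fold {i}: single-class test fold, AUC/AP undefined")
        per_fold.append(ms)
    return CrossValidationResult(per_fold, folds)
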