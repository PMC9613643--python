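"""The customized-VGG16 slice classifier: architecture, training, scoring.

The classification head replaces the stock VGG16 head: two dense layers
(1049 units by default), *each* followed by batch normalization and
dropout, and a 2-unit output with per-unit sigmoid activation trained with
categorical crossentropy against one-hot targets ([1,0] ischemic, [0,1]
normal) under Adam.  A ``small_cnn`` backbone provides a desk-scale model
with the same head structure for CPU-sized experiments and tests.

Exposed statsmodels-style: ``SliceClassifier`` is the model object;
``fit()`` returns a ``FitResult`` with the loss history and early-stopping
diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nnet

__all__ = [
    "ModelSpec",
    "HyperParams",
    "LABEL_ORDER",
    "encode_labels",
    "decode_labels",
    "SliceClassifier",
    "FitResult",
    "SlicePrediction",
    "build_model",
    "train",
    "predict_slices",
    "PretrainedWeightsUnavailable",
]

#: one-hot column order: [ischemic, normal]
LABEL_ORDER = ("ischemic", "normal")

#: VGG16 convolutional stack: 13 conv layers in five pooled blocks
VGG16_CONV_PLAN = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))

SMALL_CNN_PLAN = ((8, 1), (16, 1), (32, 1))


class PretrainedWeightsUnavailable(RuntimeError):
    """Raised when ImageNet-pretrained weights are requested but absent."""


@dataclass(frozen=True)
class ModelSpec:
    backbone: str = "vgg16"
    pretrained: bool = False
    allow_random_init: bool = True
    input_size: int = 224
    softmax_output: bool = False  # comparison switch; default is the sigmoid head

    def __post_init__(self) -> None:
        if self.backbone not in ("vgg16", "small_cnn"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.input_size < 32 or self.input_size % 32:
            raise ValueError("input_size must be a positive multiple of 32")


@dataclass(frozen=True)
class HyperParams:
    """Training configuration; defaults are the tuned optimum of the study."""

    learning_rate: float = 0.001
    batch_size: int = 8
    epochs: int = 4
    steps_per_epoch: int = 1000
    dropout: float = 0.5
    decay: float = 0.01
    epsilon: float = 1e-7
    momentum: float = 0.9  # mapped to Adam's first-moment coefficient
    dense_units: int = 1049

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs + 1,
               self.steps_per_epoch, self.decay + 1, self.epsilon,
               self.momentum, self.dense_units) <= 0:
            raise ValueError("hyper-parameters must be positive")
        if not 0.0 < self.dropout < 1.0:
            raise ValueError("dropout must lie in (0, 1)")


def encode_labels(labels) -> np.ndarray:
    """One-hot encode: ischemic -> [1,0], normal -> [0,1]."""
    out = np.zeros((len(labels), 2), dtype=np.float32)
    for i, lab in enumerate(labels):
        if lab not in LABEL_ORDER:
            raise ValueError(f"unknown label {lab!r}")
        out[i, LABEL_ORDER.index(lab)] = 1.0
    return out


def decode_labels(onehot: np.ndarray) -> list[str]:
    return [LABEL_ORDER[i] for i in np.asarray(onehot).argmax(axis=1)]


@dataclass(frozen=True)
class SlicePrediction:
    subject_id: str
    slice_index: int
    score: float  # renormalized ischemic probability in [0, 1]
    predicted_label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class FitResult:
    """Training diagnostics returned by SliceClassifier.fit()."""

    history: list[dict] = field(default_factory=list)  # per-epoch train/val loss
    stopped_early: bool = False
    best_epoch: int | None = None

    @property
    def final_val_loss(self) -> float | None:
        return self.history[-1]["val_loss"] if self.history else None

    def summary(self) -> str:
        lines = ["epoch  train_loss  val_loss"]
        for h in self.history:
            lines.append(f"{h['epoch']:>5d}  {h['train_loss']:>10.4f}  {h['val_loss']:>8.4f}")
        if self.stopped_early:
            lines.append(f"early stopping after epoch {self.history[-1]['epoch']}")
        return "\n".join(lines)


class SliceClassifier:
    """Binary ischemic/normal slice classifier over 8-bit grayscale input.

    Inputs to :meth:`fit`/:meth:`predict` are (N, H, W) arrays scaled to
    [0, 1].  The decision threshold on the ischemic score is 0.5, ties
    classified ischemic (screening favors sensitivity).
    """

    def __init__(self, spec: ModelSpec = ModelSpec(), hp: HyperParams = HyperParams(),
                 seed: int = 0) -> None:
        if spec.pretrained:
            if spec.allow_random_init:
                pass  # fall through to random init, explicitly sanctioned
            else:
                raise PretrainedWeightsUnavailable(
                    "ImageNet-pretrained backbone weights are not bundled; "
                    "set allow_random_init=True to proceed from random initialization"
                )
        self.spec, self.hp, self.seed = spec, hp, seed
        rng = np.random.default_rng(seed)
        plan = VGG16_CONV_PLAN if spec.backbone == "vgg16" else SMALL_CNN_PLAN
        layers: list[nnet.Layer] = []
        ch = 1
        size = spec.input_size
        for width, reps in plan:
            for _ in range(reps):
                layers += [nnet.Conv2D(ch, width, rng=rng), nnet.ReLU()]
                ch = width
            layers.append(nnet.MaxPool2D(2))
            size //= 2
        layers.append(nnet.Flatten())
        feat = ch * size * size
        for _ in range(2):  # the customized head: dense -> batchnorm -> dropout, twice
            layers += [
                nnet.Dense(feat, hp.dense_units, rng=rng),
                nnet.BatchNorm(hp.dense_units),
                nnet.Dropout(hp.dropout, rng=rng),
            ]
            feat = hp.dense_units
        head_out = nnet.Dense(feat, 2, rng=rng)
        # near-zero output init: both units start at p≈0.5, which avoids the
        # early saturation transient of the sigmoid/crossentropy output pair
        head_out.params[0] *= 0.05
        layers.append(head_out)
        if not spec.softmax_output:
            layers.append(nnet.Sigmoid())
        self.net = nnet.Network(layers)
        self._flat_features = ch * (spec.input_size // 2 ** len(plan)) ** 2
        self.fitted = False
        self._rng = rng

    # -- structure ---------------------------------------------------------
    def manifest(self) -> dict:
        """JSON-able architecture + hyper-parameter description."""
        return {
            "backbone": self.spec.backbone,
            "input_size": self.spec.input_size,
            "output_units": 2,
            "output_activation": "softmax" if self.spec.softmax_output else "sigmoid",
            "loss": "categorical_crossentropy",
            "optimizer": "adam",
            "hyper_parameters": asdict(self.hp),
            "layers": self.net.manifest(),
        }

    def save_manifest(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)

    def n_batchnorm_layers(self) -> int:
        return sum(1 for d in self.net.manifest() if d["type"] == "BatchNorm")

    # -- training ----------------------------------------------------------
    def _forward_probs(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = self.net.forward(x[:, None].astype(np.float32), training=training)
        if self.spec.softmax_output:
            e = np.exp(out - out.max(axis=1, keepdims=True))
            out = e / e.sum(axis=1, keepdims=True)
        return out

    def _eval_loss(self, x: np.ndarray, y: np.ndarray, batch: int = 32) -> float:
        total, n = 0.0, 0
        for i in range(0, len(x), batch):
            probs = self._forward_probs(x[i : i + batch], training=False)
            loss, _ = nnet.categorical_crossentropy(probs, y[i : i + batch])
            total += loss * len(probs)
            n += len(probs)
        return total / max(n, 1)

    def fit(self, x_train: np.ndarray, y_train: np.ndarray,
            x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
            augment_fn=None, early_stopping_patience: int = 3) -> FitResult:
        """Train with mini-batch Adam and early stopping on validation loss.

        ``augment_fn(batch, rng) -> batch`` is applied to every training
        batch when given.  Runs at most ``epochs * steps_per_epoch`` update
        steps; one "epoch" is ``min(steps_per_epoch, ceil(N/batch_size))``
        steps so small datasets are not recycled a thousand times.
        """
        if len(x_train) == 0:
            raise ValueError("empty training set")
        if y_train.ndim != 2 or y_train.shape[1] != 2:
            raise ValueError("labels must be one-hot encoded with two columns")
        if len(np.unique(y_train.argmax(axis=1))) < 2:
            import warnings

            warnings.warn("single-class training set: loss is defined but degenerate")
        hp = self.hp
        result = FitResult()
        if hp.epochs == 0:
            return result
        opt = nnet.Adam(self.net.params, lr=hp.learning_rate, beta1=hp.momentum,
                        eps=hp.epsilon, decay=hp.decay)
        rng = np.random.default_rng(self.seed + 1)
        n = len(x_train)
        steps = min(hp.steps_per_epoch, max(1, -(-n // hp.batch_size)))
        best_val, best_epoch, bad = np.inf, None, 0
        for epoch in range(1, hp.epochs + 1):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for step in range(steps):
                idx = order[(step * hp.batch_size) % n : (step * hp.batch_size) % n + hp.batch_size]
                if len(idx) < hp.batch_size:  # wrap around
                    idx = np.concatenate([idx, order[: hp.batch_size - len(idx)]])
                xb = x_train[idx]
                if augment_fn is not None:
                    xb = augment_fn(xb, rng)
                probs = self._forward_probs(xb, training=True)
                loss, grad = nnet.categorical_crossentropy(probs, y_train[idx])
                if self.spec.softmax_output:
                    # chain through softmax
                    s = probs
                    grad = s * (grad - (grad * s).sum(axis=1, keepdims=True))
                self.net.backward(grad)
                opt.step(self.net.grads)
                epoch_loss += loss
                seen += 1
            self._recalibrate(x_train, rng)
            val_loss = (self._eval_loss(x_val, y_val)
                        if x_val is not None and len(x_val) else float("nan"))
            result.history.append(
                {"epoch": epoch, "train_loss": epoch_loss / seen, "val_loss": val_loss}
            )
            if np.isfinite(val_loss):
                if val_loss < best_val - 1e-6:
                    best_val, best_epoch, bad = val_loss, epoch, 0
                else:
                    bad += 1
                    if bad >= early_stopping_patience:
                        result.stopped_early = True
                        break
        result.best_epoch = best_epoch
        self.fitted = True
        return result

    def _recalibrate(self, x_train: np.ndarray, rng: np.random.Generator,
                     max_samples: int = 256, batch: int = 32) -> None:
        """Refresh BatchNorm inference statistics on dropout-free batches."""
        n = min(len(x_train), max_samples)
        idx = rng.permutation(len(x_train))[:n]
        batches = [x_train[idx[i : i + batch]][:, None].astype(np.float32)
                   for i in range(0, n, batch) if i + 1 < n]
        self.net.recalibrate_batchnorm(batches)

    # -- inference ---------------------------------------------------------
    def scores(self, x: np.ndarray, batch: int = 32) -> np.ndarray:
        """Ischemic score per slice, in [0, 1].

        The categorical crossentropy constrains only the *relative*
        activation of the two sigmoid output units, so the score is the
        renormalized ischemic probability p_isch/(p_isch + p_norm); a 0.5
        threshold on it is then the argmax decision the loss optimizes.
        """
        out = []
        for i in range(0, len(x), batch):
            p = self._forward_probs(x[i : i + batch], training=False)
            out.append(p[:, 0] / np.clip(p.sum(axis=1), 1e-12, None))
        return np.clip(np.concatenate(out) if out else np.empty(0), 0.0, 1.0)

    def predict(self, x: np.ndarray, threshold: float = 0.5,
                subject_ids=None, slice_indices=None) -> list[SlicePrediction]:
        s = self.scores(x)
        subject_ids = subject_ids if subject_ids is not None else [""] * len(s)
        slice_indices = slice_indices if slice_indices is not None else list(range(len(s)))
        return [
            SlicePrediction(
                subject_id=str(sid),
                slice_index=int(k),
                score=float(v),
                predicted_label="ischemic" if v >= threshold else "normal",
            )
            for sid, k, v in zip(subject_ids, slice_indices, s)
        ]

    def save(self, path: str) -> None:
        self.net.save(path)

    def load(self, path: str) -> None:
        self.net.load(path)
        self.fitted = True


# -- functional aliases matching the pipeline vocabulary -------------------

def build_model(spec: ModelSpec = ModelSpec(), hp: HyperParams = HyperParams(),
                seed: int = 0) -> SliceClassifier:
    return SliceClassifier(spec, hp, seed=seed)


def train(model: SliceClassifier, train_set, val_set, hp: HyperParams | None = None,
          augment_fn=None, early_stopping_patience: int = 3) -> tuple[SliceClassifier, FitResult]:
    """Functional wrapper: train ``model`` on (x, y) tuples; returns (model, history)."""
    if hp is not None and hp != model.hp:
        raise ValueError("hyper-parameters are fixed at model construction; rebuild the model")
    x_val, y_val = val_set if val_set is not None else (None, None)
    res = model.fit(*train_set, x_val, y_val, augment_fn=augment_fn,
                    early_stopping_patience=early_stopping_patience)
    return model, res


def predict_slices(model: SliceClassifier, slices: np.ndarray, threshold: float = 0.5,
                   subject_ids=None, slice_indices=None) -> list[SlicePrediction]:
    return model.predict(slices, threshold=threshold, subject_ids=subject_ids,
                         slice_indices=slice_indices)
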