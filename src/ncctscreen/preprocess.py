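"""Slice preprocessing: skull removal, noise/PSNR, denoising, brain cropping.

The chain runs on windowed 8-bit slices and is order-enforced through the
``GraySlice.stage`` tag:

    windowed -> skull_stripped -> (noisy -> denoised, optional) -> cropped

Skull stripping is morphological: bone saturates the brain window, so a
high binary threshold isolates the calvarial ring, and erosion + opening on
the complementary brain candidate detaches falx calcification and any
residual rim before masking and a final low-intensity floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology, restoration
from skimage.measure import label as cc_label

from . import nnet
from .ctio import GraySlice

__all__ = [
    "EmptyImageError",
    "SkullStripParams",
    "NoiseSpec",
    "PSNRReport",
    "BBox",
    "strip_skull",
    "add_gaussian_noise",
    "psnr",
    "denoise",
    "crop_brain",
    "DnCNNDenoiser",
    "train_dncnn_on_phantoms",
    "DENOISE_METHODS",
]


class EmptyImageError(ValueError):
    """Raised when an operation receives an all-zero image."""


@dataclass(frozen=True)
class SkullStripParams:
    skull_threshold: int = 250
    erosion_radius: int = 3
    opening_radius: int = 5
    final_pixel_threshold: int = 10
    keep_largest_component: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.skull_threshold <= 255 and 0 <= self.final_pixel_threshold <= 255):
            raise ValueError("thresholds must lie in [0, 255]")
        if self.erosion_radius < 1 or self.opening_radius < 1:
            raise ValueError("structuring-element radii must be >= 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise on the normalized [0, 1] intensity scale."""

    mean: float = 0.0
    variance: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be non-negative")


@dataclass(frozen=True)
class PSNRReport:
    mse: float
    psnr_db: float
    max_value: int = 255

    @property
    def identical(self) -> bool:
        return self.mse == 0.0


@dataclass(frozen=True)
class BBox:
    """Inclusive nonzero bounding box: rows [xmin..xmax], cols [ymin..ymax]."""

    xmin: int
    xmax: int
    ymin: int
    ymax: int

    def __post_init__(self) -> None:
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError("degenerate bounding box")


def strip_skull(sl: GraySlice, p: SkullStripParams = SkullStripParams()
                ) -> tuple[GraySlice, np.ndarray, np.ndarray]:
    """Remove the bony skull (and falx calcification) from a windowed slice.

    Four stages, in order: (1) binary threshold at ``skull_threshold``
    isolates the saturated bone; (2) erosion then morphological opening of
    the brain-candidate region detaches thin calcifications and the outer
    rim (keeping the largest connected component when enabled); (3) the
    slice is multiplied by the resulting brain mask; (4) every pixel below
    ``final_pixel_threshold`` is zeroed.

    Returns ``(stripped_slice, skull_mask, brain_mask)``.  Never increases
    any pixel value.
    """
    img = sl.pixels
    if not img.any():
        raise EmptyImageError("empty image: all pixels zero")

    skull_mask = img >= p.skull_threshold
    if not skull_mask.any():
        # nothing saturates the window: degrade gracefully, keep foreground
        brain_mask = img > 0
    else:
        candidate = (img > 0) & ~skull_mask
        eroded = morphology.erosion(candidate, morphology.disk(p.erosion_radius))
        opened = morphology.opening(eroded, morphology.disk(p.opening_radius))
        if p.keep_largest_component and opened.any():
            lab = cc_label(opened, connectivity=2)
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            opened = lab == sizes.argmax()
        # restore the eroded brain rim; (A⊖r)⊕r ⊆ A, so bone cannot re-enter
        brain_mask = morphology.dilation(opened, morphology.disk(p.erosion_radius)) & candidate

    out = img * brain_mask
    out = np.where(out < p.final_pixel_threshold, 0, out).astype(np.uint8)
    # stripping a noisy/denoised slice keeps its (later) stage tag
    stage = "skull_stripped" if sl.stage == "windowed" else sl.stage
    return sl.advance(out, stage), skull_mask, brain_mask


def add_gaussian_noise(sl: GraySlice, spec: NoiseSpec = NoiseSpec()) -> GraySlice:
    """Corrupt a skull-stripped slice with seeded Gaussian noise.

    Intensities are rescaled to [0, 1], i.i.d. N(mean, variance) noise is
    added, values are clipped back to [0, 1] and requantized to 8 bits.
    """
    if spec.variance == 0.0 and spec.mean == 0.0:
        return sl.advance(sl.pixels.copy(), "noisy")
    rng = np.random.default_rng(spec.seed)
    x = sl.pixels.astype(np.float64) / 255.0
    x = x + rng.normal(spec.mean, math.sqrt(spec.variance), size=x.shape)
    out = np.clip(np.floor(x * 255.0 + 0.5), 0, 255).astype(np.uint8)
    return sl.advance(out, "noisy")


def psnr(reference: GraySlice | np.ndarray, test: GraySlice | np.ndarray,
         max_value: int = 255) -> PSNRReport:
    """Peak signal-to-noise ratio, 10*log10(max_value^2 / MSE), in dB."""
    a = reference.pixels if isinstance(reference, GraySlice) else np.asarray(reference)
    b = test.pixels if isinstance(test, GraySlice) else np.asarray(test)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))
    if mse == 0.0:
        return PSNRReport(mse=0.0, psnr_db=math.inf, max_value=max_value)
    return PSNRReport(mse=mse, psnr_db=10.0 * math.log10(max_value**2 / mse),
                      max_value=max_value)


class DnCNNDenoiser:
    """Residual-learning convolutional denoiser.

    The network sees a noisy slice in [0, 1] and predicts the *noise*; the
    estimate is subtracted from the input.  Architecture: Conv+ReLU, then
    ``depth``−2 Conv+BatchNorm+ReLU blocks, then a final Conv back to one
    channel; all kernels 3x3, 'same' padding.
    """

    def __init__(self, depth: int = 8, width: int = 16, seed: int = 0) -> None:
        if depth < 2:
            raise ValueError("DnCNN depth must be >= 2")
        rng = np.random.default_rng(seed)
        layers: list[nnet.Layer] = [nnet.Conv2D(1, width, rng=rng), nnet.ReLU()]
        for _ in range(depth - 2):
            layers += [nnet.Conv2D(width, width, rng=rng), nnet.BatchNorm(width), nnet.ReLU()]
        final = nnet.Conv2D(width, 1, rng=rng)
        # near-zero projection: the network starts as the identity denoiser
        # (zero predicted residual) and learns the noise from there, which
        # removes a strong initialization-seed dependence of the final PSNR
        final.params[0] *= 0.1
        layers.append(final)
        self.net = nnet.Network(layers)
        self.depth, self.width = depth, width
        self.trained = False

    def denoise_array(self, img01: np.ndarray) -> np.ndarray:
        x = img01[None, None].astype(np.float32)
        residual = self.net.forward(x, training=False)[0, 0]
        return np.clip(img01 - residual, 0.0, 1.0)

    def save(self, path: str) -> None:
        self.net.save(path)

    def load(self, path: str) -> None:
        self.net.load(path)
        self.trained = True


def train_dncnn_on_phantoms(clean_slices: list[np.ndarray], noise: NoiseSpec,
                            depth: int = 8, width: int = 16, patch: int = 32,
                            steps: int = 1200, batch_size: int = 24,
                            lr: float = 2e-3, lr_decay: float = 0.002,
                            seed: int = 0) -> DnCNNDenoiser:
    """Train a residual denoiser on clean/noisy patch pairs.

    ``clean_slices`` are 8-bit arrays (typically skull-stripped phantoms);
    for every step a batch of random patches — biased toward patches with
    at least 30% tissue content, where the denoising problem actually
    lives — is corrupted with fresh Gaussian noise of the given spec and
    the network regresses the noise with an MSE loss under Adam.
    """
    rng = np.random.default_rng(seed)
    model = DnCNNDenoiser(depth=depth, width=width, seed=seed)
    opt = nnet.Adam(model.net.params, lr=lr, decay=lr_decay)
    sd = math.sqrt(noise.variance)
    imgs = [s.astype(np.float32) / 255.0 for s in clean_slices]
    fgs = [img > 0 for img in imgs]
    for _ in range(steps):
        batch = np.empty((batch_size, 1, patch, patch), dtype=np.float32)
        for b in range(batch_size):
            j = int(rng.integers(len(imgs)))
            img = imgs[j]
            for _try in range(10):
                r = int(rng.integers(0, img.shape[0] - patch + 1))
                c = int(rng.integers(0, img.shape[1] - patch + 1))
                if fgs[j][r : r + patch, c : c + patch].mean() > 0.3:
                    break
            batch[b, 0] = img[r : r + patch, c : c + patch]
        eta = rng.normal(noise.mean, sd, size=batch.shape).astype(np.float32)
        noisy = np.clip(batch + eta, 0.0, 1.0)
        target = noisy - batch  # effective noise after clipping
        pred = model.net.forward(noisy, training=True)
        _, grad = nnet.mse_loss(pred, target)
        model.net.backward(grad)
        opt.step(model.net.grads)
    model.trained = True
    return model


DENOISE_METHODS = ("median", "gaussian", "bilateral", "dncnn")


def denoise(sl: GraySlice, method: str = "dncnn", *,
            dncnn: DnCNNDenoiser | None = None,
            median_size: int = 3, gaussian_sigma: float = 0.5,
            bilateral_sigma_color: float = 0.1, bilateral_sigma_spatial: float = 2.0,
            ) -> GraySlice:
    """Denoise a noisy slice with a conventional filter or the trained DnCNN."""
    if method not in DENOISE_METHODS:
        raise ValueError(f"unknown denoise method {method!r}; choose from {DENOISE_METHODS}")
    x = sl.pixels.astype(np.float64) / 255.0
    if method == "median":
        out = ndimage.median_filter(x, size=median_size)
    elif method == "gaussian":
        out = ndimage.gaussian_filter(x, sigma=gaussian_sigma)
    elif method == "bilateral":
        out = restoration.denoise_bilateral(
            x, sigma_color=bilateral_sigma_color, sigma_spatial=bilateral_sigma_spatial
        )
    else:
        if dncnn is None or not dncnn.trained:
            raise ValueError("untrained denoiser: pass a trained DnCNNDenoiser")
        out = dncnn.denoise_array(x.astype(np.float32))
    out8 = np.clip(np.floor(out * 255.0 + 0.5), 0, 255).astype(np.uint8)
    return sl.advance(out8, "denoised")


def crop_brain(sl: GraySlice) -> tuple[GraySlice, BBox]:
    """Crop to the inclusive bounding box of all nonzero pixels."""
    img = sl.pixels
    rows = np.flatnonzero(img.any(axis=1))
    cols = np.flatnonzero(img.any(axis=0))
    if rows.size == 0:
        raise EmptyImageError("empty image: nothing to crop")
    box = BBox(int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1]))
    out = img[box.xmin : box.xmax + 1, box.ymin : box.ymax + 1]
    return sl.advance(out, "cropped"), box
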