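"""End-to-end glue: phantom cohort -> preprocessed, model-ready arrays.

Used by the CLI, the examples and the test harness.  Each HU slice is
windowed, skull-stripped, optionally noise/denoise processed, cropped to
the brain bounding box and resized to the classifier input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .ctio import GraySlice, HUSlice, SubjectSeries, WindowSpec, apply_window, read_hu_png
from .preprocess import (DnCNNDenoiser, NoiseSpec, SkullStripParams,
                         add_gaussian_noise, crop_brain, denoise, strip_skull)

__all__ = ["SliceDataset", "preprocess_slice", "prepare_dataset"]


@dataclass
class SliceDataset:
    """Flat, model-ready view of a cohort."""

    x: np.ndarray  # (N, H, W) float32 in [0, 1]
    labels: list[str]
    slice_ids: list[str]
    subject_ids: list[str]
    slice_indices: list[int]

    def __len__(self) -> int:
        return len(self.labels)

    def subject_truths(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for sid, lab in zip(self.subject_ids, self.labels):
            if lab == "ischemic":
                out[sid] = "ischemic"
            elif sid not in out:
                out[sid] = "normal"
        return out


def preprocess_slice(hu: HUSlice, window: WindowSpec = WindowSpec(),
                     strip: SkullStripParams | None = SkullStripParams(),
                     noise: NoiseSpec | None = None, denoiser_method: str | None = None,
                     dncnn: DnCNNDenoiser | None = None, crop: bool = True) -> GraySlice:
    """Run one HU slice through the preprocessing chain."""
    sl = apply_window(hu, window)
    if strip is not None:
        sl, _, _ = strip_skull(sl, strip)
    if noise is not None:
        sl = add_gaussian_noise(sl, noise)
        if denoiser_method is not None:
            sl = denoise(sl, denoiser_method, dncnn=dncnn)
    if crop:
        sl, _ = crop_brain(sl)
    return sl


def prepare_dataset(series: list[SubjectSeries], input_size: int = 64,
                    window: WindowSpec = WindowSpec(),
                    strip: SkullStripParams | None = SkullStripParams(),
                    crop: bool = True) -> SliceDataset:
    """Window/strip/crop every slice of a cohort and resize for the model.

    ``series`` slices may be HUSlice objects (in-memory phantoms) or paths
    to 16-bit HU PNGs written by the phantom module.
    """
    xs, labels, slice_ids, subject_ids, slice_indices = [], [], [], [], []
    for subj in series:
        for k, (sl, lab) in enumerate(zip(subj.slices, subj.slice_labels)):
            hu = read_hu_png(sl) if isinstance(sl, str) else sl
            g = preprocess_slice(hu, window=window, strip=strip, crop=crop)
            img = resize(g.pixels.astype(np.float32) / 255.0,
                         (input_size, input_size), order=1, anti_aliasing=True)
            xs.append(img.astype(np.float32))
            labels.append(lab)
            slice_ids.append(f"{subj.subject_id}:{k}")
            subject_ids.append(subj.subject_id)
            slice_indices.append(k)
    return SliceDataset(
        x=np.stack(xs) if xs else np.empty((0, input_size, input_size), dtype=np.float32),
        labels=labels,
        slice_ids=slice_ids,
        subject_ids=subject_ids,
        slice_indices=slice_indices,
    )
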