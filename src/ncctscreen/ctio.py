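"""Slice containers, DICOM/raster reading, brain-window conversion and cohort manifests.

Axial head-CT slices live in two representations: calibrated Hounsfield
units (HU) straight from DICOM, and the 8-bit grayscale produced by a
brain-window transform.  Every preprocessing stage tags its output so the
pipeline order (windowed -> skull_stripped -> noisy -> denoised -> cropped)
is machine-checkable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "STAGES",
    "FormatError",
    "ManifestError",
    "HUSlice",
    "WindowSpec",
    "GraySlice",
    "SubjectSeries",
    "read_dicom_slice",
    "apply_window",
    "read_gray_image",
    "write_gray_png",
    "write_hu_png",
    "read_hu_png",
    "load_manifest",
    "save_manifest",
]

HU_MIN = -1024
HU_MAX = 3071

#: forward-only provenance chain for 8-bit slices
STAGES = ("windowed", "skull_stripped", "noisy", "denoised", "cropped")

#: offset used when persisting HU data in unsigned 16-bit PNGs
_HU_PNG_OFFSET = 1024

MANIFEST_COLUMNS = (
    "subject_id",
    "slice_index",
    "path",
    "slice_label",
    "subject_label",
    "onset_group",
)


class FormatError(ValueError):
    """Raised for files that are not single-frame square CT images."""


class ManifestError(ValueError):
    """Raised for manifests that violate the subject/slice label contract."""


@dataclass
class HUSlice:
    """A single axial slice in Hounsfield units."""

    pixels: np.ndarray
    subject_id: str = ""
    slice_index: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise FormatError(f"HU slice must be square 2-D, got {self.pixels.shape}")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Linear HU -> gray display window (brain/sinus window by default)."""

    center: float = 40.0
    width: float = 150.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def lower(self) -> float:
        return self.center - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.center + self.width / 2.0


@dataclass
class GraySlice:
    """An 8-bit windowed slice with its preprocessing stage tag."""

    pixels: np.ndarray
    stage: str = "windowed"
    subject_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            if self.pixels.min(initial=0) < 0 or self.pixels.max(initial=0) > 255:
                raise ValueError("gray pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.pixels.ndim != 2:
            raise FormatError(f"gray slice must be 2-D, got {self.pixels.shape}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    def advance(self, pixels: np.ndarray, stage: str) -> "GraySlice":
        """Return a copy at a later pipeline stage; backward moves are rejected."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage may not move backwards: {self.stage} -> {stage}")
        return GraySlice(pixels, stage=stage, subject_id=self.subject_id, slice_index=self.slice_index)


@dataclass
class SubjectSeries:
    """Ordered slices of one subject with subject- and slice-level labels."""

    subject_id: str
    subject_label: str
    onset_group: str = "n/a"
    slices: list = field(default_factory=list)
    slice_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.subject_label not in ("ischemic", "normal"):
            raise ValueError(f"unknown subject label {self.subject_label!r}")
        self.validate()

    def validate(self) -> None:
        if len(self.slices) != len(self.slice_labels):
            raise ManifestError(
                f"subject {self.subject_id}: {len(self.slices)} slices but "
                f"{len(self.slice_labels)} labels"
            )
        bad = [l for l in self.slice_labels if l not in ("ischemic", "normal")]
        if bad:
            raise ManifestError(f"subject {self.subject_id}: unknown slice labels {bad}")
        n_isch = sum(l == "ischemic" for l in self.slice_labels)
        if self.subject_label == "normal" and n_isch:
            raise ManifestError(
                f"normal subject {self.subject_id} carries {n_isch} ischemic slice label(s)"
            )
        if self.subject_label == "ischemic" and self.slice_labels and n_isch == 0:
            raise ManifestError(
                f"ischemic subject {self.subject_id} has no ischemic slice label"
            )

    def __len__(self) -> int:
        return len(self.slices)


def read_dicom_slice(path: str | os.PathLike) -> HUSlice:
    """Read a single-frame CT DICOM file and rescale stored values to HU.

    HU = RescaleSlope * stored + RescaleIntercept.  Files missing pixel data
    or the rescale tags, non-CT modalities and non-square frames are rejected.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if "PixelData" not in ds:
        raise FormatError(f"{path}: no PixelData element")
    modality = getattr(ds, "Modality", None)
    if modality is not None and modality != "CT":
        raise FormatError(f"{path}: modality {modality!r}, expected CT")
    for tag in ("RescaleSlope", "RescaleIntercept"):
        if tag not in ds:
            raise FormatError(f"{path}: missing required tag {tag}")
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single frame, got shape {arr.shape}")
    if arr.shape[0] != arr.shape[1]:
        raise FormatError(f"{path}: non-square frame {arr.shape}")
    hu = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
    return HUSlice(
        hu,
        subject_id=str(getattr(ds, "PatientID", "")),
        slice_index=int(getattr(ds, "InstanceNumber", 0) or 0),
        source=str(path),
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # numpy's round() is round-half-even; the display convention here is half-up
    return np.floor(x + 0.5)


def apply_window(hu_slice: HUSlice, window: WindowSpec = WindowSpec()) -> GraySlice:
    """Map HU onto 256 gray levels through a display window.

    g = round(255 * (hu - lower) / width) clipped to [0, 255]; HU at the
    window center maps to 128 (half-up rounding of 127.5).
    """
    g = 255.0 * (hu_slice.pixels - window.lower) / window.width
    g = np.clip(_round_half_up(g), 0, 255).astype(np.uint8)
    return GraySlice(
        g, stage="windowed", subject_id=hu_slice.subject_id, slice_index=hu_slice.slice_index
    )


def read_gray_image(path: str | os.PathLike, stage: str = "windowed") -> GraySlice:
    """Read an 8-bit grayscale raster slice (PNG or JPEG)."""
    with Image.open(str(path)) as im:
        arr = np.asarray(im.convert("L"), dtype=np.uint8)
    return GraySlice(arr, stage=stage)


def write_gray_png(sl: GraySlice, path: str | os.PathLike) -> None:
    Image.fromarray(sl.pixels, mode="L").save(str(path), format="PNG")


def write_hu_png(sl: HUSlice, path: str | os.PathLike) -> None:
    """Persist HU losslessly as 16-bit PNG, offset by +1024 so air maps to 0."""
    arr = np.clip(sl.pixels, HU_MIN, HU_MAX) + _HU_PNG_OFFSET
    Image.fromarray(_round_half_up(arr).astype(np.uint16)).save(str(path), format="PNG")


def read_hu_png(path: str | os.PathLike) -> HUSlice:
    with Image.open(str(path)) as im:
        arr = np.asarray(im, dtype=np.float64) - _HU_PNG_OFFSET
    return HUSlice(arr, source=str(path))


def load_manifest(path: str | os.PathLike, check_files: bool = False) -> list[SubjectSeries]:
    """Load a cohort manifest CSV into SubjectSeries, grouped and ordered.

    Required columns: subject_id, slice_index, path, slice_label,
    subject_label, onset_group.  Slice pixel data are NOT loaded here; the
    `path` column is carried through so callers load images lazily.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} missing columns {missing}")

    bad = df[(df.subject_label == "normal") & (df.slice_label == "ischemic")]
    if len(bad):
        rows = bad.index.tolist()
        raise ManifestError(
            f"manifest {path}: normal subject(s) with ischemic slice labels at rows {rows}"
        )
    if check_files:
        absent = [p for p in df.path if not os.path.exists(p)]
        if absent:
            raise IOError(f"manifest {path}: {len(absent)} slice file(s) missing, e.g. {absent[0]}")

    series = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("slice_index")
        labels = set(grp.subject_label)
        groups = set(grp.onset_group)
        if len(labels) > 1 or len(groups) > 1:
            raise ManifestError(f"subject {sid}: inconsistent subject_label/onset_group rows")
        series.append(
            SubjectSeries(
                subject_id=str(sid),
                subject_label=labels.pop(),
                onset_group=groups.pop(),
                slices=list(grp.path),
                slice_labels=list(grp.slice_label),
            )
        )
    return series


def save_manifest(series: list[SubjectSeries], path: str | os.PathLike) -> None:
    rows = []
    for s in series:
        for i, (sl, lab) in enumerate(zip(s.slices, s.slice_labels)):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "slice_index": i,
                    "path": sl if isinstance(sl, str) else "",
                    "slice_label": lab,
                    "subject_label": s.subject_label,
                    "onset_group": s.onset_group,
                }
            )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
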