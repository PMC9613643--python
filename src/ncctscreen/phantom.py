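"""Synthetic 2-D head-CT phantoms with ground-truth masks.

The study data this pipeline targets are private clinical scans, so every
test and demonstration runs on seeded phantoms instead: a bright calvarial
ring (optionally with a thin falx calcification line), soft-tissue brain
parenchyma with CSF-filled ventricles, and optional subtle hypodense
lesions whose contrast against surrounding parenchyma is only a few HU —
the regime in which early ischemia is hard to see on non-contrast CT.

Phantoms are deliberately geometric (discs and ellipses), not atlas-based:
they give exact ground truth for skull, brain, ventricle and lesion pixels,
which is what the preprocessing and classification tests need.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ctio import HUSlice, SubjectSeries, save_manifest, write_hu_png

__all__ = [
    "GeometryError",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
]

AIR_HU = -1000.0


class GeometryError(ValueError):
    """Raised when a phantom specification describes impossible geometry."""


@dataclass(frozen=True)
class EllipseSpec:
    """Axis-aligned ellipse in (row, col) pixel coordinates."""

    center: tuple[float, float]
    radii: tuple[float, float]
    hu: float = 6.0  # CSF-range attenuation

    def mask(self, size: int) -> np.ndarray:
        rr, cc = np.ogrid[:size, :size]
        r0, c0 = self.center
        ar, ac = self.radii
        return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float]
    radius: float
    hu_delta: float = -8.0  # subtle hypodensity
    axis_ratio: float = 1.0  # 1 -> disc; <1 -> ellipse

    def __post_init__(self) -> None:
        if self.hu_delta >= 0:
            raise GeometryError("lesion hu_delta must be negative (hypodense)")
        if self.radius <= 0:
            raise GeometryError("lesion radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic axial slice, in HU."""

    image_size: int = 512
    skull_outer_radius: float = 230.0
    skull_thickness: float = 14.0
    skull_hu: float = 1000.0
    brain_hu_mean: float = 35.0
    brain_hu_sd: float = 1.5
    ventricles: tuple[EllipseSpec, ...] = None  # default pair set in __post_init__
    falx_calcification: bool = False
    falx_hu: float = 300.0
    falx_length: float = 0.5  # fraction of inner radius, anterior midline
    lesion: LesionSpec | None = None
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.skull_thickness < self.skull_outer_radius < self.image_size / 2):
            raise GeometryError(
                "require skull_thickness < skull_outer_radius < image_size/2, got "
                f"{self.skull_thickness} / {self.skull_outer_radius} / {self.image_size}"
            )
        if self.ventricles is None:
            object.__setattr__(self, "ventricles", default_ventricles(self))
        if self.lesion is not None:
            r0, c0 = self.lesion.center
            ctr = self.image_size / 2.0
            inner = self.skull_outer_radius - self.skull_thickness
            # lesion disc must lie fully inside the brain disc
            d = np.hypot(r0 - ctr, c0 - ctr)
            if d + self.lesion.radius >= inner:
                raise GeometryError(
                    f"lesion (center {self.lesion.center}, r={self.lesion.radius}) "
                    f"extends outside the brain (inner radius {inner:.1f})"
                )


def default_ventricles(spec: PhantomSpec) -> tuple[EllipseSpec, ...]:
    """Two paramedian lateral-ventricle ellipses scaled to the brain size."""
    ctr = spec.image_size / 2.0
    inner = spec.skull_outer_radius - spec.skull_thickness
    off = 0.14 * inner
    return (
        EllipseSpec(center=(ctr - 0.05 * inner, ctr - off), radii=(0.30 * inner, 0.08 * inner)),
        EllipseSpec(center=(ctr - 0.05 * inner, ctr + off), radii=(0.30 * inner, 0.08 * inner)),
    )


@dataclass
class PhantomTruth:
    """Ground-truth masks aligned with a generated slice."""

    skull_mask: np.ndarray
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    lesion_mask: np.ndarray

    def validate(self) -> None:
        pairs = [
            (self.skull_mask, self.brain_mask),
            (self.skull_mask, self.ventricle_mask),
            (self.brain_mask, self.ventricle_mask),
        ]
        for a, b in pairs:
            if np.any(a & b):
                raise GeometryError("truth masks overlap")
        if np.any(self.lesion_mask & ~self.brain_mask):
            raise GeometryError("lesion mask escapes the brain mask")


def generate_phantom(spec: PhantomSpec) -> tuple[HUSlice, PhantomTruth]:
    """Render one phantom slice and its truth masks.

    Pixel model: air background at −1000 HU; skull ring at ``skull_hu``;
    parenchyma at ``brain_hu_mean`` with per-pixel texture of SD
    ``brain_hu_sd``; ventricles at CSF attenuation; the lesion region is
    offset by ``hu_delta`` through a Gaussian-smoothed (σ=1 px) profile so
    its edge is subtle; additive Gaussian scanner noise of SD ``noise_sd``
    everywhere.  Identical spec+seed produces bit-identical output.
    """
    n = spec.image_size
    rng = np.random.default_rng(spec.seed)
    ctr = n / 2.0
    rr, cc = np.ogrid[:n, :n]
    dist = np.hypot(rr - ctr, cc - ctr)

    inner = spec.skull_outer_radius - spec.skull_thickness
    skull_mask = (dist <= spec.skull_outer_radius) & (dist > inner)
    head_mask = dist <= inner

    img = np.full((n, n), AIR_HU)
    img[skull_mask] = spec.skull_hu
    texture = rng.normal(spec.brain_hu_mean, spec.brain_hu_sd, size=(n, n))
    img[head_mask] = texture[head_mask]

    ventricle_mask = np.zeros((n, n), dtype=bool)
    for v in spec.ventricles:
        ventricle_mask |= v.mask(n)
    ventricle_mask &= head_mask
    img[ventricle_mask] = spec.ventricles[0].hu

    falx_mask = np.zeros((n, n), dtype=bool)
    if spec.falx_calcification:
        # thin bright anterior midline segment, attached to the inner table
        length = spec.falx_length * inner
        col = int(round(ctr))
        r0 = int(round(ctr - inner + 2))
        r1 = int(round(r0 + length))
        falx_mask[r0:r1, col - 1 : col + 2] = True
        falx_mask &= head_mask
        img[falx_mask] = spec.falx_hu

    brain_mask = head_mask & ~ventricle_mask & ~falx_mask

    lesion_mask = np.zeros((n, n), dtype=bool)
    if spec.lesion is not None:
        les = spec.lesion
        r0, c0 = les.center
        ar = les.radius
        ac = les.radius * les.axis_ratio
        hard = (((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2) <= 1.0
        profile = ndimage.gaussian_filter(hard.astype(float), sigma=1.0)
        img += les.hu_delta * profile
        lesion_mask = hard & brain_mask

    img += rng.normal(0.0, spec.noise_sd, size=(n, n))

    truth = PhantomTruth(
        skull_mask=skull_mask | falx_mask,
        brain_mask=brain_mask,
        ventricle_mask=ventricle_mask,
        lesion_mask=lesion_mask,
    )
    # falx is reported with the skull (it is removed with it); exclude it
    # from brain for the disjointness contract
    truth.validate()
    return HUSlice(img), truth


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level phantom parameters.

    Defaults mirror the derivation-pool composition of the target study
    scaled to whatever subject counts the caller requests: 25–40 slices
    per examination, with roughly 60% of an ischemic patient's slices
    carrying a lesion (1631 ischemic of 1631+476 slices contributed by
    ischemic patients) and a 69:31 split between onset groups.
    """

    n_ischemic_subjects: int = 5
    n_normal_subjects: int = 1
    slices_per_subject_range: tuple[int, int] = (25, 40)
    fraction_ischemic_slices_per_patient: float = 0.6
    onset_group_mix: tuple[float, float] = (0.69, 0.31)  # (≤6h, 6–12h)
    image_size: int = 512
    lesion_hu_delta: float = -8.0
    lesion_radius_range: tuple[float, float] = (0.03, 0.18)  # fraction of inner radius
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.slices_per_subject_range
        if self.n_ischemic_subjects < 0 or self.n_normal_subjects < 0:
            raise ValueError("subject counts must be non-negative")
        if self.n_ischemic_subjects + self.n_normal_subjects == 0:
            raise ValueError("empty cohort: zero subjects requested in both arms")
        if not (1 <= lo <= hi <= 64):
            raise ValueError("slices_per_subject_range must lie within [1, 64]")
        if not 0.0 <= self.fraction_ischemic_slices_per_patient <= 1.0:
            raise ValueError("fraction_ischemic_slices_per_patient must lie in [0, 1]")
        if abs(sum(self.onset_group_mix) - 1.0) > 1e-9 or min(self.onset_group_mix) < 0:
            raise ValueError("onset_group_mix must be non-negative and sum to 1")


def _random_lesion(rng: np.random.Generator, spec_size: int, inner: float,
                   hu_delta: float,
                   radius_range: tuple[float, float] = (0.03, 0.18)) -> LesionSpec:
    ctr = spec_size / 2.0
    lo, hi = radius_range
    radius = float(rng.uniform(lo * inner, hi * inner))  # incl. small lacunar
    max_d = inner - radius - 2.0
    d = float(rng.uniform(0.0, 0.8 * max_d))
    theta = float(rng.uniform(0.0, 2.0 * np.pi))
    center = (ctr + d * np.sin(theta), ctr + d * np.cos(theta))
    return LesionSpec(center=center, radius=radius, hu_delta=hu_delta,
                      axis_ratio=float(rng.uniform(0.7, 1.0)))


def generate_cohort(cohort: CohortSpec) -> tuple[list[SubjectSeries], list[list[PhantomTruth]]]:
    """Generate a whole cohort of subject series plus per-slice truth.

    Each ischemic subject receives at least one lesion-bearing slice; normal
    subjects receive none.  Slice labels are derived from the truth masks,
    never assigned independently.
    """
    rng = np.random.default_rng(cohort.seed)
    lo, hi = cohort.slices_per_subject_range
    series: list[SubjectSeries] = []
    truths: list[list[PhantomTruth]] = []

    arms = [("ischemic", i) for i in range(cohort.n_ischemic_subjects)] + [
        ("normal", i) for i in range(cohort.n_normal_subjects)
    ]
    for subject_label, idx in arms:
        sid = f"{'isch' if subject_label == 'ischemic' else 'norm'}-{idx:04d}"
        n_slices = int(rng.integers(lo, hi + 1))
        if subject_label == "ischemic":
            n_lesion = max(1, int(round(cohort.fraction_ischemic_slices_per_patient * n_slices)))
            lesion_slots = rng.choice(n_slices, size=min(n_lesion, n_slices), replace=False)
            onset = "≤6h" if rng.random() < cohort.onset_group_mix[0] else "6–12h"
        else:
            lesion_slots = np.empty(0, dtype=int)
            onset = "n/a"
        slots = set(int(s) for s in lesion_slots)

        slices, labels, subject_truth = [], [], []
        # default 512-px geometry scales linearly with image size
        scale = cohort.image_size / 512.0
        outer = 230.0 * scale
        thickness = max(3.0, 14.0 * scale)
        inner = outer - thickness
        for k in range(n_slices):
            slice_seed = int(rng.integers(0, 2**31 - 1))
            while True:
                lesion = None
                if k in slots:
                    lesion = _random_lesion(rng, cohort.image_size, inner,
                                            cohort.lesion_hu_delta,
                                            cohort.lesion_radius_range)
                spec = PhantomSpec(
                    image_size=cohort.image_size,
                    skull_outer_radius=outer,
                    skull_thickness=thickness,
                    lesion=lesion,
                    noise_sd=cohort.noise_sd,
                    seed=slice_seed,
                )
                hu, truth = generate_phantom(spec)
                # a lesion swallowed whole by a ventricle leaves no labelled
                # brain pixels; redraw its placement
                if lesion is None or truth.lesion_mask.any():
                    break
            hu.subject_id = sid
            hu.slice_index = k
            slices.append(hu)
            labels.append("ischemic" if truth.lesion_mask.any() else "normal")
            subject_truth.append(truth)
        series.append(
            SubjectSeries(
                subject_id=sid,
                subject_label=subject_label,
                onset_group=onset,
                slices=slices,
                slice_labels=labels,
            )
        )
        truths.append(subject_truth)
    return series, truths


def _mask_to_rle(mask: np.ndarray) -> dict:
    """Row-major run-length encoding; compact JSON-able truth sidecar."""
    flat = mask.ravel(order="C").astype(np.int8)
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [flat.size])))
    return {
        "shape": list(mask.shape),
        "first_value": int(flat[0]),
        "run_lengths": lengths.tolist(),
    }


def write_cohort(series: list[SubjectSeries], truths: list[list[PhantomTruth]],
                 outdir: str | os.PathLike) -> str:
    """Persist a cohort: 16-bit HU PNGs, JSON truth sidecars, CSV manifest.

    Returns the manifest path.  HU values are offset by +1024 in the PNGs.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    manifest_series = []
    for subj, subj_truths in zip(series, truths):
        paths = []
        for k, (hu, truth) in enumerate(zip(subj.slices, subj_truths)):
            stem = os.path.join(outdir, f"{subj.subject_id}_{k:03d}")
            write_hu_png(hu, stem + ".png")
            sidecar = {
                name: _mask_to_rle(getattr(truth, name))
                for name in ("skull_mask", "brain_mask", "ventricle_mask", "lesion_mask")
            }
            with open(stem + ".truth.json", "w") as fh:
                json.dump(sidecar, fh)
            paths.append(stem + ".png")
        manifest_series.append(
            SubjectSeries(
                subject_id=subj.subject_id,
                subject_label=subj.subject_label,
                onset_group=subj.onset_group,
                slices=paths,
                slice_labels=list(subj.slice_labels),
            )
        )
    manifest = os.path.join(outdir, "manifest.csv")
    save_manifest(manifest_series, manifest)
    return manifest
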