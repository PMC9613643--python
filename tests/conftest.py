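"""Shared fixtures: seeded phantoms and (expensively) trained models.

Session-scoped so the trained classifier and denoiser are built once and
reused across the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import ncctscreen as ncs
from ncctscreen.cnnmodel import HyperParams, ModelSpec, SliceClassifier, encode_labels
from ncctscreen.pipeline import prepare_dataset
from ncctscreen.preprocess import NoiseSpec, add_gaussian_noise, strip_skull, train_dncnn_on_phantoms


@pytest.fixture(scope="session")
def phantom_slice():
    """One default-geometry 512-px phantom with a visible lesion."""
    from ncctscreen.phantom import LesionSpec

    spec = ncs.PhantomSpec(
        lesion=LesionSpec(center=(300.0, 300.0), radius=20.0, hu_delta=-8.0), seed=11
    )
    hu, truth = ncs.generate_phantom(spec)
    return spec, hu, truth


@pytest.fixture(scope="session")
def stripped_phantoms():
    """Twenty-eight small clean skull-stripped phantom slices: 8 train + 20 eval."""
    out = []
    for seed in range(28):
        spec = ncs.PhantomSpec(
            image_size=128, skull_outer_radius=55.0, skull_thickness=5.0,
            noise_sd=1.0, seed=seed,
        )
        hu, truth = ncs.generate_phantom(spec)
        sl, _, _ = strip_skull(ncs.apply_window(hu))
        out.append((sl, truth))
    return out


@pytest.fixture(scope="session")
def trained_dncnn(stripped_phantoms):
    """A residual denoiser trained on the first 8 phantom slices.

    Evaluation slices (indices 8+) stay held out.
    """
    train_imgs = [sl.pixels for sl, _ in stripped_phantoms[:8]]
    return train_dncnn_on_phantoms(
        train_imgs, NoiseSpec(variance=0.001), depth=4, width=16,
        patch=32, steps=1200, batch_size=24, lr=2e-3, seed=0,
    )


@pytest.fixture(scope="session")
def easy_cohort():
    """An easy-contrast phantom cohort (~250–300 slices) for learning tests."""
    cohort = ncs.CohortSpec(
        n_ischemic_subjects=5, n_normal_subjects=4, image_size=128,
        lesion_hu_delta=-40.0, lesion_radius_range=(0.08, 0.2),
        noise_sd=1.0, seed=7,
    )
    series, truths = ncs.generate_cohort(cohort)
    return cohort, series, truths


@pytest.fixture(scope="session")
def easy_dataset(easy_cohort):
    _, series, _ = easy_cohort
    return prepare_dataset(series, input_size=64)


@pytest.fixture(scope="session")
def trained_easy_model(easy_dataset):
    """small_cnn trained on the easy cohort; returns (model, splits dict)."""
    ds = easy_dataset
    rng = np.random.default_rng(0)
    order = rng.permutation(len(ds))
    test, rest = order[:50], order[50:]
    val, tr = rest[:25], rest[25:]
    y = encode_labels(ds.labels)
    model = SliceClassifier(
        ModelSpec(backbone="small_cnn", input_size=64),
        HyperParams(epochs=4, dense_units=64), seed=1,
    )
    result = model.fit(ds.x[tr], y[tr], ds.x[val], y[val], early_stopping_patience=3)
    return model, {"train": tr, "val": val, "test": test}, result
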