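# ncctscreen

Early ischemic lesions are often invisible, or nearly so, on the
non-contrast head CT (NCCT) taken at emergency presentation — the exam that
decides whether a stroke patient is triaged toward thrombolysis.
`ncctscreen` is a reimplementation of a deep-learning screening pipeline
for this problem: it preprocesses axial NCCT slices, classifies each slice
as *ischemic* or *normal* with a customized-VGG16 convolutional network,
and calls a patient ischemic as soon as **any** of their slices is flagged
(the any-slice rule). It is aimed at researchers who want a tested,
reproducible skeleton of such a pipeline — the clinical images behind the
original model are private, so the package ships a seeded synthetic
head-CT phantom generator that stands in for them end to end.

## What is inside

- **`phantom`** — seeded 2-D head-CT phantoms in Hounsfield units (skull
  ring, parenchyma, ventricles, optional falx calcification and subtle
  hypodense lesions) with exact ground-truth masks, plus whole cohorts
  (25–40 slices per subject) written as 16-bit PNG + JSON sidecars + CSV
  manifest.
- **`ctio`** — DICOM reading (rescale slope/intercept → HU), the
  brain/sinus display window (center 40 HU, width 150 HU) onto 256 gray
  levels, raster I/O and cohort manifests.
- **`preprocess`** — four-step morphological skull stripping (binary
  threshold → erosion + opening → masking → pixel floor), seeded Gaussian
  noise (mean 0, variance 0.001 on the [0,1] scale), PSNR scoring, four
  denoisers (median / Gaussian / bilateral / a trainable residual "DnCNN"),
  and nonzero-bounding-box brain cropping.
- **`cnnmodel`** — the customized-VGG16 classifier: 13-conv backbone, a
  head of two dense layers (1049 units) each followed by batch
  normalization and dropout 0.5, a 2-unit sigmoid output trained with
  categorical crossentropy on one-hot labels ([1,0] ischemic, [0,1]
  normal) under Adam (lr 0.001, batch 8, 4 epochs × 1000 steps, decay
  0.01, ε 1e-7, first-moment 0.9). A `small_cnn` backbone provides the
  same head at desk scale. Implemented on a compact numpy CNN engine
  (`nnet`) with finite-difference-verified gradients.
- **`traincv`** — the tuned augmentation (rescale 1/255, intensity shift
  ±8, horizontal flip, ±3° rotation, zoom 0.7–1.0), tenfold slice-wise
  cross-validation with a nested 10% validation split and early stopping,
  and random hyper-parameter search.
- **`evalmetrics`** — confusion counts and the nine-metric suite: FP/FN/TN
  rates, sensitivity, specificity, precision, accuracy, F-score, ROC-AUC
  (tie-aware concordance) and step-function average precision.
- **`report`** — the any-slice subject decision, subject accuracy, and the
  onset-stratified (≤6 h / 6–12 h / normal) patient-wise evaluation table.
- **`reference`** — the published evaluation tables of the original
  clinical study (stratum confusion counts for the model and radiologist
  arms; per-fold derivation metrics) shipped as structured *inputs* so the
  metric suite can recompute every published rate from its counts.

## Worked example

```python
import ncctscreen as ncs
from ncctscreen.pipeline import prepare_dataset
from ncctscreen.cnnmodel import SliceClassifier, ModelSpec, HyperParams, encode_labels
from ncctscreen.traincv import cross_validate

cohort = ncs.CohortSpec(n_ischemic_subjects=5, n_normal_subjects=4,
                        image_size=128, lesion_hu_delta=-40.0,
                        lesion_radius_range=(0.08, 0.2), noise_sd=1.0, seed=7)
series, truths = ncs.generate_cohort(cohort)          # 9 subjects, 307 slices
ds = prepare_dataset(series, input_size=64)           # window→strip→crop→resize

cv = cross_validate(ds.x, ds.labels,
                    ModelSpec(backbone="small_cnn", input_size=64),
                    HyperParams(epochs=4, dense_units=64),
                    k=10, seed=42, slice_ids=ds.slice_ids,
                    early_stopping_patience=3)
mean, sd = cv.mean_sd["accuracy"]
print(f"tenfold accuracy {mean:.3f} ± {sd:.3f}")
```

On this easy-contrast phantom cohort (lesions at −40 HU, far stronger than
real early ischemia) the run prints

```
tenfold accuracy 0.981 ± 0.017
```

meaning the desk-scale model separates lesion-bearing from normal phantom
slices almost perfectly — a sanity check of the learning machinery, not a
clinical claim. The published evaluation numbers can be recomputed from
the published confusion counts:

```python
from ncctscreen.evalmetrics import compute_metrics
from ncctscreen.reference import EVAL_CONFUSION
m = compute_metrics(EVAL_CONFUSION["cnn"]["≤6h"])
print(round(m.accuracy, 2))   # 0.75  (= 320/425 slices, onset ≤ 6 h)
```

A CLI covers the same ground:

```bash
ncctscreen simulate --ischemic 5 --normal 4 --image-size 128 \
    --lesion-delta -40 --seed 7 --out cohort/
ncctscreen crossval --manifest cohort/manifest.csv --k 10 --seed 42 --out cv.csv
ncctscreen report --out table.csv
```

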