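# Methods

## The pipeline

`autocontour` reproduces a per-organ deep-learning autocontouring workflow
for head-and-neck planning CT: DICOM CT series in, DICOM-compliant RT
Structure Set out.  One independent 2D U-Net is trained per organ at risk
(OAR); there is no weight sharing or multi-class head.  The stages are:

1. **Ingestion** (`dicom_io`): the CT series is read, stored pixels are
   mapped to Hounsfield units (HU) with the per-file rescale slope and
   intercept, and slices are sorted by patient-z.  Only axial-aligned,
   uniformly spaced series are accepted; anything else is rejected rather
   than silently resampled.  Ground-truth RTSTRUCT contours are rasterized
   onto the CT grid with a pixel-center-inside, even-odd rule.
2. **Preprocessing** (`preprocess`): each slice is resampled in-plane to
   1.0 × 1.0 mm pixels (bilinear for HU, nearest for labels; through-plane
   geometry is never resampled — the model is strictly 2D on native slice
   thickness), cropped to the centermost 256 × 256 pixels (smaller fields
   of view are padded with −1000 HU air), and passed through a window/level
   filter onto [0, 1]: tissue W/L 400/40 for most organs, bone W/L 2000/400
   for the spinal cord and brachial plexus.
3. **Slice selection**: all slices bearing the organ are kept; of the empty
   slices, enumerated in ascending order, every 20th (positions 0, 20, 40,
   …) is kept.  This balances small organs — which may appear on ~10 of
   200+ slices — against the background class.
4. **Training** (`model`): a U-Net (encoder–decoder with skip connections,
   two 3 × 3 ReLU convolutions per level, dropout 0.5 at the two deepest
   levels, sigmoid 1 × 1 output head) is optimized with Adam on the summed
   loss

       L = (1 − (2|Y·P̂| + s) / (|Y| + |P̂| + s)) + BCE(Y, P̂)

   with soft intersection Σ(Y·P̂), smoothing s = 1e-6 (defining the
   empty/empty case as zero loss), and mean-over-pixels binary
   cross-entropy with probabilities clipped to [1e-7, 1−1e-7] inside the
   logs only.  The Dice term is computed per sample and averaged over the
   batch, the way 2D segmentation frameworks reduce their losses.
   Augmentation draws one random affine per pair — rotation ≤ 10°,
   translation ≤ 15% per axis, zoom ≤ 10%, shear ≤ 0.2° — applied
   bilinearly to the image and nearest-neighbor to the label.
5. **Inference**: each slice is preprocessed identically, inferred
   independently, and the 256 × 256 probability map is placed back on the
   native grid through the inverse crop and inverse resample (probability 0
   outside the cropped field of view).
6. **Post-processing** (`postprocess`): probabilities are binarized at
   0.33 (ties positive), only the largest 26-connected 3D component is
   kept, and for the parotid glands, submandibular glands, brainstem and
   larynx the cranio-caudal extent is capped at the training cohort's mean
   organ height plus k ∈ {1, 2} standard deviations (default k = 2),
   trimming whole end slices farthest from the center-of-mass slice.
7. **Evaluation** (`metrics`): Dice similarity coefficient, symmetric mean
   surface distance, and 95th-percentile Hausdorff distance, plus paired
   two-tailed Student t tests at α = 0.05 for method comparisons.

## Defaults that matter

| Parameter | Default | Notes |
| --- | --- | --- |
| learning rate | 5e-5 | Adam; multiplied by 0.25 on validation plateau, floored at 1e-6 |
| plateau patience | 10 epochs | configurable |
| epochs / batch | 200 / 32 | full-scale protocol |
| validation split | last 15% | at *patient* granularity (see below) |
| U-Net depth / filters | 4 / 32 (doubling) | architecture family is the contract, not exact weight counts |
| binarization threshold | 0.33 | ties count positive |
| axial-limit k | 2 | per-organ override available |
| tissue / bone window | 400/40, 2000/400 HU | W/L |

## Design choices where the design was open

* **"Last 15%" validation split.**  Interpreted at patient granularity
  (`ceil(0.15·n)` trailing patients in stable order), never slice-level:
  adjacent slices of one patient are nearly identical, and a slice-level
  split would leak them across partitions.
* **Empty-slice stride anchor.**  The every-20th rule starts at the first
  empty slice (position 0 of the empty-slice list).
* **Loss reduction.**  The per-sample Dice + batch-mean BCE reduction (see
  above); the single-array `combined_loss(Y, P̂)` is the reference
  definition and the training loss equals its per-sample mean.
* **Best-weights restore.**  `train()` returns the weights of the epoch
  with the lowest validation loss, not the final epoch.  Soft-Dice training
  of heavily imbalanced slices can destabilize after converging (the
  foreground term collapses back toward the all-background trough); the
  checkpoint-and-restore pattern keeps the state one would deploy.
* **HD95 convention.**  The two directed nearest-surface distance multisets
  are pooled and the 95th percentile (linear interpolation) of the pooled
  multiset is taken.  The max-of-directed-percentiles convention gives
  different numbers; reports name the convention.
* **Surface definition.**  Boundary voxel *centers* (6-connectivity
  background test), scaled by (slice, row, col) spacing.  MSD/HD are
  convention-sensitive; both choices are stated because values are only
  comparable under identical conventions.
* **Empty masks.**  Surface metrics on an empty mask are NaN, never 0 or
  ∞, so a failed structure cannot fake a good (or catastrophic) score; DSC
  of two empty masks is 1.0 (agreement on absence).  NaNs are dropped
  pairwise from t tests with the count reported.
* **Component connectivity.**  26-connectivity in 3D — the most permissive
  choice, merging diagonal slice-to-slice touches that 2D slice-wise
  predictions commonly produce.  After axial trimming the largest component
  is re-extracted so the output is always a single piece and the
  post-processing composition is idempotent.
* **Axial trim anchor.**  Slices are removed from whichever end lies
  farther from the center-of-mass slice (ties trim the superior end);
  center-of-mass is more robust to boundary noise than the largest-area
  slice.  If the cap is below one slice thickness, the single positive
  slice nearest the center of mass survives.
* **Rasterization.**  Pixel-center-inside with the even-odd rule and a
  half-open boundary convention — determinism over geometric fidelity.
  Holes are filled on contour export; RTSTRUCT inner/outer polarity is not
  modeled because none of the targeted OARs is annular at this fidelity.
* **Significance direction.**  p < 0.05 flags a significant difference
  (two-tailed paired t).

## The NumPy training backend

No deep-learning framework is part of the dependency set; the U-Net,
Adam, plateau scheduler and augmentation are implemented in
`autocontour.model._nn` directly on NumPy/BLAS in float32.  Convolutions
exploit the fact that shifting a padded row-major image grid by a kernel
tap offset is a contiguous 1D slide, so each 3 × 3 convolution is nine
BLAS GEMMs on contiguous views with β = 1 accumulation — no im2col
gathers.  Gradients were verified against central-difference directional
derivatives.  Training histories are bit-reproducible for a fixed seed on
a fixed NumPy/BLAS build; reproducibility across BLAS builds is not
promised.

## The synthetic phantom cohort

`synthetic_data` generates head phantoms: a soft-tissue elliptical body
(≈40 HU) with a bony ring (≈700 HU) on air (−1000 HU), embedded
ellipsoid/cylinder organs of distinct HU (≥80 HU contrast against their
surroundings), Gaussian noise (σ = 8 HU), written as a real DICOM CT
series (512 × 512, 0.977 mm pixels — deliberately not 1.0 mm so the
resampling path is always exercised — 2.5 mm slices) plus a ground-truth
RTSTRUCT.  Cohorts jitter organ centers (±6, ±6, ±2.5 mm) and semi-axes
(±10%) per patient with per-patient seeds derived from the cohort seed.

What the phantoms do *not* emulate: realistic anatomy and texture, CT
physics (beam hardening, partial volume), scanner-to-scanner intensity
variation, metal artifacts.  Organ contrast is exaggerated relative to
real anatomy, so passing phantom tests demonstrates that the plumbing,
geometry handling, training loop and post-processing are correct and that
the network can learn a learnable target — not that clinical-difficulty
accuracy is reached.

## Scaled validation protocol

Full-scale training (hundreds of patients × 200 epochs) is not a desk-scale
computation, so the end-to-end check runs a fixed scaled protocol
(`autocontour.validation`): 25 phantoms (20 train / 5 held-out), one organ
(the midline cylinder, trained through the complete DICOM round trip),
U-Net depth 3 with 8 base filters, 30 epochs at batch size 8.  Two settings
deviate from the library defaults, chosen when the protocol was designed:
`lr_init = 1e-3` (the conventional Adam default — a ~400-step schedule
needs a proportionally larger step than 5e-5, whose total Adam displacement
over 400 steps is ~0.02 per weight and cannot train any network from
scratch), and the library-default plateau patience 10 rather than something
shorter, since early LR decays during the slow-start phase of imbalanced
Dice+BCE training freeze the network before the foreground engages.  The
held-out phantoms are scored with DSC/MSD/HD95 after full post-processing.

## Known limitations

* Axial-aligned, uniformly spaced CT only; no MR/PET, no oblique gantry.
* 2D slice model: no through-plane context or 3D convolution.
* RTSTRUCT holes are filled on export.
* CPU training is practical only at phantom scale; the backend is exact
  but not competitive with GPU frameworks at clinical scale.
* The phantom cohort cannot certify clinical accuracy (see above).
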