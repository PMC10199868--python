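# Methods

## Problem

The partial volume effect (PVE) in brain PET is the mixing of activity
between neighbouring tissues caused by the scanner's finite spatial
resolution (typically 3.5–6 mm FWHM). Classical partial volume correction
(PVC) restores regional activity using an anatomical parcellation from a
co-registered MRI. `pvcbrain` implements a complete desk-scale version of
an *anatomy-free* PVC study: an anatomically guided reference correction
(Iterative Yang) produces paired training data, and a cycle-consistent
adversarial translator then learns to map uncorrected PET directly to PVC
PET without anatomical input at inference time.

Because clinical PET/MRI pairs cannot be redistributed, the package ships
a phantom generator that emulates the study data, and every quantitative
claim made by the tests is a claim about those phantoms (see
*What the phantoms do and do not show*).

## Forward model and phantoms

The scanner PSF is a separable 3D Gaussian parameterised by per-axis FWHM
in mm, `sigma = FWHM / (2*sqrt(2*ln 2))`. Convolutions use edge
replication so constant plateaus are preserved exactly — with zero
padding the cortex at the edge of the field would be artificially
darkened, which would contaminate every downstream recovery test.

Phantoms are nested ellipsoids on a 64^3 grid at 2 mm spacing (defaults):
an outer CSF shell, a cortical grey-matter shell split into 8 angular
sectors, a white-matter core, and two deep-grey nuclei — 12 regions, a
small-scale stand-in for an 83-region atlas. Each sample draws one
activity per region from the range of its tissue class under a named
tracer profile:

| profile | CSF | cortex | white | deep | emulates |
|---|---|---|---|---|---|
| `fdg-like` | 0.1–0.3 | 6–8 | 1.5–2 | 6–8 | ~4:1 grey:white metabolic contrast |
| `dopa-like` | 0.05–0.2 | 1.5–2.5 | 1–1.5 | 8–12 | focal striatal uptake |
| `amyloid-like` | 0.1–0.3 | 2–6 | 4–6 | 3–5 | high white-matter retention |
| `tau-like` | 0.1–0.3 | 2–7 | 1.5–2.5 | 2–4 | heterogeneous cortical uptake |

These are named parameter sets, not biologically validated uptake models.
Units are arbitrary SUV-like numbers. The observation model blurs the
piecewise-constant truth at 6 mm FWHM (a scanner-like resolution) and
adds zero-mean Gaussian noise with SD `noise_level * sqrt(local mean)`
(`noise_level = 0.02` by default) — the standard variance-proportional
surrogate for reconstructed count noise. Sector boundaries are randomly
rotated per sample so cases differ geometrically as well as in contrast.
All randomness descends from one master seed through spawned seed
sequences; every artefact is bit-reproducible.

## Iterative Yang correction

Starting from `f_PVC^0 = f`, each iteration (10 by default) computes
probability-weighted region means of the current estimate, assembles the
piecewise "artificial" image `f_a = sum_j A_j P_j`, and multiplies the
*original* observation by `f_a / (f_a ⊗ PSF)`. Numerical choices:

- The region mean is the probability-weighted mean (reduces to the plain
  label mean for binary maps). Background is excluded; voxels without
  membership keep ratio 1.
- Where the blurred artificial image falls below `1e-8 * max(f_a)` the
  ratio is forced to 1 — division safety for empty background.
- The correction kernel defaults to 3 mm FWHM even though the simulation
  blurs at 6 mm. The mismatch is deliberate (a conservative kernel is the
  common clinical choice when the true PSF is unknown) and configurable;
  with a matched kernel and exact binary maps the correction recovers a
  noiseless piecewise-constant phantom almost exactly, which is the
  strongest available correctness probe.
- A delta PSF makes the whole iteration the identity, bit for bit.

## Augmentation

New semi-realistic cases are composed from two parents by Laplacian-pyramid
blending under a smoothed hemisphere (or axial, or user-supplied) mask;
3 pyramid levels by default for 64^3 grids. The same mask blends the
non-PVC channels together and the reference-PVC channels together, so a
synthetic pair remains internally consistent. Synthetic samples carry no
ground-truth activity (the parents' truths do not commute with the IY
correction under blending) and are excluded from truth-recovery tests.

## Translator

Two generators (G: non-PVC→PVC, F: PVC→non-PVC) and two patch
discriminators are trained with the least-squares adversarial loss plus
cycle consistency (`lambda_cycle = 10`) and identity (`lambda_identity = 5`)
terms, Adam (lr 2e-4, beta1 0.5), and a 50-image buffer for discriminator
updates. Although the phantom pipeline produces paired data, the pairing
never enters the default objective — the model is trained as a genuinely
unpaired distribution-to-distribution translation, which is what makes
the approach applicable where no voxel-wise reference exists. A
supervised L1 term exists as a clearly labelled extension, off by default.

Design choices where the design was open:

- **Engine.** The networks are small enough (tens of thousands of
  parameters, 64x64 axial slices) to run on the package's own explicit
  forward/backward layer stack (`pvcbrain.nn`, float32), which keeps
  single-device training bit-deterministic under a fixed seed.
- **Architecture.** Width-16 residual generators with one downsampling
  stage and one residual block; 3-layer strided patch discriminators.
- **Global identity skip.** Each generator predicts the *correction* to
  its input (`y = x + body(x)`), so training starts at the identity map.
  Without the skip, the desk-scale budget is consumed re-learning the
  input image and the trained generator does not improve on it; with the
  skip the adversarial/cycle signal acts on the residual from epoch one.
  This is the standard inductive bias for restoration-style translation.
- **Normalisation.** Per-volume scaling by the 99.5th percentile of the
  positive intensities into [-1, 1], inverted at prediction; SUV ranges
  differ across tracer profiles, so a global scale would compress some of
  them.
- **Scale.** 2D axial slices, a 40-slice training pool, 30 epochs: the
  desk-scale configuration used throughout the tests and the acceptance
  script. A k-fold split utility (`kfold_splits`) supports the
  cross-validated protocol of larger studies; the fixture uses a single
  train/held-out split for runtime.

## Evaluation battery

- **RMSE / PSNR / SSIM** over the brain mask; PSNR's data range defaults
  to the reference maximum (configurable); SSIM uses a Gaussian window
  (sigma 1.5, k1 = 0.01, k2 = 0.03) with sample-covariance correction and
  border cropping, verified to 1e-6 against an independent reference
  implementation.
- **Region agreement**: per-region SUV_mean tables, OLS fit with R^2, and
  Bland–Altman bias with 95% limits of agreement (mean ± 1.96 x sample SD).
- **Radiomics**: 20 features per region across 7 categories
  (conventional SUV indices; histogram kurtosis/entropy/uniformity;
  AUC-CSH; GLCM homogeneity/energy/dissimilarity; GLRLM run percentage;
  NGLDM contrast; GLZLM SZE/LGZE/HGZE). Settings: fixed-bin-number
  discretisation (64 bins between region min and max); GLCM and GLRLM
  over the 13 unique 3D directions at distance 1 with symmetric
  accumulation, features averaged over directions; 26-connected zones;
  NGLDM contrast uses the 26-neighbour mean level. Kurtosis is the
  Pearson ratio mu4/sigma^4 (not excess) on raw SUV values; entropy and
  uniformity are computed on the discretised histogram. AUC-CSH uses
  1000 thresholds and the trapezoidal rule. Constant regions are flagged
  degenerate and take their closed-form values (uniformity 1, entropy 0,
  homogeneity 1). Every texture feature is validated against brute-force
  pair/run/zone enumeration on a 50-case battery of random small regions.
- **Voxel-wise statistics**: mass-univariate pooled-variance two-sample
  t-test with Bonferroni family-wise error control over the brain mask at
  alpha 0.05. Bonferroni is conservative and dependency-free; it stands
  in for random-field-theory FWE. The test is two-sample by default even
  for paired designs (matching common practice in voxel-based PET
  comparisons); a paired option is provided. Voxels with zero variance in
  both groups get t = 0. In a 500-repetition null calibration
  (10 vs 10 volumes, 10^4 voxels) the measured family-wise error rate is
  ~0.06, consistent with the nominal 0.05 within Monte-Carlo noise.

## What the phantoms do and do not show

The phantoms reproduce the *structure* of the study — paired non-PVC/PVC
volumes, region parcellations, tracer-dependent contrast, resolution
blur, count-like noise — but not clinical reality: no anatomical
variability beyond sector rotation, no motion or registration error, no
MR segmentation error, piecewise-constant truth, and a spatially
invariant Gaussian PSF. Passing tests therefore demonstrate the
correctness of the algorithms and the presence of a learning signal at
desk scale, not clinical performance. Problem sizes (64^3 grids,
12 regions, 40 training slices, 30 epochs) are the package's chosen
desk-scale operating point.

## Known limitations

- The translator is 2D slice-wise; no 3D patch mode is implemented.
- Bonferroni FWE is conservative relative to random-field methods.
- The IY region means assume the probability maps tile the brain; heavily
  overlapping soft maps are supported but untested against an external
  PVC implementation.
- Checkpoints store raw parameter arrays; architectures must match the
  saved config to reload.
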