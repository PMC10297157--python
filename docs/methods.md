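# Methods

`srbpmri` implements a spectral (hyperspectral-style) analysis of
spatially registered bi-parametric prostate MRI: a tumor signature is
scored against the normal-prostate background by covariance whitening,
several covariance-conditioning variants are compared, and the scores are
evaluated against ISUP grade and the binary CsPCa endpoint.  Because the
pipeline is exercised on synthetic phantom cohorts, this note documents
both the analysis itself and the generative model behind the phantoms —
including what the phantoms deliberately do and do not emulate.

## 1. The registered hypercube

Each exam consists of three sequences — ADC, high-b-value DWI (HBV) and
T2 — acquired on their own grids with different in-plane resolution and
small origin offsets.  Registration proceeds exactly as a header-driven
workflow would:

1. every channel is resampled in-plane to the grid of the channel with
   the coarsest in-plane spacing (ties break ADC > HBV > T2), bilinear
   per axial slice;
2. the integer voxel translation implied by the header origins is
   applied, and axial slices are *selected* by nearest world z-position
   rather than interpolated;
3. the channels are cropped to the common field of view and stacked, so
   each voxel is a vector `x = (ADC, HBV, T2)`.

Sub-voxel registration is out of scope: offsets are rounded to whole
voxels, which matches the few-pixel translations that header offsets
encode.  An optional per-channel manual shift (in voxels) mirrors the
small visual-inspection adjustments a reader would apply.  Axial slices
can be unrolled side by side into a 2-D mosaic (with an invertible index
map back to 3-D), and an RGB composite with R=ADC, G=HBV, B=T2 renders
tumors green (low ADC, high HBV, low T2).

## 2. Scores

Let `mu` and `Sigma` be the mean and covariance of the normal-prostate
voxels (prostate mask minus tumor ROI; unbiased `n-1` denominator; at
least 30 voxels required), `sigma_i` the per-channel SDs, and `s` the
mean vector over the candidate tumor ROI (with several candidates, the
largest-area one is primary).

* **z-score**: `z = sqrt( sum_i ((s_i - mu_i)/sigma_i)^2 )` — per-channel
  standardisation, correlations ignored.  (An alternative combination,
  the mean of |z_i|, is available via `z_combine="mean_abs"`.)
* **SCR** (signal-to-clutter ratio):
  `SCR = (s - mu)^T C^{-1} (s - mu)` — the squared Mahalanobis distance
  under a conditioned covariance `C`.  Whitening decorrelates the
  channels, so redundant sequences are not double-counted and contrast
  along low-clutter directions is amplified.  The square-root variant is
  available (`squared=False`); it is a monotone transform, so every
  ordering property (and every ROC result) is identical.  The squared
  form is the default.

With a diagonal covariance, `SCR = z^2` exactly.  The unprocessed SCR is
invariant under any invertible linear re-mixing of the channels.

## 3. Covariance conditioning

The three sequences are strongly redundant, so `Sigma` is
ill-conditioned; its smallest eigenvalue is dominated by noise and by
rare aberrant voxels, and the raw inverse amplifies whatever sits there.
Three remedies are implemented:

* **PC filtering** (`pc1_removed`, `pc2_removed`): eigendecompose
  `Sigma`, drop the k smallest-eigenvalue components, invert on the
  retained subspace (pseudo-inverse).
* **Shrinkage** (`regularized`, `modified_regularized`):
  `CM(gamma) = (1-gamma) Sigma + gamma D` with `D = diag(Sigma)`
  (regularized) or `D = (trace(Sigma)/3) I` (modified).  `gamma` is
  selected per patient by minimising the leave-one-out average negative
  Gaussian log-density of held-out voxels (Hoffbeck–Landgrebe
  discriminant), computed exactly via rank-one mean/covariance downdates
  on a grid with step 0.05; ties take the smallest grid value.
  `select_gamma`'s default grid spans {0, 0.05, …, 1}.  When shrinkage
  backs an SCR *variant*, the grid starts at 0.05: selecting `gamma = 0`
  is no shrinkage at all and reproduces the unprocessed variant; worse,
  with a near-singular covariance the 0-vs-0.05 selection boundary flips
  score *magnitudes* by more than an order of magnitude between patients,
  which is an artifact of grid selection rather than a property of the
  estimator.  The floor keeps the regularized family a genuine
  regularizer for every patient.
* **EVM** (elliptical volume minimization, `evm`): repeatedly remove a
  random 10% of the prostate voxels, record the ellipsoid log-volume
  `0.5 * log det` of the remaining 90%'s covariance, and keep the
  minimum-volume subset.  Rare gross artifact voxels inflate the
  determinant, so the winning subset tends to exclude them.  The number
  of trials defaults to 6000: a specific set of k planted aberrant voxels
  is only jointly removed with probability `1-(1-0.1^k)^T`, so isolating
  two or three of them reliably needs thousands of trials; a hundred
  would almost never succeed.  All trials are seeded and the search is
  vectorised (running sums plus closed-form 3×3 determinants), so the
  default costs well under a second per exam.  This is deliberately the
  simple random-subset search, not FAST-MCD.

## 4. Evaluation

* **Linear**: least-squares fit and Pearson R of each score (and each
  clinical covariate) against ISUP grade 0–5; subgroup fits by scanner
  and histopathology technique (groups under 3 patients skipped), with
  `ΔR` = mean over the seven variants of `R_group − R_all` and a normal
  95% interval from the spread over variants.
* **Logistic / ROC**: CsPCa is ISUP ≥ 2.  For each of 1000 seeded random
  70/30 train/test splits, a maximum-likelihood logistic model (IRLS,
  standardised design, iteration cap 50 for separable folds; the capped
  fit is still a monotone score map, which is all ranking needs) is fit
  on the training fold and the held-out fold's Mann–Whitney AUC recorded
  (ties half-credit, midranks).  Splits are unstratified; a split whose
  folds miss a class is redrawn and counted.  The summary is the mean AUC
  and the 2.5/97.5 percentiles of the per-split AUC distribution (linear
  interpolation between order statistics).  The per-fold mean — not a
  pooled ROC — is reported, consistent with summarising a *distribution*
  of AUCs.  Multivariable fits (PSA+volume+age, volume+age) use the same
  IRLS with a multi-column design.

## 5. The phantom generator

The generator reproduces the statistical structure the analysis rests
on, with no anatomical pretension (a standardized ellipsoidal prostate
with a single ellipsoidal focus placed at a seeded random interior
position; no zonal anatomy, bias fields, or motion).

**Geometry.** The reference (ADC) grid is 14 slices of 56×56 voxels at
3.6×2.4×2.4 mm.  HBV (1.2 mm) and T2 (0.8 mm) are sampled from the
latent tissue field on finer in-plane grids with origin offsets of a few
reference voxels (defaults: HBV +2/−1 voxels in-plane; T2 one slice
axially and −1/+3 in-plane), so the registration stage has real work to
do.  Offsets are integer multiples of the reference spacing and the finer
spacings divide it — the header-driven registration therefore recovers
the latent voxel values exactly on the common field of view, which is
what makes phantom-based oracles sharp.  The prostate spans roughly
2200–3000 reference voxels (a ±7% per-exam size jitter); the ROI about
200–260.  The `prostate_vol_cc` column of the cohort table is an
independent clinical covariate, deliberately *not* tied to phantom
geometry: covariates must carry no grade signal, and tying anatomy to a
19–192 cc range would also make the artifact-count calibration
patient-dependent.

**Tissue model.** Normal-prostate voxels are multivariate normal — the
minimal model consistent with an analysis that uses only second-order
statistics.  The default covariance (arbitrary intensity units, mean 10
per channel) has eigenvalues **(1.6, 0.7, 0.002)**: one channel
combination is almost deterministic, reflecting the strong redundancy
among the three sequences.  The tumor contrast direction
`d ∝ (−0.55, +0.65, −0.52)` (low ADC, high HBV, low T2 — green in the
composite) overlaps the near-degenerate minor eigvector by 0.71 and the
two leading eigvectors by 0.55 and 0.44.  This geometry is the crux of
the design: contrast along a low-clutter direction is what whitening
detection exploits (SCR ≫ z² there), it is also exactly where the raw
inverse is fragile, and the residual overlaps with the stable leading
eigvectors are what lets the PC-filtered variants retain signal after the
minor axis is discarded.  The matrix is a designed object, not a fit to
real tissue; its channel variances are kept the same order of magnitude
so no single sequence is degenerate.

**Tumor signal.** The ROI mean departs from normal tissue by
`grade · c · d` with `c = 0.35` intensity units per ISUP grade step
(grade 0 gives zero contrast), plus a per-patient ROI offset drawn
`N(0, (0.05 σ̄)² I)` where σ̄ is the RMS channel SD.  The offset models
two real effects with one knob: candidate ROIs are *selected* for looking
abnormal, so even benign foci carry a mild signature of their own, and
residual misregistration perturbs small-ROI means.  `c` was calibrated —
as the one free effect-size in the model — so that the synthetic cohort
reproduces the qualitative published ordering (conditioned variants ≫
unprocessed SCR, covariates uninformative) without saturating every
variant at R ≈ 1.

**Aberrant voxels.** Each exam replaces a fixed fraction
`f_out = 0.0011` of its normal-prostate voxels (two to three voxels) with
artifact spikes: displacements of fixed magnitude in a uniformly random
channel direction, with the magnitude drawn once per exam from
U(8, 16)·σ̄ (artifact severity varies between exams).  Rare
fixed-magnitude spikes — rather than a diffuse inflated-variance
population — are the one contamination model that simultaneously (i)
destabilises the unconditioned inverse (any spike is enormous relative to
the 0.002 minor eigenvalue, and its random orientation makes the damage
patient-specific), (ii) can actually be isolated by the random-subset
volume search, and (iii) leaves the leading eigenstructure intact so the
PC-filtered variants are unharmed (spikes comparable to the λ1−λ2 gap
would make the sample eigenbasis swap).  A diffuse population whose
covariance is a scalar multiple of the tissue covariance is statistically
invisible at these voxel counts: it rescales the sample covariance almost
uniformly, and Pearson R is scale-invariant.

**Cohort.** 42 patients with ISUP grade counts {0:17, 1:14, 2:5, 3:3,
4:1, 5:2}; scanner labels (Skyra 24, Ingenia 12, Trio Tim 1, Aera 2,
Prisma Fit 3) and histopathology techniques (SysBx 15, MRBx 16,
SysBx+MRBx 8, RP 3) assigned by largest-remainder scaling and shuffled;
age, PSA and prostate volume drawn from scaled Beta distributions matched
to the published ranges and central values, independent of grade.  An
optional per-scanner multiplier on `f_out` introduces scanner-linked
artifact-burden heterogeneity (off by default; the subgroup tests use
it).  All randomness flows from the cohort seed through spawned
per-patient streams; identical specs and seed give byte-identical
outputs.

## 6. What passing tests do and do not show

The phantoms demonstrate that the *pipeline* behaves as the analysis
assumes: registration is voxel-accurate under known offsets, the scores
respond to the planted contrast, conditioning rescues the SCR from the
planted instability mechanism, and the evaluation machinery is exact
against brute-force oracles.  They do not validate the clinical claim:
real tissue is non-Gaussian and spatially correlated, real artifact
structure is richer than rare isotropic spikes, real registration error
is sub-voxel and deformable, and real signature selection involves a
reader.  Numbers obtained on the synthetic cohort (R ≈ 0.85–0.99,
AUC ≈ 0.95–1.0 at the default settings) characterise the method under
its own assumptions, not its accuracy on patients.

## 7. Numerical choices and degenerate inputs

* 3×3 determinants/inverses on large stacks use closed-form adjugate
  arithmetic (×10–50 faster than batched LAPACK at this size); EVM works
  in log-determinant space to avoid under/overflow.
* `filtered_inverse` refuses retained eigenvalues below `1e-12 · λ1`;
  `compute_normal_stats` refuses constant channels and fewer than 30
  voxels; ROC/logistic routines refuse single-class inputs; resampled
  splits that miss a class are redrawn (and the redraw count reported).
* Shrinkage-γ ties take the smallest grid value; the LOO discriminant
  marks singular grid points as +inf rather than failing, and errors only
  if the whole grid is singular.
* Grade-0 exams carry a zero-contrast ROI (a benign candidate focus), so
  every patient contributes a score.
* The per-exam prostate mask is required on the reference grid; volumes
  with non-identity direction matrices are rejected rather than silently
  resampled.

## 8. Problem sizes

Default problem sizes were chosen so a full study runs on a laptop core:
42 patients × (registration + 7 variants + per-patient γ selection at
~2700 voxels × 21 grid points + 6000 EVM trials) plus 1000×12 logistic
refits completes in about a minute.  The same sizes are used by the test
suite and the acceptance script.
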