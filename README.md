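# srbpmri

Spectral tumor-aggressiveness scoring on **spatially registered
bi-parametric prostate MRI** (ADC, high-b-value DWI, T2), with covariance
conditioning and resampled ROC evaluation — exercised end to end on
synthetic phantom cohorts.

## The problem

Bi-parametric prostate MRI omits contrast injection, which makes it
attractive clinically but leaves only three channels to separate tumor
from normal tissue.  Borrowing from hyperspectral target detection, the
three sequences are resized, translated and cropped until every voxel is
a registered 3-vector `x = (ADC, HBV, T2)`; a candidate tumor ROI (green
in the R=ADC, G=HBV, B=T2 composite: low ADC, high HBV, low T2) is then
scored against the normal-prostate background:

* **z-score** — per-channel standardised contrast, correlations ignored:
  `z = sqrt( Σ_i ((s_i − μ_i)/σ_i)² )`
* **SCR** (signal-to-clutter ratio) — squared Mahalanobis distance under
  the background covariance Σ:
  `SCR = (s − μ)ᵀ C⁻¹ (s − μ)`

The raw inverse of Σ is fragile — the channels are highly redundant, so
Σ's smallest eigenvalue is noise-dominated — and the package implements
the three standard remedies as scoring variants: principal-component
filtering (1 or 2 PCs removed), shrinkage regularization
`CM(γ) = (1−γ)Σ + γD` with two diagonal targets and a leave-one-out
likelihood choice of γ, and elliptical volume minimization (EVM; keep the
minimum-volume 90% voxel subset over random removal trials).  Scores are
fitted linearly to ISUP grade (Pearson R, with scanner/technique
subgroups) and logistically to clinically significant cancer
(CsPCa = ISUP ≥ 2), the latter summarised by the mean and 2.5–97.5%
percentile interval of the test AUC over 1000 random 70/30 splits.

Because the matched public imaging collection cannot be redistributed,
the package ships a first-class synthetic cohort generator that
reproduces the statistical structure the analysis rests on (three
channels on mismatched grids, a near-degenerate background covariance,
grade-linear contrast, rare artifact voxels, grade-independent clinical
covariates); see `docs/methods.md` for the generative model and its
limitations.

## Worked example

```python
import numpy as np
from srbpmri import PhantomSpec, generate_phantom, PatientSpectralModel

spec = PhantomSpec(seed=3)                      # default study conditions
seqs, prostate, tumor = generate_phantom(spec, grade=4,
                                         rng=np.random.default_rng(3))
model = PatientSpectralModel.from_sequences(seqs, prostate, tumor, "pt_demo")
res = model.fit(evm_seed=np.random.default_rng(3))
print(res.summary())
```

```
Spectral scores -- pt_demo
  normal voxels: 1982, ROI voxels: 218
  contrast (s - mu): [-0.819   0.9761 -0.7594]
  variant               score
  unprocessed            34.4853
  regularized            18.9007   (gamma=0.05)
  modified_regularized   16.9051   (gamma=0.05)
  pc1_removed             0.9925
  pc2_removed             0.4177
  evm                   561.4335
  zscore                  1.7343
```

Reading this: the grade-4 focus sits ~1 SD below background in ADC and
T2 and ~1 SD above in HBV (`contrast`), i.e. along the low-clutter
channel combination.  EVM removes the exam's few artifact voxels and
restores the sharp whitened metric, hence its large score; the raw
(`unprocessed`) inverse is diluted by those artifacts; the PC-filtered
scores live on the retained high-variance subspace and are therefore
much smaller in magnitude — only the *ordering across patients* matters,
and that is what the cohort stage evaluates:

```python
from srbpmri.pipeline import PipelineConfig, run_pipeline
out = run_pipeline(PipelineConfig(out_dir="run", seed=0))
print((out / "summary.txt").read_text())
```

```
Cohort evaluation -- n=42, 1000 x 70/30 resampled ROC (seed 0)
predictor                          R     AUC    2.5%   97.5%
evm                            0.923   1.000   1.000   1.000
modified_regularized           0.921   1.000   1.000   1.000
pc1_removed                    0.922   0.966   0.817   1.000
pc2_removed                    0.894   0.957   0.750   1.000
regularized                    0.916   0.953   0.750   1.000
unprocessed                    0.847   0.955   0.773   1.000
zscore                         0.992   1.000   1.000   1.000
psa_ng_ml                      0.018   0.450   0.167   0.727
prostate_vol_cc               -0.121   0.598   0.227   0.900
age_years                     -0.051   0.386   0.091   0.595
...
```

The qualitative pattern of the method on its own assumptions: every
conditioned SCR variant and the z-score fit ISUP grade well and separate
CsPCa cleanly, the unconditioned SCR is strictly the worst of the SCR
family, and PSA, prostate volume and age carry essentially no signal.

There is also a CLI mirroring the stages:

```bash
srbpmri simulate --out-dir cohort --seed 0      # write volumes + cohort.csv
srbpmri register cohort/pt001                   # composite PNG for one exam
srbpmri score cohort --out-dir run              # all 7 variants per patient
srbpmri evaluate cohort --scores-csv run/scores.csv --out-dir run
srbpmri run-all --out-dir run --seed 0          # everything in one go
```

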