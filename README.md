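# hippopred

ROI-level fMRI analysis of hippocampal-subfield dynamics during cued
memory retrieval, packaged as a tested, reusable pipeline and exercised
end-to-end on synthetic BOLD data with known ground truth.

## The scientific problem

When a retrieval cue brings back a detailed memory and the world then
disagrees with it — a *mnemonic prediction error* — the hippocampus is
thought to shift from a retrieval-dominated state (CA3 → CA1) toward an
encoding-dominated state (entorhinal cortex → CA1). The experimental
design this package models: participants learn 30 complex room images,
then in the scanner are cued with a room's name (1.5 s), retrieve it
across a 1 s blank, and see a probe image (4 s) containing 0–2 furniture
changes crossed with 0–2 layout changes (nine trial types, 270 trials
over 10 scans at TR 2.5 s; two blocked change-detection tasks alternate
across scans). The total number of changes (0–4) grades the prediction
error.

The pipeline asks two questions of such data:

1. **Connectivity** — does trial-to-trial coupling of CA1 with entorhinal
   cortex rise, and with CA2/3/DG fall, as the number of changes grows?
2. **Representation** — does the CA1 activity pattern at cue reinstate
   the specific room (prediction strength), and does cue↔probe pattern
   similarity fall as the probe diverges from the memory
   (prediction-error similarity)?

## Methods implemented

- **LSS single-trial estimation.** One GLM per trial with the target
  event as the sole regressor of interest; all cues pooled into one
  nuisance regressor and remaining images binned by trial type (≤ 9
  regressors); boxcars convolved with a double-gamma HRF, a temporal
  derivative per regressor, polynomial drift; voxelwise
  t = β / √(σ̂² [(XᵀX)⁻¹]ⱼⱼ).
- **Beta-series functional connectivity.** Per-trial voxel-mean t values,
  binned by changes (0–4) × task into 10 series per ROI; Pearson r per
  ROI pair and bin, Fisher-transformed (z = atanh r), tasks averaged on
  the z scale.
- **RSA statistics in CA1.** Prediction strength: per eligible cue,
  z(cue, matched intact image) minus mean z(cue, other rooms' intact
  images), with cues of 0-change trials, same-scan pairs and cross-task
  pairs excluded; voxel selection drops the third of voxels least
  activated by the task. Prediction-error similarity: within-trial
  z(cue, probe) per changes level.
- **Group inference.** Within-subject ANOVAs (1–3 factors, subject ×
  effect error strata, partial η²), planned contrasts (linear: −2…+2;
  match < mismatch: −1, +0.25×4) tested by one-sample t with Cohen's d,
  and random-intercept Gaussian mixed models fit by exact profiled ML
  with likelihood-ratio model comparison (χ² = 2Δlog L, AIC/BIC).
- **Synthetic cohorts.** Room-specific multivoxel templates reinstated
  at cue and corrupted in proportion to the number of changes at probe;
  latent trial amplitudes with condition-dependent inter-ROI correlation
  (the estimand of beta-series connectivity); AR(1) noise and polynomial
  drift. Ground truth is stored so every stage is checkable.

## Worked example

```python
from hippopred import pipeline as pl

result = pl.run_pipeline(pl.PipelineConfig(seed=7), "out/demo")
```

With the default 19-participant synthetic cohort this prints tables into
`out/demo/` and yields (seed 7):

```
interaction:            F(4,72) = 23.46, p = 1.9e-12, eta_p2 = 0.57
ERC match<mismatch:     mean z diff = 0.296, t(18) = 6.62, p = 3.3e-06
CA3 linear:             mean = -0.741, t(18) = -4.45, p = 0.00031
prediction strength:    mean z = 0.490, t(18) = 44.85, p < 1e-19
pred. error match>mismatch: t(18) = 2.74, p = 0.013, d = 0.63
ERC LRT full vs linear-only: chi2(1) = 19.88, p = 8.3e-06
ERC LRT full vs match-only:  chi2(1) = 0.57,  p = 0.45
```

Reading: the Changes × ROI interaction confirms that the number of
changes moves the two CA1 pathways in opposite directions; group-mean
collapsed z per condition is CA1–ERC ≈ (−0.02, 0.28, 0.26, 0.27, 0.31)
(a step up from 0 changes to any change) and CA1–CA2/3/DG ≈ (0.38, 0.25,
0.19, 0.11, 0.08) (a graded fall) — recovering the generative coupling
profiles. The likelihood-ratio comparison says the match<mismatch term
explains CA1–entorhinal connectivity beyond the linear trend, but not
vice versa. Prediction strength is positive (cue patterns reinstate the
specific room) and cue↔probe similarity declines with changes.

The same stages are exposed on the command line:

```bash
hippopred design generate --seed 1 --out out/design
hippopred pipeline run --out out/run --seed 7
hippopred pipeline recover --replicates 20 --seed 1 --out out/recovery
hippopred stats compare --in out/run/connectivity_collapsed.tsv --out lrt.json
```

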