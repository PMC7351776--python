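# Methods

This note records the models, defaults, numerical choices, and known
limitations of the pipeline. Everything quantitative below is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Task design and schedule generation

A design is 30 rooms × 9 trial types (0–2 furniture changes × 0–2 layout
changes) = 270 trials over 10 scans at TR 2.5 s. Each trial is a name
cue (1.5 s), a blank (1.0 s), and a probe image (4.0 s). Counts by total
changes are forced by the factorial structure: 30/60/90/60/30 for
0/1/2/3/4 changes. Constraints honored by `design.generate_schedule`:

- each room appears exactly once per trial type;
- within each trial type, rooms are split evenly between the two blocked
  tasks (so each changes × task cell holds 15/30/45/30/15 trials);
- tasks alternate across scans (5 scans per task), each scan holds
  `n_rooms × 9 / n_scans` trials of a single task;
- onsets increase strictly within scan; inter-trial intervals are drawn
  uniformly from {2.5, 5.0} s. The source material does not specify the
  ITI distribution or the room-to-scan assignment; jitter at TR
  multiples keeps the design estimable, and scan assignment is otherwise
  random per seed. 10 s of pre-trial rest and 15 s of post-trial rest
  bound each scan.

Choices left open by the task description: no constraint is imposed on
trial order within a scan (e.g., back-to-back room repeats are allowed),
and the cohort is homogeneous (no participants with fewer scans).

## Synthetic BOLD model

Per ROI (CA1, CA2/3/DG as one region, entorhinal cortex) and scan, the
voxel × time data are

    baseline + polynomial drift + Σ_events amplitude × HRF-convolved boxcar + AR(1) noise.

Room templates are unit-variance Gaussian patterns per ROI. The voxel
amplitude of an event is `gain × (1 + strength × pattern)`: the `1`
carries the univariate response (so ROI-mean beta series reflect the
latent gain), the pattern rides on top for the multivoxel statistics.
Cue events carry the intact room template; image events carry a
corrupted copy in which `total_changes × corruption_fraction` of the
components are resampled, giving expected template correlation
`1 − k·f` at k changes.

Image-event gains are the connectivity estimand: a shared standard
normal factor drives CA1 and the other ROI of each pair loads on it
with weight ρ(changes), so the across-trial gain correlation per
condition equals the requested coupling by construction (verified
directly against stored ground truth in the tests, independent of any
GLM). The factor construction implies corr(ERC, CA2/3/DG) = ρ₁ρ₂, which
keeps the joint covariance positive definite for any profiles in [0,1).

Defaults (frozen after one calibration pass against the implemented
pipeline, then never revisited):

| parameter | default | meaning |
|---|---|---|
| roi_specs | CA1 24, CA23DG 20, ERC 20 voxels | small anatomical ROIs |
| coupling CA1–ERC | .05, .28, .28, .34, .34 | match<mismatch-shaped rise |
| coupling CA1–CA3 | .40, .30, .25, .15, .10 | linear-shaped fall |
| gain_mean / gain_sd | 1.0 / 0.6 | single-trial amplitude variability |
| cue_gain_sd | = gain_sd | cue amplitudes, uncoupled |
| pattern_strength (cue, image) | 0.7, 0.7 | pattern amplitude relative to the univariate response |
| change_corruption_fraction | 0.15 | template components resampled per unit change |
| noise_sd / ar1 | 0.7 / 0.3 | AR(1) marginal SD and coefficient |
| drift_order / drift_amp | 1 / 1.0 | per-voxel random polynomial drift |
| baseline_amp | 100 | arbitrary units |

The coupling profiles are free parameters of the generator chosen so
the designed detection targets are attainable at n = 19: the
match<mismatch contrast of a shallower rise (0.10 vs ~0.28) is
intrinsically underpowered at these trial counts — the limiting noise
is the sampling error of a correlation estimated from 15–45 trials per
cell, which no SNR setting removes — so the step was deepened while
keeping the qualitative shape (flat-after-first-change vs graded fall).

## HRF and design matrices

The double-gamma kernel is the difference of two gamma densities with
the shape chosen as `1 + delay/dispersion` so that each gamma's mode
equals its stated delay — i.e., `peak_delay_s = 6` puts the kernel peak
at 6.0 s exactly (dispersions 1 s, undershoot delay 16 s, peak:undershoot
6:1, length 32 s; kernel normalized to peak 1). Boxcars are laid out on
a 0.1 s grid as per-bin coverage fractions (trial onsets live on a 0.5 s
grid that is not TR-aligned), convolved at that resolution, and averaged
within TR bins. Temporal derivatives are finite differences of the
convolved regressor and are not orthogonalized against their parents.
Drift is polynomial (default order 1) rather than a high-pass filter, to
match the simulator's drift model; degrees of freedom use n − p of each
separate model.

## Single-trial estimation (LSS)

Image models: the target image, one pooled regressor for all cues, and
the remaining images binned by trial type (≤ 9 nuisance regressors).
Cue models: the target cue, one pooled regressor for all other cues, and
nine trial-type image regressors. Empty nuisance bins (e.g., a target
that is the sole trial of its type in the scan) are dropped. Targets
with identical column structure within a scan are solved in one batched
OLS (Cholesky-checked normal equations); the tests pin every trial's
estimate to an independently assembled per-trial GLM at 1e-8.

A structural property worth knowing: the cue and image of one trial are
only 2.5 s apart, so their regressors are substantially collinear, and
the trial-type nuisance bin absorbs only the *type-average* image
signal. Each cue estimate therefore carries a bleed of its own trial's
image pattern and vice versa. Consequences: (i) within-trial cue↔probe
similarity has a level-independent positive floor, which compresses
adjacent-level differences of the prediction-error profile; (ii) with
image patterns present, prediction strength acquires a small
room-specific pathway even without any cue reinstatement, which is why
the no-reinstatement null in the calibration experiments switches off
*both* pattern strengths. Both effects are properties of the estimator
on real data too, not artifacts of the simulator.

## Connectivity

Per-trial voxel-mean t values are binned by (total changes, task) into
10 series per ROI; each bin needs ≥ 3 trials and non-constant series.
Pearson r is Fisher-transformed per task and the two tasks are averaged
on the z scale (variance-stabilized averaging; the alternative —
average r then transform — differs only at third order but is not
used). |r| = 1 and constant series raise rather than clamp. All trials
enter regardless of behavioral accuracy.

## Pattern statistics

Voxel selection ranks voxels by the condition-GLM image activation
averaged over changes levels (within task, then across tasks) and keeps
the top `ceil((1 − 1/3) n)`, ties broken by index. Eligibility for
prediction strength: cues of 0-change trials are excluded (their
matched image shares the trial), the cue and the matched intact image
must not share a scan and must share a task; the "other rooms" baseline
applies the same scan/task rules (symmetry of the bias being
controlled), and a cue with no eligible baseline image is dropped and
logged. Per-pattern correlations are Fisher-transformed *before*
subtraction and averaging — a z-difference of r values can otherwise
leave the valid domain — then averaged per task and across tasks. The
prediction-error similarity aggregates per-trial z within
(changes, task) cells and collapses tasks; the other-room control
subtracts, per trial, the mean z to other rooms' images of the same
trial type under the same eligibility.

## Group statistics

The rm-ANOVA is the balanced within-subject decomposition for 1–3
factors; each effect is tested against its own subject × effect
interaction stratum, with partial η² = SS_eff/(SS_eff + SS_err). No
sphericity correction by default (Greenhouse–Geisser behind a flag),
matching the uncorrected-df reporting convention for this design. The
three-way and two-way connectivity ANOVAs take Fisher-z values.

Mixed models are Gaussian with a single random intercept per
participant, fit by *maximum likelihood* (not REML) so that
likelihood-ratio comparisons of fixed effects are valid. The fit is
exact: β and σ² have closed forms given λ = τ²/σ² (per-group
Sherman–Morrison inverse), and λ is optimized by bounded scalar search
on [0, 1e4] with the zero boundary evaluated explicitly — so a vanishing
random-intercept variance is handled cleanly rather than crashing a
Hessian inversion. Parameter count k = fixed effects + 2 variance
parameters; AIC = 2k − 2logL, BIC = k ln n − 2logL. The match<mismatch
term enters as a two-level indicator (0-changes vs any change), the
linear term as a numeric covariate. Per-coefficient p-values are not
reported; inference is via nested model comparison only.

## Validation experiments and problem sizes

The standing experiments (module `hippopred.experiments`) use
19-participant cohorts: 50 replicates for the recovery arms, 200 for the
flat-coupling type-I calibration (without the pattern stages), and 100
for the no-reinstatement null. The type-I arm runs at the default ROI
sizes deliberately: because CA1's beta series enters both ROI pairs,
shrinking the ROIs inflates the estimation noise the two pairs share,
violates sphericity, and makes the uncorrected interaction F measurably
liberal — a sensitivity worth knowing about when ROIs are small on real
data.
"Ordering recovered" means the sign of the theoretically matched
contrast on group-mean z (CA1–ERC match<mismatch > 0; CA1–CA3
linear < 0); full rank-ordering of five condition means is ill-posed
when the generative profile contains ties. "Prediction-error profile
decreasing" means a negative linear trend of the five group means
together with mean(0) > mean(4); strict five-level ordering per cohort
is additionally reported but is not expected to hold reliably, for the
leakage reason above.

## What the synthetic data do and do not show

The generator emulates the design's timing, counterbalancing,
condition-dependent amplitude coupling, graded pattern corruption, AR(1)
noise and slow drift. It does not emulate: physiological noise and
motion, susceptibility dropout near entorhinal cortex, hemispheric
differences (left hemisphere only; a flat-coupling profile stands in
for a null hemisphere), behavioral errors, participant-varying scan
counts, or any neural distinction between task-relevant and
task-irrelevant changes (all changes are treated identically). Passing
recovery tests therefore show the *estimators and inference chain* are
correct and calibrated under the stated generative model — not that the
biological effects exist; and the reported detection rates are specific
to the frozen effect sizes and noise levels above.
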