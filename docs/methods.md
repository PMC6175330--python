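# Methods

## The simulated experiment

The generator emulates a two-condition (e.g. two grating orientations)
alternating block design: 16 s blocks, 8 blocks per subrun (4 per
condition), 4 subruns, sampled every 2 s, with the leading condition
alternating across subruns so neither condition is systematically
first. Regressors are plain boxcars; no haemodynamic convolution is
applied — the simulated signal is treated as the steady-state response
amplitude itself, which is adequate for 16 s blocks where the response
plateau dominates and keeps every downstream estimate exactly linear
in the generating amplitudes. Blocks are contiguous by default;
`inter_block_gap_s` inserts fixation gaps between blocks when a more
literal replica of a gapped acquisition is wanted. The simulation
sampling interval is a free parameter of the generator; 2 s (8 samples
per block) is the default and all reported numbers use it.

Ground truth per participant: per-voxel condition amplitudes are i.i.d.
standard normal. The expected mean absolute difference of two such
draws is 2/√π, and both condition vectors are rescaled by the realized
mean absolute difference so the contrast has mean |A − B| = 1 exactly.
A zero-contrast draw (probability zero) triggers a logged redraw.
Defaults are 500 voxels and 15 participants.

Three noise sources are added, each with its own stream:

- **Attention noise** — Gaussian jitter (SD 1) of the condition
  amplitude, drawn independently per block and voxel, modulated by the
  block boxcar. It models trial-to-trial engagement fluctuations and
  is held constant across conditions and noise levels.
- **Thermal noise** — i.i.d. Gaussian per timepoint and voxel, SD 1.8,
  the white-noise floor; also constant across conditions.
- **Physiological noise** — 10 Gaussian timecourse components (SD 1
  each, redrawn independently per subrun) projected onto voxels by a
  weight matrix drawn once per participant (i.i.d. standard normal, 10
  weights per voxel) and reused across subruns. This yields spatially
  correlated noise with a participant-stable covariance structure —
  precisely what a whitening estimator can learn from training
  residuals. A single multiplier on this source (`phys_scale`) is the
  experimental knob: reducing physiological noise is how prospective
  motion correction is modelled, leaving the other sources untouched.

All randomness descends from one root seed through named
`SeedSequence` spawn keys (role, level, dataset, participant), so any
participant, cohort or grid cell regenerates bit-identically on its
own.

## GLM and fCNR

Each subrun is detrended independently by projecting out a constant, a
linear ramp, and one sine/cosine pair at the segment's fundamental
period; the same projection is applied to the regressors. Per-subrun
detrending is deliberate: trends must not leak across subruns, which
are the cross-validation folds. OLS then yields betas, the A − B
contrast, and residuals. Residual SDs use `n − rank(X) − 4`
denominators (the 4 counts the detrend basis).

One subtlety of the contiguous design: the two detrended condition
boxcars sum to zero (their raw sum is the constant the detrend
removes), so the per-condition betas are not separately identifiable —
but the A − B contrast is, exactly. The fits therefore use the
minimum-norm OLS solution with pseudoinverse-based standard errors;
with gaps in the design the same code path is simply full-rank. The
same degeneracy applies to the one-regressor-per-block design used for
the classifier: the minimum-norm fit centres the block patterns within
subrun, a common and harmless normalization for two-class decoding.

Two fCNR definitions are implemented:

- **Stimulus-vs-baseline** (`compute_fcnr_stimulus`): single on/off
  regressor with implicit zero baseline; amplitude is the fitted
  timecourse peak |β|·max(regressor), noise is the residual SD. This
  matches how presence-vs-absence fCNR is reported for real data.
- **Between-condition** (`compute_sim_fcnr`): amplitude is the
  |subrun-averaged A − B contrast|; the default noise denominator is
  the pooled GLM *standard error of that contrast*. The residual-SD
  variant is available (`denominator="residual_sd"`), but it is
  bounded near 0.5 under unit contrasts with thermal SD 1.8 — the
  contrast-SE form is the definition under which calibration targets
  of 1.6–1.8 are meaningful, spanning ≈ 4.2 (no physiological noise)
  down to ≈ 0.9 (physiological noise dominating), and it is the
  calibration quantity throughout.

**Calibration** holds thermal and attention noise fixed and bisects on
`phys_scale` against the measured mean fCNR at a fixed calibration
seed, making the objective deterministic and strictly decreasing. The
guaranteed relative accuracy is 2% (default); the bisection converges
to a quarter of that so replicate sampling noise cannot consume the
whole band. Each objective evaluation averages `n_reps` simulated
participants (20 by default; the experiment configs use fewer for grid
work, and high-precision checks use more — the per-participant
sampling SD of the mean fCNR is ≈ 0.08, so precision scales as
0.08/√n_reps). Targets above the `phys_scale = 0` ceiling or below the
large-scale floor raise a `CalibrationError` reporting the achievable
bound.

## Decoding statistics

**Crossnobis / LDC.** Per fold (leave one subrun out): training
contrast = mean of the 3 training subruns' contrasts; noise covariance
= Ledoit–Wolf shrinkage estimate on the pooled training residuals
only (the test subrun's residuals never enter, preserving fold
independence); fold value = (Σ̂⁻¹c̄_train)·c_test via Cholesky solve.
The result records per-fold values, their mean, and the mean divided
by √P. The shrinkage target is the diagonal of the sample covariance
(voxel variances preserved, off-diagonals shrunk), the standard choice
for MVPA noise normalization when voxels outnumber residual
timepoints; the intensity follows the Ledoit–Wolf quadratic-loss
formula adapted to that target. A scaled-identity target (delegating
to scikit-learn's estimator) is available via `cov_target="identity"`.
The raw mean training contrast is whitened without prior
normalization, so the statistic scales quadratically with the true
contrast magnitude.

**SVM.** One beta pattern per block (16 per condition over the 4
subruns), linear kernel with unit box constraint, features
standardized by training-fold statistics only, leave-one-subrun-out:
24 training patterns, 8 test patterns per fold, so fold accuracies are
multiples of 1/8. Test patterns exactly on the decision boundary go to
the first class and are counted/logged.

## Group inference

The fixed-effects permutation test swaps each participant's condition
pair independently with probability ½ per iteration (10,000 by
default) and refers the observed mean difference to the null
distribution two-sidedly with the add-one estimator
`(#{|null| ≥ |obs|} + 1)/(n + 1)`. Two-sided testing is used
throughout. Zero-variance t-test degeneracies follow a documented
convention: all differences exactly zero → p = 1; identical nonzero
differences → p = 0.

## The rejection-probability grid

For a pairing (fCNR_A, fCNR_B), each of `n_datasets` iterations
simulates two cohorts sharing each participant's ground-truth contrast
but drawing independent noise at the two calibrated levels — the
within-participant manipulation a motion-correction on/off comparison
performs — and applies a paired t-test (α = .05) to the
per-participant statistic (normalized LDC, or mean SVM accuracy). The
rejection probability is the fraction of significant datasets.
Diagonal cells use two independent cohorts at the same level and
estimate the false-positive rate (≈ α). The vs-chance variant tests
one cohort's statistic against its null value (0 for LDC, ½ for SVM)
with a one-sample t-test. Default grid levels are 8 values from 1.0 to
2.4, bracketing the 1.6/1.8 study regime; levels below ≈ 0.9 are
unreachable by physiological scaling alone (the fCNR floor above) and
fail calibration explicitly.

## Problem sizes used by the shipped checks

The full-scale result (100 datasets × 15 participants × 500 voxels,
LDC vs chance at fCNR 1.8) runs as specified. Supporting checks choose
sizes that keep each property's Monte-Carlo error well inside the band
being asserted while remaining desk-scale: null-centering uses 1000
participants at 250 voxels (the unbiasedness claim is
voxel-count-agnostic), the directional LDC-vs-SVM grid comparison uses
25 datasets at 200 voxels, and calibration verification averages 200
replicate participants.

## What the generator does and does not emulate

It reproduces the design geometry, amplitude statistics, and the
three-source noise structure, including the participant-stable
physiological covariance that whitening exploits. It does not simulate
haemodynamic dynamics, temporal autocorrelation beyond the block
structure, head-motion trajectories, spin-history or distortion
artefacts, anatomical voxel layout, or between-session nonstationarity.
Passing tests therefore certify the *statistical* behaviour of the
estimators under this noise model — unbiasedness, calibration,
relative sensitivity — not performance on any particular scanner's
data; on real data the LDC's advantage additionally depends on how
well the residual covariance is estimated under autocorrelated noise.

## Known limitations and open choices

- The between-condition fCNR uses the contrast-standard-error
  denominator (see above); analyses comparing against
  residual-SD-based fCNR values from other pipelines should use the
  provided variant and expect different scales.
- Calibration scales only physiological noise; a joint
  thermal+physiological scaling would change the whitening problem and
  is intentionally not the default (thermal noise is unaffected by
  motion correction).
- The permutation machinery covers paired comparisons; multi-condition
  simultaneous relabelling (needed for ≥ 3 conditions) coincides with
  per-pair swaps only in the two-condition case implemented here.
- Repeated-measures ANOVA post-hocs are out of scope; the permutation
  test and t-tests are the supported inference.
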