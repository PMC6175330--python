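"""Synthetic block-design fMRI data with known ground truth.

The generator emulates a two-condition alternating block experiment on
an ROI of voxels, with three noise sources layered on a noiseless
boxcar activation timecourse:

1. *Attention* noise — per-block, per-voxel Gaussian jitter of the
   condition amplitude (SD 1 by default), modelling trial-to-trial
   fluctuations in engagement with the stimulus.
2. *Thermal* noise — i.i.d. Gaussian noise per timepoint and voxel
   (SD 1.8 by default), the scanner's white-noise floor.
3. *Physiological* noise — a random weighted projection of a small set
   of shared Gaussian timecourse components (10 by default) onto the
   voxels.  The projection weights are drawn once per participant and
   reused across subruns, so the induced voxel covariance structure is
   stable within a participant (and can be learned by a whitening
   estimator), while the component timecourses themselves are redrawn
   per subrun.  Scaling this source up or down is how a change in
   physiological noise level (e.g. from prospective motion correction)
   is modelled.

Condition amplitudes are i.i.d. standard normal per voxel and then
rescaled so the mean absolute between-condition contrast over voxels is
exactly 1; the pre-normalization mean absolute difference of two
standard normals is 2/sqrt(pi).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .design import BlockDesign
from .glm import compute_sim_fcnr

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "SimulatedDataset",
    "CalibrationError",
    "draw_ground_truth",
    "simulate_participant",
    "simulate_dataset",
    "measure_mean_fcnr",
    "calibrate_noise_to_fcnr",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels for the three simulated sources (amplitude units).

    ``phys_scale`` multiplies the physiological projection and is the
    knob the calibration turns; the component timecourses have SD
    ``phys_component_sd`` each.
    """

    attention_sd: float = 1.0
    thermal_sd: float = 1.8
    phys_n_components: int = 10
    phys_component_sd: float = 1.0
    phys_scale: float = 1.0

    def __post_init__(self):
        if min(self.attention_sd, self.thermal_sd,
               self.phys_component_sd, self.phys_scale) < 0:
            raise ValueError("noise SDs and scales must be >= 0")
        if self.phys_n_components < 1:
            raise ValueError("phys_n_components must be >= 1")

    @property
    def is_silent(self) -> bool:
        """True when every source has zero effective amplitude."""
        return (self.attention_sd == 0 and self.thermal_sd == 0
                and self.phys_scale * self.phys_component_sd == 0)


@dataclass(frozen=True)
class GroundTruth:
    """Per-voxel condition amplitudes with a normalized contrast.

    ``condition_means`` is (voxels, 2); the contrast (A - B) has mean
    absolute value 1 over voxels.
    """

    condition_means: np.ndarray

    @property
    def contrast_vector(self) -> np.ndarray:
        return self.condition_means[:, 0] - self.condition_means[:, 1]

    @property
    def n_voxels(self) -> int:
        return self.condition_means.shape[0]


@dataclass
class SimulatedDataset:
    """A simulated cohort: (participants, subruns, timepoints, voxels)."""

    data: np.ndarray
    design: BlockDesign
    truths: list[GroundTruth]
    noise: NoiseSpec
    seed: int | None = None

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[3]


class CalibrationError(RuntimeError):
    """Raised when no physiological scale can reach the fCNR target."""


def draw_ground_truth(n_voxels: int, rng: np.random.Generator,
                      max_redraws: int = 100) -> GroundTruth:
    """Draw per-voxel condition amplitudes and normalize the contrast.

    Amplitudes are i.i.d. N(0, 1) per voxel and condition; both
    conditions are then divided by the mean absolute contrast so the
    normalized contrast has mean |A - B| = 1 exactly.  The
    probability-zero event of a zero contrast triggers a logged redraw.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    for _ in range(max_redraws):
        means = rng.standard_normal((n_voxels, 2))
        scale = np.abs(means[:, 0] - means[:, 1]).mean()
        if scale > 0:
            return GroundTruth(condition_means=means / scale)
        warnings.warn("degenerate zero-contrast draw; redrawing",
                      RuntimeWarning, stacklevel=2)
    raise RuntimeError("could not draw a nonzero contrast")


def simulate_participant(design: BlockDesign,
                         truth: GroundTruth,
                         noise: NoiseSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """Simulate one participant: (subruns, timepoints, voxels).

    Per subrun the signal is the block boxcar times the condition
    amplitude plus per-block attention jitter, plus thermal noise, plus
    the scaled physiological projection.  The physiological projection
    weights (voxels x components) are drawn once here and shared across
    the participant's subruns; the component timecourses are redrawn
    independently for every subrun.
    """
    P = truth.n_voxels
    T = design.samples_per_subrun
    # One weight per voxel per component, fixed for the participant.
    weights = rng.standard_normal((P, noise.phys_n_components))
    out = np.empty((design.n_subruns, T, P))
    for s in range(design.n_subruns):
        B, labels = design.blockwise_regressors(s)  # (T, blocks)
        amplitudes = truth.condition_means[:, labels].T  # (blocks, P)
        if noise.attention_sd > 0:
            amplitudes = amplitudes + rng.normal(
                0.0, noise.attention_sd, size=amplitudes.shape)
        signal = B @ amplitudes
        if noise.thermal_sd > 0:
            signal = signal + rng.normal(0.0, noise.thermal_sd, size=(T, P))
        if noise.phys_scale > 0 and noise.phys_component_sd > 0:
            comps = rng.normal(0.0, noise.phys_component_sd,
                               size=(T, noise.phys_n_components))
            signal = signal + noise.phys_scale * (comps @ weights.T)
        out[s] = signal
    return out


def simulate_dataset(design: BlockDesign,
                     noise: NoiseSpec,
                     n_participants: int = 15,
                     n_voxels: int = 500,
                     seed: int | None = 0) -> SimulatedDataset:
    """Simulate an independent cohort with per-participant ground truths.

    One root seed drives everything; each participant gets its own
    spawned stream (truth first, then noise) so regenerating with the
    same seed is bit-identical.
    """
    root = np.random.SeedSequence(seed)
    truths: list[GroundTruth] = []
    data = None
    for i, child in enumerate(root.spawn(n_participants)):
        rng = np.random.default_rng(child)
        truth = draw_ground_truth(n_voxels, rng)
        sub = simulate_participant(design, truth, noise, rng)
        if data is None:
            data = np.empty((n_participants,) + sub.shape)
        data[i] = sub
        truths.append(truth)
    return SimulatedDataset(data=data, design=design, truths=truths,
                            noise=noise, seed=seed)


def measure_mean_fcnr(design: BlockDesign,
                      noise: NoiseSpec,
                      n_voxels: int = 500,
                      n_reps: int = 6,
                      seed: int | None = 0,
                      truth: GroundTruth | None = None) -> float:
    """Mean over voxels (and replicate participants) of the simulated
    between-condition fCNR.

    When ``truth`` is given it is reused for every replicate; otherwise
    each replicate draws its own ground truth.
    """
    root = np.random.SeedSequence(seed)
    vals = []
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        t = truth if truth is not None else draw_ground_truth(n_voxels, rng)
        data = simulate_participant(design, t, noise, rng)
        vals.append(compute_sim_fcnr(data, design).mean_over_roi)
    return float(np.mean(vals))


def calibrate_noise_to_fcnr(design: BlockDesign,
                            truth: GroundTruth | None,
                            noise_template: NoiseSpec,
                            target_fcnr: float,
                            rng: np.random.Generator | int | None = 0,
                            tol: float = 0.02,
                            n_reps: int = 20,
                            n_voxels: int | None = None,
                            max_scale: float = 4096.0) -> NoiseSpec:
    """Find the physiological scale that hits a target mean fCNR.

    Thermal and attention SDs are held at the template's values and only
    ``phys_scale`` is adjusted, by bisection against the measured mean
    simulation-fCNR at a fixed calibration seed (so the objective is a
    deterministic, monotonically decreasing function of the scale).
    ``tol`` is the guaranteed relative accuracy; the bisection itself
    converges to a quarter of it so that replicate-to-replicate sampling
    noise does not eat the whole budget.

    Raises
    ------
    CalibrationError
        If the target exceeds the fCNR achievable at ``phys_scale = 0``
        (the reported bound), or lies below what the maximum scale
        reaches.
    ValueError
        If the template has no noise at all (fCNR would be infinite).
    """
    if target_fcnr <= 0:
        raise ValueError("target_fcnr must be > 0")
    if noise_template.is_silent:
        raise ValueError(
            "noise template has no noise source; fCNR is unbounded and "
            "cannot be calibrated")
    if n_voxels is None:
        n_voxels = truth.n_voxels if truth is not None else 500
    if isinstance(rng, np.random.Generator):
        cal_seed = int(rng.integers(0, 2 ** 31))
    else:
        cal_seed = int(np.random.default_rng(rng).integers(0, 2 ** 31))

    def f(scale: float) -> float:
        spec = replace(noise_template, phys_scale=scale)
        return measure_mean_fcnr(design, spec, n_voxels=n_voxels,
                                 n_reps=n_reps, seed=cal_seed, truth=truth)

    tol_inner = 0.25 * tol
    f0 = f(0.0)
    if f0 < target_fcnr * (1 - tol):
        raise CalibrationError(
            f"target fCNR {target_fcnr} unreachable: even with no "
            f"physiological noise the mean fCNR is {f0:.4f}")
    if abs(f0 - target_fcnr) <= tol_inner * target_fcnr:
        return replace(noise_template, phys_scale=0.0)

    lo, hi = 0.0, max(noise_template.phys_scale, 1.0)
    f_hi = f(hi)
    while f_hi > target_fcnr:
        lo, hi = hi, hi * 2.0
        if hi > max_scale:
            raise CalibrationError(
                f"target fCNR {target_fcnr} below the {f_hi:.4f} reached "
                f"at phys_scale={lo}")
        f_hi = f(hi)

    for _ in range(100):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - target_fcnr) <= tol_inner * target_fcnr:
            logger.info("calibrated phys_scale=%.5f -> mean fCNR %.4f "
                        "(target %.4f)", mid, f_mid, target_fcnr)
            return replace(noise_template, phys_scale=mid)
        if f_mid > target_fcnr:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection failed to converge")
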