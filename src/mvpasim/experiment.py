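"""The decoding-sensitivity experiment: rejection-probability grids.

This module orchestrates the full simulation study: physiological
noise is calibrated so the mean between-condition fCNR hits each
requested level, cohorts of simulated participants are generated and
pushed through the LDC and SVM pipelines, and for every (fCNR_A,
fCNR_B) pairing the *rejection probability* — the fraction of
independently simulated datasets in which the group-level test reaches
significance — is tabulated per method.

Off-diagonal cells measure a method's sensitivity to a change in
contrast-to-noise (the simulated analogue of switching prospective
motion correction on or off); diagonal cells, where both cohorts share
the same noise level, estimate the false-positive rate and should sit
near alpha.  Within a pairing the two cohorts share each participant's
ground-truth contrast and differ only in noise, mirroring a
within-participant manipulation.

Randomness is organized as a seed tree: every (role, level, dataset,
participant) combination maps to its own deterministic stream derived
from the root seed, so any cell of the grid can be recomputed
independently and bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import BlockDesign, make_block_design
from .glm import fit_condition_glm, fit_blockwise_glm
from .mvpa import LdcResult, SvmResult, compute_ldc, svm_decode
from .stats import one_sample_ttest, paired_ttest
from .synth import (GroundTruth, NoiseSpec, calibrate_noise_to_fcnr,
                    draw_ground_truth, simulate_participant)

__all__ = [
    "ExperimentConfig",
    "ParticipantResult",
    "CellResult",
    "RejectionGrid",
    "CHANCE_LEVEL",
    "analyze_participant",
    "run_cohort",
    "calibrate_levels",
    "rejection_probability",
    "build_grid",
]

logger = logging.getLogger(__name__)

# Expected statistic value under the null, per method.
CHANCE_LEVEL = {"ldc": 0.0, "svm": 0.5}

# Seed-tree role tags (first element of every spawn key).
_ROLE_TRUTH = 1
_ROLE_NOISE = 2
_ROLE_CALIBRATION = 3


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=tuple(int(k) for k in key)))


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a rejection-probability grid."""

    block_duration_s: float = 16.0
    blocks_per_subrun: int = 8
    n_subruns: int = 4
    sample_period_s: float = 2.0
    inter_block_gap_s: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fcnr_levels: tuple[float, ...] = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4)
    n_datasets: int = 100
    n_participants: int = 15
    n_voxels: int = 500
    alpha: float = 0.05
    seed: int = 0
    methods: tuple[str, ...] = ("ldc", "svm")
    cov_target: str = "diagonal"
    calibration_reps: int = 6
    calibration_tol: float = 0.02

    def __post_init__(self):
        levels = tuple(self.fcnr_levels)
        if any(l <= 0 for l in levels):
            raise ValueError("fcnr_levels must be strictly positive")
        if list(levels) != sorted(levels):
            raise ValueError("fcnr_levels must be sorted ascending")
        object.__setattr__(self, "fcnr_levels", levels)
        object.__setattr__(self, "methods", tuple(self.methods))
        unknown = set(self.methods) - set(CHANCE_LEVEL)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def design(self) -> BlockDesign:
        return make_block_design(self.block_duration_s, self.blocks_per_subrun,
                                 self.n_subruns, self.sample_period_s,
                                 self.inter_block_gap_s)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise"] = asdict(self.noise)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseSpec(**d["noise"])
        if "fcnr_levels" in d:
            d["fcnr_levels"] = tuple(d["fcnr_levels"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)


@dataclass
class ParticipantResult:
    """Decoding statistics for one simulated (or real) participant."""

    ldc: LdcResult | None = None
    svm: SvmResult | None = None

    def statistic(self, method: str) -> float:
        if method == "ldc":
            if self.ldc is None:
                raise ValueError("LDC was not computed for this participant")
            return self.ldc.normalized
        if method == "svm":
            if self.svm is None:
                raise ValueError("SVM was not computed for this participant")
            return self.svm.mean_accuracy
        raise ValueError(f"unknown method {method!r}")


def analyze_participant(data_subruns: np.ndarray,
                        design: BlockDesign,
                        methods: Sequence[str] = ("ldc", "svm"),
                        cov_target: str = "diagonal") -> ParticipantResult:
    """Run one participant's data through the decoding pipelines.

    Each subrun is detrended and fitted twice: one event per condition
    (contrast + residuals for the crossnobis statistic) and one event
    per block (beta patterns for the SVM).
    """
    result = ParticipantResult()
    if "ldc" in methods:
        contrasts, residuals = [], []
        for s in range(design.n_subruns):
            fit = fit_condition_glm(data_subruns[s], design, s)
            contrasts.append(fit.contrast_estimate)
            residuals.append(fit.residuals)
        result.ldc = compute_ldc(np.array(contrasts), residuals,
                                 cov_target=cov_target)
    if "svm" in methods:
        betas, conds, subs = [], [], []
        for s in range(design.n_subruns):
            fit = fit_blockwise_glm(data_subruns[s], design, s)
            betas.append(fit.betas)
            conds.append(fit.regressor_labels)
            subs.append(np.full(fit.betas.shape[0], s))
        result.svm = svm_decode(np.vstack(betas), np.concatenate(conds),
                                np.concatenate(subs))
    return result


def run_cohort(config: ExperimentConfig,
               noise: NoiseSpec,
               dataset_index: int = 0,
               level_index: int = 0,
               side: int = 0,
               truths: Sequence[GroundTruth] | None = None,
               methods: Sequence[str] | None = None
               ) -> list[ParticipantResult]:
    """Simulate and analyze one cohort of participants.

    ``dataset_index`` selects the shared ground-truth draw (cohorts of
    the same dataset index share truths, so paired noise levels are a
    within-participant manipulation); ``level_index`` and ``side``
    separate the noise streams of the two cohorts of a pairing.
    """
    design = config.design()
    methods = config.methods if methods is None else tuple(methods)
    results = []
    for i in range(config.n_participants):
        if truths is not None:
            truth = truths[i]
        else:
            truth = draw_ground_truth(
                config.n_voxels,
                _stream(config.seed, _ROLE_TRUTH, dataset_index, i))
        noise_rng = _stream(config.seed, _ROLE_NOISE, level_index, side,
                            dataset_index, i)
        data = simulate_participant(design, truth, noise, noise_rng)
        results.append(analyze_participant(data, design, methods=methods,
                                           cov_target=config.cov_target))
    return results


def calibrate_levels(config: ExperimentConfig,
                     levels: Sequence[float] | None = None
                     ) -> dict[float, NoiseSpec]:
    """Calibrate the physiological scale for each requested fCNR level."""
    design = config.design()
    levels = config.fcnr_levels if levels is None else levels
    out: dict[float, NoiseSpec] = {}
    for k, level in enumerate(levels):
        cal_seed = int(_stream(config.seed, _ROLE_CALIBRATION, k)
                       .integers(0, 2 ** 31))
        out[level] = calibrate_noise_to_fcnr(
            design, None, config.noise, level, rng=cal_seed,
            tol=config.calibration_tol, n_reps=config.calibration_reps,
            n_voxels=config.n_voxels)
        logger.info("level %.3g calibrated: phys_scale=%.5f",
                    level, out[level].phys_scale)
    return out


@dataclass
class CellResult:
    """One grid cell: rejection probability plus per-dataset p-values."""

    probability: float
    p_values: np.ndarray
    method: str
    level_a: float
    level_b: float | None


def rejection_probability(config: ExperimentConfig,
                          level_a: float,
                          level_b: float | None,
                          method: str = "ldc",
                          calibrations: dict[float, NoiseSpec] | None = None
                          ) -> CellResult:
    """Fraction of simulated datasets whose group test rejects the null.

    With two levels, each dataset simulates paired cohorts (shared
    ground truths, independent noise at each level) and applies a paired
    t-test to the per-participant statistics.  With ``level_b=None``
    the statistic is tested against its chance level with a one-sample
    t-test (LDC vs 0, SVM accuracy vs 1/2).
    """
    levels = [level_a] if level_b is None else [level_a, level_b]
    for lv in levels:
        if lv not in config.fcnr_levels:
            raise ValueError(f"level {lv} not in config.fcnr_levels")
    if calibrations is None:
        calibrations = calibrate_levels(config, levels)
    idx_a = config.fcnr_levels.index(level_a)
    p_values = np.empty(config.n_datasets)
    for d in range(config.n_datasets):
        cohort_a = run_cohort(config, calibrations[level_a],
                              dataset_index=d, level_index=idx_a, side=0,
                              methods=(method,))
        stats_a = [r.statistic(method) for r in cohort_a]
        if level_b is None:
            test = one_sample_ttest(stats_a, alpha=config.alpha,
                                    popmean=CHANCE_LEVEL[method])
        else:
            idx_b = config.fcnr_levels.index(level_b)
            cohort_b = run_cohort(config, calibrations[level_b],
                                  dataset_index=d, level_index=idx_b, side=1,
                                  methods=(method,))
            stats_b = [r.statistic(method) for r in cohort_b]
            test = paired_ttest(stats_a, stats_b, alpha=config.alpha)
        p_values[d] = test.p_value
    prob = float(np.mean(p_values < config.alpha))
    return CellResult(probability=prob, p_values=p_values, method=method,
                      level_a=level_a, level_b=level_b)


@dataclass
class RejectionGrid:
    """Rejection probabilities for every fCNR pairing, per method.

    ``cells[method]`` is an (L, L) array over ``fcnr_levels`` x
    ``fcnr_levels``; entry (i, j) is the probability of rejecting the
    null of no difference between cohorts at levels i and j.  The grid
    is symmetric by construction (the paired test is two-sided).
    """

    fcnr_levels: tuple[float, ...]
    cells: dict[str, np.ndarray]
    n_datasets: int
    n_participants: int
    alpha: float
    seed: int

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for method, grid in self.cells.items():
            for i, la in enumerate(self.fcnr_levels):
                for j, lb in enumerate(self.fcnr_levels):
                    rows.append({"method": method, "fcnr_a": la, "fcnr_b": lb,
                                 "rejection_probability": grid[i, j]})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "fcnr_levels": list(self.fcnr_levels),
            "n_datasets": self.n_datasets,
            "n_participants": self.n_participants,
            "alpha": self.alpha,
            "seed": self.seed,
            "cells": {m: g.tolist() for m, g in self.cells.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "RejectionGrid":
        d = json.loads(Path(path).read_text())
        return cls(fcnr_levels=tuple(d["fcnr_levels"]),
                   cells={m: np.array(g) for m, g in d["cells"].items()},
                   n_datasets=d["n_datasets"],
                   n_participants=d["n_participants"],
                   alpha=d["alpha"], seed=d["seed"])


def build_grid(config: ExperimentConfig,
               manifest_path=None) -> RejectionGrid:
    """Fill the full rejection-probability grid for every method.

    Only the upper triangle (including the diagonal) is computed; the
    lower triangle mirrors it.  When ``manifest_path`` is given,
    finished cells are persisted there after each computation and reused
    on restart, making long grids resumable.
    """
    calibrations = calibrate_levels(config)
    L = len(config.fcnr_levels)
    done: dict[str, float] = {}
    if manifest_path is not None and Path(manifest_path).exists():
        done = json.loads(Path(manifest_path).read_text())
        logger.info("resuming grid: %d cells already done", len(done))
    cells = {m: np.full((L, L), np.nan) for m in config.methods}
    for method in config.methods:
        for i in range(L):
            for j in range(i, L):
                key = f"{method}:{i}:{j}"
                if key in done:
                    prob = done[key]
                else:
                    cell = rejection_probability(
                        config, config.fcnr_levels[i], config.fcnr_levels[j],
                        method=method, calibrations=calibrations)
                    prob = cell.probability
                    done[key] = prob
                    if manifest_path is not None:
                        Path(manifest_path).write_text(json.dumps(done))
                cells[method][i, j] = cells[method][j, i] = prob
                logger.info("cell %s -> %.3f", key, prob)
    return RejectionGrid(fcnr_levels=config.fcnr_levels, cells=cells,
                         n_datasets=config.n_datasets,
                         n_participants=config.n_participants,
                         alpha=config.alpha, seed=config.seed)
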