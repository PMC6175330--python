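"""Multivoxel pattern analysis: crossnobis LDC and linear-SVM decoding.

The linear discriminant contrast (LDC, a.k.a. crossnobis distance) is a
cross-validated, continuous pattern-discriminability statistic.  For
each leave-one-subrun-out fold, the training subruns supply (i) a mean
condition-contrast pattern and (ii) noise residuals from which a
shrinkage covariance is estimated; the whitened training contrast
``w = Sigma^{-1} c_train`` is the discriminant, and the fold statistic
is ``w . c_test`` against the held-out subrun's independent contrast
estimate.  Because train and test noise are independent, the statistic
is unbiased: centred on zero when there is no true pattern difference,
with negative values perfectly legal.  The fold average is divided by
sqrt(n_voxels) so values are comparable across ROI sizes.

The SVM route follows common decoding practice: one beta pattern per
presentation block, a linear-kernel SVM with unit box constraint
trained on the blocks of the training subruns (features standardized by
training-fold statistics), accuracy measured on the held-out subrun's
blocks.  Its output is bounded and discretized (multiples of one over
the test-block count per fold), which is what limits its sensitivity
relative to the LDC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.covariance import ledoit_wolf as _sk_ledoit_wolf
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ShrinkageCovariance",
    "LdcResult",
    "SvmResult",
    "ledoit_wolf_covariance",
    "compute_ldc",
    "svm_decode",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# shrinkage covariance

@dataclass
class ShrinkageCovariance:
    """A Ledoit-Wolf-regularized covariance estimate.

    ``matrix = (1 - lambda) * S + lambda * T`` for sample covariance S,
    shrinkage target T and analytically estimated intensity lambda.
    """

    matrix: np.ndarray
    shrinkage_intensity: float
    source_df: int
    target: str = "diagonal"


def ledoit_wolf_covariance(residuals: np.ndarray,
                           target: str = "diagonal",
                           shrinkage: float | None = None) -> ShrinkageCovariance:
    """Shrinkage covariance of noise residuals (timepoints x voxels).

    ``target="diagonal"`` shrinks off-diagonals toward zero while
    preserving the sample variances — the usual choice for MVPA noise
    normalization, where voxel variances are meaningful but the
    off-diagonal sample covariance is rank-deficient noise.  The
    intensity follows the Ledoit-Wolf quadratic-loss estimate adapted to
    the diagonal target.  ``target="identity"`` delegates to
    scikit-learn's scaled-identity Ledoit-Wolf estimator.

    ``shrinkage`` overrides the estimated intensity (useful for the
    lambda = 1 boundary, which returns the target exactly).
    """
    X = np.asarray(residuals, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (timepoints >= 2, voxels) residual matrix")
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / n
    diag = np.diag(S)
    if np.all(S == 0):
        raise ValueError("residuals are constant; covariance is zero")

    if target == "identity":
        if shrinkage is None:
            matrix, lam = _sk_ledoit_wolf(X, assume_centered=False)
        else:
            lam = float(shrinkage)
            mu = diag.mean()
            matrix = (1 - lam) * S + lam * mu * np.eye(p)
        return ShrinkageCovariance(matrix=np.asarray(matrix),
                                   shrinkage_intensity=float(lam),
                                   source_df=n, target="identity")
    if target != "diagonal":
        raise ValueError(f"unknown shrinkage target {target!r}")

    T = np.diag(diag)
    if shrinkage is None:
        # Variance of the sample covariance entries, estimated from the
        # fourth moments; shrink in proportion to the off-diagonal
        # misfit (Ledoit-Wolf intensity for the diagonal target).
        Y = Xc ** 2
        phi_mat = (Y.T @ Y) / n - S ** 2
        phi = float(phi_mat.sum())
        gamma = float(((S - T) ** 2).sum())
        lam = 1.0 if gamma == 0 else min(1.0, max(0.0, phi / gamma / n))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
    matrix = (1 - lam) * S + lam * T
    return ShrinkageCovariance(matrix=matrix, shrinkage_intensity=lam,
                               source_df=n, target="diagonal")


# ---------------------------------------------------------------------------
# crossnobis / LDC

@dataclass
class LdcResult:
    """Cross-validated linear discriminant contrast for one participant."""

    per_fold: np.ndarray
    mean: float
    normalized: float
    n_voxels: int

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)


def compute_ldc(contrasts_per_subrun: np.ndarray,
                residuals_per_subrun: Sequence[np.ndarray],
                n_subruns: int | None = None,
                cov_target: str = "diagonal") -> LdcResult:
    """Leave-one-subrun-out crossnobis statistic.

    Parameters
    ----------
    contrasts_per_subrun : (n_subruns, n_voxels)
        Independent condition-contrast estimates, one per subrun.
    residuals_per_subrun : sequence of (timepoints, voxels)
        GLM noise residuals per subrun; only the training subruns' pooled
        residuals enter each fold's covariance, preserving fold
        independence.
    cov_target : "diagonal" or "identity"
        Shrinkage target for the noise covariance.

    Each fold computes ``(Sigma_train^{-1} c_train) . c_test`` with
    ``c_train`` the mean training contrast; the result carries the fold
    values, their mean, and the sqrt(n_voxels)-normalized mean.
    """
    C = np.asarray(contrasts_per_subrun, dtype=float)
    if C.ndim != 2:
        raise ValueError("contrasts_per_subrun must be (subruns, voxels)")
    S, P = C.shape
    if n_subruns is not None and n_subruns != S:
        raise ValueError(f"got {S} contrasts for n_subruns={n_subruns}")
    if S < 2:
        raise ValueError("need at least 2 subruns for cross-validation")
    if len(residuals_per_subrun) != S:
        raise ValueError("one residual matrix per subrun required")
    for R in residuals_per_subrun:
        if np.shape(R)[1] != P:
            raise ValueError("residual voxel dimension mismatch")

    per_fold = np.empty(S)
    for test in range(S):
        train = [s for s in range(S) if s != test]
        c_train = C[train].mean(axis=0)
        pooled = np.vstack([residuals_per_subrun[s] for s in train])
        cov = ledoit_wolf_covariance(pooled, target=cov_target)
        cho = scipy.linalg.cho_factor(cov.matrix, lower=True)
        w = scipy.linalg.cho_solve(cho, c_train)
        per_fold[test] = float(w @ C[test])
    mean = float(per_fold.mean())
    return LdcResult(per_fold=per_fold, mean=mean,
                     normalized=mean / np.sqrt(P), n_voxels=P)


# ---------------------------------------------------------------------------
# SVM decoding

@dataclass
class SvmResult:
    """Leave-one-subrun-out linear-SVM decoding accuracies."""

    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    n_test_per_fold: int
    n_boundary_ties: int = 0


def svm_decode(block_betas: np.ndarray,
               conditions: np.ndarray,
               subruns: np.ndarray,
               C: float = 1.0) -> SvmResult:
    """Leave-one-subrun-out linear-SVM classification of block patterns.

    ``block_betas`` is (n_blocks_total, n_voxels) with parallel
    ``conditions`` and ``subruns`` label vectors.  Features are
    standardized using training-fold statistics only.  Test patterns
    exactly on the decision boundary are assigned to the first class
    (sorted label order) and counted in ``n_boundary_ties``.
    """
    X = np.asarray(block_betas, dtype=float)
    conditions = np.asarray(conditions)
    subruns = np.asarray(subruns)
    if not (len(X) == len(conditions) == len(subruns)):
        raise ValueError("block_betas, conditions and subruns must align")
    classes = np.unique(conditions)
    if len(classes) != 2:
        raise ValueError("exactly two condition labels required")
    fold_ids = np.unique(subruns)
    accs = []
    n_ties = 0
    n_test = None
    for fold in fold_ids:
        test_mask = subruns == fold
        train_mask = ~test_mask
        y_train = conditions[train_mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"training fold for subrun {fold} contains a single class")
        scaler = StandardScaler().fit(X[train_mask])
        clf = SVC(kernel="linear", C=C)
        clf.fit(scaler.transform(X[train_mask]), y_train)
        scores = clf.decision_function(scaler.transform(X[test_mask]))
        ties = scores == 0.0
        n_ties += int(ties.sum())
        # decision_function > 0 corresponds to clf.classes_[1]
        pred = np.where(scores > 0, clf.classes_[1], clf.classes_[0])
        accs.append(float(np.mean(pred == conditions[test_mask])))
        n_test = int(test_mask.sum()) if n_test is None else n_test
    if n_ties:
        logger.info("svm_decode: %d test pattern(s) fell exactly on the "
                    "decision boundary; assigned to the first class", n_ties)
    per_fold = np.array(accs)
    return SvmResult(per_fold_accuracy=per_fold,
                     mean_accuracy=float(per_fold.mean()),
                     n_test_per_fold=n_test,
                     n_boundary_ties=n_ties)
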