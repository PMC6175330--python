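"""Detrending, ordinary-least-squares model fitting, and fCNR.

The analysis chain mirrors a standard block-design univariate pipeline:
each subrun is detrended (constant + linear ramp + one sine/cosine pair
at the segment's fundamental period), the same detrending projection is
applied to the regressor matrix, and an OLS fit yields per-voxel
coefficients, a two-condition contrast, and residuals.

Two functional contrast-to-noise definitions are provided:

``compute_fcnr_stimulus``
    Stimulus-vs-baseline fCNR for a single on/off regressor: signal
    peak of the fitted timecourse divided by the residual standard
    deviation.

``compute_sim_fcnr``
    Between-condition fCNR for the two-condition design: the absolute
    condition-contrast estimate divided by its pooled GLM standard
    error (the ``contrast_se`` denominator, default).  A variant that
    divides by the raw residual SD is available via
    ``denominator="residual_sd"``; note that with unit-scale contrasts
    and thermal noise of SD ~1.8 that variant is bounded well below 1
    and cannot reach calibration targets in the 1.6-1.8 range, which is
    why the standard-error form is the calibration quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .design import BlockDesign

__all__ = [
    "GlmFit",
    "FcnrResult",
    "detrend_basis",
    "detrend",
    "fit_glm",
    "fit_condition_glm",
    "fit_blockwise_glm",
    "compute_fcnr_stimulus",
    "compute_sim_fcnr",
]


# ---------------------------------------------------------------------------
# detrending

def detrend_basis(n_timepoints: int) -> np.ndarray:
    """Orthonormal basis (n, 4): constant, linear ramp, sin and cos at the
    segment's fundamental period."""
    if n_timepoints < 4:
        raise ValueError(
            f"need >= 4 timepoints to fit the detrending basis, "
            f"got {n_timepoints}")
    t = np.arange(n_timepoints, dtype=float)
    phase = 2.0 * np.pi * t / n_timepoints
    B = np.column_stack([np.ones_like(t), t, np.sin(phase), np.cos(phase)])
    Q, _ = np.linalg.qr(B)
    return Q


def detrend(timecourse_matrix: np.ndarray,
            sample_period_s: float | None = None) -> np.ndarray:
    """Project constant, linear and first-harmonic sinusoidal drift out of
    a (timepoints, voxels) segment.

    The basis period equals the segment length, so this is applied per
    subrun.  ``sample_period_s`` is accepted for interface symmetry; the
    basis depends only on the number of samples.  Output columns have
    zero mean (the constant is in the basis).
    """
    X = np.asarray(timecourse_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Q = detrend_basis(X.shape[0])
    return X - Q @ (Q.T @ X)


# ---------------------------------------------------------------------------
# OLS

@dataclass
class GlmFit:
    """Ordinary-least-squares fit of one data segment.

    Attributes
    ----------
    betas : (n_regressors, n_voxels)
    contrast_estimate : (n_voxels,) or None
        ``c' @ betas`` for the supplied contrast weights.
    residuals : (n_timepoints, n_voxels)
    design_used : (n_timepoints, n_regressors)
        The regressor matrix actually fitted (post-detrend if the caller
        detrended it).
    contrast_weights : (n_regressors,) or None
    regressor_labels : (n_regressors,) int array or None
        Condition label per regressor (used by block-wise fits).
    rank : int
        Column rank of ``design_used``.  A contiguous alternating design
        loses one rank after detrending (the condition boxcars sum to
        the constant the detrend removes); the fit is then minimum-norm
        and only contrasts orthogonal to the null space — such as the
        condition difference — are estimable.
    df_lost_to_detrend : int
        Rank of any detrending basis projected out before the fit;
        charged against the residual degrees of freedom.
    """

    betas: np.ndarray
    contrast_estimate: np.ndarray | None
    residuals: np.ndarray
    design_used: np.ndarray
    contrast_weights: np.ndarray | None = None
    regressor_labels: np.ndarray | None = None
    rank: int = 0
    df_lost_to_detrend: int = 0

    @property
    def df_residual(self) -> int:
        return (self.design_used.shape[0] - self.rank
                - self.df_lost_to_detrend)

    def residual_sd(self) -> np.ndarray:
        """Per-voxel residual SD with n - rank(design) - detrend df
        denominator (unbiased under white noise)."""
        df = self.df_residual
        if df <= 0:
            raise ValueError("no residual degrees of freedom")
        return np.sqrt((self.residuals ** 2).sum(axis=0) / df)

    def contrast_se(self) -> np.ndarray:
        """Per-voxel standard error of the contrast estimate (white-noise
        OLS formula; pseudoinverse-based so estimable contrasts of
        rank-deficient minimum-norm fits are handled)."""
        if self.contrast_weights is None:
            raise ValueError("fit has no contrast weights")
        X = self.design_used
        c = self.contrast_weights
        xtx_pinv = np.linalg.pinv(X.T @ X)
        return self.residual_sd() * np.sqrt(c @ xtx_pinv @ c)


def _dependent_columns(X: np.ndarray) -> list[int]:
    """Indices of columns that are linearly dependent on earlier ones."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return sorted(int(j) for j in piv[rank:])


def fit_glm(data: np.ndarray,
            design: np.ndarray,
            contrast_weights: np.ndarray | None = None,
            regressor_labels: np.ndarray | None = None,
            rank_policy: str = "strict",
            df_lost_to_detrend: int = 0) -> GlmFit:
    """OLS fit of ``data`` (timepoints x voxels) on ``design``.

    With ``rank_policy="strict"`` (default) the design must be full
    column rank; otherwise a ``ValueError`` naming the dependent column
    indices is raised.  ``rank_policy="minimum_norm"`` accepts a
    rank-deficient design and returns the minimum-norm solution, in
    which case only estimable contrasts are meaningful.
    """
    Y = np.asarray(data, dtype=float)
    X = np.asarray(design, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim == 1:
        X = X[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"data has {Y.shape[0]} timepoints but design has {X.shape[0]}")
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1] and rank_policy == "strict":
        bad = _dependent_columns(X)
        raise ValueError(f"design is rank deficient; dependent columns: {bad}")
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ betas
    contrast = None
    cw = None
    if contrast_weights is not None:
        cw = np.asarray(contrast_weights, dtype=float)
        contrast = cw @ betas
    return GlmFit(betas=betas, contrast_estimate=contrast,
                  residuals=residuals, design_used=X,
                  contrast_weights=cw, regressor_labels=regressor_labels,
                  rank=rank, df_lost_to_detrend=df_lost_to_detrend)


def fit_condition_glm(data_subrun: np.ndarray,
                      design: BlockDesign,
                      subrun: int,
                      apply_detrend: bool = True) -> GlmFit:
    """One-event-per-condition fit of one subrun.

    Detrending (when enabled) is applied identically to the data and the
    boxcar regressors before the fit.  The contrast is condition A minus
    condition B, i.e. weights (+1, -1).
    """
    X = design.condition_regressors(subrun)
    Y = np.asarray(data_subrun, dtype=float)
    df_lost = 0
    if apply_detrend:
        Y = detrend(Y)
        X = detrend(X)
        df_lost = 4
    c = np.zeros(design.n_conditions)
    c[0], c[1] = 1.0, -1.0
    # A gap-free alternating design loses one rank after detrending
    # (boxcars sum to the removed constant); the A-B contrast remains
    # estimable, so accept the minimum-norm fit.
    return fit_glm(Y, X, contrast_weights=c,
                   regressor_labels=np.arange(design.n_conditions),
                   rank_policy="minimum_norm", df_lost_to_detrend=df_lost)


def fit_blockwise_glm(data_subrun: np.ndarray,
                      design: BlockDesign,
                      subrun: int,
                      apply_detrend: bool = True) -> GlmFit:
    """One-event-per-block fit of one subrun (for classifier samples).

    Yields one beta pattern per presentation block; ``regressor_labels``
    carries each block's condition.  The contrast weights average the A
    blocks minus the B blocks, so the contrast estimate agrees with the
    one-event-per-condition fit on balanced noiseless data.
    """
    X, labels = design.blockwise_regressors(subrun)
    Y = np.asarray(data_subrun, dtype=float)
    df_lost = 0
    if apply_detrend:
        Y = detrend(Y)
        X = detrend(X)
        df_lost = 4
    c = np.where(labels == 0, 1.0, -1.0).astype(float)
    c /= (labels == 0).sum()
    return fit_glm(Y, X, contrast_weights=c, regressor_labels=labels,
                   rank_policy="minimum_norm", df_lost_to_detrend=df_lost)


# ---------------------------------------------------------------------------
# fCNR

@dataclass
class FcnrResult:
    """Per-voxel fCNR values plus the ROI mean.

    Voxels whose noise denominator is zero are NaN in ``per_voxel``,
    excluded from ``mean_over_roi`` and counted in ``n_undefined``.
    """

    per_voxel: np.ndarray
    mean_over_roi: float
    n_undefined: int = 0


def _finalize_fcnr(amplitude: np.ndarray, noise_sd: np.ndarray) -> FcnrResult:
    # Treat numerically-zero noise (e.g. noiseless data whose residuals
    # are pure round-off) as undefined rather than yielding huge ratios.
    defined = noise_sd > 1e-12 * np.maximum(1.0, amplitude)
    per_voxel = np.full(amplitude.shape, np.nan)
    per_voxel[defined] = amplitude[defined] / noise_sd[defined]
    n_undef = int((~defined).sum())
    mean = float(np.nanmean(per_voxel)) if defined.any() else float("nan")
    return FcnrResult(per_voxel=per_voxel, mean_over_roi=mean,
                      n_undefined=n_undef)


def compute_fcnr_stimulus(data: np.ndarray,
                          design_on_off: np.ndarray) -> FcnrResult:
    """Stimulus-vs-baseline fCNR from a single on/off regressor.

    The baseline is implicit (zero), so the signal amplitude is the peak
    of the fitted timecourse, ``|beta| * max(regressor)``, and the noise
    is the residual SD of the GLM.
    """
    X = np.asarray(design_on_off, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != 1:
        raise ValueError("expected a single on/off stimulus regressor")
    fit = fit_glm(data, X)
    amplitude = np.abs(fit.betas[0]) * float(np.max(np.abs(X)))
    return _finalize_fcnr(amplitude, fit.residual_sd())


def compute_sim_fcnr(data_subruns: np.ndarray,
                     design: BlockDesign,
                     denominator: str = "contrast_se") -> FcnrResult:
    """Between-condition fCNR of a simulated (or real) multi-subrun run.

    Fits the one-event-per-condition GLM per detrended subrun, averages
    the condition-contrast estimate over subruns, and divides by the
    chosen noise measure:

    - ``"contrast_se"`` (default): pooled standard error of the
      subrun-averaged contrast estimate — the calibration quantity.
    - ``"residual_sd"``: pooled residual SD of the GLM.
    """
    data_subruns = np.asarray(data_subruns, dtype=float)
    if data_subruns.ndim != 3:
        raise ValueError("expected (subruns, timepoints, voxels) data")
    n_subruns = data_subruns.shape[0]
    contrasts = []
    se2 = 0.0
    rss = 0.0
    df = 0
    for s in range(n_subruns):
        fit = fit_condition_glm(data_subruns[s], design, s)
        contrasts.append(fit.contrast_estimate)
        se2 = se2 + fit.contrast_se() ** 2
        rss = rss + (fit.residuals ** 2).sum(axis=0)
        df += fit.df_residual
    mean_contrast = np.mean(contrasts, axis=0)
    amplitude = np.abs(mean_contrast)
    if denominator == "contrast_se":
        noise = np.sqrt(se2) / n_subruns  # SE of the subrun average
    elif denominator == "residual_sd":
        noise = np.sqrt(rss / df)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return _finalize_fcnr(amplitude, noise)
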