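import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvpasim import (NoiseSpec, compute_fcnr_stimulus, compute_sim_fcnr,
                     detrend, draw_ground_truth, fit_blockwise_glm,
                     fit_condition_glm, fit_glm, make_block_design,
                     simulate_participant)

SILENT = NoiseSpec(attention_sd=0.0, thermal_sd=0.0, phys_scale=0.0)


def qr_detrend_oracle(X):
    """Independent projection oracle: raw basis + lstsq residual."""
    t = np.arange(X.shape[0], dtype=float)
    B = np.column_stack([np.ones_like(t), t,
                         np.sin(2 * np.pi * t / len(t)),
                         np.cos(2 * np.pi * t / len(t))])
    coef, *_ = np.linalg.lstsq(B, X, rcond=None)
    return X - B @ coef


# ---------------------------------------------------------------------------
# detrending

@settings(deadline=None, derandomize=True, max_examples=25)
@given(slope=st.floats(-5, 5), intercept=st.floats(-10, 10))
def test_detrend_removes_any_ramp(slope, intercept):
    t = np.arange(64, dtype=float)
    out = detrend(slope * t + intercept)
    assert np.max(np.abs(out)) < 1e-10


def test_detrend_removes_first_harmonic():
    t = np.arange(100, dtype=float)
    sig = np.column_stack([np.sin(2 * np.pi * t / 100),
                           np.cos(2 * np.pi * t / 100)])
    assert np.max(np.abs(detrend(sig))) < 1e-10


def test_detrend_matches_independent_oracle_and_reduces_variance(rng):
    X = rng.standard_normal((120, 30))
    out = detrend(X)
    np.testing.assert_allclose(out, qr_detrend_oracle(X), atol=1e-10)
    assert np.all(out.var(axis=0) < X.var(axis=0))
    np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)


def test_detrend_requires_four_timepoints():
    with pytest.raises(ValueError, match="4 timepoints"):
        detrend(np.ones((3, 2)))


# ---------------------------------------------------------------------------
# OLS fitting

def test_noiseless_fit_recovers_condition_means(default_design, rng):
    truth = draw_ground_truth(30, rng)
    data = simulate_participant(default_design, truth, SILENT, rng)
    for s in range(default_design.n_subruns):
        fit = fit_condition_glm(data[s], default_design, s,
                                apply_detrend=False)
        np.testing.assert_allclose(fit.betas, truth.condition_means.T,
                                   atol=1e-8)
        np.testing.assert_allclose(fit.contrast_estimate,
                                   truth.contrast_vector, atol=1e-8)


def test_noiseless_contrast_survives_detrending(default_design, rng):
    # With contiguous alternating blocks, detrending removes the mean
    # response but the A-B contrast stays exactly estimable.
    truth = draw_ground_truth(30, rng)
    data = simulate_participant(default_design, truth, SILENT, rng)
    fit = fit_condition_glm(data[0], default_design, 0)
    np.testing.assert_allclose(fit.contrast_estimate, truth.contrast_vector,
                               atol=1e-8)


def test_blockwise_betas_average_to_condition_betas(default_design, rng):
    truth = draw_ground_truth(25, rng)
    data = simulate_participant(default_design, truth, SILENT, rng)
    cond = fit_condition_glm(data[0], default_design, 0, apply_detrend=False)
    block = fit_blockwise_glm(data[0], default_design, 0, apply_detrend=False)
    assert block.betas.shape[0] == default_design.blocks_per_subrun
    for c in (0, 1):
        mean_beta = block.betas[block.regressor_labels == c].mean(axis=0)
        np.testing.assert_allclose(mean_beta, cond.betas[c], atol=1e-8)
    np.testing.assert_allclose(block.contrast_estimate,
                               cond.contrast_estimate, atol=1e-8)


def test_duplicated_column_rejected_with_indices(rng):
    X = rng.standard_normal((50, 2))
    X = np.column_stack([X, X[:, 1]])
    with pytest.raises(ValueError, match=r"dependent columns: \[2\]"):
        fit_glm(rng.standard_normal(50), X)


def test_residuals_orthogonal_to_design(default_design, rng):
    truth = draw_ground_truth(40, rng)
    data = simulate_participant(default_design, truth, NoiseSpec(), rng)
    for s in range(default_design.n_subruns):
        fit = fit_condition_glm(data[s], default_design, s)
        xtr = fit.design_used.T @ fit.residuals
        scale = np.abs(fit.design_used).max() * np.abs(data[s]).max()
        assert np.max(np.abs(xtr)) < 1e-8 * max(scale, 1.0)


def test_refitting_residuals_gives_zero_betas(default_design, rng):
    truth = draw_ground_truth(20, rng)
    data = simulate_participant(default_design, truth, NoiseSpec(), rng)
    fit = fit_condition_glm(data[0], default_design, 0)
    refit = fit_glm(fit.residuals, fit.design_used,
                    rank_policy="minimum_norm")
    assert np.max(np.abs(refit.betas)) < 1e-8


# ---------------------------------------------------------------------------
# fCNR

def _orthogonal_unit_sd_noise(X, n, rng, df):
    e = rng.standard_normal(n)
    e -= X @ np.linalg.lstsq(X, e, rcond=None)[0]
    return e / np.sqrt((e ** 2).sum() / df)


@pytest.mark.parametrize("beta", [2.0, -2.0])
def test_stimulus_fcnr_direct_substitution(beta, rng):
    # boxcar peaking at 1, residual SD exactly 1 -> fCNR == |beta|
    n = 80
    x = np.zeros(n)
    x[10:30] = 1.0
    x[50:70] = 1.0
    e = _orthogonal_unit_sd_noise(x[:, None], n, rng, df=n - 1)
    data = beta * x + e
    res = compute_fcnr_stimulus(data, x)
    np.testing.assert_allclose(res.per_voxel, [2.0], atol=1e-10)
    assert res.n_undefined == 0


def test_stimulus_fcnr_flags_zero_residual_voxels():
    n = 40
    x = np.zeros(n)
    x[5:15] = 1.0
    data = np.column_stack([2.0 * x, 2.0 * x])  # zero residuals
    res = compute_fcnr_stimulus(data, x)
    assert res.n_undefined == 2
    assert np.isnan(res.mean_over_roi)


def test_sim_fcnr_scale_invariance(default_design, rng):
    truth = draw_ground_truth(50, rng)
    data = simulate_participant(default_design, truth, NoiseSpec(), rng)
    for denom in ("contrast_se", "residual_sd"):
        a = compute_sim_fcnr(data, default_design, denominator=denom)
        b = compute_sim_fcnr(3.0 * data, default_design, denominator=denom)
        np.testing.assert_allclose(a.per_voxel, b.per_voxel, rtol=1e-10)


def test_sim_fcnr_zero_noise_is_undefined(default_design, rng):
    truth = draw_ground_truth(20, rng)
    data = simulate_participant(default_design, truth, SILENT, rng)
    res = compute_sim_fcnr(data, default_design)
    assert res.n_undefined == 20
    assert np.isnan(res.mean_over_roi)


def test_sim_fcnr_in_calibrated_regime(default_design, rng):
    # At the study's noise levels the between-condition fCNR sits in the
    # low single digits, the regime the calibration targets live in.
    truth = draw_ground_truth(200, rng)
    data = simulate_participant(default_design, truth, NoiseSpec(), rng)
    res = compute_sim_fcnr(data, default_design)
    assert 1.0 < res.mean_over_roi < 4.0

def test_sim_fcnr_unknown_denominator(default_design, rng):
    truth = draw_ground_truth(10, rng)
    data = simulate_participant(default_design, truth, NoiseSpec(), rng)
    with pytest.raises(ValueError, match="denominator"):
        compute_sim_fcnr(data, default_design, denominator="bogus")
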