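import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.covariance import ledoit_wolf as sk_ledoit_wolf

from mvpasim import (NoiseSpec, compute_ldc, draw_ground_truth,
                     ledoit_wolf_covariance, simulate_participant, svm_decode)
from mvpasim.experiment import analyze_participant
from mvpasim.synth import GroundTruth


# ---------------------------------------------------------------------------
# shrinkage covariance

def covdiag_oracle(X):
    """Hand-rolled diagonal-target Ledoit-Wolf, explicit loops."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            S[i, j] = (Xc[:, i] * Xc[:, j]).sum() / n
    T = np.diag(np.diag(S))
    phi = 0.0
    for i in range(p):
        for j in range(p):
            phi += ((Xc[:, i] ** 2 * Xc[:, j] ** 2).sum() / n - S[i, j] ** 2)
    gamma = ((S - T) ** 2).sum()
    lam = 1.0 if gamma == 0 else min(1.0, max(0.0, phi / gamma / n))
    return (1 - lam) * S + lam * T


def test_full_shrinkage_returns_target_exactly(rng):
    X = rng.standard_normal((30, 5))
    cov = ledoit_wolf_covariance(X, shrinkage=1.0)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    np.testing.assert_allclose(cov.matrix, np.diag(np.diag(S)), atol=1e-12)
    assert cov.shrinkage_intensity == 1.0


def test_estimate_converges_to_true_covariance(rng):
    true_cov = 0.7 ** np.abs(np.subtract.outer(np.arange(5), np.arange(5)))
    errs = []
    for n in (100, 10_000):
        X = rng.multivariate_normal(np.zeros(5), true_cov, size=n)
        est = ledoit_wolf_covariance(X).matrix
        errs.append(np.linalg.norm(est - true_cov))
    assert errs[1] < errs[0]
    assert errs[1] < 0.1


def test_iid_two_voxel_limit(rng):
    X = rng.standard_normal((4000, 2))
    cov = ledoit_wolf_covariance(X).matrix
    np.testing.assert_allclose(np.diag(cov), 1.0, atol=0.1)
    assert abs(cov[0, 1]) < 0.05


def test_identity_target_matches_sklearn(rng):
    X = rng.standard_normal((40, 8)) @ rng.standard_normal((8, 8))
    ours = ledoit_wolf_covariance(X, target="identity")
    ref_cov, ref_shrink = sk_ledoit_wolf(X, assume_centered=False)
    np.testing.assert_allclose(ours.matrix, ref_cov, atol=1e-12)
    assert ours.shrinkage_intensity == pytest.approx(ref_shrink)


def test_positive_definite_with_more_voxels_than_timepoints(rng):
    X = rng.standard_normal((10, 50))  # p >> n, the whole point of shrinkage
    cov = ledoit_wolf_covariance(X)
    np.linalg.cholesky(cov.matrix)  # raises if not PD


def test_constant_residuals_rejected():
    with pytest.raises(ValueError, match="constant"):
        ledoit_wolf_covariance(np.ones((20, 3)))


# ---------------------------------------------------------------------------
# crossnobis / LDC

def identity_cov_residuals(n=8, p=3):
    """Zero-mean residuals whose sample covariance is exactly identity."""
    t = np.arange(n)
    cols = [np.cos(np.pi * (t + 0.5) * k / n) for k in range(1, p + 1)]
    X = np.column_stack(cols)
    X *= np.sqrt(n / (X ** 2).sum(axis=0))
    return X


def test_identity_whitening_closed_form():
    P = 3
    R = identity_cov_residuals(p=P)
    e1 = np.eye(P)[0]
    contrasts = np.tile(e1, (4, 1))
    res = compute_ldc(contrasts, [R] * 4)
    np.testing.assert_allclose(res.per_fold, 1.0, atol=1e-10)
    np.testing.assert_allclose(res.normalized, 1.0 / np.sqrt(P), atol=1e-10)
    assert res.n_voxels == P


def test_sign_antisymmetry_negative_test_contrast(rng):
    P = 3
    R = identity_cov_residuals(p=P)
    c = np.array([0.5, -1.0, 2.0])
    contrasts = np.vstack([c, c, c, -c])
    res = compute_ldc(contrasts, [R] * 4)
    np.testing.assert_allclose(res.per_fold[3], -c @ c, atol=1e-10)


def test_normalization_identity(rng):
    contrasts = rng.standard_normal((4, 6))
    residuals = [rng.standard_normal((20, 6)) for _ in range(4)]
    res = compute_ldc(contrasts, residuals)
    assert res.normalized == pytest.approx(res.mean / np.sqrt(6))
    assert len(res.per_fold) == 4


@settings(deadline=None, derandomize=True, max_examples=10)
@given(perm_seed=st.integers(0, 10_000))
def test_fold_order_invariance(perm_seed):
    rng = np.random.default_rng(31)
    contrasts = rng.standard_normal((4, 5))
    residuals = [rng.standard_normal((25, 5)) for _ in range(4)]
    base = compute_ldc(contrasts, residuals)
    order = np.random.default_rng(perm_seed).permutation(4)
    permuted = compute_ldc(contrasts[order], [residuals[i] for i in order])
    assert permuted.mean == pytest.approx(base.mean, rel=1e-12)


def test_dense_oracle_equivalence_on_tiny_instance(rng):
    """Against an explicit-inverse, explicit-dot-product reimplementation."""
    contrasts = rng.standard_normal((2, 3))
    residuals = [rng.standard_normal((12, 3)) for _ in range(2)]
    res = compute_ldc(contrasts, residuals)
    for test in range(2):
        train = 1 - test
        sigma = covdiag_oracle(residuals[train])
        w = np.linalg.inv(sigma) @ contrasts[train]
        expected = float(np.dot(w, contrasts[test]))
        assert res.per_fold[test] == pytest.approx(expected, abs=1e-10)


def test_ldc_scales_quadratically_with_contrast(default_design, rng):
    noise = NoiseSpec(attention_sd=0.2, thermal_sd=0.4, phys_scale=0.0)
    means = []
    for factor in (1.0, 2.0):
        vals = []
        for k in range(3):
            truth = draw_ground_truth(150, np.random.default_rng(50 + k))
            truth = GroundTruth(condition_means=factor
                                * truth.condition_means)
            data = simulate_participant(default_design, truth, noise,
                                        np.random.default_rng(90 + k))
            vals.append(analyze_participant(
                data, default_design, methods=("ldc",)).ldc.mean)
        means.append(np.mean(vals))
    assert 3.5 < means[1] / means[0] < 4.5


def test_too_few_subruns_rejected(rng):
    with pytest.raises(ValueError, match="2 subruns"):
        compute_ldc(rng.standard_normal((1, 3)),
                    [rng.standard_normal((10, 3))])


# ---------------------------------------------------------------------------
# SVM decoding

def make_blocks(centres, n_per_subrun=8, n_subruns=4, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X, conds, subs = [], [], []
    for s in range(n_subruns):
        for b in range(n_per_subrun):
            c = b % 2
            X.append(centres[c] + sd * rng.standard_normal(len(centres[0])))
            conds.append(c)
            subs.append(s)
    return np.array(X), np.array(conds), np.array(subs)


def test_separable_clouds_decode_perfectly():
    centres = np.array([[5.0, 0.0, 0.0], [-5.0, 0.0, 0.0]])
    X, conds, subs = make_blocks(centres)
    res = svm_decode(X, conds, subs)
    assert res.mean_accuracy == 1.0
    assert res.n_test_per_fold == 8


def test_accuracy_has_one_eighth_granularity(default_design, rng):
    truth = draw_ground_truth(50, rng)
    data = simulate_participant(default_design, truth, NoiseSpec(), rng)
    res = analyze_participant(data, default_design, methods=("svm",)).svm
    for acc in res.per_fold_accuracy:
        assert (acc * 8) == pytest.approx(round(acc * 8))
        assert 0.0 <= acc <= 1.0


def test_null_data_decodes_at_chance(default_design):
    # Many simulated participants with no condition difference: the
    # grand mean accuracy converges to 1/2.
    accs = []
    for k in range(150):
        rng = np.random.default_rng(3000 + k)
        col = rng.standard_normal((60, 1))
        truth = GroundTruth(condition_means=np.repeat(col, 2, axis=1))
        data = simulate_participant(default_design, truth, NoiseSpec(), rng)
        accs.append(analyze_participant(
            data, default_design, methods=("svm",)).svm.mean_accuracy)
    assert abs(np.mean(accs) - 0.5) < 0.03


def test_accuracy_grows_as_thermal_noise_shrinks(default_design):
    # One informative voxel among noise: decoding should sharpen as the
    # thermal SD drops.
    means = []
    for thermal in (4.0, 2.0, 0.5):
        noise = NoiseSpec(attention_sd=0.0, thermal_sd=thermal,
                          phys_scale=0.0)
        vals = []
        for k in range(10):
            rng = np.random.default_rng(100 + k)
            cm = np.zeros((40, 2))
            cm[0] = (1.5, -1.5)
            truth = GroundTruth(condition_means=cm)
            data = simulate_participant(default_design, truth, noise, rng)
            vals.append(analyze_participant(
                data, default_design, methods=("svm",)).svm.mean_accuracy)
        means.append(np.mean(vals))
    assert means[0] < means[2]
    assert means[1] <= means[2]
    assert 0.5 < means[1] < 1.0


def test_single_class_training_fold_rejected():
    X = np.random.default_rng(0).standard_normal((8, 3))
    conds = np.array([0, 0, 0, 0, 0, 0, 0, 1])
    subs = np.array([0, 0, 1, 1, 2, 2, 3, 3])
    with pytest.raises(ValueError, match="single class"):
        svm_decode(X, conds, subs)
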