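"""Group-level inference: fixed-effects permutation test and t-tests.

The permutation test treats participants as fixed effects: under the
null of exchangeable condition labels within participant, each
participant's (a, b) pair may be swapped independently, which flips the
sign of that participant's difference.  The null distribution of the
group mean difference is built from random sign assignments and the
observed mean difference is referred to it two-sidedly with the add-one
correction ``p = (#{|null| >= |observed|} + 1) / (n_iterations + 1)``,
so p is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "TTestResult",
    "ffx_permutation_test",
    "paired_ttest",
    "one_sample_ttest",
]


@dataclass
class PermutationResult:
    observed_mean_diff: float
    null_distribution: np.ndarray
    p_value: float
    n_iterations: int


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    reject: bool
    df: int


def _pair_inputs(values_a, values_b):
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be equal-length vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 participants")
    return a, b


def ffx_permutation_test(values_a,
                         values_b,
                         n_iterations: int = 10_000,
                         rng: np.random.Generator | int | None = None
                         ) -> PermutationResult:
    """Two-sided fixed-effects permutation test of paired condition means.

    Each iteration independently swaps each participant's condition pair
    with probability 1/2 and records the group mean difference.
    """
    a, b = _pair_inputs(values_a, values_b)
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    diffs = a - b
    observed = float(diffs.mean())
    if np.all(diffs == 0):
        warnings.warn("all condition pairs are identical; permutation "
                      "distribution is degenerate (p = 1)", RuntimeWarning,
                      stacklevel=2)
    signs = rng.integers(0, 2, size=(n_iterations, len(diffs))) * 2 - 1
    null = (signs * diffs).mean(axis=1)
    p = (np.count_nonzero(np.abs(null) >= abs(observed)) + 1) \
        / (n_iterations + 1)
    return PermutationResult(observed_mean_diff=observed,
                             null_distribution=null,
                             p_value=float(p),
                             n_iterations=n_iterations)


def _degenerate_t(diffs: np.ndarray, alpha: float, df: int) -> TTestResult:
    # Zero-variance convention: all differences identically zero is a
    # perfect null (p = 1); identical nonzero differences are a perfect
    # effect (p -> 0).
    if np.all(diffs == 0):
        return TTestResult(statistic=0.0, p_value=1.0, reject=False, df=df)
    stat = np.inf if diffs.mean() > 0 else -np.inf
    return TTestResult(statistic=stat, p_value=0.0, reject=True, df=df)


def paired_ttest(values_a, values_b, alpha: float = 0.05) -> TTestResult:
    """Two-sided paired t-test with a reject flag at ``alpha``."""
    a, b = _pair_inputs(values_a, values_b)
    diffs = a - b
    df = len(diffs) - 1
    if np.std(diffs) == 0:
        return _degenerate_t(diffs, alpha, df)
    res = sps.ttest_rel(a, b)
    return TTestResult(statistic=float(res.statistic),
                       p_value=float(res.pvalue),
                       reject=bool(res.pvalue < alpha), df=df)


def one_sample_ttest(values, alpha: float = 0.05,
                     popmean: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of the mean against ``popmean``."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a vector of at least 2 values")
    diffs = v - popmean
    df = len(v) - 1
    if np.std(diffs) == 0:
        return _degenerate_t(diffs, alpha, df)
    res = sps.ttest_1samp(v, popmean)
    return TTestResult(statistic=float(res.statistic),
                       p_value=float(res.pvalue),
                       reject=bool(res.pvalue < alpha), df=df)
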