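"""Block-design timelines and their regressor matrices.

The experiment emulated throughout the package is a two-condition
alternating block design: within each subrun the two conditions take
turns (A B A B ... or B A B A ...), and the condition that leads
alternates across subruns so that neither condition is systematically
first.  Regressors are boxcars sampled on a regular grid; no
haemodynamic convolution is applied (the simulated signal is taken to
be the neural/BOLD amplitude directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlockDesign", "make_block_design"]


def _as_samples(duration_s: float, sample_period_s: float, name: str) -> int:
    """Convert a duration to an integer sample count, or complain."""
    n = duration_s / sample_period_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"{name}={duration_s} is not divisible by "
            f"sample_period_s={sample_period_s}"
        )
    return int(round(n))


@dataclass(frozen=True)
class BlockDesign:
    """Temporal layout of a two-condition alternating block experiment.

    All durations are in seconds.  ``blocks_per_subrun`` counts blocks of
    both conditions combined, so each condition contributes
    ``blocks_per_subrun / 2`` blocks per subrun.
    """

    block_duration_s: float
    blocks_per_subrun: int
    n_subruns: int
    sample_period_s: float
    inter_block_gap_s: float = 0.0
    n_conditions: int = 2

    @property
    def block_samples(self) -> int:
        return _as_samples(self.block_duration_s, self.sample_period_s,
                           "block_duration_s")

    @property
    def gap_samples(self) -> int:
        return _as_samples(self.inter_block_gap_s, self.sample_period_s,
                           "inter_block_gap_s")

    @property
    def samples_per_subrun(self) -> int:
        # Gaps separate blocks; no leading/trailing gap.
        return (self.blocks_per_subrun * self.block_samples
                + (self.blocks_per_subrun - 1) * self.gap_samples)

    @property
    def n_timepoints(self) -> int:
        return self.samples_per_subrun * self.n_subruns

    def block_table(self, subrun: int) -> np.ndarray:
        """(n_blocks, 2) int array of (onset_sample, condition) for a subrun.

        Condition alternates within the subrun; the leading condition is
        ``subrun % 2`` so it alternates across subruns.
        """
        if not 0 <= subrun < self.n_subruns:
            raise ValueError(f"subrun {subrun} out of range")
        leading = subrun % self.n_conditions
        stride = self.block_samples + self.gap_samples
        table = np.empty((self.blocks_per_subrun, 2), dtype=np.intp)
        for b in range(self.blocks_per_subrun):
            table[b, 0] = b * stride
            table[b, 1] = (leading + b) % self.n_conditions
        return table

    def condition_regressors(self, subrun: int) -> np.ndarray:
        """(timepoints, n_conditions) boxcar matrix: one regressor per condition."""
        X = np.zeros((self.samples_per_subrun, self.n_conditions))
        for onset, cond in self.block_table(subrun):
            X[onset:onset + self.block_samples, cond] = 1.0
        return X

    def blockwise_regressors(self, subrun: int) -> tuple[np.ndarray, np.ndarray]:
        """(timepoints, n_blocks) boxcar matrix with one regressor per block.

        Returns ``(X, labels)`` where ``labels[j]`` is the condition of
        block/regressor ``j``.
        """
        table = self.block_table(subrun)
        X = np.zeros((self.samples_per_subrun, len(table)))
        for j, (onset, _cond) in enumerate(table):
            X[onset:onset + self.block_samples, j] = 1.0
        return X, table[:, 1].copy()

    @property
    def regressor_matrix(self) -> np.ndarray:
        """Full (n_subruns * timepoints, n_conditions) stacked boxcar matrix."""
        return np.vstack([self.condition_regressors(s)
                          for s in range(self.n_subruns)])


def make_block_design(block_duration_s: float = 16.0,
                      blocks_per_subrun: int = 8,
                      n_subruns: int = 4,
                      sample_period_s: float = 2.0,
                      inter_block_gap_s: float = 0.0) -> BlockDesign:
    """Build an alternating two-condition block design.

    Defaults reproduce the study layout: 16 s blocks, 8 blocks per
    subrun, 4 subruns, sampled every 2 s, blocks contiguous.

    Raises
    ------
    ValueError
        If a duration is not divisible by the sampling period, or
        ``blocks_per_subrun`` is odd (conditions must balance).
    """
    if blocks_per_subrun % 2:
        raise ValueError(
            f"blocks_per_subrun={blocks_per_subrun} must be even so both "
            "conditions get equal numbers of blocks")
    if n_subruns < 1:
        raise ValueError("n_subruns must be >= 1")
    design = BlockDesign(block_duration_s, blocks_per_subrun, n_subruns,
                         sample_period_s, inter_block_gap_s)
    # Trigger divisibility validation eagerly.
    design.block_samples
    design.gap_samples
    return design
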