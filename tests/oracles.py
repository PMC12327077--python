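"""Independent reference implementations used only by the tests.

These deliberately use the most literal, least optimized formulation of each
quantity (double loops, full per-trial model fits) so agreement with the
package is evidence of correctness rather than shared code.
"""
from __future__ import annotations

import numpy as np


def ps_brute_force(patterns: dict[tuple[int, int], np.ndarray], pairs) -> float:
    """Identity-specific pattern similarity by explicit pair enumeration.

    For every repetition pair (i, j): Pearson r between every stimulus's
    pattern at i and every stimulus's pattern at j; mean of same-stimulus r
    minus mean over all ordered different-stimulus pairs; then the mean over
    repetition pairs.
    """
    stimuli = sorted({s for s, _ in patterns})
    pair_values = []
    for i, j in pairs:
        same, diff = [], []
        for s_a in stimuli:
            for s_b in stimuli:
                a = patterns.get((s_a, i))
                b = patterns.get((s_b, j))
                if a is None or b is None:
                    continue
                if np.std(a) == 0 or np.std(b) == 0:
                    continue
                r = float(np.corrcoef(a, b)[0, 1])
                (same if s_a == s_b else diff).append(r)
        if same or diff:
            value = (np.mean(same) if same else np.nan) - (
                np.mean(diff) if diff else np.nan
            )
            if np.isfinite(value):
                pair_values.append(value)
    return float(np.mean(pair_values))


def lsa_trial_betas(R: np.ndarray, nuisance: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares-all: one model containing every trial regressor.

    Returns (n_trials, n_voxels) betas from the single joint OLS fit of
    [R, nuisance] on Y.
    """
    X = np.column_stack([R, nuisance])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef[: R.shape[1]]


def ols_t(X: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """Contrast t statistic from first principles for one voxel."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    c = np.asarray(weights, dtype=float)
    return float(c @ beta) / np.sqrt(sigma2 * float(c @ xtx_inv @ c))
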