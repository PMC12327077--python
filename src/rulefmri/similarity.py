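"""Identity-specific pattern similarity.

For one block, similarity between two repetition levels i and j is the mean
Pearson correlation between same-stimulus patterns minus the mean correlation
between different-stimulus patterns (all ordered pairs s != s' across the
(i, j) pair). Block values are averaged over a scheme of repetition pairs:

* stage-specific learning: unordered pairs within repetitions {2, 3, 4};
* stage-specific implementation: unordered pairs within {5, 6, 7, 8};
* cross-stage: the 12 ordered learning x implementation pairs
  (within-stage pairs excluded), indexing rule representations that stay
  consistent from learning to implementation;
* pooled schemes (all pairs within {2..8} or within {5..8}) for the
  searchlight maps.

Repetition 1 is excluded throughout (high early error rates); correct and
incorrect trials enter alike at their original repetition coding by default.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Condition, ExperimentDesign, IMPLEMENTATION, LEARNING
from .lss import TrialPatternSet

__all__ = [
    "PairScheme",
    "block_pattern_similarity",
    "stage_specific_ps",
    "cross_stage_ps",
    "incorrect_trial_policy",
]

LEARNING_REPS = (2, 3, 4)
IMPLEMENTATION_REPS = (5, 6, 7, 8)


class PatternSimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class PairScheme:
    """A named set of repetition pairs entering the similarity average."""

    mode: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def repetitions(self) -> tuple[int, ...]:
        return tuple(sorted({r for p in self.pairs for r in p}))

    @classmethod
    def stage_specific(cls, stage: str) -> "PairScheme":
        if stage == LEARNING:
            reps, mode = LEARNING_REPS, "stage_specific_learning"
        elif stage == IMPLEMENTATION:
            reps, mode = IMPLEMENTATION_REPS, "stage_specific_implementation"
        else:
            raise PatternSimilarityError(f"unknown stage {stage!r}")
        return cls(mode, tuple(itertools.combinations(reps, 2)))

    @classmethod
    def cross_stage(cls) -> "PairScheme":
        pairs = tuple(itertools.product(LEARNING_REPS, IMPLEMENTATION_REPS))
        return cls("cross_stage", pairs)

    @classmethod
    def pooled(cls, which: str = "2to8") -> "PairScheme":
        if which == "2to8":
            reps = LEARNING_REPS + IMPLEMENTATION_REPS
        elif which == "5to8":
            reps = IMPLEMENTATION_REPS
        else:
            raise PatternSimilarityError(f"unknown pooled scheme {which!r}")
        return cls(f"pooled_{which}", tuple(itertools.combinations(reps, 2)))


def _normalize_rows(A: np.ndarray) -> np.ndarray:
    """Center and unit-normalize rows; zero-variance rows become NaN."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN (missing) rows
        A = A - np.nanmean(A, axis=1, keepdims=True)
    norms = np.sqrt(np.nansum(A**2, axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = A / norms
    out[np.squeeze(norms, axis=1) == 0] = np.nan
    return out


def pairwise_value(corr: np.ndarray) -> float:
    """Same-minus-different statistic from a stimulus x stimulus correlation
    matrix at one repetition pair (NaN entries are dropped)."""
    diag = np.diagonal(corr)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_same = np.nanmean(diag)
        r_diff = np.nanmean(off)
    return float(r_same - r_diff)


def block_pattern_similarity(
    patterns: dict[tuple[int, int], np.ndarray],
    scheme: PairScheme,
    allow_missing: bool = False,
) -> float:
    """Identity-specific pattern similarity for one block.

    ``patterns`` maps (stimulus, repetition) to a voxel vector. For every
    repetition pair (i, j) of the scheme the same-stimulus correlations
    (mean over stimuli) minus the different-stimulus correlations (mean over
    ordered pairs s != s') is computed; the scheme mean is returned.

    Zero-variance vectors are flagged with a warning and their correlations
    dropped. Missing (stimulus, repetition) cells raise unless
    ``allow_missing`` (then their correlations are dropped too).
    """
    stimuli = sorted({s for s, _ in patterns})
    if len(stimuli) < 2:
        raise PatternSimilarityError("need at least 2 stimuli")
    reps = scheme.repetitions
    lengths = {len(np.atleast_1d(v)) for v in patterns.values()}
    if len(lengths) != 1:
        raise PatternSimilarityError("pattern vectors differ in length")
    n_vox = lengths.pop()
    if n_vox < 2:
        raise PatternSimilarityError("pattern vectors need >= 2 voxels")

    mat = np.full((len(stimuli), len(reps), n_vox), np.nan)
    rep_col = {r: k for k, r in enumerate(reps)}
    for (s, r), v in patterns.items():
        if r in rep_col:
            mat[stimuli.index(s), rep_col[r]] = np.asarray(v, dtype=float)
    missing = np.isnan(mat).all(axis=2)
    if missing.any() and not allow_missing:
        cells = [
            (stimuli[i], reps[j]) for i, j in zip(*np.nonzero(missing))
        ]
        raise PatternSimilarityError(f"missing repetition cells: {cells}")

    normed = np.stack([_normalize_rows(mat[:, k, :]) for k in range(len(reps))], axis=1)
    flat_ok = ~np.isnan(normed).any(axis=2)
    if (~flat_ok & ~missing).any():
        warnings.warn(
            "zero-variance pattern vector(s) dropped from similarity",
            RuntimeWarning,
            stacklevel=2,
        )
    values = []
    for i, j in scheme.pairs:
        A = normed[:, rep_col[i], :]
        B = normed[:, rep_col[j], :]
        corr = np.where(
            flat_ok[:, rep_col[i]][:, None] & flat_ok[:, rep_col[j]][None, :],
            np.nan_to_num(A) @ np.nan_to_num(B).T,
            np.nan,
        )
        v = pairwise_value(corr)
        if np.isfinite(v):
            values.append(v)
    if not values:
        raise PatternSimilarityError("no valid repetition pairs in block")
    return float(np.mean(values))


def incorrect_trial_policy(
    tps: TrialPatternSet, policy: str = "include_all"
) -> np.ndarray:
    """Boolean inclusion mask over trials for the MVPA.

    The default keeps correct and incorrect trials alike at their original
    repetition coding (excluding errors would break the repetition-chunk
    balance). ``exclude_incorrect`` is available but emits a warning; pairs
    with missing cells are then dropped downstream.
    """
    if policy == "include_all":
        return np.ones(tps.n_trials, dtype=bool)
    if policy == "exclude_incorrect":
        correct = tps.index["correct"].fillna(True).to_numpy(dtype=bool)
        if not correct.all():
            warnings.warn(
                "excluding incorrect trials breaks the repetition-chunk balance; "
                "pairs with missing cells will be dropped",
                RuntimeWarning,
                stacklevel=2,
            )
        return correct
    raise PatternSimilarityError(f"unknown incorrect-trial policy {policy!r}")


def _check_roi(tps: TrialPatternSet, roi_mask: np.ndarray | None) -> TrialPatternSet:
    if roi_mask is None:
        return tps
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if np.any(roi_mask & ~tps.mask):
        raise PatternSimilarityError("ROI extends outside the pattern mask")
    return tps.restrict(roi_mask)


def _block_patterns(
    tps: TrialPatternSet, block: int, reps: tuple[int, ...], include: np.ndarray
) -> dict[tuple[int, int], np.ndarray]:
    rows = tps.select(block=block, repetition=tuple(reps))
    out: dict[tuple[int, int], np.ndarray] = {}
    for r in rows:
        if not include[r]:
            continue
        key = (int(tps.index["stimulus"].iat[r]), int(tps.index["repetition"].iat[r]))
        if key in out:
            raise PatternSimilarityError(
                f"duplicate pattern for stimulus/repetition {key} in block {block}"
            )
        out[key] = tps.data[r]
    return out


def _condition_mean(
    tps: TrialPatternSet,
    design: ExperimentDesign,
    condition: Condition,
    scheme: PairScheme,
    include: np.ndarray,
    allow_missing: bool,
) -> tuple[float, int]:
    blocks = design.blocks_of_condition(condition)
    vals = [
        block_pattern_similarity(
            _block_patterns(tps, b, scheme.repetitions, include), scheme, allow_missing
        )
        for b in blocks
    ]
    return float(np.mean(vals)), len(blocks)


def stage_specific_ps(
    tps: TrialPatternSet,
    design: ExperimentDesign,
    roi_mask: np.ndarray | None = None,
    roi_name: str = "roi",
    hemisphere: str = "bilateral",
    policy: str = "include_all",
) -> pd.DataFrame:
    """Stage-specific pattern similarity per condition.

    Learning uses repetition pairs within {2, 3, 4} (3 pairs), implementation
    pairs within {5..8} (6 pairs); block values are averaged over each
    condition's blocks. Returns one row per condition x stage.
    """
    tps = _check_roi(tps, roi_mask)
    include = incorrect_trial_policy(tps, policy)
    allow_missing = policy == "exclude_incorrect"
    rows = []
    for cond in Condition:
        for stage in (LEARNING, IMPLEMENTATION):
            scheme = PairScheme.stage_specific(stage)
            value, n_blocks = _condition_mean(
                tps, design, cond, scheme, include, allow_missing
            )
            rows.append(
                dict(
                    subject=design.subject_id,
                    condition=cond.value,
                    scheme=scheme.mode,
                    roi=roi_name,
                    hemisphere=hemisphere,
                    value=value,
                    n_blocks=n_blocks,
                )
            )
    return pd.DataFrame(rows)


def cross_stage_ps(
    tps: TrialPatternSet,
    design: ExperimentDesign,
    roi_mask: np.ndarray | None = None,
    roi_name: str = "roi",
    hemisphere: str = "bilateral",
    policy: str = "include_all",
) -> pd.DataFrame:
    """Cross-stage consistency pattern similarity per condition: the mean over
    the 12 learning-to-implementation repetition pairs, averaged over each
    condition's blocks. Within-stage pairs are excluded by construction."""
    tps = _check_roi(tps, roi_mask)
    include = incorrect_trial_policy(tps, policy)
    allow_missing = policy == "exclude_incorrect"
    scheme = PairScheme.cross_stage()
    rows = []
    for cond in Condition:
        value, n_blocks = _condition_mean(
            tps, design, cond, scheme, include, allow_missing
        )
        rows.append(
            dict(
                subject=design.subject_id,
                condition=cond.value,
                scheme=scheme.mode,
                roi=roi_name,
                hemisphere=hemisphere,
                value=value,
                n_blocks=n_blocks,
            )
        )
    return pd.DataFrame(rows)
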