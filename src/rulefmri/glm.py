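"""First-level GLM: design-matrix construction, OLS fitting, linear trend
contrasts over repetition levels, and minimum-statistic conjunctions.

Events are modeled as stick functions convolved with the canonical HRF.
Task regressors split trials by condition x stage x correctness x
accuracy-recoded repetition, with the first trial of each stage modeled
separately; block-level events (condition cue per condition, shared stage
warning and block feedback) and a block-long sustained boxcar complete the
model. Slow drift is captured by a discrete-cosine basis with a 200 s
high-pass cutoff, included as columns of the design matrix.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .design import (
    Condition,
    ExperimentDesign,
    IMPLEMENTATION,
    LEARNING,
    TrialEvent,
)
from .simulate import BoldDataset, canonical_hrf, trial_response_matrix

__all__ = [
    "DesignMatrix",
    "FirstLevelResult",
    "dct_highpass_basis",
    "build_first_level_design",
    "fit_glm",
    "linear_trend_weights",
    "trend_contrast_weights",
    "condition_mean_weights",
    "conjunction",
    "highpass_project",
]

DEFAULT_HIGHPASS = 200.0


class GlmError(ValueError):
    pass


class RankDeficientError(GlmError):
    pass


def dct_highpass_basis(frame_times: np.ndarray, cutoff: float = DEFAULT_HIGHPASS) -> np.ndarray:
    """Discrete-cosine drift basis containing only periods above ``cutoff``.

    Component k has period 2 * duration / k; components up to but excluding
    the cutoff period are returned, as (n_frames, K). The constant is not
    included.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    n = len(frame_times)
    duration = frame_times[-1] - frame_times[0] + (
        frame_times[1] - frame_times[0] if n > 1 else 0.0
    )
    n_comp = max(int(np.ceil(2.0 * duration / cutoff)) - 1, 0)
    if n_comp == 0:
        return np.zeros((n, 0))
    i = np.arange(n)
    k = np.arange(1, n_comp + 1)
    basis = np.cos(np.pi * k[None, :] * (2 * i[:, None] + 1) / (2 * n))
    return basis / np.linalg.norm(basis, axis=0)


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # scans x regressors
    names: list[str]
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != self.matrix.shape[1]:
            raise GlmError("regressor names do not match matrix columns")
        if len(set(self.names)) != len(self.names):
            raise GlmError("regressor names must be unique")
        task = [
            j
            for j, n in enumerate(self.names)
            if not (n.startswith("drift_") or n == "constant")
        ]
        zero = [self.names[j] for j in task if np.allclose(self.matrix[:, j], 0)]
        if zero:
            raise GlmError(f"all-zero task regressors: {zero}")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class FirstLevelResult:
    betas: np.ndarray  # regressors x voxels
    sigma2: np.ndarray  # voxels
    dof: int
    names: list[str]
    xtx_inv: np.ndarray

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]

    def contrast_estimate(self, weights: np.ndarray) -> np.ndarray:
        return np.asarray(weights) @ self.betas

    def contrast_t(self, weights: np.ndarray) -> np.ndarray:
        c = np.asarray(weights, dtype=float)
        var_scale = float(c @ self.xtx_inv @ c)
        denom = np.sqrt(self.sigma2 * var_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, (c @ self.betas) / denom, 0.0)


def _boxcar_response(
    intervals: list[tuple[float, float]],
    frame_times: np.ndarray,
    tr: float,
    oversampling: int = 16,
) -> np.ndarray:
    """HRF-convolved boxcar spanning the given (start, stop) intervals."""
    dt = tr / oversampling
    t_hi = np.arange(0.0, frame_times[-1] + tr, dt)
    box = np.zeros_like(t_hi)
    for start, stop in intervals:
        box[(t_hi >= start) & (t_hi < stop)] = 1.0
    _, kernel = canonical_hrf(tr, oversampling)
    conv = np.convolve(box, kernel)[: len(t_hi)] * dt
    return np.interp(frame_times, t_hi, conv)


def _first_trials_of_stage(design: ExperimentDesign, run: int) -> set[int]:
    """ids (by list identity) of each block's first learning and first
    implementation trial."""
    first: set[int] = set()
    trials = design.trials_in_run(run)
    for block in {t.block for t in trials}:
        for stage in (LEARNING, IMPLEMENTATION):
            group = [t for t in trials if t.block == block and t.stage == stage]
            first.add(id(min(group, key=lambda t: t.onset)))
    return first


def task_regressor_events(
    design: ExperimentDesign, run: int
) -> dict[str, list[TrialEvent]]:
    """Group a run's trials into the univariate model's task regressors."""
    trials = design.trials_in_run(run)
    first = _first_trials_of_stage(design, run)
    groups: dict[str, list[TrialEvent]] = {}
    for t in trials:
        if t.recoded_repetition is None:
            raise GlmError("repetitions must be recoded before model construction")
        if id(t) in first:
            name = f"first_{t.stage}"
        else:
            corr = "correct" if t.correct else "incorrect"
            name = f"{t.condition.value}_{t.stage}_{corr}_rep{t.recoded_repetition}"
        groups.setdefault(name, []).append(t)
    return groups


def build_first_level_design(
    design: ExperimentDesign,
    run: int,
    tr: float = 2.07,
    n_scans: int | None = None,
    high_pass: float = DEFAULT_HIGHPASS,
    oversampling: int = 16,
) -> DesignMatrix:
    """Construct the run's design matrix.

    Requires populated responses and recoded repetitions. Raises if events
    extend past the scan window.
    """
    if n_scans is None:
        n_scans = int(np.ceil(design.run_duration(run) / tr))
    frame_times = np.arange(n_scans) * tr
    scan_end = n_scans * tr
    trials = design.trials_in_run(run)
    aux = design.aux_in_run(run)
    last_event = max(
        [t.onset for t in trials] + [a.onset for a in aux], default=0.0
    )
    if last_event >= scan_end:
        raise GlmError(
            f"events extend past the scan window ({last_event:.1f} s >= {scan_end:.1f} s)"
        )

    cols: list[np.ndarray] = []
    names: list[str] = []

    groups = task_regressor_events(design, run)
    for name in sorted(groups):
        onsets = np.array(sorted(t.onset for t in groups[name]))
        cols.append(trial_response_matrix(onsets, frame_times, tr, oversampling).sum(axis=1))
        names.append(name)

    # cues per condition; warning and block feedback shared
    for cond in Condition:
        onsets = np.array([a.onset for a in aux if a.kind == "cue" and a.condition is cond])
        if len(onsets):
            cols.append(trial_response_matrix(onsets, frame_times, tr, oversampling).sum(axis=1))
            names.append(f"cue_{cond.value}")
    for kind in ("warning", "block_feedback"):
        onsets = np.array([a.onset for a in aux if a.kind == kind])
        if len(onsets):
            cols.append(trial_response_matrix(onsets, frame_times, tr, oversampling).sum(axis=1))
            names.append(kind)

    # sustained activity: block-long boxcar (cue onset to block feedback end)
    intervals = []
    for block in design.blocks_in_run(run):
        block_aux = [a for a in aux if a.block == block]
        start = min(a.onset for a in block_aux if a.kind == "cue")
        stop = max(a.onset + a.duration for a in block_aux)
        intervals.append((start, stop))
    cols.append(_boxcar_response(intervals, frame_times, tr, oversampling))
    names.append("sustained")

    drift = dct_highpass_basis(frame_times, high_pass)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(n_scans))
    names.append("constant")

    return DesignMatrix(np.column_stack(cols), names, frame_times)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name the offending columns: those nearly in the span of their predecessors
    offenders = []
    q: np.ndarray | None = None
    for j in range(X.shape[1]):
        col = X[:, j]
        resid = col if q is None else col - q @ (q.T @ col)
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(col), 1.0):
            offenders.append(names[j])
        else:
            new = resid / np.linalg.norm(resid)
            q = new[:, None] if q is None else np.column_stack([q, new])
    raise RankDeficientError(
        f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
        f"dependent columns: {offenders}"
    )


def fit_glm(
    bold: BoldDataset | np.ndarray,
    X: DesignMatrix,
    mask: np.ndarray | None = None,
) -> FirstLevelResult:
    """Ordinary least squares per voxel.

    ``bold`` may be a :class:`BoldDataset` (initial volumes discarded, data
    extracted under ``mask``) or a ready (time, voxels) array.
    """
    if isinstance(bold, BoldDataset):
        Y = bold.time_series(mask)
    else:
        Y = np.asarray(bold, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
    if Y.shape[0] != X.matrix.shape[0]:
        raise GlmError(
            f"{Y.shape[0]} scans in data vs {X.matrix.shape[0]} rows in design"
        )
    _check_rank(X.matrix, X.names)
    xtx_inv = np.linalg.inv(X.matrix.T @ X.matrix)
    betas = xtx_inv @ X.matrix.T @ Y
    resid = Y - X.matrix @ betas
    dof = Y.shape[0] - X.matrix.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    return FirstLevelResult(betas, sigma2, dof, list(X.names), xtx_inv)


def linear_trend_weights(n_levels: int, direction: str = "increase") -> np.ndarray:
    """Centered, unit-norm linear contrast over ordered levels
    (4 levels -> (-3, -1, 1, 3) / sqrt(20)); ``decrease`` negates."""
    if n_levels < 2:
        raise GlmError("a linear trend needs at least 2 levels")
    if direction not in ("increase", "decrease"):
        raise GlmError(f"unknown direction {direction!r}")
    w = np.arange(n_levels, dtype=float)
    w -= w.mean()
    w /= np.linalg.norm(w)
    return w if direction == "increase" else -w


def _rep_regressors(
    names: list[str], condition: Condition, stage: str, correctness: str
) -> list[tuple[int, str]]:
    prefix = f"{condition.value}_{stage}_{correctness}_rep"
    found = [(int(n[len(prefix) :]), n) for n in names if n.startswith(prefix)]
    return sorted(found)


def trend_contrast_weights(
    names: list[str],
    condition: Condition,
    stage: str,
    direction: str = "increase",
    correctness: str = "correct",
) -> np.ndarray:
    """Full-length weight vector for the linear repetition trend of one
    condition and stage (over accuracy-recoded correct repetitions)."""
    reps = _rep_regressors(names, condition, stage, correctness)
    if len(reps) < 2:
        raise GlmError(
            f"need >= 2 repetition regressors for {condition.value}/{stage}"
        )
    w = linear_trend_weights(len(reps), direction)
    weights = np.zeros(len(names))
    for wk, (_, name) in zip(w, reps):
        weights[names.index(name)] = wk
    return weights


def condition_mean_weights(
    names: list[str],
    condition: Condition,
    stage: str = IMPLEMENTATION,
    correctness: str = "correct",
) -> np.ndarray:
    """Equal-weight average over a condition's repetition regressors (the
    across-repetition condition mean used for implementation trials)."""
    reps = _rep_regressors(names, condition, stage, correctness)
    if not reps:
        raise GlmError(f"no repetition regressors for {condition.value}/{stage}")
    weights = np.zeros(len(names))
    for _, name in reps:
        weights[names.index(name)] = 1.0 / len(reps)
    return weights


def conjunction(
    t_maps: list[np.ndarray],
    mode: str = "conjunction_null",
    alpha_voxel: float = 0.001,
    dof: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-statistic conjunction over t maps.

    ``conjunction_null`` requires every effect present: the voxelwise minimum
    t must exceed the single-map threshold for ``alpha_voxel``.
    ``global_null`` tests that at least one effect is present: the minimum of
    n independent null t statistics exceeds its threshold with probability
    ``alpha_voxel`` when each map is thresholded at tail probability
    ``alpha_voxel ** (1/n)``. Returns ``(min_t, pass_mask)``.
    """
    if len(t_maps) < 2:
        raise GlmError("a conjunction needs at least 2 maps")
    shapes = {np.asarray(m).shape for m in t_maps}
    if len(shapes) != 1:
        raise GlmError(f"t maps on different grids: {shapes}")
    stack = np.stack([np.asarray(m, dtype=float) for m in t_maps])
    min_t = stack.min(axis=0)
    if mode == "conjunction_null":
        threshold = sp_stats.t.isf(alpha_voxel, dof)
    elif mode == "global_null":
        threshold = sp_stats.t.isf(alpha_voxel ** (1.0 / len(t_maps)), dof)
    else:
        raise GlmError(f"unknown conjunction mode {mode!r}")
    return min_t, min_t > threshold


def highpass_project(
    Y: np.ndarray, frame_times: np.ndarray, cutoff: float = DEFAULT_HIGHPASS
) -> np.ndarray:
    """Residual-forming projection removing the constant and all drift
    components below the cutoff frequency (idempotent)."""
    basis = np.column_stack(
        [np.ones(len(frame_times)), dct_highpass_basis(frame_times, cutoff)]
    )
    q, _ = np.linalg.qr(basis)
    return Y - q @ (q.T @ Y)
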