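"""Least-Squares-Separate (LSS) single-trial estimation.

Each trial gets its own GLM in which the target trial is one stick regressor
and all other events are collapsed into six nuisance event regressors: the
other trials of the same learning condition, the trials of each of the other
two conditions, and the condition cues (one regressor per condition) — seven
event regressors in total, plus drift (200 s high-pass cosine basis) and a
constant. Models are fit on the run containing the target trial.

The default solver exploits the structure shared by all models of one
condition: the span of {target, same-condition-others, nuisance} equals the
span of {target, condition-sum, nuisance}, so the shared nuisance block is
projected out once (QR) and each trial reduces to a 2-column regression
(Frisch–Waugh–Lovell). This is algebraically exact OLS; a naive per-trial
full-model fit is provided for verification.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Condition, ExperimentDesign, TrialEvent
from .glm import DEFAULT_HIGHPASS, dct_highpass_basis
from .simulate import BoldDataset, VolumeGeometry, trial_response_matrix

__all__ = [
    "LssModelSpec",
    "TrialPatternSet",
    "ordered_trials",
    "build_lss_model",
    "estimate_all_trials",
]


class LssError(ValueError):
    pass


def ordered_trials(design: ExperimentDesign) -> list[TrialEvent]:
    """Design trials in canonical (run, onset) order; trial ids index this."""
    return sorted(design.trials, key=lambda t: (t.run, t.onset))


@dataclass
class LssModelSpec:
    """The 7-event-regressor layout of one single-trial model."""

    trial_id: int
    run: int
    regressors: dict[str, list[float]]  # regressor name -> event onsets
    high_pass: float = DEFAULT_HIGHPASS

    @property
    def n_event_regressors(self) -> int:
        return len(self.regressors)


@dataclass
class TrialPatternSet:
    """Per-trial activity maps (t by default) on a common voxel set.

    ``data`` is (n_trials, n_voxels) over the voxels of ``mask``; ``index``
    carries one row per trial (id, run, block, condition, stage, stimulus,
    repetition, recoded repetition, correctness) in the same order.
    """

    data: np.ndarray
    index: pd.DataFrame
    mask: np.ndarray
    geometry: VolumeGeometry | None = None
    stat: str = "t"
    beta_data: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.index) != self.data.shape[0]:
            raise LssError("index rows do not match pattern rows")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def select(self, **criteria) -> np.ndarray:
        """Row positions of trials matching all column=value criteria
        (a tuple/list/set value matches any of its members)."""
        keep = np.ones(len(self.index), dtype=bool)
        for col, val in criteria.items():
            series = self.index[col]
            if isinstance(val, (tuple, list, set, frozenset)):
                keep &= series.isin(list(val)).to_numpy()
            else:
                keep &= (series == val).to_numpy()
        return np.flatnonzero(keep)

    def restrict(self, voxel_mask: np.ndarray) -> "TrialPatternSet":
        """Restrict patterns to a sub-mask (3D boolean within the same grid)."""
        sub = voxel_mask[self.mask]
        return TrialPatternSet(
            data=self.data[:, sub],
            index=self.index,
            mask=self.mask & voxel_mask,
            geometry=self.geometry,
            stat=self.stat,
            beta_data=None if self.beta_data is None else self.beta_data[:, sub],
        )


def _cue_onsets(design: ExperimentDesign, run: int) -> dict[Condition, list[float]]:
    out: dict[Condition, list[float]] = {c: [] for c in Condition}
    for a in design.aux_in_run(run):
        if a.kind == "cue":
            out[a.condition].append(a.onset)
    return out


def build_lss_model(design: ExperimentDesign, trial_id: int) -> LssModelSpec:
    """The 7-regressor model for one trial: target; other same-condition
    trials; each other condition's trials; and the instruction cue per
    condition. All events come from the target's run."""
    trials = ordered_trials(design)
    if not 0 <= trial_id < len(trials):
        raise LssError(f"unknown trial id {trial_id}")
    target = trials[trial_id]
    run_trials = [t for t in trials if t.run == target.run]
    regs: dict[str, list[float]] = {
        "target": [target.onset],
        "same_condition_other": [
            t.onset
            for t in run_trials
            if t.condition is target.condition and t is not target
        ],
    }
    for cond in Condition:
        if cond is not target.condition:
            regs[f"other_condition_{cond.value}"] = [
                t.onset for t in run_trials if t.condition is cond
            ]
    cues = _cue_onsets(design, target.run)
    for cond in Condition:
        regs[f"cue_{cond.value}"] = list(cues[cond])
    return LssModelSpec(trial_id=trial_id, run=target.run, regressors=regs)


def _index_frame(trials: list[TrialEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            trial=np.arange(len(trials)),
            run=[t.run for t in trials],
            block=[t.block for t in trials],
            condition=[t.condition.value for t in trials],
            stage=[t.stage for t in trials],
            stimulus=[t.stimulus for t in trials],
            repetition=[t.repetition for t in trials],
            recoded_repetition=[t.recoded_repetition for t in trials],
            correct=[t.correct for t in trials],
            onset=[t.onset for t in trials],
        )
    )


def _run_design_pieces(
    design: ExperimentDesign,
    run: int,
    run_trials: list[TrialEvent],
    frame_times: np.ndarray,
    tr: float,
    high_pass: float,
    oversampling: int,
):
    onsets = np.array([t.onset for t in run_trials])
    R = trial_response_matrix(onsets, frame_times, tr, oversampling)
    cond_sum = {
        c: R[:, [j for j, t in enumerate(run_trials) if t.condition is c]].sum(axis=1)
        for c in Condition
    }
    cues = _cue_onsets(design, run)
    cue_cols = {
        c: trial_response_matrix(np.array(cues[c]), frame_times, tr, oversampling).sum(
            axis=1
        )
        for c in Condition
        if cues[c]
    }
    drift = dct_highpass_basis(frame_times, high_pass)
    const = np.ones((len(frame_times), 1))
    return R, cond_sum, cue_cols, drift, const


def _fit_run_fast(
    Y: np.ndarray,
    run_trials: list[TrialEvent],
    R: np.ndarray,
    cond_sum,
    cue_cols,
    drift,
    const,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-trial OLS target betas and t values for one run."""
    n_scans = Y.shape[0]
    betas = np.empty((len(run_trials), Y.shape[1]))
    tvals = np.empty_like(betas)
    conds = {t.condition for t in run_trials}
    for c in conds:
        others = [cc for cc in Condition if cc is not c]
        z_cols = [cond_sum[cc] for cc in others if cond_sum[cc].any()]
        z_cols += [cue_cols[cc] for cc in cue_cols]
        Z = np.column_stack(z_cols + [drift, const]) if z_cols else np.hstack([drift, const])
        Q, _ = np.linalg.qr(Z)
        p_full = 2 + Z.shape[1]
        dof = n_scans - p_full
        Yr = Y - Q @ (Q.T @ Y)
        s = cond_sum[c] - Q @ (Q.T @ cond_sum[c])
        idx = [j for j, t in enumerate(run_trials) if t.condition is c]
        Tres = R[:, idx] - Q @ (Q.T @ R[:, idx])
        s_dot_s = float(s @ s)
        s_dot_Y = s @ Yr  # (V,)
        rss0 = (Yr**2).sum(axis=0)  # (V,)
        # closed-form 2x2 OLS for all trials of the condition at once:
        # columns [target residual x1, condition-sum residual s]
        g11 = (Tres**2).sum(axis=0)  # (m,)
        g12 = Tres.T @ s  # (m,)
        x1_dot_Y = Tres.T @ Yr  # (m, V)
        det = g11 * s_dot_s - g12**2
        c_u = (s_dot_s * x1_dot_Y - g12[:, None] * s_dot_Y[None, :]) / det[:, None]
        c_v = (-g12[:, None] * x1_dot_Y + g11[:, None] * s_dot_Y[None, :]) / det[:, None]
        b_target = c_u + c_v  # target beta in the original parameterization
        rss = rss0[None, :] - c_u * x1_dot_Y - c_v * s_dot_Y[None, :]
        sigma2 = np.maximum(rss, 0.0) / dof
        var_scale = (s_dot_s - 2.0 * g12 + g11) / det  # (1,1) G^-1 (1,1)'
        denom = np.sqrt(sigma2 * var_scale[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, b_target / denom, 0.0)
        betas[idx] = b_target
        tvals[idx] = t
    return betas, tvals


def _fit_run_naive(
    Y: np.ndarray,
    run_trials: list[TrialEvent],
    R: np.ndarray,
    cond_sum,
    cue_cols,
    drift,
    const,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference solver: build and fit each trial's full model explicitly."""
    n_scans = Y.shape[0]
    betas = np.empty((len(run_trials), Y.shape[1]))
    tvals = np.empty_like(betas)
    for j, target in enumerate(run_trials):
        cols = [R[:, j]]
        same = [k for k, t in enumerate(run_trials) if t.condition is target.condition and k != j]
        cols.append(R[:, same].sum(axis=1))
        for cc in Condition:
            if cc is not target.condition and cond_sum[cc].any():
                cols.append(cond_sum[cc])
        cols.extend(cue_cols[cc] for cc in cue_cols)
        X = np.column_stack(cols + [drift, const])
        xtx_inv = np.linalg.inv(X.T @ X)
        B = xtx_inv @ X.T @ Y
        resid = Y - X @ B
        dof = n_scans - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * xtx_inv[0, 0])
        betas[j] = B[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals[j] = np.where(se > 0, B[0] / se, 0.0)
    return betas, tvals


def estimate_all_trials(
    bolds: list[BoldDataset],
    design: ExperimentDesign,
    mask: np.ndarray | None = None,
    stat: str = "t",
    high_pass: float = DEFAULT_HIGHPASS,
    oversampling: int = 16,
    solver: str = "fast",
) -> TrialPatternSet:
    """Estimate every trial's activity map (one LSS model per trial).

    ``mask`` restricts estimation to a voxel subset (default: the brain
    mask). ``stat`` selects the downstream pattern values: ``"t"`` (beta over
    its standard error, the default) or ``"beta"``; both are retained.
    """
    if stat not in ("t", "beta"):
        raise LssError(f"unknown stat {stat!r}")
    if solver not in ("fast", "naive"):
        raise LssError(f"unknown solver {solver!r}")
    by_run = {b.run: b for b in bolds}
    if sorted(by_run) != design.runs:
        raise LssError(
            f"runs in data {sorted(by_run)} do not match design runs {design.runs}"
        )
    trials = ordered_trials(design)
    geometry = bolds[0].geometry
    if mask is None:
        mask = geometry.brain_mask
    n_voxels = int(mask.sum())
    all_betas = np.empty((len(trials), n_voxels))
    all_t = np.empty_like(all_betas)
    fit = _fit_run_fast if solver == "fast" else _fit_run_naive
    offset = 0
    for run in design.runs:
        bold = by_run[run]
        run_trials = [t for t in trials if t.run == run]
        Y = bold.time_series(mask)
        frame_times = bold.frame_times
        try:
            pieces = _run_design_pieces(
                design, run, run_trials, frame_times, bold.tr, high_pass, oversampling
            )
            b, t = fit(Y, run_trials, *pieces)
        except np.linalg.LinAlgError as err:
            raise LssError(f"LSS model failed in run {run}: {err}") from err
        n = len(run_trials)
        all_betas[offset : offset + n] = b
        all_t[offset : offset + n] = t
        offset += n
    return TrialPatternSet(
        data=all_t if stat == "t" else all_betas,
        index=_index_frame(trials),
        mask=mask,
        geometry=geometry,
        stat=stat,
        beta_data=all_betas if stat == "t" else None,
    )
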