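"""First-level GLM: drift basis, OLS identities, trend contrasts, conjunction."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sp_stats

from oracles import ols_t
from rulefmri.design import Condition, generate_design, generate_subject
from rulefmri.glm import (
    DesignMatrix,
    GlmError,
    RankDeficientError,
    build_first_level_design,
    condition_mean_weights,
    conjunction,
    dct_highpass_basis,
    fit_glm,
    highpass_project,
    linear_trend_weights,
    task_regressor_events,
    trend_contrast_weights,
)
from rulefmri.simulate import (
    NoiseConfig,
    RegionEffectSpec,
    default_geometry,
    simulate_bold,
    trial_response_matrix,
)
from rulefmri.pipeline import central_region_mask


# ---------------------------------------------------------------------------
# DCT high-pass basis
# ---------------------------------------------------------------------------

def test_dct_component_count():
    """K = ceil(2 * duration / cutoff) - 1; 1200 s at a 200 s cutoff -> 11."""
    frame_times = np.arange(600) * 2.0  # duration 1200 s
    basis = dct_highpass_basis(frame_times, cutoff=200.0)
    assert basis.shape == (600, 11)
    # shorter than half the cutoff -> no components
    assert dct_highpass_basis(np.arange(40) * 2.0, cutoff=200.0).shape == (40, 0)


def test_dct_orthonormal_and_zero_mean():
    basis = dct_highpass_basis(np.arange(500) * 2.07, cutoff=200.0)
    gram = basis.T @ basis
    assert np.allclose(gram, np.eye(basis.shape[1]), atol=1e-10)
    assert np.allclose(basis.sum(axis=0), 0.0, atol=1e-9)


def test_highpass_projection_idempotent(rng):
    frame_times = np.arange(400) * 2.07
    Y = rng.standard_normal((400, 5))
    once = highpass_project(Y, frame_times)
    twice = highpass_project(once, frame_times)
    assert np.allclose(once, twice, atol=1e-10)
    # removes the constant
    assert np.allclose(highpass_project(np.ones((400, 1)), frame_times), 0.0, atol=1e-10)


# ---------------------------------------------------------------------------
# Design matrix construction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def design_and_matrix():
    design = generate_subject("sub-01", seed=41, n_blocks=6)
    X = build_first_level_design(design, run=1)
    return design, X


def test_design_matrix_columns(design_and_matrix):
    design, X = design_and_matrix
    names = set(X.names)
    # block-level events and structural columns
    assert {"cue_instruction", "cue_trial_and_error", "cue_observation"} <= names
    assert {"warning", "block_feedback", "sustained", "constant"} <= names
    assert {"first_learning", "first_implementation"} <= names
    assert any(n.startswith("drift_") for n in names)
    # task regressors cover every trial exactly once
    groups = task_regressor_events(design, 1)
    assert sum(len(v) for v in groups.values()) == len(design.trials_in_run(1))


def test_first_trials_split_out(design_and_matrix):
    design, _ = design_and_matrix
    groups = task_regressor_events(design, 1)
    # one first-trial per stage per block
    n_blocks = len(design.blocks_in_run(1))
    assert len(groups["first_learning"]) == n_blocks
    assert len(groups["first_implementation"]) == n_blocks
    # the split-out trials are each block's earliest trial of the stage
    for name in ("first_learning", "first_implementation"):
        for t in groups[name]:
            earlier = [
                u
                for u in design.trials_in_run(1)
                if u.block == t.block and u.stage == t.stage and u.onset < t.onset
            ]
            assert not earlier


def test_repetition_regressors_are_recoded(design_and_matrix):
    design, _ = design_and_matrix
    groups = task_regressor_events(design, 1)
    for name, trials in groups.items():
        if "_rep" in name:
            rep = int(name.rsplit("rep", 1)[1])
            assert all(t.recoded_repetition == rep for t in trials)
            want_correct = "_correct_" in name
            assert all(bool(t.correct) is want_correct for t in trials)


def test_unrecoded_design_rejected():
    design = generate_design("s", seed=41, n_blocks=6)
    with pytest.raises(GlmError, match="recoded"):
        build_first_level_design(design, run=1)


def test_events_past_scan_window_rejected(design_and_matrix):
    design, _ = design_and_matrix
    with pytest.raises(GlmError, match="past the scan window"):
        build_first_level_design(design, run=1, n_scans=10)


def test_duplicate_names_rejected():
    with pytest.raises(GlmError, match="unique"):
        DesignMatrix(np.ones((10, 2)), ["a", "a"], np.arange(10.0))


def test_all_zero_regressor_rejected():
    mat = np.column_stack([np.zeros(10), np.ones(10)])
    with pytest.raises(GlmError, match="all-zero"):
        DesignMatrix(mat, ["task", "constant"], np.arange(10.0))


# ---------------------------------------------------------------------------
# OLS fitting
# ---------------------------------------------------------------------------

def test_ols_against_first_principles(rng):
    """fit_glm's contrast t equals a from-scratch OLS computation."""
    n = 120
    X_mat = np.column_stack(
        [rng.standard_normal((n, 3)), np.ones(n)]
    )
    X = DesignMatrix(X_mat, ["a", "b", "c", "constant"], np.arange(n) * 2.0)
    beta_true = np.array([1.0, -0.5, 0.2, 3.0])
    y = X_mat @ beta_true + 0.3 * rng.standard_normal(n)
    result = fit_glm(y, X)
    w = np.array([1.0, -1.0, 0.0, 0.0])
    assert result.contrast_t(w)[0] == pytest.approx(ols_t(X_mat, y, w), abs=1e-10)
    assert result.dof == n - 4
    # perfect fit recovers exact betas
    exact = fit_glm(X_mat @ beta_true, X)
    assert np.allclose(exact.betas[:, 0], beta_true, atol=1e-8)


def test_rank_deficiency_names_offender():
    n = 50
    a = np.arange(n, dtype=float)
    X = DesignMatrix(
        np.column_stack([a, 2 * a, np.ones(n)]),
        ["a", "a_copy", "constant"],
        np.arange(n) * 2.0,
    )
    with pytest.raises(RankDeficientError, match="a_copy"):
        fit_glm(np.random.default_rng(0).standard_normal(n), X)


def test_scan_count_mismatch_rejected(rng):
    X = DesignMatrix(np.ones((10, 1)), ["constant"], np.arange(10.0))
    with pytest.raises(GlmError, match="scans"):
        fit_glm(rng.standard_normal(12), X)


# ---------------------------------------------------------------------------
# Trend contrasts
# ---------------------------------------------------------------------------

def test_linear_trend_weights():
    w4 = linear_trend_weights(4)
    assert np.allclose(w4, np.array([-3.0, -1.0, 1.0, 3.0]) / np.sqrt(20.0))
    assert w4.sum() == pytest.approx(0.0)
    assert np.linalg.norm(w4) == pytest.approx(1.0)
    assert np.allclose(linear_trend_weights(4, "decrease"), -w4)
    w2 = linear_trend_weights(2)
    assert np.allclose(w2, [-np.sqrt(0.5), np.sqrt(0.5)])
    with pytest.raises(GlmError):
        linear_trend_weights(1)


def test_trend_contrast_targets_right_columns(design_and_matrix):
    _, X = design_and_matrix
    w = trend_contrast_weights(X.names, Condition.INSTRUCTION, "learning")
    nz = {X.names[j]: w[j] for j in np.flatnonzero(w)}
    reps = sorted(int(n.rsplit("rep", 1)[1]) for n in nz)
    assert reps == list(range(1, len(reps) + 1))
    assert all(n.startswith("instruction_learning_correct_rep") for n in nz)
    assert sum(nz.values()) == pytest.approx(0.0)


def test_condition_mean_weights(design_and_matrix):
    _, X = design_and_matrix
    w = condition_mean_weights(X.names, Condition.OBSERVATION)
    nz = np.flatnonzero(w)
    assert np.allclose(w[nz], 1.0 / len(nz))
    assert all(
        X.names[j].startswith("observation_implementation_correct_rep") for j in nz
    )


# ---------------------------------------------------------------------------
# Noiseless slope-sign recovery
# ---------------------------------------------------------------------------

def test_noiseless_trend_sign_recovery():
    """With zero noise, the sign of the learning-stage repetition trend is
    recovered for every condition in every run."""
    geom = default_geometry((8, 8, 8))
    region = central_region_mask(geom, 2)
    slopes = {
        Condition.INSTRUCTION: -0.2,
        Condition.TRIAL_AND_ERROR: 0.25,
        Condition.OBSERVATION: -0.1,
    }
    design = generate_subject("s", seed=53, n_blocks=6)
    spec = RegionEffectSpec(
        name="r", region_mask=region, identity_snr=0.0,
        trend_slope_by_condition=slopes,
    )
    bolds, _ = simulate_bold(
        design, [spec], geom, NoiseConfig(sigma=0.0, drift_amplitude=0.0), seed=53
    )
    for bold in bolds:
        X = build_first_level_design(design, bold.run, n_scans=bold.n_scans)
        result = fit_glm(bold, X, mask=region)
        for cond, slope in slopes.items():
            w = trend_contrast_weights(X.names, cond, "learning", "increase")
            est = result.contrast_estimate(w).mean()
            assert np.sign(est) == np.sign(slope)


# ---------------------------------------------------------------------------
# Conjunction
# ---------------------------------------------------------------------------

def test_conjunction_identical_maps_degenerate(rng):
    """Identical maps: the conjunction-null mask equals single-map
    thresholding of any one map."""
    m = rng.standard_normal((5, 5, 5)) * 3
    min_t, mask = conjunction([m, m, m], "conjunction_null", alpha_voxel=0.01, dof=40)
    assert np.array_equal(min_t, m)
    thr = sp_stats.t.isf(0.01, 40)
    assert np.array_equal(mask, m > thr)


def test_conjunction_global_null_threshold():
    """Global-null per-map tail level: 0.001^(1/3) = 0.1 for three maps."""
    maps = [np.full((2, 2, 2), 3.5), np.full((2, 2, 2), 3.3), np.full((2, 2, 2), 1.4)]
    dof = 79
    min_t, mask_gn = conjunction(maps, "global_null", alpha_voxel=0.001, dof=dof)
    assert np.allclose(min_t, 1.4)
    thr_gn = sp_stats.t.isf(0.001 ** (1 / 3), dof)
    assert thr_gn == pytest.approx(sp_stats.t.isf(0.1, dof))
    assert mask_gn.all() == (1.4 > thr_gn)
    # conjunction null with the same maps needs min t above the 0.001 threshold
    _, mask_cn = conjunction(maps, "conjunction_null", alpha_voxel=0.001, dof=dof)
    assert not mask_cn.any()


def test_conjunction_mask_monotone_in_alpha(rng):
    maps = [rng.standard_normal((6, 6, 6)) + 1 for _ in range(3)]
    _, strict = conjunction(maps, "conjunction_null", alpha_voxel=0.001, dof=50)
    _, lax = conjunction(maps, "conjunction_null", alpha_voxel=0.05, dof=50)
    assert (strict <= lax).all()  # stricter alpha passes a subset


def test_conjunction_input_validation(rng):
    m = rng.standard_normal((3, 3, 3))
    with pytest.raises(GlmError):
        conjunction([m], "conjunction_null")
    with pytest.raises(GlmError):
        conjunction([m, rng.standard_normal((4, 4, 4))])
    with pytest.raises(GlmError):
        conjunction([m, m], mode="nope")
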