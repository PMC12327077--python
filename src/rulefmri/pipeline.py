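"""End-to-end orchestration: simulate a cohort, estimate single-trial
patterns, compute pattern similarity, and run group statistics.

These helpers tie the modules together for the command-line interface and
for simulation studies (calibration, recovery, dissociation). Observation
blocks are yoked across cohort sets of 5 subjects: each subject of set k+1
replays the trial-and-error feedback record of the matching subject of set k,
and the first set falls back to simulated pilot-like behavior.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    BehaviorParams,
    Condition,
    ExperimentDesign,
    IMPLEMENTATION,
    LEARNING,
    YokeLedger,
    generate_design,
    recode_repetitions_by_accuracy,
    simulate_te_behavior,
    yoke_observation,
)
from .lss import TrialPatternSet, estimate_all_trials
from .roi import sphere_roi
from .simulate import (
    BoldDataset,
    GroundTruth,
    NoiseConfig,
    RegionEffectSpec,
    VolumeGeometry,
    default_geometry,
    simulate_bold,
)
from .similarity import cross_stage_ps, stage_specific_ps
from .stats import one_sample_t, rm_anova

logger = logging.getLogger("rulefmri")

__all__ = [
    "SubjectData",
    "default_config",
    "subject_seed",
    "simulate_subject",
    "simulate_cohort_designs",
    "subject_ps_tables",
    "group_ps_study",
    "te_accuracy_table",
    "implementation_behavior_table",
    "run_pipeline",
]


@dataclass
class SubjectData:
    design: ExperimentDesign
    bolds: list[BoldDataset]
    ground_truth: GroundTruth


def default_config() -> dict:
    """The shipped small configuration: an 8-subject, 6-block study on a
    12x12x12 grid with one rule-coding region."""
    return dict(
        design=dict(n_subjects=8, n_blocks=6, seed=7),
        simulation=dict(
            grid_shape=[12, 12, 12],
            voxel_size=3.0,
            tr=2.07,
            region=dict(
                radius_voxels=2,
                identity_snr=0.5,
                cross_stage_consistency=0.6,
                trend_slope_by_condition=dict(
                    instruction=-0.15, trial_and_error=-0.15, observation=-0.15
                ),
            ),
            noise=dict(sigma=1.0, ar1_phi=0.3, drift_amplitude=1.0),
        ),
        analysis=dict(
            high_pass=200.0,
            restrict_to_region=True,
            searchlight=dict(enabled=False, radius_voxels=3, min_voxels_in_sphere=10),
            group=dict(alpha=0.05),
        ),
    )


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def central_region_mask(
    geometry: VolumeGeometry, radius_voxels: int = 2
) -> np.ndarray:
    """Spherical region at the grid center (ROI machinery reused)."""
    voxel = geometry.voxel_size.mean()
    center_ijk = (np.array(geometry.shape) - 1) / 2.0
    center_mm = geometry.voxel_to_mm(np.round(center_ijk))[0]
    return sphere_roi(tuple(center_mm), radius_voxels * voxel, geometry).mask


def simulate_subject(
    subject_id: str,
    seed: int,
    n_blocks: int = 6,
    geometry: VolumeGeometry | None = None,
    specs: list[RegionEffectSpec] | None = None,
    noise: NoiseConfig | None = None,
    behavior: BehaviorParams | None = None,
    tr: float = 2.07,
    ledger: YokeLedger | None = None,
) -> SubjectData:
    """Simulate one subject's design, behavior, and BOLD runs."""
    geometry = geometry or default_geometry()
    if specs is None:
        specs = [
            RegionEffectSpec(
                name="region", region_mask=central_region_mask(geometry)
            )
        ]
    design = generate_design(subject_id=subject_id, seed=seed, n_blocks=n_blocks, behavior=behavior)
    simulate_te_behavior(design, behavior)
    yoke_observation(design, ledger, behavior)
    recode_repetitions_by_accuracy(design)
    bolds, gt = simulate_bold(design, specs, geometry, noise, seed=seed, tr=tr)
    logger.info(
        "simulated %s: seed=%d blocks=%d grid=%s", subject_id, seed, n_blocks, geometry.shape
    )
    return SubjectData(design, bolds, gt)


def simulate_cohort_designs(
    n_subjects: int,
    master_seed: int,
    n_blocks: int = 24,
    behavior: BehaviorParams | None = None,
    cohort_set_size: int = 5,
) -> list[ExperimentDesign]:
    """Behavioral cohort (designs only) with cross-set observation yoking."""
    designs: list[ExperimentDesign] = []
    for i in range(n_subjects):
        design = generate_design(
            subject_id=f"sub-{i + 1:02d}",
            seed=subject_seed(master_seed, i),
            n_blocks=n_blocks,
            behavior=behavior,
        )
        simulate_te_behavior(design, behavior)
        ledger = (
            YokeLedger.from_design(designs[i - cohort_set_size], i // cohort_set_size)
            if i >= cohort_set_size
            else None
        )
        yoke_observation(design, ledger, behavior)
        recode_repetitions_by_accuracy(design)
        designs.append(design)
    return designs


def subject_ps_tables(
    tps: TrialPatternSet,
    design: ExperimentDesign,
    roi_mask: np.ndarray | None = None,
    roi_name: str = "region",
) -> pd.DataFrame:
    """Stage-specific and cross-stage pattern similarity, one table."""
    stage = stage_specific_ps(tps, design, roi_mask, roi_name=roi_name)
    cross = cross_stage_ps(tps, design, roi_mask, roi_name=roi_name)
    return pd.concat([stage, cross], ignore_index=True)


def group_ps_study(
    n_subjects: int,
    master_seed: int,
    identity_snr: float = 0.5,
    rho: float = 0.6,
    n_blocks: int = 6,
    grid_shape: tuple[int, int, int] = (10, 10, 10),
    region_radius_voxels: int = 2,
    noise: NoiseConfig | None = None,
    trend_slopes: dict[Condition, float] | None = None,
    cohort_set_size: int = 5,
) -> pd.DataFrame:
    """Simulate a group end to end and return its pattern-similarity table.

    Each subject runs the full chain (design -> behavior -> BOLD -> LSS ->
    pattern similarity); estimation is restricted to the rule-coding region,
    which is also the analysis ROI.
    """
    geometry = default_geometry(grid_shape)
    region = central_region_mask(geometry, region_radius_voxels)
    tables = []
    sources: list[ExperimentDesign] = []
    for i in range(n_subjects):
        spec = RegionEffectSpec(
            name="region",
            region_mask=region,
            identity_snr=identity_snr,
            cross_stage_consistency=rho,
            trend_slope_by_condition=dict(trend_slopes or {}),
        )
        ledger = (
            YokeLedger.from_design(sources[i - cohort_set_size], i // cohort_set_size)
            if i >= cohort_set_size
            else None
        )
        data = simulate_subject(
            f"sub-{i + 1:02d}",
            subject_seed(master_seed, i),
            n_blocks=n_blocks,
            geometry=geometry,
            specs=[spec],
            noise=noise,
            ledger=ledger,
        )
        sources.append(data.design)
        tps = estimate_all_trials(data.bolds, data.design, mask=region)
        tables.append(subject_ps_tables(tps, data.design))
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# Behavioral tables
# ---------------------------------------------------------------------------

def te_accuracy_table(designs: list[ExperimentDesign]) -> pd.DataFrame:
    """Accuracy per subject x stimulus repetition in trial-and-error learning."""
    rows = []
    for d in designs:
        trials = [
            t
            for t in d.trials
            if t.condition is Condition.TRIAL_AND_ERROR and t.stage == LEARNING
        ]
        for rep in (1, 2, 3, 4):
            vals = [t.correct for t in trials if t.repetition == rep]
            rows.append(
                dict(subject=d.subject_id, repetition=rep, accuracy=float(np.mean(vals)))
            )
    return pd.DataFrame(rows)


def implementation_behavior_table(designs: list[ExperimentDesign]) -> pd.DataFrame:
    """Accuracy and RT per subject x condition x implementation repetition."""
    rows = []
    for d in designs:
        for cond in Condition:
            for rep in (5, 6, 7, 8):
                trials = [
                    t
                    for t in d.trials
                    if t.condition is cond
                    and t.stage == IMPLEMENTATION
                    and t.repetition == rep
                ]
                rows.append(
                    dict(
                        subject=d.subject_id,
                        condition=cond.value,
                        repetition=rep - 4,
                        accuracy=float(np.mean([t.correct for t in trials])),
                        rt=float(np.mean([t.rt for t in trials])),
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline (CLI backend)
# ---------------------------------------------------------------------------

def _spec_from_config(config: dict, geometry: VolumeGeometry) -> RegionEffectSpec:
    rcfg = config["simulation"]["region"]
    slopes = {
        Condition(k): float(v)
        for k, v in rcfg.get("trend_slope_by_condition", {}).items()
    }
    return RegionEffectSpec(
        name="region",
        region_mask=central_region_mask(geometry, int(rcfg.get("radius_voxels", 2))),
        identity_snr=float(rcfg.get("identity_snr", 0.5)),
        cross_stage_consistency=float(rcfg.get("cross_stage_consistency", 0.5)),
        trend_slope_by_condition=slopes,
    )


def run_pipeline(config: dict, outdir) -> dict:
    """Run simulate -> LSS -> pattern similarity -> group stats from a config
    mapping; writes a BIDS-derivative-shaped tree and returns the group
    tables."""
    from pathlib import Path

    from . import io as rio

    outdir = Path(outdir)
    dcfg, scfg, acfg = config["design"], config["simulation"], config["analysis"]
    geometry = default_geometry(
        tuple(scfg.get("grid_shape", [12, 12, 12])), float(scfg.get("voxel_size", 3.0))
    )
    spec = _spec_from_config(config, geometry)
    ncfg = scfg.get("noise", {})
    noise = NoiseConfig(
        sigma=float(ncfg.get("sigma", 1.0)),
        ar1_phi=float(ncfg.get("ar1_phi", 0.3)),
        drift_amplitude=float(ncfg.get("drift_amplitude", 1.0)),
    )
    n_subjects = int(dcfg.get("n_subjects", 8))
    master_seed = int(dcfg.get("seed", 0))
    n_blocks = int(dcfg.get("n_blocks", 6))
    restrict = bool(acfg.get("restrict_to_region", True))
    mask = spec.region_mask if restrict else geometry.brain_mask

    tables = []
    sources: list[ExperimentDesign] = []
    for i in range(n_subjects):
        sid = f"sub-{i + 1:02d}"
        ledger = (
            YokeLedger.from_design(sources[i - 5], i // 5) if i >= 5 else None
        )
        data = simulate_subject(
            sid,
            subject_seed(master_seed, i),
            n_blocks=n_blocks,
            geometry=geometry,
            specs=[spec],
            noise=noise,
            tr=float(scfg.get("tr", 2.07)),
            ledger=ledger,
        )
        sources.append(data.design)
        func_dir = outdir / sid / "func"
        rio.write_events_tsv(data.design, func_dir / f"{sid}_task-rules_events.tsv")
        for bold in data.bolds:
            rio.save_bold(
                bold, func_dir / f"{sid}_task-rules_run-{bold.run}_bold.nii.gz"
            )
        rio.save_ground_truth(data.ground_truth, func_dir / f"{sid}_truth.json")
        tps = estimate_all_trials(
            data.bolds, data.design, mask=mask, high_pass=float(acfg.get("high_pass", 200.0))
        )
        rio.save_pattern_set(tps, outdir / "derivatives" / "lss" / sid)
        tables.append(subject_ps_tables(tps, data.design))
    ps_table = pd.concat(tables, ignore_index=True)
    rio.write_table(ps_table, outdir / "derivatives" / "ps" / "pattern_similarity.tsv")

    stage = ps_table[ps_table["scheme"].str.startswith("stage_specific")].copy()
    stage["stage"] = stage["scheme"].str.replace("stage_specific_", "")
    anova = rm_anova(stage, dv="value", within=["condition", "stage"], subject="subject")
    tests = []
    for scheme, grp in ps_table.groupby("scheme"):
        values = grp.groupby("subject")["value"].mean()
        t, df, p = one_sample_t(values.to_numpy())
        tests.append(dict(scheme=scheme, mean=values.mean(), t=t, df=df, p=p))
    group_dir = outdir / "derivatives" / "group"
    rio.write_table(anova, group_dir / "stage_anova.tsv")
    tests_df = pd.DataFrame(tests)
    rio.write_table(tests_df, group_dir / "one_sample_tests.tsv")
    rio.save_config(config, outdir / "config.yaml")
    logger.info(
        "pipeline complete: %d subjects, outputs under %s", n_subjects, outdir
    )
    return dict(ps_table=ps_table, anova=anova, tests=tests_df)
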