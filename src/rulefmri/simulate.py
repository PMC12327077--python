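"""Synthetic 4D BOLD generation with known ground truth.

The signal model plants two effects inside user-defined regions:

* **rule-identity patterns** — each stimulus evokes a fixed voxel pattern;
  learning-stage and implementation-stage patterns of the same stimulus are
  correlated at a controllable level ``rho`` (cross-stage consistency);
* **condition-dependent amplitude trends** — the trial's mean neural
  amplitude changes linearly with stimulus repetition at a per-condition
  slope, emulating learning-related univariate increases/decreases.

Trials are modeled as stick (impulse) events convolved with the canonical
double-gamma hemodynamic response, superimposed on slow cosine drift and
stationary AR(1) Gaussian noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from scipy.signal import lfilter

from .design import Condition, ExperimentDesign, IMPLEMENTATION, LEARNING

__all__ = [
    "VolumeGeometry",
    "RegionEffectSpec",
    "NoiseConfig",
    "BoldDataset",
    "GroundTruth",
    "canonical_hrf",
    "make_region_patterns",
    "simulate_bold",
    "default_geometry",
]

HRF_DURATION = 32.0  # seconds of kernel support


class SimulationError(ValueError):
    pass


@dataclass
class VolumeGeometry:
    """Voxel grid, voxel-to-mm affine, and brain mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel -> mm
    brain_mask: np.ndarray  # boolean, same shape

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise SimulationError("affine must be an invertible 4x4 transform")
        if self.brain_mask.shape != tuple(self.shape):
            raise SimulationError("brain mask shape does not match grid shape")
        if not self.brain_mask.any():
            raise SimulationError("brain mask is empty")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]


def default_geometry(
    shape: tuple[int, int, int] = (10, 10, 10), voxel_size: float = 3.0
) -> VolumeGeometry:
    """Isotropic grid at analysis resolution (3 mm default), centered on the
    origin, with a full brain mask."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -voxel_size * (np.array(shape) - 1) / 2.0
    return VolumeGeometry(tuple(shape), affine, np.ones(shape, dtype=bool))


@dataclass
class RegionEffectSpec:
    """Ground-truth effects planted in one region.

    ``identity_snr`` is the per-voxel rule-pattern amplitude divided by the
    noise standard deviation. ``cross_stage_consistency`` (rho) sets the
    expected correlation between a stimulus's learning- and
    implementation-stage patterns. ``trend_slope_by_condition`` maps each
    learning condition to the neural-amplitude change per stimulus repetition
    (repetitions centered on their mean).
    """

    name: str
    region_mask: np.ndarray
    identity_snr: float = 0.5
    cross_stage_consistency: float = 0.5
    trend_slope_by_condition: dict[Condition, float] = field(default_factory=dict)
    baseline_amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.trend_slope_by_condition = {
            Condition(c): float(v) for c, v in self.trend_slope_by_condition.items()
        }

    def validate(self, geometry: VolumeGeometry) -> None:
        mask = np.asarray(self.region_mask, dtype=bool)
        if mask.shape != tuple(geometry.shape):
            raise SimulationError(f"region {self.name}: mask shape mismatch")
        if np.any(mask & ~geometry.brain_mask):
            raise SimulationError(f"region {self.name}: extends outside brain mask")
        if not -1.0 <= self.cross_stage_consistency <= 1.0:
            raise SimulationError("cross_stage_consistency must lie in [-1, 1]")
        if self.identity_snr < 0:
            raise SimulationError("identity_snr must be nonnegative")


@dataclass
class NoiseConfig:
    """Additive noise: stationary AR(1) Gaussian per voxel plus slow cosine
    drift. ``drift_high_pass`` places all drift power below the given cutoff
    frequency, so a matched high-pass filter removes it by construction."""

    sigma: float = 1.0
    ar1_phi: float = 0.3
    drift_amplitude: float = 1.0
    drift_high_pass: float = 200.0  # seconds; drift periods exceed this

    def validate(self) -> None:
        if self.sigma < 0:
            raise SimulationError("noise sigma must be nonnegative")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise SimulationError("AR(1) coefficient must lie in [0, 1)")


@dataclass
class BoldDataset:
    """4D voxel time-series for one run.

    ``data`` includes ``n_discard`` initial volumes acquired before the run's
    reference time 0 (analysis code drops them); frame times of the retained
    volumes are ``0, tr, 2*tr, ...``.
    """

    data: np.ndarray  # (x, y, z, time)
    tr: float = 2.07
    geometry: VolumeGeometry | None = None
    n_discard: int = 3
    run: int = 1

    @property
    def n_scans(self) -> int:
        """Number of retained (analyzed) volumes."""
        return self.data.shape[3] - self.n_discard

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.tr

    def time_series(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Retained volumes as (time, voxels), optionally mask-restricted."""
        if mask is None:
            mask = self.geometry.brain_mask
        return self.data[mask][:, self.n_discard :].T


@dataclass
class GroundTruth:
    """What the simulator injected, for parameter-recovery checks."""

    patterns_learning: dict[str, dict[int, np.ndarray]]  # region -> stimulus -> voxel vector
    patterns_implementation: dict[str, dict[int, np.ndarray]]
    trial_amplitudes: dict[str, np.ndarray]  # region -> mean (trend) amplitude per trial
    region_voxels: dict[str, np.ndarray]  # region -> flat voxel indices into brain mask order
    params: dict


def canonical_hrf(tr: float, oversampling: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Canonical double-gamma hemodynamic response.

    Peak delay 6 s, undershoot delay 16 s, peak:undershoot ratio 6, 32 s
    support; unit dispersions. Returns ``(times, values)`` sampled every
    ``tr / oversampling`` seconds, normalized to peak 1.
    """
    if tr <= 0:
        raise SimulationError("tr must be positive")
    dt = tr / oversampling
    t = np.arange(0.0, HRF_DURATION + dt / 2, dt)
    h = sp_stats.gamma.pdf(t, 6.0) - sp_stats.gamma.pdf(t, 16.0) / 6.0
    return t, h / h.max()


def make_region_patterns(
    n_voxels: int, n_stimuli: int, rho: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired stage patterns with expected cross-stage correlation rho.

    Learning patterns are i.i.d. standard normal per stimulus; each
    implementation pattern is ``rho * learning + sqrt(1 - rho^2) * fresh``.
    Both are returned with unit-normalized columns, shape (n_voxels, n_stimuli).
    """
    if n_voxels < 2:
        raise SimulationError("need at least 2 voxels for a pattern")
    if not -1.0 <= rho <= 1.0:
        raise SimulationError("|rho| must not exceed 1")
    rng = np.random.default_rng(seed)
    learning = rng.standard_normal((n_voxels, n_stimuli))
    fresh = rng.standard_normal((n_voxels, n_stimuli))
    implementation = rho * learning + np.sqrt(1.0 - rho**2) * fresh
    learning = learning / np.linalg.norm(learning, axis=0)
    implementation = implementation / np.linalg.norm(implementation, axis=0)
    return learning, implementation


def trial_response_matrix(
    onsets: np.ndarray, frame_times: np.ndarray, tr: float, oversampling: int = 16
) -> np.ndarray:
    """HRF response of each stick event sampled at the frame times.

    For impulse events the convolution reduces to evaluating the kernel at
    ``frame_time - onset``; evaluation interpolates an oversampled kernel.
    Returns (n_frames, n_events).
    """
    tk, h = canonical_hrf(tr, oversampling)
    lags = frame_times[:, None] - np.asarray(onsets)[None, :]
    return np.interp(lags, tk, h, left=0.0, right=0.0)


def _drift(
    rng: np.random.Generator,
    n_scans: int,
    n_discard: int,
    tr: float,
    cfg: NoiseConfig,
) -> np.ndarray:
    """Slow drift over the discard + retained volumes.

    Components are the discrete cosines of the retained window with periods
    above ``drift_high_pass``, evaluated backward over the discard volumes, so
    the retained portion lies exactly in the span of a matched (or stricter)
    high-pass cosine basis.
    """
    duration = n_scans * tr
    n_comp = max(int(np.ceil(2.0 * duration / cfg.drift_high_pass)) - 1, 0)
    total = n_scans + n_discard
    if n_comp == 0 or cfg.drift_amplitude == 0:
        return np.zeros(total)
    i = np.arange(-n_discard, n_scans)
    k = np.arange(1, n_comp + 1)
    basis = np.cos(np.pi * k[None, :] * (2 * i[:, None] + 1) / (2 * n_scans))
    amps = rng.normal(0.0, cfg.drift_amplitude, n_comp)
    return basis @ amps


def _ar1_noise(
    rng: np.random.Generator, n_scans: int, n_voxels: int, cfg: NoiseConfig
) -> np.ndarray:
    if cfg.sigma == 0:
        return np.zeros((n_scans, n_voxels))
    innov_sd = cfg.sigma * np.sqrt(1.0 - cfg.ar1_phi**2)
    e = rng.normal(0.0, innov_sd, (n_scans, n_voxels))
    # stationary start
    e[0] *= cfg.sigma / innov_sd
    return lfilter([1.0], [1.0, -cfg.ar1_phi], e, axis=0)


def simulate_bold(
    design: ExperimentDesign,
    specs: list[RegionEffectSpec],
    geometry: VolumeGeometry,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    tr: float = 2.07,
    n_discard: int = 3,
    hrf_oversampling: int = 16,
) -> tuple[list[BoldDataset], GroundTruth]:
    """Simulate one subject's runs.

    Per trial the neural amplitude is ``baseline + slope(condition) *
    (repetition - mean repetition)``; inside a region each voxel responds with
    that amplitude plus the stimulus's stage pattern scaled to
    ``identity_snr x noise sigma`` per voxel. Outside all regions the signal
    is zero. Returns one :class:`BoldDataset` per run plus the ground truth.
    """
    noise = noise or NoiseConfig()
    noise.validate()
    for spec in specs:
        spec.validate(geometry)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB01D]))

    mask = geometry.brain_mask
    n_voxels = int(mask.sum())
    flat_region_idx: dict[str, np.ndarray] = {}
    mask_order = np.zeros(geometry.shape, dtype=int)
    mask_order[mask] = np.arange(n_voxels)

    stimuli = sorted(design.unique_stimuli - {t.stimulus for t in design.practice_trials})
    stim_col = {s: j for j, s in enumerate(stimuli)}
    noise_ref = noise.sigma if noise.sigma > 0 else 1.0

    patterns_l: dict[str, dict[int, np.ndarray]] = {}
    patterns_i: dict[str, dict[int, np.ndarray]] = {}
    region_amp: dict[str, dict[str, np.ndarray]] = {}
    for k, spec in enumerate(specs):
        rmask = np.asarray(spec.region_mask, dtype=bool)
        idx = mask_order[rmask]
        flat_region_idx[spec.name] = idx
        nv = len(idx)
        pattern_seed = np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)
        pl, pi = make_region_patterns(
            nv, len(stimuli), spec.cross_stage_consistency, seed=int(pattern_seed)
        )
        scale = spec.identity_snr * noise_ref * np.sqrt(nv)
        region_amp[spec.name] = {"learning": pl * scale, "implementation": pi * scale}
        patterns_l[spec.name] = {s: pl[:, stim_col[s]].copy() for s in stimuli}
        patterns_i[spec.name] = {s: pi[:, stim_col[s]].copy() for s in stimuli}

    mean_rep = 4.5  # repetitions 1..8
    all_trials = sorted(design.trials, key=lambda t: (t.run, t.onset))
    trial_amps = {
        spec.name: np.array(
            [
                spec.baseline_amplitude
                + spec.trend_slope_by_condition.get(t.condition, 0.0)
                * (t.repetition - mean_rep)
                for t in all_trials
            ]
        )
        for spec in specs
    }

    datasets: list[BoldDataset] = []
    for run in design.runs:
        run_trials = [t for t in all_trials if t.run == run]
        duration = design.run_duration(run)
        n_scans = int(np.ceil(duration / tr))
        frame_times = np.arange(n_scans) * tr
        onsets = np.array([t.onset for t in run_trials])
        R = trial_response_matrix(onsets, frame_times, tr, hrf_oversampling)

        # amplitude matrix: trials x in-mask voxels
        A = np.zeros((len(run_trials), n_voxels))
        for spec in specs:
            idx = flat_region_idx[spec.name]
            if len(idx) == 0:
                continue
            for j, t in enumerate(run_trials):
                slope = spec.trend_slope_by_condition.get(t.condition, 0.0)
                amp = spec.baseline_amplitude + slope * (t.repetition - mean_rep)
                stage_pat = region_amp[spec.name][t.stage][:, stim_col[t.stimulus]]
                A[j, idx] += amp + stage_pat
        signal = R @ A

        total = n_scans + n_discard
        noise_mat = _ar1_noise(rng, total, n_voxels, noise)
        drift = _drift(rng, n_scans, n_discard, tr, noise)
        series = noise_mat + drift[:, None]
        series[n_discard:] += signal

        data = np.zeros(geometry.shape + (total,))
        data[mask] = series.T
        datasets.append(
            BoldDataset(data=data, tr=tr, geometry=geometry, n_discard=n_discard, run=run)
        )

    gt = GroundTruth(
        patterns_learning=patterns_l,
        patterns_implementation=patterns_i,
        trial_amplitudes=trial_amps,
        region_voxels=flat_region_idx,
        params=dict(
            seed=seed,
            tr=tr,
            noise=dict(
                sigma=noise.sigma,
                ar1_phi=noise.ar1_phi,
                drift_amplitude=noise.drift_amplitude,
                drift_high_pass=noise.drift_high_pass,
            ),
            regions=[
                dict(
                    name=s.name,
                    identity_snr=s.identity_snr,
                    cross_stage_consistency=s.cross_stage_consistency,
                    baseline_amplitude=s.baseline_amplitude,
                    trend_slope_by_condition={
                        c.value: v for c, v in s.trend_slope_by_condition.items()
                    },
                )
                for s in specs
            ],
        ),
    )
    return datasets, gt
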