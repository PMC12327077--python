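"""Whole-brain spherical searchlight over identity-specific pattern similarity.

At every in-mask voxel a sphere (default 3-voxel / 9-mm radius) is clipped to
the brain mask and the block-wise same-minus-different pattern similarity is
computed over a pooled repetition scheme, averaged across all blocks of all
conditions. The main map pools repetitions 2-8; an implementation-only
variant pools 5-8 (used, e.g., to localize motor rule representations).

Each center's value is, by construction, exactly what
:func:`~rulefmri.similarity.block_pattern_similarity` returns on that
sphere's voxels, so results are independent of how centers are traversed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ExperimentDesign
from .lss import TrialPatternSet
from .similarity import PairScheme, block_pattern_similarity

__all__ = ["SearchlightSpec", "PsMap", "sphere_offsets", "run_searchlight"]


class SearchlightError(ValueError):
    pass


def sphere_offsets(radius_voxels: int) -> np.ndarray:
    """All integer offsets (dx, dy, dz) with squared norm <= radius^2,
    including the center; shape (n, 3)."""
    if radius_voxels < 0:
        raise SearchlightError("radius must be nonnegative")
    r = int(radius_voxels)
    grid = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(grid, grid, grid, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


@dataclass(frozen=True)
class SearchlightSpec:
    radius_voxels: int = 3
    radius_mm: float = 9.0
    scheme: PairScheme = field(default_factory=PairScheme.pooled)
    min_voxels_in_sphere: int = 10

    def __post_init__(self) -> None:
        if self.radius_voxels < 1:
            raise SearchlightError("radius_voxels must be >= 1")
        if not self.scheme.mode.startswith("pooled"):
            raise SearchlightError("searchlight schemes must be pooled modes")


@dataclass
class PsMap:
    """Per-subject 3D pattern-similarity map (NaN outside the mask or where
    the clipped sphere falls below the voxel minimum)."""

    values: np.ndarray
    mask: np.ndarray
    spec: SearchlightSpec
    subject: str = ""


def run_searchlight(
    tps: TrialPatternSet,
    design: ExperimentDesign,
    spec: SearchlightSpec | None = None,
) -> PsMap:
    """Compute the searchlight map from a subject's trial patterns."""
    spec = spec or SearchlightSpec()
    mask = tps.mask
    shape = mask.shape
    col_of = np.full(shape, -1, dtype=int)
    col_of[mask] = np.arange(int(mask.sum()))
    offsets = sphere_offsets(spec.radius_voxels)

    reps = spec.scheme.repetitions
    blocks = sorted({int(b) for b in tps.index["block"]})
    # per block: (stimulus, repetition) -> row in tps.data
    block_rows: dict[int, dict[tuple[int, int], int]] = {}
    for b in blocks:
        rows = tps.select(block=b, repetition=tuple(reps))
        block_rows[b] = {
            (
                int(tps.index["stimulus"].iat[r]),
                int(tps.index["repetition"].iat[r]),
            ): r
            for r in rows
        }

    values = np.full(shape, np.nan)
    centers = np.argwhere(mask)
    for center in centers:
        pos = center[None, :] + offsets
        inside = np.all((pos >= 0) & (pos < np.array(shape)), axis=1)
        pos = pos[inside]
        cols = col_of[pos[:, 0], pos[:, 1], pos[:, 2]]
        cols = cols[cols >= 0]
        if len(cols) < spec.min_voxels_in_sphere:
            continue
        total = 0.0
        for b in blocks:
            patterns = {
                key: tps.data[r][cols] for key, r in block_rows[b].items()
            }
            total += block_pattern_similarity(patterns, spec.scheme)
        values[tuple(center)] = total / len(blocks)
    return PsMap(values=values, mask=mask, spec=spec, subject=design.subject_id)
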