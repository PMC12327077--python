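"""Region-of-interest construction: spheres at mm coordinates, mask
intersection, and cluster extraction from thresholded group maps.

Atlas extraction is out of scope; any user-supplied mask volume can stand in
for an atlas region. Peak coordinates from standard space are carried as
named presets for users with real normalized data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .simulate import VolumeGeometry

__all__ = [
    "RoiMask",
    "sphere_roi",
    "intersect_masks",
    "threshold_to_roi",
    "MNI_PRESETS",
]

# 12-mm sphere centers (mm) used with real standard-space data: premotor and
# motor peaks from the rule-decoding searchlight maps.
MNI_PRESETS: dict[str, tuple[float, float, float]] = {
    "dPMC_R": (42.0, -15.0, 57.0),
    "vPMC_IFJ_R": (48.0, 6.0, 33.0),
    "dPMC_L": (-25.0, -13.0, 63.0),
    "vPMC_IFJ_L": (-43.0, 3.0, 42.0),
    "motor_L": (-46.0, -28.0, 63.0),
}


class RoiError(ValueError):
    pass


@dataclass
class RoiMask:
    name: str
    mask: np.ndarray  # boolean volume
    geometry: VolumeGeometry
    hemisphere: str = "bilateral"  # "L" | "R" | "bilateral"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise RoiError(f"ROI {self.name!r} is empty")
        if self.mask.shape != tuple(self.geometry.shape):
            raise RoiError(f"ROI {self.name!r}: shape mismatch with geometry")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def sphere_roi(
    center_mm: tuple[float, float, float],
    radius_mm: float,
    geometry: VolumeGeometry,
    name: str | None = None,
    hemisphere: str = "bilateral",
    clip_to_brain: bool = True,
) -> RoiMask:
    """Voxels whose mm-center lies within ``radius_mm`` of ``center_mm``."""
    center = np.asarray(center_mm, dtype=float)
    ijk = np.argwhere(np.ones(geometry.shape, dtype=bool))
    xyz = geometry.voxel_to_mm(ijk)
    dist2 = ((xyz - center) ** 2).sum(axis=1)
    mask = np.zeros(geometry.shape, dtype=bool)
    inside = ijk[dist2 <= radius_mm**2]
    mask[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    if clip_to_brain:
        mask &= geometry.brain_mask
    if not mask.any():
        raise RoiError(
            f"sphere at {tuple(center)} mm (r={radius_mm} mm) contains no voxels"
        )
    return RoiMask(
        name=name or f"sphere_{radius_mm:g}mm",
        mask=mask,
        geometry=geometry,
        hemisphere=hemisphere,
        provenance=f"sphere center={tuple(center)} radius={radius_mm} mm",
    )


def intersect_masks(a: RoiMask, b: RoiMask, name: str | None = None) -> RoiMask:
    """Logical AND of two ROIs on the same geometry."""
    if a.mask.shape != b.mask.shape or not np.allclose(
        a.geometry.affine, b.geometry.affine
    ):
        raise RoiError("ROIs are defined on different geometries")
    mask = a.mask & b.mask
    if not mask.any():
        raise RoiError(
            f"empty intersection of {a.name!r} ({a.n_voxels} vox) and "
            f"{b.name!r} ({b.n_voxels} vox)"
        )
    hemisphere = a.hemisphere if a.hemisphere == b.hemisphere else "bilateral"
    return RoiMask(
        name=name or f"{a.name}&{b.name}",
        mask=mask,
        geometry=a.geometry,
        hemisphere=hemisphere,
        provenance=f"intersection of [{a.name}] and [{b.name}]",
    )


def threshold_to_roi(
    group_map: np.ndarray,
    geometry: VolumeGeometry,
    t_threshold: float,
    min_cluster_voxels: int = 1,
    name_prefix: str = "cluster",
) -> list[RoiMask]:
    """Label suprathreshold voxels into 26-connected clusters; clusters below
    the size floor are dropped. Returns ROIs sorted by descending size."""
    supra = np.nan_to_num(np.asarray(group_map, dtype=float), nan=-np.inf) > t_threshold
    labels, n = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=int))
    rois = []
    for k in range(1, n + 1):
        mask = labels == k
        if mask.sum() < min_cluster_voxels:
            continue
        rois.append(
            RoiMask(
                name=f"{name_prefix}_{k}",
                mask=mask,
                geometry=geometry,
                provenance=f"t > {t_threshold:g}, 26-connected, "
                f"size >= {min_cluster_voxels}",
            )
        )
    return sorted(rois, key=lambda r: -r.n_voxels)
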