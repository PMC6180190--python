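"""NIfTI volume and label-map I/O with a single internal coordinate convention.

Every image entering the pipeline is normalized to RAS+ voxel order on load, so
downstream ROI statistics, resampling and registration can treat array axis 0
as right(-to-left is negative), axis 1 as anterior, axis 2 as superior without
re-checking headers. World (scanner mm) coordinates are preserved exactly by
the accompanying affine; only the in-memory axis order/direction changes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

#: FreeSurfer-convention defaults; every code is overridable through config.
DEFAULT_LABEL_CONFIG: dict = {
    "left_hippocampus": 17,
    "right_hippocampus": 53,
    "brain": "nonzero",  # all nonzero labels
    # cerebellar cortex/WM (L 7,8 / R 46,47) and brainstem (16) are excluded
    # from the supratentorial set used for volume normalization
    "supratentorial_exclude": [7, 8, 16, 46, 47],
}


@dataclass
class VolumeGrid:
    """A 3D scalar image with its voxel-index -> world-mm affine.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (arbitrary units) or integer labels.
    affine : ndarray, shape (4, 4)
        Homogeneous map from 0-based voxel indices to world millimetres.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("singular affine: zero voxel volume")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the affine's linear block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge length of a voxel along each array axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coords(self, index: Sequence[float]) -> np.ndarray:
        """World-mm position of a (possibly fractional) voxel index."""
        idx = np.asarray(index, dtype=float)
        return self.affine[:3, :3] @ idx + self.affine[:3, 3]

    def world_center(self) -> np.ndarray:
        """World position of the geometric center of the grid."""
        return self.world_coords((np.asarray(self.shape) - 1) / 2.0)

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """New grid sharing this geometry with different voxel data."""
        return VolumeGrid(data=np.asarray(data), affine=self.affine.copy())


@dataclass
class LabelMap:
    """Integer label volume plus a role -> label-code mapping.

    Roles used by the pipeline: ``left_hippocampus``, ``right_hippocampus``,
    ``brain`` (either explicit codes or the string ``"nonzero"``) and
    ``supratentorial_exclude`` (codes removed from the brain set when
    computing the supratentorial normalization volume).
    """

    grid: VolumeGrid
    labels: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_CONFIG))

    def __post_init__(self) -> None:
        if not np.issubdtype(self.grid.data.dtype, np.integer):
            raise ValueError("label map data must be integer-valued")
        merged = dict(DEFAULT_LABEL_CONFIG)
        merged.update(self.labels)
        self.labels = merged

    def codes_for(self, role: str) -> list:
        value = self.labels[role]
        if isinstance(value, (int, np.integer)):
            return [int(value)]
        return [int(v) for v in value]

    def role_mask(self, role: str) -> np.ndarray:
        """Boolean mask of voxels carrying any of the role's codes."""
        if role == "brain" and self.labels.get("brain") == "nonzero":
            return self.grid.data != 0
        return np.isin(self.grid.data, self.codes_for(role))


def normalize_orientation(grid: VolumeGrid) -> VolumeGrid:
    """Reorder/flip axes so the array is RAS+; world geometry is unchanged.

    Idempotent: an already-RAS grid is returned with identical data/affine.
    """
    ornt = nib.orientations.io_orientation(grid.affine)
    if np.array_equal(ornt, [[0, 1], [1, 1], [2, 1]]):
        return grid
    data = nib.orientations.apply_orientation(grid.data, ornt)
    affine = grid.affine @ nib.orientations.inv_ornt_aff(ornt, grid.shape)
    return VolumeGrid(data=data, affine=affine)


def read_volume(path) -> VolumeGrid:
    """Load a NIfTI-1/2 file (optionally .gz) as an RAS+ :class:`VolumeGrid`.

    Raises
    ------
    ValueError
        If the image is not 3D, contains NaN/Inf voxels, or has a singular
        affine.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path.name}: volume contains NaN/Inf voxels")
    grid = VolumeGrid(data=data, affine=np.asarray(img.affine))
    return normalize_orientation(grid)


def write_volume(grid: VolumeGrid, path, dtype=np.float32) -> None:
    """Write a grid to NIfTI; float data is stored as float32."""
    data = grid.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, grid.affine)
    nib.save(img, str(path))


def read_label_map(path, labels: Mapping | None = None) -> LabelMap:
    """Load an integer NIfTI label volume with an optional role->code config.

    FreeSurfer ``aseg.mgz`` must be converted to NIfTI upstream
    (``mri_convert aseg.mgz aseg.nii.gz``); MGH/MGZ is not parsed here.
    """
    grid = read_volume(path)
    int_data = np.rint(grid.data).astype(np.int32)
    if not np.allclose(grid.data, int_data, atol=1e-3):
        raise ValueError(f"{Path(path).name}: label map has non-integer voxel values")
    lm = LabelMap(grid=VolumeGrid(int_data, grid.affine), labels=dict(labels or {}))
    for role in ("left_hippocampus", "right_hippocampus"):
        if not lm.role_mask(role).any():
            log.warning("label code(s) for role %s absent from %s", role, path)
    return lm


def extract_masks(lm: LabelMap) -> tuple[VolumeGrid, VolumeGrid, VolumeGrid]:
    """Binary (left hippocampus, right hippocampus, brain) masks on lm's grid.

    Raises
    ------
    ValueError
        ``"empty mask: <role>"`` if a hippocampal role resolves to no voxels,
        or if the brain role is empty.
    """
    out = []
    for role in ("left_hippocampus", "right_hippocampus", "brain"):
        mask = lm.role_mask(role)
        if not mask.any():
            raise ValueError(f"empty mask: {role}")
        log.info("mask %s: %d voxels (%.1f mm^3)", role, mask.sum(),
                 mask.sum() * lm.grid.voxel_volume)
        out.append(lm.grid.like(mask.astype(np.uint8)))
    return tuple(out)


def supratentorial_mask(lm: LabelMap) -> VolumeGrid:
    """Brain mask minus the configured infratentorial/exclusion codes."""
    mask = lm.role_mask("brain")
    excl = lm.labels.get("supratentorial_exclude", [])
    if excl:
        mask = mask & ~np.isin(lm.grid.data, [int(c) for c in excl])
    if not mask.any():
        raise ValueError("empty mask: supratentorial")
    return lm.grid.like(mask.astype(np.uint8))
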