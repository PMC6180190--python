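"""The measurement core: normalized volume, relative FLAIR intensity, SUVR.

Each subject is reduced to three (right, left) value pairs:

* **volume** — hippocampal volume divided by the supratentorial volume, a
  dimensionless ratio that removes head-size differences;
* **flair** — mean of the whole-brain-normalized FLAIR image over each
  hippocampal mask (relative FLAIR intensity);
* **suvr** — mean of the whole-brain-normalized PET image over each mask
  (standardized uptake value ratio).

FLAIR and PET are first normalized by their skull-stripped whole-brain mean,
so all three measures are invariant to global intensity scaling of the raw
scans.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess
from .volumes_io import LabelMap, VolumeGrid, extract_masks, supratentorial_mask


@dataclass
class BilateralMeasure:
    """One subject's (right, left) value pair for a single modality."""

    modality: str  # volume | flair | suvr
    right: float
    left: float

    def as_point(self) -> np.ndarray:
        """(right, left) vector: x-axis right hippocampus, y-axis left."""
        return np.array([self.right, self.left], dtype=float)


@dataclass
class SubjectQuantification:
    subject_id: str
    measures: dict  # modality -> BilateralMeasure
    provenance: dict = field(default_factory=dict)


def normalized_hippocampal_volume(labels: LabelMap) -> BilateralMeasure:
    """Per-side hippocampal volume / supratentorial volume.

    Voxel volume cancels in the ratio, so the result is invariant to voxel
    size given the same anatomy. Raw mm^3 values are attached as
    ``raw_mm3`` for provenance.
    """
    left, right, _ = extract_masks(labels)
    supra = supratentorial_mask(labels)
    n_supra = int(np.count_nonzero(supra.data))
    if n_supra == 0:
        raise ValueError("zero supratentorial volume")
    vv = labels.grid.voxel_volume
    n_l = int(np.count_nonzero(left.data))
    n_r = int(np.count_nonzero(right.data))
    m = BilateralMeasure("volume", right=n_r / n_supra, left=n_l / n_supra)
    m.raw_mm3 = {"right": n_r * vv, "left": n_l * vv, "supratentorial": n_supra * vv}
    return m


def standardize_image(img: VolumeGrid, brain_mask: VolumeGrid) -> VolumeGrid:
    """Divide an image by its mean over the brain mask.

    After standardization the within-mask mean is exactly 1, making the
    output a relative-intensity (FLAIR) or SUVR (PET) image. Idempotent.
    """
    mask = brain_mask.data > 0
    if not mask.any():
        raise ValueError("standardize_image: empty brain mask")
    mean = float(img.data[mask].mean())
    if mean <= 0:
        raise ValueError(f"standardize_image: non-positive mask mean ({mean})")
    return img.like(img.data / mean)


def roi_bilateral_mean(
    std_img: VolumeGrid,
    left_mask: VolumeGrid,
    right_mask: VolumeGrid,
    modality: str,
) -> BilateralMeasure:
    """Arithmetic mean of a standardized image over each hippocampal mask."""
    for name, m in (("left", left_mask), ("right", right_mask)):
        if m.shape != std_img.shape:
            raise ValueError(f"geometry mismatch between image and {name} mask")
        if not (m.data > 0).any():
            raise ValueError(f"empty mask: {name}")
    return BilateralMeasure(
        modality,
        right=float(std_img.data[right_mask.data > 0].mean()),
        left=float(std_img.data[left_mask.data > 0].mean()),
    )


def _foreground_mask(img: VolumeGrid, fraction: float = 0.05) -> VolumeGrid:
    """Crude head mask for native-space bias correction: voxels above a small
    fraction of the maximum intensity."""
    thr = fraction * float(img.data.max())
    return img.like((img.data > thr).astype(np.uint8))


def quantify_subject(
    t1: VolumeGrid,
    flair: VolumeGrid,
    pet: VolumeGrid,
    labels: LabelMap,
    cfg: dict | None = None,
    skip_coreg: bool = False,
    subject_id: str = "subject",
) -> SubjectQuantification:
    """Run the full per-subject measurement pipeline.

    Stages: FLAIR bias correction (native space) -> rigid coregistration and
    reslicing of FLAIR and PET onto the T1 grid -> whole-brain-mean
    standardization -> hippocampal ROI means, plus the normalized volume from
    the label map. PET is not bias-corrected. With ``skip_coreg`` the inputs
    are assumed pre-aligned and identity transforms are used.
    """
    cfg = cfg or {}
    prov: dict = {"config": dict(cfg), "skip_coreg": skip_coreg}
    left, right, brain = _stage("extract_masks", extract_masks, labels)

    order = int(cfg.get("bias_order", 3))
    flair_corr, _ = _stage(
        "bias_correct", preprocess.bias_correct, flair, _foreground_mask(flair), order
    )

    identity = preprocess.RigidTransform(center=t1.world_center())
    transforms = {}
    resliced = {}
    for name, img in (("flair", flair_corr), ("pet", pet)):
        if skip_coreg:
            tr = identity
        else:
            tr = _stage(f"rigid_coregister[{name}]", preprocess.rigid_coregister, img, t1)
        transforms[name] = tr
        resliced[name] = _stage(
            f"reslice[{name}]", preprocess.reslice, img, tr, t1, "trilinear"
        )
    prov["transforms"] = {
        k: {"translations_mm": v.translations.tolist(), "rotations_deg": v.rotations.tolist()}
        for k, v in transforms.items()
    }

    measures = {"volume": _stage("volume", normalized_hippocampal_volume, labels)}
    for name, modality in (("flair", "flair"), ("pet", "suvr")):
        std = _stage(f"standardize[{name}]", standardize_image, resliced[name], brain)
        measures[modality] = _stage(
            f"roi_mean[{name}]", roi_bilateral_mean, std, left, right, modality
        )
    prov["mask_voxels"] = {
        "left": int(np.count_nonzero(left.data)),
        "right": int(np.count_nonzero(right.data)),
        "brain": int(np.count_nonzero(brain.data)),
    }
    return SubjectQuantification(subject_id, measures, prov)


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc
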