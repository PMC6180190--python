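"""Synthetic phantoms, measurement cohorts, and the packaged clinical table.

The phantom is a deliberately miniature brain: a uniform sphere containing two
ellipsoidal hippocampus-like ROIs, mirrored about the mid-sagittal plane.
Pathology is injected per side as a volume multiplier (atrophy), a FLAIR
intensity multiplier (hyperintensity) and a PET uptake multiplier
(hypometabolism); the FLAIR/PET copies additionally carry a rigid
misalignment, a smooth multiplicative bias field and additive Gaussian noise,
which is exactly the degradation model the preprocessing stage claims to
undo. Ground truth (applied field, transform, ROI volumes) is returned so
recovery can be tested quantitatively.

The cohort generator skips imaging entirely and draws per-subject
(right, left) measurement pairs from bivariate normal control distributions,
displacing the pathological side of patients along each modality's clinical
direction: volume down, FLAIR up, SUVR down.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .preprocess import RigidTransform, reslice
from .volumes_io import LabelMap, VolumeGrid

PATHOLOGICAL_DIRECTION = {"volume": "low", "flair": "high", "suvr": "low"}

LEFT_HIPPOCAMPUS_CODE = 17
RIGHT_HIPPOCAMPUS_CODE = 53
BRAIN_TISSUE_CODE = 2


@dataclass
class PhantomSpec:
    """Parameters of the miniature imaging phantom.

    Pairs are ordered (right, left) throughout, matching the scatter-plot
    axis convention of the analysis (x = right hippocampus, y = left).
    """

    grid_shape: tuple = (64, 64, 64)
    voxel_mm: float = 1.0
    brain_radius_mm: float = 25.0
    hippocampus_center_mm: tuple = (12.0, -4.0, -2.0)  # right side; left is x-mirrored
    hippocampus_radii_mm: tuple = (11.0, 5.0, 4.0)
    tissue_means: dict = field(
        default_factory=lambda: {
            "t1": {"brain": 100.0, "hippocampus": 130.0},
            "flair": {"brain": 100.0, "hippocampus": 120.0},
            "pet": {"brain": 100.0, "hippocampus": 110.0},
        }
    )
    atrophy_factor: tuple = (1.0, 1.0)  # hippocampal volume multiplier (right, left)
    flair_boost: tuple = (1.0, 1.0)  # hippocampal FLAIR intensity multiplier
    pet_drop: tuple = (1.0, 1.0)  # hippocampal PET uptake multiplier
    texture_amplitude: float = 0.15  # low-frequency tissue texture contrast
    bias_order: int = 2
    bias_amplitude: float = 0.0  # RMS of the log bias field inside the brain
    noise_sd: float = 0.0  # additive Gaussian noise, intensity units
    rigid_offset: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)  # tx,ty,tz mm, rx,ry,rz deg
    seed: int = 0

    def validate(self) -> None:
        for name in ("atrophy_factor", "flair_boost", "pet_drop"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} entries must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        half_extent = min(self.grid_shape) * self.voxel_mm / 2.0
        if self.brain_radius_mm >= half_extent:
            raise ValueError("grid too small to contain the brain sphere")


def _grid_affine(spec: PhantomSpec) -> np.ndarray:
    """Isotropic affine placing the world origin at the grid center (RAS+)."""
    aff = np.diag([spec.voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -spec.voxel_mm * (np.asarray(spec.grid_shape) - 1) / 2.0
    return aff


def _bias_field(spec: PhantomSpec, brain: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """exp(polynomial) field with RMS(log field) = bias_amplitude inside brain."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    axes = [np.linspace(-1, 1, n) for n in spec.grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    log_f = np.zeros(spec.grid_shape)
    for i, j, k in itertools.product(range(spec.bias_order + 1), repeat=3):
        if 0 < i + j + k <= spec.bias_order:
            log_f += rng.normal() * gx**i * gy**j * gz**k
    log_f -= log_f[brain].mean()
    rms = np.sqrt(np.mean(log_f[brain] ** 2))
    if rms > 0:
        log_f *= spec.bias_amplitude / rms
    return np.exp(log_f)


def generate_phantom(spec: PhantomSpec):
    """Generate (t1, flair, pet, labels, truth) for a phantom spec.

    Returns
    -------
    t1, flair, pet : VolumeGrid
        T1 stays on the reference grid; FLAIR and PET carry the configured
        rigid offset, bias field and noise.
    labels : LabelMap
        Hippocampus codes 17 (left) / 53 (right), remaining brain tissue 2.
    truth : dict
        ``transform_to_t1`` (the rigid transform registration should
        recover, i.e. the inverse of the applied offset), ``bias_field``,
        per-side ROI volumes (analytic mm^3 and voxel counts), and the spec.
    """
    spec.validate()
    affine = _grid_affine(spec)
    ref = VolumeGrid(np.zeros(spec.grid_shape), affine)
    idx = np.indices(spec.grid_shape, dtype=float)
    world = np.einsum("ij,j...->i...", affine[:3, :3], idx) + affine[:3, 3].reshape(3, 1, 1, 1)

    brain = (world**2).sum(axis=0) <= spec.brain_radius_mm**2
    labels_data = np.where(brain, BRAIN_TISSUE_CODE, 0).astype(np.int32)

    roi_volumes = {}
    roi_voxels = {}
    masks = {}
    radii = np.asarray(spec.hippocampus_radii_mm, dtype=float)
    center_r = np.asarray(spec.hippocampus_center_mm, dtype=float)
    for side, sign, factor, code in (
        ("right", +1, spec.atrophy_factor[0], RIGHT_HIPPOCAMPUS_CODE),
        ("left", -1, spec.atrophy_factor[1], LEFT_HIPPOCAMPUS_CODE),
    ):
        c = center_r * np.array([sign, 1.0, 1.0])
        r = radii * factor ** (1.0 / 3.0)
        if np.any(np.abs(c) + r > spec.brain_radius_mm):
            raise ValueError(f"{side} hippocampus ellipsoid extends outside the brain")
        d2 = sum(((world[i] - c[i]) / r[i]) ** 2 for i in range(3))
        mask = d2 <= 1.0
        labels_data[mask] = code
        masks[side] = mask
        roi_voxels[side] = int(mask.sum())
        roi_volumes[side] = float(4.0 / 3.0 * np.pi * np.prod(r))
    if (masks["right"] & masks["left"]).any():
        raise ValueError("left and right hippocampus ellipsoids overlap")

    labels = LabelMap(grid=VolumeGrid(labels_data, affine))

    def template(modality: str, side_factors: tuple) -> np.ndarray:
        means = spec.tissue_means[modality]
        img = np.where(brain, means["brain"], 0.0)
        img[masks["right"]] = means["hippocampus"] * side_factors[0]
        img[masks["left"]] = means["hippocampus"] * side_factors[1]
        return img

    # Deterministic low-frequency texture inside the brain, shared by all
    # modalities. Real tissue contrast is what makes rigid registration
    # well-posed; without it a sphere is rotationally ambiguous. The x term
    # is even so the phantom stays bilaterally symmetric (like a brain), and
    # the hippocampal ROIs are excluded so ROI means stay analytically
    # predictable.
    texture = 1.0 + spec.texture_amplitude * (
        np.cos(world[0] / 6.5) + np.sin(world[1] / 8.0 + 1.0) + np.sin(world[2] / 9.5 + 2.0)
    ) / 3.0
    in_roi = masks["right"] | masks["left"]
    texture = np.where(brain & ~in_roi, texture, 1.0)

    t1 = VolumeGrid(template("t1", (1.0, 1.0)) * texture, affine)
    flair_tpl = VolumeGrid(template("flair", spec.flair_boost) * texture, affine)
    pet_tpl = VolumeGrid(template("pet", spec.pet_drop) * texture, affine)

    rng = np.random.default_rng(spec.seed)
    offset = RigidTransform(
        np.asarray(spec.rigid_offset[:3], dtype=float),
        np.asarray(spec.rigid_offset[3:], dtype=float),
        center=ref.world_center(),
    )
    bias = _bias_field(spec, brain, rng)

    def degrade(tpl: VolumeGrid) -> VolumeGrid:
        data = tpl.data
        if np.any(np.asarray(spec.rigid_offset) != 0):
            data = reslice(tpl, offset, ref, "trilinear").data
        data = data * bias
        if spec.noise_sd > 0:
            data = data + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        return VolumeGrid(data, affine)

    flair = degrade(flair_tpl)
    pet = degrade(pet_tpl)

    truth = {
        "transform_to_t1": offset.inverse(),
        "applied_offset": offset,
        "bias_field": VolumeGrid(bias, affine),
        "roi_volumes_mm3": roi_volumes,
        "roi_voxels": roi_voxels,
        "spec": spec,
    }
    return t1, flair, pet, labels, truth


# ---------------------------------------------------------------------------
# measurement cohorts


def _default_cov(sd: float, corr: float = 0.5) -> np.ndarray:
    return np.array([[sd**2, corr * sd**2], [corr * sd**2, sd**2]])


@dataclass
class CohortSpec:
    """Bivariate-normal control clouds plus displaced patients.

    ``control_mean``/``control_cov`` are per-modality (right, left) means and
    2x2 covariances; ``effect`` is the displacement of the pathological side
    in units of that side's control SD, applied along each modality's
    clinical direction. Defaults mirror the study cohort sizes (54 patients,
    22 controls, two thirds left-sided) with effects graded so that volume
    separates well, FLAIR poorly, and SUVR best.
    """

    n_controls: int = 22
    n_patients: int = 54
    control_mean: dict = field(
        default_factory=lambda: {
            "volume": (0.0040, 0.0040),
            "flair": (1.30, 1.30),
            "suvr": (1.05, 1.05),
        }
    )
    control_cov: dict = field(
        default_factory=lambda: {
            "volume": _default_cov(0.00035),
            "flair": _default_cov(0.06),
            "suvr": _default_cov(0.05),
        }
    )
    effect: dict = field(
        default_factory=lambda: {"volume": 4.0, "flair": 1.0, "suvr": 5.0}
    )
    side_assignment: float = 36.0 / 54.0  # fraction of patients with left-sided HS
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 3:
            raise ValueError("need at least 3 controls")
        for mod, cov in self.control_cov.items():
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise ValueError(f"{mod}: covariance must be symmetric 2x2")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise ValueError(f"{mod}: covariance not positive definite") from None


MODALITIES = ("volume", "flair", "suvr")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a measurement table of controls and lateralized patients.

    Columns: ``subject_id, group, true_side`` plus ``<modality>_right`` /
    ``<modality>_left`` for volume, flair and suvr. Controls have
    ``true_side = "none"``. Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_controls):
        row = {"subject_id": f"C{i+1:03d}", "group": "control", "true_side": "none"}
        for mod in MODALITIES:
            r, l = rng.multivariate_normal(spec.control_mean[mod], spec.control_cov[mod])
            row[f"{mod}_right"], row[f"{mod}_left"] = r, l
        rows.append(row)
    sides = np.where(rng.random(spec.n_patients) < spec.side_assignment, "left", "right")
    for i in range(spec.n_patients):
        side = sides[i]
        row = {"subject_id": f"P{i+1:03d}", "group": "patient", "true_side": side}
        for mod in MODALITIES:
            v = rng.multivariate_normal(spec.control_mean[mod], spec.control_cov[mod])
            k = 0 if side == "right" else 1  # index into (right, left)
            sd = np.sqrt(np.asarray(spec.control_cov[mod])[k, k])
            shift = spec.effect.get(mod, 0.0) * sd
            v[k] += shift if PATHOLOGICAL_DIRECTION[mod] == "high" else -shift
            row[f"{mod}_right"], row[f"{mod}_left"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged clinical fixture


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged 54-patient clinical outcome table.

    Per-method columns (``cva_mri, cva_pet, q_volume, q_flair, q_pet``) hold
    classification codes: ``p`` detected with correct lateralization, ``w``
    detected with wrong lateralization, ``n`` not detected. ``hs_type`` is
    the ILAE histopathological subtype (1-3); ``resection_side`` is the
    ground-truth side; ``follow_up_months`` is post-surgical follow-up.
    """
    path = resources.files("hsquant.data").joinpath("table1.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    df["group"] = "patient"
    df["true_side"] = df["resection_side"].map({"L": "left", "R": "right"})
    return df
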