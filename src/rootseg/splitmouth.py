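"""Split-mouth analysis: mirror, rigid registration, tooth movement, resorption.

The contralateral (control) hemi-jaw is mirrored across the mid-sagittal
plane, rigidly registered to the test side on bone, and the residual rigid
motion of the tooth itself — recovered by a second, tooth-masked
registration — quantifies orthodontic tooth movement (OTM).  Root
resorption (RR) is the per-root volume difference between control and test
(absolute, μm³) and its fraction of the control volume (relative, %).

Registration minimises the mean squared intensity difference restricted to
the reference structure's mask (multi-resolution, gradient descent,
moments-of-mask initialisation); same-modality μCT pairs make this metric
well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import RegistrationError, StatsError
from .morphometry import RootMorphometry, ToothFrame
from .volume_io import LabelMap, MOLAR_ROLES, ROOT_ROLES, Volume3D

# full-sampling metric + a single thread make registration bit-reproducible
sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)


@dataclass
class RigidMotion:
    """Proper rotation + translation in mm, mapping fixed-space points to
    moving-space points: ``p_moving = rotation @ p_fixed + translation``.

    ``reflection_applied`` records whether a mirror operation preceded the
    rigid part (the mirror itself is kept as a separate operator)."""

    rotation: np.ndarray
    translation: np.ndarray
    reflection_applied: bool = False

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or not np.allclose(
            self.rotation @ self.rotation.T, np.eye(3), atol=1e-6
        ):
            raise RegistrationError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(self.rotation) < 0:
            raise RegistrationError("rotation must be proper (det +1); use mirror() for reflections")
        if not np.all(np.isfinite(self.translation)):
            raise RegistrationError("translation must be finite")

    @classmethod
    def identity(cls) -> "RigidMotion":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points_mm).ndim == 1 else out

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def mirror(obj: Volume3D | LabelMap, axis: int = 1):
    """Reflect a volume or label map across a mid-grid plane (default: the
    mid-sagittal plane, axis 1).  Mirroring twice is the identity; the
    returned object carries ``reflection_applied = True``."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    if isinstance(obj, LabelMap):
        out = LabelMap(np.ascontiguousarray(np.flip(obj.labels, axis=axis)), dict(obj.legend), obj.voxel_size)
    else:
        out = Volume3D(np.ascontiguousarray(np.flip(obj.data, axis=axis)), obj.voxel_size)
    out.reflection_applied = not getattr(obj, "reflection_applied", False)
    return out


# ---------------------------------------------------------------------------
# SimpleITK plumbing
# ---------------------------------------------------------------------------


def _to_sitk(data: np.ndarray, voxel_mm: float) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing((voxel_mm,) * 3)
    return img


def _role_mask(lab: LabelMap, reference_role: str) -> np.ndarray:
    roles = tuple(MOLAR_ROLES) if reference_role == "molar" else (reference_role,)
    return lab.mask_for_role(*roles)


def register_rigid(
    moving: tuple[Volume3D, LabelMap],
    fixed: tuple[Volume3D, LabelMap],
    reference_role: str = "bone",
    shrink_factors=(4, 2),
    smoothing_sigmas=(2.0, 1.0),
    max_iterations: int = 200,
    learning_rate: float = 0.05,
) -> tuple[RigidMotion, float]:
    """Rigidly register ``moving`` to ``fixed`` on the reference structure.

    Returns the motion (fixed→moving point map, mm) and the final masked
    mean-squared-difference residual.  Initialisation translates the moving
    reference-mask centroid onto the fixed one (moments of the masks).
    """
    mov_vol, mov_lab = moving
    fix_vol, fix_lab = fixed
    v_mm = fix_vol.voxel_size * 1e-3
    fix_mask = _role_mask(fix_lab, reference_role)
    mov_mask = _role_mask(mov_lab, reference_role)
    if not fix_mask.any() or not mov_mask.any():
        raise RegistrationError(f"reference role {reference_role!r} has an empty mask")

    if reference_role == "bone":
        # bone near the (possibly moved) tooth is remodelled and differs
        # between the sides; keep only bone clear of either molar so the
        # reference is the shared, unchanged skeleton
        excl = fix_lab.mask_for_role(*MOLAR_ROLES) | mov_lab.mask_for_role(*MOLAR_ROLES)
        metric_mask = fix_mask & ~ndimage.binary_dilation(excl, iterations=16)
        if not metric_mask.any():
            metric_mask = fix_mask
    else:
        metric_mask = ndimage.binary_dilation(fix_mask, iterations=2)

    f_img = _to_sitk(np.asarray(fix_vol.data, np.float32), v_mm)
    m_img = _to_sitk(np.asarray(mov_vol.data, np.float32), v_mm)
    mask_img = _to_sitk(metric_mask.astype(np.uint8), v_mm)

    c_fix = np.argwhere(fix_mask).mean(axis=0) * v_mm
    c_mov = np.argwhere(mov_mask).mean(axis=0) * v_mm
    initial = sitk.Euler3DTransform()
    initial.SetCenter(tuple(c_fix))
    initial.SetTranslation(tuple(c_mov - c_fix))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricFixedMask(mask_img)
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=learning_rate,
        minStep=1e-6,
        numberOfIterations=max_iterations,
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        final = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise RegistrationError(f"registration failed: {exc}") from exc
    residual = float(reg.GetMetricValue())

    tx = final.Downcast()
    if isinstance(tx, sitk.CompositeTransform):
        tx = tx.GetNthTransform(0).Downcast()
    tx = sitk.Euler3DTransform(tx)
    R = np.array(tx.GetMatrix()).reshape(3, 3)
    C = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    t_eff = C + t - R @ C
    return RigidMotion(rotation=R, translation=t_eff), residual


def resample_through(
    moving: tuple[Volume3D, LabelMap], fixed: tuple[Volume3D, LabelMap], motion: RigidMotion
) -> tuple[Volume3D, LabelMap]:
    """Resample ``moving`` onto the fixed grid through ``motion``.

    Intensities are interpolated trilinearly, labels nearest-neighbour."""
    mov_vol, mov_lab = moving
    fix_vol, _ = fixed
    v_mm = fix_vol.voxel_size * 1e-3
    tx = sitk.AffineTransform(3)
    tx.SetMatrix(tuple(motion.rotation.ravel()))
    tx.SetTranslation(tuple(motion.translation))
    f_img = _to_sitk(np.asarray(fix_vol.data, np.float32), v_mm)
    m_img = _to_sitk(np.asarray(mov_vol.data, np.float32), v_mm)
    l_img = _to_sitk(np.asarray(mov_lab.labels, np.int32), v_mm)
    out_v = sitk.Resample(m_img, f_img, tx, sitk.sitkLinear, 0.0)
    out_l = sitk.Resample(l_img, f_img, tx, sitk.sitkNearestNeighbor, 0)
    vol = Volume3D(sitk.GetArrayFromImage(out_v).transpose(2, 1, 0), fix_vol.voxel_size)
    lab = LabelMap(
        sitk.GetArrayFromImage(out_l).transpose(2, 1, 0).astype(np.int32), dict(mov_lab.legend), fix_vol.voxel_size
    )
    return vol, lab


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class SplitMouthResult:
    """OTM translation components (mm) and per-root resorption."""

    otm: dict = field(default_factory=dict)  # mesial / palatal / intrusion, mm
    rr_abs: dict = field(default_factory=dict)  # per root, μm³ (control − test)
    rr_rel: dict = field(default_factory=dict)  # per root, % of control
    tipping_deg: float | None = None
    registration_residuals: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "otm_mesial_mm": self.otm.get("mesial"),
            "otm_palatal_mm": self.otm.get("palatal"),
            "otm_intrusion_mm": self.otm.get("intrusion"),
            "rr_abs_um3": dict(self.rr_abs),
            "rr_rel_pct": dict(self.rr_rel),
            "tipping_deg": self.tipping_deg,
            "registration_residuals": dict(self.registration_residuals),
        }

    def to_records(self) -> list[dict]:
        rows = [
            {"quantity": f"otm_{k}", "value": v, "unit": "mm"} for k, v in self.otm.items()
        ]
        for root in self.rr_abs:
            rows.append({"quantity": f"rr_abs_{root}", "value": self.rr_abs[root], "unit": "um3"})
            rows.append({"quantity": f"rr_rel_{root}", "value": self.rr_rel[root], "unit": "%"})
        if self.tipping_deg is not None:
            rows.append({"quantity": "tipping", "value": self.tipping_deg, "unit": "deg"})
        return rows


def compute_otm(
    test: tuple[Volume3D, LabelMap],
    control: tuple[Volume3D, LabelMap],
    frame: ToothFrame,
    mirror_axis: int = 1,
) -> SplitMouthResult:
    """Quantify tooth movement using the mirrored contralateral side.

    Pipeline: mirror(control) → rigid registration on bone → residual
    tooth-masked rigid registration → translation of the test molar centroid
    relative to the aligned control tooth, projected onto the anatomical
    axes of ``frame`` (fitted on the mirrored control).  Components are
    signed: positive mesial / palatal / intrusion mean movement towards
    mesial, towards the palate and into the socket, respectively.  The
    residual rotation (tipping) is reported separately, not folded into the
    translation components.
    """
    mc = (mirror(control[0], mirror_axis), mirror(control[1], mirror_axis))
    bone_motion, res_bone = register_rigid(mc, test, reference_role="bone")
    aligned = resample_through(mc, test, bone_motion)
    tooth_motion, res_tooth = register_rigid(aligned, test, reference_role="molar")

    molar = test[1].molar_mask()
    if not molar.any():
        raise RegistrationError("test side has no molar label")
    centroid_mm = np.argwhere(molar).mean(axis=0) * test[0].voxel_size * 1e-3
    d = centroid_mm - tooth_motion.apply(centroid_mm)  # test − aligned control, mm
    otm = {
        "mesial": float(np.dot(d, frame.mesial_dir)),
        "palatal": float(np.dot(d, frame.palatal_dir)),
        "intrusion": float(-np.dot(d, frame.occlusal_dir)),
    }
    return SplitMouthResult(
        otm=otm,
        tipping_deg=tooth_motion.rotation_angle_deg(),
        registration_residuals={"bone": res_bone, "molar": res_tooth},
    )


def compute_rr(test_morph: RootMorphometry, control_morph: RootMorphometry) -> SplitMouthResult:
    """Per-root absolute (control − test, μm³) and relative (%) resorption."""
    rr_abs, rr_rel = {}, {}
    for role in (*ROOT_ROLES, "whole_tooth"):
        if role not in test_morph.volumes or role not in control_morph.volumes:
            continue
        c = control_morph.volumes[role]
        t = test_morph.volumes[role]
        if c <= 0:
            raise StatsError(f"control volume for {role} is zero")
        rr_abs[role] = float(c - t)
        rr_rel[role] = float(100.0 * (c - t) / c)
    if not rr_abs:
        raise StatsError("no common root volumes between test and control")
    return SplitMouthResult(rr_abs=rr_abs, rr_rel=rr_rel)
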