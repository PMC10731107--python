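"""Rigid serial-scan registration.

Postflight and follow-up volumes are registered to the preflight volume of
the same subject with a 6-DOF rigid transform (same scanner, same modality,
so a mean-squared-intensity metric with multi-resolution regular-step
gradient descent is used).  Masks are always drawn on the preflight grid
and mapped *forward* into each session with the inverse of the recovered
session transform using nearest-neighbour interpolation, so labels stay
categorical.

Conventions
-----------
A :class:`RigidTransform` maps points in the fixed (preflight) world space
to points in the moving (session) world space:  ``x_moving = R (x - c) + c
+ t`` with rotation centre ``c``.  Angles are reported as intrinsic Z-Y-X
Euler angles in degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import RegistrationError, ValidationError
from .volume import CTVolume, from_sitk, to_sitk

__all__ = [
    "RigidTransform",
    "RegistrationOptions",
    "RegistrationResult",
    "register_rigid",
    "resample",
    "map_mask_to_session",
]


def _rot_zyx(angles_deg) -> np.ndarray:
    """Rotation matrix for intrinsic Z-Y-X Euler angles (degrees): Rz @ Ry @ Rx."""
    rx, ry, rz = np.radians(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _angles_zyx_deg(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`_rot_zyx` (gimbal-safe for |ry| < 90 deg)."""
    ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    cy = np.cos(ry)
    if abs(cy) > 1e-8:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # degenerate: pitch at +-90
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    return tuple(np.degrees([rx, ry, rz]))


@dataclass
class RigidTransform:
    """6-DOF rotation + translation, fixed-space -> moving-space."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    fixed_space_id: str = "fixed"
    moving_space_id: str = "moving"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.allclose(self.matrix @ self.matrix.T, np.eye(3), atol=1e-6):
            raise ValidationError("RigidTransform.matrix: not orthonormal")
        if np.linalg.det(self.matrix) < 0:
            raise ValidationError("RigidTransform.matrix: determinant must be +1")

    @classmethod
    def from_angles(
        cls,
        angles_deg,
        translation,
        center=(0.0, 0.0, 0.0),
        fixed_space_id: str = "fixed",
        moving_space_id: str = "moving",
    ) -> "RigidTransform":
        return cls(_rot_zyx(angles_deg), np.asarray(translation, float),
                   np.asarray(center, float), fixed_space_id, moving_space_id)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def angles_zyx_deg(self) -> tuple[float, float, float]:
        """Intrinsic Z-Y-X Euler angles, degrees, returned as (rx, ry, rz)."""
        return _angles_zyx_deg(self.matrix)

    @property
    def effective_translation(self) -> np.ndarray:
        """Translation of the equivalent centre-at-origin map x -> R x + t_eff."""
        return self.center + self.translation - self.matrix @ self.center

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array of world points."""
        p = np.atleast_2d(np.asarray(points, float))
        return (p - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            self.matrix.T,
            -self.matrix.T @ self.translation,
            self.center,
            fixed_space_id=self.moving_space_id,
            moving_space_id=self.fixed_space_id,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply *other* first, then *self* (centres folded in)."""
        R = self.matrix @ other.matrix
        t_eff = self.matrix @ other.effective_translation + self.effective_translation
        return RigidTransform(R, t_eff, np.zeros(3),
                              other.fixed_space_id, self.moving_space_id)

    def as_sitk(self) -> sitk.Euler3DTransform:
        tf = sitk.Euler3DTransform()
        tf.SetCenter(tuple(self.center))
        tf.SetMatrix(tuple(self.matrix.ravel()))
        tf.SetTranslation(tuple(self.translation))
        return tf

    def to_dict(self) -> dict:
        return {
            "convention": "intrinsic-ZYX-degrees, x_moving = R (x - c) + c + t",
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
            "angles_zyx_deg": list(self.angles_zyx_deg),
            "fixed_space_id": self.fixed_space_id,
            "moving_space_id": self.moving_space_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["matrix"]), np.array(d["translation"]),
                   np.array(d["center"]), d.get("fixed_space_id", "fixed"),
                   d.get("moving_space_id", "moving"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class RegistrationOptions:
    """Knobs of the mono-modal rigid registration.

    Defaults are the standard serial-CT choices: mean-squared intensity
    metric, 3-level pyramid, regular-step gradient descent initialised at
    the intensity centre of mass.
    """

    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas_mm: tuple[float, ...] = (2.0, 1.0, 0.0)
    sampling_fraction: float = 0.5
    sampling_seed: int = 12345
    learning_rate: float = 1.0
    min_step: float = 2e-5
    max_iterations: int = 300
    relaxation_factor: float = 0.6
    initializer: str = "moments"  # "moments" (centre of mass) or "geometry"


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_metric: float
    converged: bool
    iterations: int
    stop_description: str


def _check_overlap(moving: CTVolume, fixed: CTVolume) -> None:
    for vol, name in ((moving, "moving"), (fixed, "fixed")):
        if vol.data.size < 1000:
            raise RegistrationError(f"{name} volume has {vol.data.size} voxels (< 1000)")
    lo_m = np.asarray(moving.origin)
    hi_m = lo_m + (np.asarray(moving.shape) - 1) * np.asarray(moving.spacing)
    lo_f = np.asarray(fixed.origin)
    hi_f = lo_f + (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing)
    if np.any(hi_m < lo_f) or np.any(hi_f < lo_m):
        raise RegistrationError("moving and fixed volumes do not overlap in world space")


def register_rigid(
    moving: CTVolume,
    fixed: CTVolume,
    options: RegistrationOptions | None = None,
    fixed_mask: CTVolume | None = None,
) -> RegistrationResult:
    """Recover the rigid transform mapping *fixed*-space points into *moving* space.

    Resampling *moving* through the returned transform aligns it with
    *fixed*.  ``fixed_mask`` optionally restricts the similarity metric to a
    region of the fixed image (e.g. excluding tissue that genuinely changes
    between sessions).  Non-convergence within the iteration budget is
    reported via ``converged=False``, never silently.
    """
    opts = options or RegistrationOptions()
    _check_overlap(moving, fixed)

    f_img = to_sitk(fixed.like(fixed.data.astype(np.float64)))
    m_img = to_sitk(moving.like(moving.data.astype(np.float64)))

    init_mode = {
        "moments": sitk.CenteredTransformInitializerFilter.MOMENTS,
        "geometry": sitk.CenteredTransformInitializerFilter.GEOMETRY,
    }[opts.initializer]
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(), init_mode
    )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    if fixed_mask is not None:
        mask_img = to_sitk(fixed_mask.like(fixed_mask.data.astype(np.uint8)))
        reg.SetMetricFixedMask(mask_img)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(opts.sampling_fraction, opts.sampling_seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=opts.learning_rate,
        minStep=opts.min_step,
        numberOfIterations=opts.max_iterations,
        relaxationFactor=opts.relaxation_factor,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(opts.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(opts.smoothing_sigmas_mm))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=True)

    out = reg.Execute(f_img, m_img)
    euler = sitk.Euler3DTransform(out)
    transform = RigidTransform(
        np.array(euler.GetMatrix()).reshape(3, 3),
        np.array(euler.GetTranslation()),
        np.array(euler.GetCenter()),
        fixed_space_id="fixed",
        moving_space_id="moving",
    )
    stop = reg.GetOptimizerStopConditionDescription()
    converged = reg.GetOptimizerIteration() < opts.max_iterations
    return RegistrationResult(
        transform=transform,
        final_metric=float(reg.GetMetricValue()),
        converged=converged,
        iterations=int(reg.GetOptimizerIteration()),
        stop_description=stop,
    )


def resample(
    volume_or_mask: CTVolume,
    transform: RigidTransform,
    target_grid: CTVolume,
    interpolation: str,
) -> CTVolume:
    """Resample onto ``target_grid`` through ``transform``.

    ``transform`` maps target-grid world points into the input volume's
    world space (the SimpleITK resampling convention).  Intensity volumes
    use trilinear interpolation; label masks must use nearest-neighbour —
    resampling an integer mask with ``"linear"`` is an error because
    interpolated labels are meaningless.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValidationError(f"interpolation: must be 'linear' or 'nearest', got {interpolation!r}")
    if interpolation == "linear" and volume_or_mask.is_label:
        raise ValidationError(
            "interpolation: label masks must be resampled with 'nearest', not 'linear'"
        )
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    in_dtype = volume_or_mask.data.dtype
    img = to_sitk(volume_or_mask)
    ref = to_sitk(target_grid)
    out = sitk.Resample(img, ref, transform.as_sitk(), interp, 0.0, img.GetPixelID())
    result = from_sitk(out)
    result.data = result.data.astype(in_dtype, copy=False)
    return result


def map_mask_to_session(
    mask_on_preflight: CTVolume,
    preflight_to_session: RigidTransform,
    session_grid: CTVolume,
) -> CTVolume:
    """Map a preflight-defined mask forward into a session's grid.

    The resampler needs the session->preflight point map, i.e. the inverse
    of the registration result.
    """
    return resample(
        mask_on_preflight,
        preflight_to_session.inverse(),
        session_grid,
        interpolation="nearest",
    )
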