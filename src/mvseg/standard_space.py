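"""Head-and-neck template space and two-step affine/rigid registration.

The template is built by voxel-wise *non-zero* averaging of a stack of
co-registered T1-weighted volumes, keeping only voxels present (non-zero) in at
least a configurable fraction (default 30%) of the contributing images.  Cases
enter the template space through a two-step scheme: a full affine registration
first, then a rigid registration initialized with the rigid component of the
affine and weighted by the template occupancy mask so that background voxels do
not drive the metric.  Other sequences of the same subject are registered to
their own T1 by the same scheme and the transforms are concatenated.

All transforms are expressed as 4x4 homogeneous matrices in world millimetres,
mapping moving-space points to fixed-space points.  Conversion to voxel indices
happens only at the resampling boundary.

Registration and resampling are performed with SimpleITK (negative normalized
correlation for same-contrast pairs, Mattes mutual information across
sequences, 3-level multiresolution pyramid).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence as Seq

import numpy as np
import SimpleITK as sitk

from mvseg.volume_io import LabelMask, MultiSequenceCase, Sequence, Volume

sitk.ProcessObject.GlobalWarningDisplayOff()


class Dof(enum.Enum):
    RIGID = "rigid"
    AFFINE = "affine"


class Interp(enum.Enum):
    SPLINE = "spline"
    LINEAR = "linear"
    NEAREST = "nearest"


_SITK_INTERP = {
    Interp.SPLINE: sitk.sitkBSpline,
    Interp.LINEAR: sitk.sitkLinear,
    Interp.NEAREST: sitk.sitkNearestNeighbor,
}


@dataclass(frozen=True)
class AffineTransform:
    """4x4 homogeneous world-mm transform, moving -> fixed."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(m[3], (0, 0, 0, 1), atol=1e-9):
            raise ValueError("bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("transform must be invertible")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rigid(
        cls,
        translation_mm: Seq[float] = (0.0, 0.0, 0.0),
        rotation_deg: Seq[float] = (0.0, 0.0, 0.0),
        center_mm: Seq[float] = (0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """Rigid motion from Euler angles (deg, applied as Rz·Ry·Rx about
        ``center_mm``) and a translation."""
        rx, ry, rz = np.deg2rad(rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        R = Rz @ Ry @ Rx
        c = np.asarray(center_mm, dtype=float)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(translation_mm, dtype=float) + c - R @ c
        return cls(m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points through the transform."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def rigid_parameters(self) -> tuple[np.ndarray, np.ndarray]:
        """(translation_mm, rotation_deg) of the rigid part, Euler zyx order."""
        R = rigid_component(self).matrix[:3, :3]
        ry = -np.arcsin(np.clip(R[2, 0], -1, 1))
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        return self.translation.copy(), np.rad2deg([rx, ry, rz])


@dataclass
class TemplateSpace:
    """The head-and-neck standard space: template volume + occupancy mask."""

    template: Volume
    occupancy_mask: LabelMask
    occupancy_threshold: float = 0.30

    def __post_init__(self) -> None:
        if not self.template.same_grid(self.occupancy_mask):
            raise ValueError("template and occupancy mask must share a grid")
        if np.any(self.template.data[self.occupancy_mask.data == 0] != 0):
            raise ValueError("template must be zero outside the occupancy mask")


@dataclass
class CaseTransforms:
    """Registration result for one case: T1 -> standard plus per-sequence
    intra-subject transforms (each sequence -> native T1)."""

    t1_to_std: AffineTransform
    stir_to_t1: AffineTransform
    t1gad_to_t1: Optional[AffineTransform] = None

    def to_std(self, seq: Sequence) -> AffineTransform:
        """Concatenated transform taking the given sequence to standard space."""
        if seq == Sequence.T1:
            return self.t1_to_std
        if seq == Sequence.STIR:
            return compose(self.t1_to_std, self.stir_to_t1)
        if seq == Sequence.T1GAD:
            if self.t1gad_to_t1 is None:
                raise ValueError("case has no T1gad transform")
            return compose(self.t1_to_std, self.t1gad_to_t1)
        raise ValueError(f"unknown sequence {seq}")


class RegistrationError(RuntimeError):
    """Raised when the optimizer fails; carries the last transform and metric."""

    def __init__(self, message: str, last_transform: Optional[AffineTransform], metric: float):
        super().__init__(message)
        self.last_transform = last_transform
        self.metric = metric


# ---------------------------------------------------------------------------
# template construction


def build_template(t1_stack: Seq[Volume], threshold: float = 0.30) -> TemplateSpace:
    """Average a stack of co-registered T1 volumes into a template.

    Per voxel, occupancy is the fraction of volumes with a non-zero value
    there; voxels with occupancy >= ``threshold`` enter the occupancy mask and
    get the mean over their *non-zero* contributors, all others are zero.
    """
    if len(t1_stack) < 2:
        raise ValueError("need at least 2 volumes to build a template")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    first = t1_stack[0]
    for v in t1_stack[1:]:
        if not first.same_grid(v):
            raise ValueError("all stack volumes must share a grid")
    stack = np.stack([v.data for v in t1_stack]).astype(np.float64)
    nonzero = stack != 0
    count = nonzero.sum(axis=0)
    occupancy = count / len(t1_stack)
    mask = (occupancy >= threshold).astype(np.uint8)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nonzero = np.where(count > 0, stack.sum(axis=0) / np.maximum(count, 1), 0.0)
    template = np.where(mask == 1, mean_nonzero, 0.0)
    return TemplateSpace(
        template=Volume(template, first.affine.copy(), Sequence.T1),
        occupancy_mask=LabelMask(mask, first.affine.copy()),
        occupancy_threshold=threshold,
    )


# ---------------------------------------------------------------------------
# SimpleITK bridging

def _decompose_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a voxel->world affine into (origin, spacing, direction)."""
    A = affine[:3, :3]
    spacing = np.linalg.norm(A, axis=0)
    direction = A / spacing
    return affine[:3, 3].copy(), spacing, direction


def _to_sitk(v: Volume, dtype=np.float32) -> sitk.Image:
    # sitk array order is (z, y, x); our arrays are (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0).astype(dtype)))
    origin, spacing, direction = _decompose_affine(v.affine)
    img.SetOrigin(tuple(origin))
    img.SetSpacing(tuple(spacing))
    img.SetDirection(tuple(direction.ravel()))
    return img


def _sitk_transform_to_matrix(t: sitk.Transform) -> np.ndarray:
    """4x4 matrix of a (possibly composite) sitk transform, fixed -> moving."""
    t = sitk.CompositeTransform(t) if not isinstance(t, sitk.CompositeTransform) else t
    m = np.eye(4)
    for i in range(t.GetNumberOfTransforms()):
        sub = t.GetNthTransform(i)
        A = np.asarray(sub.GetMatrix()).reshape(3, 3)
        c = np.asarray(sub.GetCenter())
        tr = np.asarray(sub.GetTranslation())
        sm = np.eye(4)
        sm[:3, :3] = A
        sm[:3, 3] = tr + c - A @ c
        m = sm @ m
    return m


def _matrix_to_sitk_affine(matrix: np.ndarray) -> sitk.AffineTransform:
    t = sitk.AffineTransform(3)
    t.SetMatrix(tuple(matrix[:3, :3].ravel()))
    t.SetTranslation(tuple(matrix[:3, 3]))
    return t


# ---------------------------------------------------------------------------
# transform algebra


def compose(a: AffineTransform, b: AffineTransform) -> AffineTransform:
    """Transform equivalent to applying ``b`` first, then ``a``."""
    return AffineTransform(a.matrix @ b.matrix)


def rigid_component(a: AffineTransform) -> AffineTransform:
    """Rotation + translation factor of an affine transform.

    The 3x3 block is replaced by the orthogonal factor of its polar
    decomposition (scale and shear removed); the translation is kept.
    Reflections are rejected: they are not rigid motions.
    """
    A = a.matrix[:3, :3]
    if np.linalg.det(A) <= 0:
        raise ValueError("3x3 block has non-positive determinant (reflection/degenerate)")
    U, _, Vt = np.linalg.svd(A)
    R = U @ Vt
    if np.linalg.det(R) < 0:  # unreachable for det(A) > 0, kept as guard
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = a.matrix[:3, 3]
    return AffineTransform(m)


# ---------------------------------------------------------------------------
# registration and resampling


def register_affine(
    moving: Volume,
    fixed: Volume,
    init: Optional[AffineTransform] = None,
    weight_mask: Optional[LabelMask] = None,
    dof: Dof = Dof.RIGID,
    cross_sequence: Optional[bool] = None,
    sampling_fraction: float = 0.25,
) -> AffineTransform:
    """Intensity-based registration of ``moving`` onto ``fixed``.

    Returns the world-mm moving->fixed transform with 6 (RIGID) or 12 (AFFINE)
    degrees of freedom.  The similarity metric is negative normalized
    correlation for same-contrast pairs and Mattes mutual information when the
    two volumes come from different sequences, optimized over a 3-level
    multiresolution pyramid.  When ``weight_mask`` is given, fixed-image voxels
    outside the mask carry zero weight in the metric.
    """
    for name, v in (("moving", moving), ("fixed", fixed)):
        if np.ptp(v.data) == 0:
            raise ValueError(f"{name} volume is constant; registration is undefined")
    if cross_sequence is None:
        cross_sequence = (
            moving.sequence != fixed.sequence
            and Sequence.OTHER not in (moving.sequence, fixed.sequence)
        )

    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    if dof == Dof.RIGID:
        tx = sitk.Euler3DTransform()
    else:
        tx = sitk.AffineTransform(3)
    if init is not None:
        # sitk transforms map fixed physical points into moving space
        inv = init.inverse().matrix
        if dof == Dof.RIGID:
            tx.SetMatrix(tuple(inv[:3, :3].ravel()), tolerance=1e-6)
            tx.SetTranslation(tuple(inv[:3, 3]))
        else:
            tx.SetMatrix(tuple(inv[:3, :3].ravel()))
            tx.SetTranslation(tuple(inv[:3, 3]))
    else:
        tx = sitk.CenteredTransformInitializer(
            f_img, m_img, tx, sitk.CenteredTransformInitializerFilter.GEOMETRY
        )

    reg = sitk.ImageRegistrationMethod()
    if cross_sequence:
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    else:
        reg.SetMetricAsCorrelation()
    # regular-grid subsampling keeps the optimization deterministic
    if sampling_fraction >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(sampling_fraction, 12345)
    if weight_mask is not None:
        reg.SetMetricFixedMask(_to_sitk(weight_mask, dtype=np.uint8))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0,
        minStep=1e-4,
        numberOfIterations=150,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(tx, inPlace=True)

    try:
        result = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # optimizer failure inside ITK
        raise RegistrationError(str(exc), None, float("nan")) from exc

    fixed_to_moving = _sitk_transform_to_matrix(result)
    out = AffineTransform(np.linalg.inv(fixed_to_moving))
    if not np.all(np.isfinite(out.matrix)):
        raise RegistrationError(
            f"optimizer diverged: {reg.GetOptimizerStopConditionDescription()}",
            out,
            reg.GetMetricValue(),
        )
    return out


def _target_grid(target) -> tuple[tuple[int, int, int], np.ndarray]:
    if isinstance(target, TemplateSpace):
        return target.template.shape, target.template.affine
    if isinstance(target, Volume):
        return target.shape, target.affine
    shape, affine = target
    return tuple(shape), np.asarray(affine, dtype=float)


def resample(v: Volume, t: AffineTransform, target, interp: Interp = Interp.LINEAR):
    """Resample ``v`` through moving->fixed transform ``t`` onto the target grid.

    ``target`` may be a :class:`Volume`, :class:`TemplateSpace` or a
    ``(shape, affine)`` pair.  Out-of-field voxels are set to 0.  Label masks
    must use NEAREST so the output stays binary.
    """
    is_mask = isinstance(v, LabelMask)
    if is_mask and interp != Interp.NEAREST:
        raise ValueError("label masks must be resampled with NEAREST interpolation")
    shape, affine = _target_grid(target)

    ref = sitk.Image(int(shape[0]), int(shape[1]), int(shape[2]), sitk.sitkFloat32)
    origin, spacing, direction = _decompose_affine(affine)
    ref.SetOrigin(tuple(origin))
    ref.SetSpacing(tuple(spacing))
    ref.SetDirection(tuple(direction.ravel()))

    sitk_tx = _matrix_to_sitk_affine(t.inverse().matrix)  # fixed -> moving
    img = _to_sitk(v, dtype=np.uint8 if is_mask else np.float32)
    out = sitk.Resample(img, ref, sitk_tx, _SITK_INTERP[interp], 0.0)
    arr = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    if is_mask:
        return LabelMask(arr.astype(np.uint8), affine.copy())
    return Volume(np.ascontiguousarray(arr), affine.copy(), v.sequence)


def _two_step(
    moving: Volume,
    fixed: Volume,
    weight_mask: Optional[LabelMask],
    cross_sequence: bool,
) -> AffineTransform:
    """Affine registration, then rigid registration initialized with its rigid
    component (weighted by the occupancy mask when given)."""
    step1 = register_affine(moving, fixed, dof=Dof.AFFINE, cross_sequence=cross_sequence)
    return register_affine(
        moving,
        fixed,
        init=rigid_component(step1),
        weight_mask=weight_mask,
        dof=Dof.RIGID,
        cross_sequence=cross_sequence,
    )


def case_to_standard(
    case: MultiSequenceCase, tpl: TemplateSpace
) -> tuple[MultiSequenceCase, CaseTransforms]:
    """Move a native case into the template space.

    T1 is registered to the template by the two-step scheme; STIR and the
    optional T1gad are registered to the native T1 the same way and their
    transforms concatenated with ``t1_to_std``.  Intensities travel with spline
    interpolation, the reference mask with nearest-neighbour.  An absent T1gad
    stays absent.
    """
    try:
        t1_to_std = _two_step(case.t1, tpl.template, tpl.occupancy_mask, cross_sequence=False)
        stir_to_t1 = _two_step(case.stir, case.t1, None, cross_sequence=True)
        t1gad_to_t1 = None
        if case.t1gad is not None:
            t1gad_to_t1 = _two_step(case.t1gad, case.t1, None, cross_sequence=True)
    except RegistrationError as exc:
        raise RegistrationError(f"case {case.case_id}: {exc}", exc.last_transform, exc.metric)

    ct = CaseTransforms(t1_to_std=t1_to_std, stir_to_t1=stir_to_t1, t1gad_to_t1=t1gad_to_t1)
    t1_std = resample(case.t1, t1_to_std, tpl, Interp.SPLINE)
    stir_std = resample(case.stir, ct.to_std(Sequence.STIR), tpl, Interp.SPLINE)
    t1gad_std = None
    if case.t1gad is not None:
        t1gad_std = resample(case.t1gad, ct.to_std(Sequence.T1GAD), tpl, Interp.SPLINE)
    ref_std = resample(case.reference, t1_to_std, tpl, Interp.NEAREST)
    std_case = MultiSequenceCase(
        case_id=case.case_id,
        t1=t1_std,
        stir=stir_std,
        t1gad=t1gad_std,
        reference=ref_std,
        location=case.location,
        t_stage=case.t_stage,
        n_stage=case.n_stage,
    )
    return std_case, ct


def mask_to_native(m: LabelMask, ct: CaseTransforms, native_grid) -> LabelMask:
    """Map a standard-space mask back onto the native T1 grid (inverse of the
    T1->standard transform, nearest-neighbour)."""
    return resample(m, ct.t1_to_std.inverse(), native_grid, Interp.NEAREST)
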