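"""Histology-to-autoradiography coregistration and serial-section stacking.

The same physical sections are imaged twice — on the alpha camera and, after
staining, on a slide scanner — so a rigid mapping between the two modalities
exists by construction. Three sections per slide keep their relative positions
fixed between the two imaging rounds, which lets the whole slide be registered
as one rigid body: the extra sections act as geometric constraints that resolve
rotation ambiguities of individually near-symmetric sections.

For 3D reconstruction, adjacent sections are registered to the middle
(reference) section. Two stacking strategies are provided:

* ``activity_only`` — transforms fitted on the activity maps (rigid Euler then
  similarity), then applied to the anatomy images for evaluation;
* ``anatomy_guided`` — the same initial stages fitted on the anatomy images,
  plus a free-form B-spline refinement with a coarse-to-fine grid schedule.

The two are compared via the Dice similarity coefficient (DSC) of adjacent
anatomical masks after registration, with a paired t-test across tumor sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import stats

__all__ = [
    "RigidTransform2D",
    "Section",
    "SlideGroup",
    "SectionStack",
    "StackingComparison",
    "landmark_rigid_fit",
    "register_histology_to_autoradiography",
    "stack_sections",
    "dice",
    "compare_stacking",
]


@dataclass
class RigidTransform2D:
    """Rotation + translation (no scaling), mapping fixed-image points to moving-image points."""

    rotation: float  # radians
    translation: tuple[float, float]  # micrometres
    center: tuple[float, float] = (0.0, 0.0)
    residual_rms: float | None = None

    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        ctr = np.asarray(self.center)
        return (points - ctr) @ self.matrix().T + ctr + np.asarray(self.translation)

    def to_sitk(self) -> sitk.Euler2DTransform:
        tf = sitk.Euler2DTransform()
        tf.SetCenter(self.center)
        tf.SetAngle(self.rotation)
        tf.SetTranslation(self.translation)
        return tf


def landmark_rigid_fit(fixed_points: np.ndarray, moving_points: np.ndarray) -> RigidTransform2D:
    """Closed-form least-squares rigid transform from >= 3 paired landmarks.

    Solves for rotation and translation (no scale) mapping the fixed points
    onto the moving points via SVD of the cross-covariance matrix. Collinear or
    insufficient points leave the rotation unconstrained and raise.
    """
    fixed_points = np.asarray(fixed_points, dtype=float)
    moving_points = np.asarray(moving_points, dtype=float)
    if fixed_points.shape != moving_points.shape or fixed_points.ndim != 2:
        raise ValueError("landmark sets must be equal-shaped (N, 2) arrays")
    if len(fixed_points) < 3:
        raise ValueError("at least 3 landmark pairs are required")
    mu_f = fixed_points.mean(axis=0)
    mu_m = moving_points.mean(axis=0)
    a = fixed_points - mu_f
    b = moving_points - mu_m
    # collinearity check: centered points must span 2D
    sv_pts = np.linalg.svd(a, compute_uv=False)
    if sv_pts[-1] < 1e-9 * max(sv_pts[0], 1.0):
        raise ValueError("degenerate landmark configuration (collinear points)")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, d]) @ u.T
    angle = math.atan2(rot[1, 0], rot[0, 0])
    trans = mu_m - rot @ mu_f
    tf = RigidTransform2D(rotation=angle, translation=(float(trans[0]), float(trans[1])))
    resid = tf.apply(fixed_points) - moving_points
    tf.residual_rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return tf


@dataclass
class Section:
    """One tissue section imaged in both modalities.

    ``landmarks_*`` are paired reference points ((N, 2), micrometres) on the
    activity and anatomy images respectively; None if not annotated.
    """

    activity: np.ndarray
    anatomy: np.ndarray
    activity_spacing: float
    anatomy_spacing: float
    landmarks_activity: np.ndarray | None = None
    landmarks_anatomy: np.ndarray | None = None


@dataclass
class SlideGroup:
    """Sections sharing one microscope slide, registered as a single rigid body."""

    sections: list[Section]
    group_constraint: bool = True

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("slide group needs at least one section")
        if self.group_constraint and len(self.sections) < 3:
            raise ValueError("group-constrained registration requires >= 3 sections per slide")

    def composite(self, modality: str) -> tuple[np.ndarray, float]:
        """Concatenate section images left-to-right, preserving relative layout."""
        imgs = [getattr(s, modality) for s in self.sections]
        spacing = getattr(self.sections[0], f"{modality}_spacing")
        return np.hstack(imgs), spacing

    def pooled_landmarks(self) -> tuple[np.ndarray, np.ndarray]:
        fixed, moving = [], []
        x_off_act = 0.0
        x_off_ana = 0.0
        for s in self.sections:
            if s.landmarks_activity is not None:
                fixed.append(np.asarray(s.landmarks_activity) + [x_off_act, 0.0])
                moving.append(np.asarray(s.landmarks_anatomy) + [x_off_ana, 0.0])
            x_off_act += s.activity.shape[1] * s.activity_spacing
            x_off_ana += s.anatomy.shape[1] * s.anatomy_spacing
        if not fixed:
            raise ValueError("no landmarks annotated on this slide group")
        return np.vstack(fixed), np.vstack(moving)


def _to_sitk(arr: np.ndarray, spacing: float) -> sitk.Image:
    arr = np.asarray(arr, dtype=np.float32)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:  # intensity-normalize for histogram metrics
        arr = (arr - lo) / (hi - lo)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing((float(spacing), float(spacing)))
    return img


class _MetricTrace:
    def __init__(self, reg: sitk.ImageRegistrationMethod):
        self.values: list[float] = []
        reg.AddCommand(sitk.sitkIterationEvent, lambda: self.values.append(reg.GetMetricValue()))

    def converged(self, max_iterations: int | None = None, tail_frac: float = 0.1,
                  rel_tol: float = 1e-6) -> bool:
        """Plateau criterion: relative metric change < rel_tol over the trailing
        10% of iterations, or the optimizer stopped on its own step criterion."""
        v = np.asarray(self.values)
        if len(v) < 10:
            return True
        if max_iterations is not None and len(v) < max_iterations:
            return True  # optimizer hit its own convergence criterion early
        tail = v[-max(2, int(len(v) * tail_frac)) :]
        scale = max(float(np.abs(v).max()), 1e-12)
        return bool((tail.max() - tail.min()) / scale < rel_tol)


def _new_registration(
    iterations: int, learning_rate: float = 1.0, sampling: float | None = None
) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    if sampling is None:
        reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    else:
        # seeded random sampling: still reproducible, much faster on large images
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(sampling, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=learning_rate,
        minStep=1e-5,
        numberOfIterations=iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    return reg


def register_histology_to_autoradiography(
    group: SlideGroup,
    iterations: int = 1000,
) -> tuple[RigidTransform2D, dict]:
    """Register the stained-slide image onto the (warp-corrected) activity image.

    Landmark initialization (three points per slide, closed-form rigid fit)
    followed by an intensity-driven rigid Euler refinement under mutual
    information. No scaling stage exists: after warp correction the activity
    grid is physically calibrated, so scale adjustments are not permitted.
    Returns the slide-level rigid transform (fixed = activity frame, moving =
    anatomy frame) and a report with the metric trace and convergence flag.
    """
    fixed_arr, fixed_spacing = group.composite("activity")
    moving_arr, moving_spacing = group.composite("anatomy")
    fixed = _to_sitk(fixed_arr, fixed_spacing)
    moving = _to_sitk(moving_arr, moving_spacing)

    fixed_pts, moving_pts = group.pooled_landmarks()
    init = landmark_rigid_fit(fixed_pts, moving_pts)

    reg = _new_registration(iterations)
    trace = _MetricTrace(reg)
    reg.SetInitialTransform(init.to_sitk(), inPlace=False)
    out = reg.Execute(fixed, moving)
    euler = sitk.Euler2DTransform(sitk.CompositeTransform(out).GetNthTransform(0))
    result = RigidTransform2D(
        rotation=euler.GetAngle(),
        translation=tuple(euler.GetTranslation()),
        center=tuple(euler.GetCenter()),
    )
    report = {
        "metric_trace": trace.values,
        "final_metric": trace.values[-1] if trace.values else None,
        "converged": trace.converged(),
        "landmark_residual_rms_um": init.residual_rms,
        "n_sections": len(group.sections),
    }
    return result, report


@dataclass
class SectionStack:
    """Serial sections resampled into the reference (middle) section's frame."""

    z_positions: np.ndarray  # micrometres, strictly increasing
    transforms: list[sitk.Transform]
    activity: list[np.ndarray]  # resampled, reference frame
    anatomy: list[np.ndarray]
    activity_spacing: float
    anatomy_spacing: float
    method: str  # activity_only | anatomy_guided
    reports: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.z_positions) > 0):
            raise ValueError("z positions must be strictly increasing")


def _resample(moving: sitk.Image, reference: sitk.Image, tf: sitk.Transform, nearest=False):
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
    return sitk.GetArrayFromImage(sitk.Resample(moving, reference, tf, interp, 0.0))


def _check_folding(tf: sitk.Transform, reference: sitk.Image) -> float:
    disp = sitk.TransformToDisplacementField(
        tf,
        sitk.sitkVectorFloat64,
        reference.GetSize(),
        reference.GetOrigin(),
        reference.GetSpacing(),
        reference.GetDirection(),
    )
    jac = sitk.GetArrayFromImage(sitk.DisplacementFieldJacobianDeterminant(disp))
    return float(jac.min())


def _register_pair(
    fixed_arr: np.ndarray,
    moving_arr: np.ndarray,
    spacing: float,
    method: str,
    init: RigidTransform2D | None,
    rigid_iterations: int,
    similarity_iterations: int,
    bspline_iterations: int,
    bspline_grid_um: float,
) -> tuple[sitk.Transform, dict]:
    fixed = _to_sitk(fixed_arr, spacing)
    moving = _to_sitk(moving_arr, spacing)
    report: dict = {}

    # stage 1: rigid Euler
    reg = _new_registration(rigid_iterations)
    if init is None:
        init_tf = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.Euler2DTransform(), sitk.CenteredTransformInitializerFilter.MOMENTS
        )
    else:
        init_tf = init.to_sitk()
    reg.SetInitialTransform(init_tf, inPlace=False)
    trace = _MetricTrace(reg)
    euler_out = reg.Execute(fixed, moving)
    euler = sitk.Euler2DTransform(sitk.CompositeTransform(euler_out).GetNthTransform(0))
    report["rigid_metric"] = trace.values[-1] if trace.values else None

    # stage 2: similarity (adds one isotropic scale DOF)
    sim = sitk.Similarity2DTransform()
    sim.SetCenter(euler.GetCenter())
    sim.SetAngle(euler.GetAngle())
    sim.SetTranslation(euler.GetTranslation())
    reg = _new_registration(similarity_iterations)
    reg.SetInitialTransform(sim, inPlace=True)
    trace = _MetricTrace(reg)
    reg.Execute(fixed, moving)
    report["similarity_metric"] = trace.values[-1] if trace.values else None
    current: sitk.Transform = sim

    if method == "anatomy_guided":
        # stage 3: free-form B-spline, coarse-to-fine control grid
        mesh = [
            max(1, int(round(sz * sp / bspline_grid_um)))
            for sz, sp in zip(fixed.GetSize(), fixed.GetSpacing())
        ]
        bspl = sitk.BSplineTransformInitializer(fixed, mesh, order=3)
        reg = _new_registration(bspline_iterations, learning_rate=1.0, sampling=0.25)
        reg.SetMovingInitialTransform(current)
        reg.SetInitialTransformAsBSpline(bspl, inPlace=True, scaleFactors=[1, 2, 4])
        trace = _MetricTrace(reg)
        reg.Execute(fixed, moving)
        report["bspline_metric"] = trace.values[-1] if trace.values else None
        total = sitk.CompositeTransform(2)
        total.AddTransform(current)
        total.AddTransform(bspl)  # applied first: p -> bspline -> similarity
        min_jac = _check_folding(total, fixed)
        report["min_jacobian"] = min_jac
        if min_jac <= 0:
            raise ValueError(
                f"free-form stage produced a folded field (min Jacobian {min_jac:.3g}); rejected"
            )
        current = total
    return current, report


def stack_sections(
    sections: list[Section],
    method: str,
    z_spacing: float = 28.0,
    rigid_iterations: int = 300,
    similarity_iterations: int = 300,
    bspline_iterations: int = 80,
    bspline_grid_um: float | None = None,
) -> SectionStack:
    """Register serial sections into a common 3D stack frame.

    The middle section is the reference. Each remaining section is registered
    to its neighbour toward the reference and the transforms are composed. With
    ``method='activity_only'`` all stages are fitted on the activity maps and
    the resulting transforms applied to the anatomy images (for evaluation);
    with ``method='anatomy_guided'`` fitting happens on the anatomy images
    (rigid, similarity, then free-form B-spline) and the identical transforms
    move the activity maps. A free-form fold (non-positive Jacobian) is
    rejected with an error. Default ``z_spacing`` is 28 um (every other 14 um
    section mounted).
    """
    if method not in ("activity_only", "anatomy_guided"):
        raise ValueError(f"unknown stacking method {method!r}")
    if not sections:
        raise ValueError("empty stack")
    n = len(sections)
    ref = n // 2
    spacing = sections[0].anatomy_spacing if method == "anatomy_guided" else sections[0].activity_spacing
    if bspline_grid_um is None:
        # coarse default: ~1/4 of the section extent
        bspline_grid_um = sections[0].anatomy.shape[0] * sections[0].anatomy_spacing / 4

    modality = "anatomy" if method == "anatomy_guided" else "activity"
    transforms: list[sitk.Transform] = [sitk.Transform(2, sitk.sitkIdentity) for _ in range(n)]
    reports: list[dict] = [{} for _ in range(n)]
    # register outward neighbours toward the reference and compose
    order = list(range(ref - 1, -1, -1)) + list(range(ref + 1, n))
    for i in order:
        j = i + 1 if i < ref else i - 1  # neighbour toward reference
        init = None
        if sections[i].landmarks_activity is not None and sections[j].landmarks_activity is not None:
            lm = "landmarks_anatomy" if method == "anatomy_guided" else "landmarks_activity"
            try:
                init = landmark_rigid_fit(getattr(sections[j], lm), getattr(sections[i], lm))
            except ValueError:
                init = None
        tf, rep = _register_pair(
            getattr(sections[j], modality),
            getattr(sections[i], modality),
            spacing,
            method,
            init,
            rigid_iterations,
            similarity_iterations,
            bspline_iterations,
            bspline_grid_um,
        )
        # total: reference frame -> neighbour frame (transforms[j]) -> section i frame
        total = sitk.CompositeTransform(2)
        total.AddTransform(tf)
        total.AddTransform(transforms[j])  # applied first
        transforms[i] = total
        reports[i] = rep

    act_ref = _to_sitk(sections[ref].activity, sections[ref].activity_spacing)
    ana_ref = _to_sitk(sections[ref].anatomy, sections[ref].anatomy_spacing)
    activity_out, anatomy_out = [], []
    for i, sec in enumerate(sections):
        mov_act = sitk.GetImageFromArray(np.asarray(sec.activity, dtype=np.float32))
        mov_act.SetSpacing((sec.activity_spacing,) * 2)
        mov_ana = sitk.GetImageFromArray(np.asarray(sec.anatomy, dtype=np.float32))
        mov_ana.SetSpacing((sec.anatomy_spacing,) * 2)
        activity_out.append(_resample(mov_act, act_ref, transforms[i]))
        anatomy_out.append(_resample(mov_ana, ana_ref, transforms[i]))
    return SectionStack(
        z_positions=np.arange(n) * z_spacing,
        transforms=transforms,
        activity=activity_out,
        anatomy=anatomy_out,
        activity_spacing=sections[ref].activity_spacing,
        anatomy_spacing=sections[ref].anatomy_spacing,
        method=method,
        reports=reports,
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Two empty masks overlap perfectly by convention (returns 1.0).
    """
    mask_a = np.asarray(mask_a).astype(bool)
    mask_b = np.asarray(mask_b).astype(bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must have the same shape")
    denom = mask_a.sum() + mask_b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(mask_a, mask_b).sum() / denom)


@dataclass
class StackingComparison:
    dsc_activity_only: np.ndarray
    dsc_anatomy_guided: np.ndarray
    mean_relative_improvement: float
    t_statistic: float | None
    p_value: float | None

    def __post_init__(self) -> None:
        for arr in (self.dsc_activity_only, self.dsc_anatomy_guided):
            if ((np.asarray(arr) < 0) | (np.asarray(arr) > 1)).any():
                raise ValueError("DSC values must lie in [0, 1]")


def compare_stacking(
    dsc_activity_only: np.ndarray, dsc_anatomy_guided: np.ndarray
) -> StackingComparison:
    """Paired comparison of the two stacking strategies across tumor sets.

    Reports the mean relative improvement of the anatomy-guided method and a
    two-sided paired t-test. Identical pairs give zero variance of differences,
    leaving the t statistic undefined (reported as None).
    """
    a = np.asarray(dsc_activity_only, dtype=float)
    b = np.asarray(dsc_anatomy_guided, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired DSC lists must be equal-length 1D arrays")
    if len(a) < 2:
        raise ValueError("need at least 2 paired sets")
    improvement = float((b.mean() - a.mean()) / a.mean())
    diff = b - a
    if np.allclose(diff.std(ddof=1), 0.0):
        return StackingComparison(a, b, improvement, None, None)
    t_stat, p = stats.ttest_rel(b, a)
    return StackingComparison(a, b, improvement, float(t_stat), float(p))
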