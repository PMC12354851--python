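"""Phantom-based geometric distortion correction for the alpha camera.

Wide-angle optics leave the raw event images with a residual barrel-like
distortion: displacements are largest in the corners of the field of view and
an overall isotropic pixel-scale error may be present. Both are estimated by
imaging regular calibration phantoms (circle, square or dot lattices), matching
the measured element centroids to a digitally generated ideal lattice, and
fitting a composed transform: a global rigid/scale stage followed by a smooth
free-form residual field.

The correction resamples each raw quantitative image onto the corrected grid
and multiplies by the Jacobian determinant of the total mapping, so that local
area changes do not create or destroy counts (intensity preservation).

Conventions: the deformation field lives on the corrected grid and maps
corrected coordinates to raw coordinates, ``raw = p + displacement(p)``, with
displacement stored in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree

__all__ = [
    "PhantomSpec",
    "DeformationField",
    "WarpCorrectionModel",
    "render_phantom",
    "find_centroids",
    "estimate_isotropic_scale",
    "estimate_warp_field",
    "apply_correction",
    "displacement_magnitude_map",
]


@dataclass(frozen=True)
class PhantomSpec:
    """A regular lattice calibration phantom.

    ``element_size`` is the diameter (circles/dots) or edge length (squares) in
    micrometres; ``spacing`` is the centre-to-centre lattice pitch.
    """

    kind: str  # circles | squares | dots
    element_size: float
    spacing: float
    grid_rows: int
    grid_cols: int
    image_shape: tuple[int, int]
    pixel_spacing: float

    def __post_init__(self) -> None:
        if self.kind not in ("circles", "squares", "dots"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not (self.spacing > self.element_size > 0):
            raise ValueError("need spacing > element_size > 0")

    def lattice_um(self) -> np.ndarray:
        """Ideal element centres (x, y) in micrometres, lattice centred in the image."""
        h, w = self.image_shape
        cx = 0.5 * w * self.pixel_spacing
        cy = 0.5 * h * self.pixel_spacing
        xs = (np.arange(self.grid_cols) - (self.grid_cols - 1) / 2) * self.spacing + cx
        ys = (np.arange(self.grid_rows) - (self.grid_rows - 1) / 2) * self.spacing + cy
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class DeformationField:
    """Dense displacement grid mapping corrected -> raw coordinates.

    ``displacement`` has shape (H, W, 2) holding (dx, dy) in micrometres on the
    corrected pixel grid; ``jacobian_det`` is the area scale of the total
    mapping (strictly positive for fold-free fields).
    """

    displacement: np.ndarray
    pixel_spacing: float
    jacobian_det: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: tuple[str, ...] = ()
    fit_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 3 or self.displacement.shape[2] != 2:
            raise ValueError("displacement must have shape (H, W, 2)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement must be finite")
        if self.jacobian_det is None:
            self.jacobian_det = jacobian_determinant(self.displacement, self.pixel_spacing)

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement.shape[:2]


@dataclass
class WarpCorrectionModel:
    """Composed correction: global isotropic scale plus free-form residual field."""

    isotropic_scale: float
    field: DeformationField
    fit_report: dict

    def __post_init__(self) -> None:
        if not (0.5 < self.isotropic_scale < 2.0):
            raise ValueError(f"isotropic scale {self.isotropic_scale} outside sanity band (0.5, 2)")


def jacobian_determinant(displacement: np.ndarray, pixel_spacing: float) -> np.ndarray:
    """det of the Jacobian of the mapping p -> p + displacement(p).

    Central differences in the interior, one-sided at the borders (numpy
    gradient semantics). Displacement is in micrometres, so gradients are taken
    against the physical grid spacing to stay dimensionless.
    """
    dx = displacement[..., 0]
    dy = displacement[..., 1]
    ddx_dy, ddx_dx = np.gradient(dx, pixel_spacing)
    ddy_dy, ddy_dx = np.gradient(dy, pixel_spacing)
    return (1.0 + ddx_dx) * (1.0 + ddy_dy) - ddx_dy * ddy_dx


def render_phantom(spec: PhantomSpec) -> np.ndarray:
    """Digitally generate the idealized phantom image.

    Element edges are anti-aliased (one-pixel coverage ramp, values in [0, 1])
    rather than hard-thresholded: the phantom exists to provide subpixel
    centroid references, and binary rasterization would quantize centroids at
    the ~0.25 px level for small elements.
    """
    centers = spec.lattice_um()
    return _render_elements(spec, centers)


def _render_elements(spec: PhantomSpec, centers_um: np.ndarray) -> np.ndarray:
    h, w = spec.image_shape
    half = spec.element_size / 2.0
    dx = spec.pixel_spacing
    # physical coordinates of pixel centres
    xs = (np.arange(w) + 0.5) * dx
    ys = (np.arange(h) + 0.5) * dx
    lo_x, hi_x = centers_um[:, 0].min() - half, centers_um[:, 0].max() + half
    lo_y, hi_y = centers_um[:, 1].min() - half, centers_um[:, 1].max() + half
    if lo_x < 0 or lo_y < 0 or hi_x > w * dx or hi_y > h * dx:
        raise ValueError("phantom elements exceed image bounds")
    img = np.zeros((h, w), dtype=np.float32)
    r_px = half / dx
    for cx, cy in centers_um:
        ci = cx / dx
        cj = cy / dx
        j0, j1 = int(max(0, cj - r_px - 2)), int(min(h, cj + r_px + 3))
        i0, i1 = int(max(0, ci - r_px - 2)), int(min(w, ci + r_px + 3))
        yy = ys[j0:j1, None]
        xx = xs[None, i0:i1]
        if spec.kind == "squares":
            cov_x = np.clip((half - np.abs(xx - cx)) / dx + 0.5, 0.0, 1.0)
            cov_y = np.clip((half - np.abs(yy - cy)) / dx + 0.5, 0.0, 1.0)
            patch = cov_x * cov_y
        else:
            d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
            patch = np.clip((half - d) / dx + 0.5, 0.0, 1.0)
        np.maximum(img[j0:j1, i0:i1], patch, out=img[j0:j1, i0:i1])
    return img


def find_centroids(image: np.ndarray, pixel_spacing: float) -> np.ndarray:
    """Connected-component centroids (x, y) in micrometres, weighted by intensity."""
    binary = image > 0.1 * image.max()  # include anti-aliased edge ramps
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no phantom elements found in image")
    cms = ndimage.center_of_mass(image.astype(float), labels, index=np.arange(1, n + 1))
    cms = np.asarray(cms)  # (row, col) = (y, x) in pixel index units
    # pixel index i has centre at (i + 0.5) * spacing
    return np.column_stack([(cms[:, 1] + 0.5) * pixel_spacing, (cms[:, 0] + 0.5) * pixel_spacing])


def _pair_centroids(
    ideal: np.ndarray, measured: np.ndarray, max_mismatch: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Pair each ideal centroid with its nearest measured centroid."""
    n_i, n_m = len(ideal), len(measured)
    if abs(n_i - n_m) / n_i > max_mismatch:
        raise ValueError(
            f"phantom component count mismatch: ideal {n_i} vs measured {n_m} (> 20%)"
        )
    tree = cKDTree(measured)
    _, idx = tree.query(ideal)
    return ideal, measured[idx]


def estimate_isotropic_scale(
    measured: np.ndarray, ideal: np.ndarray, pixel_spacing: float = 1.0
) -> float:
    """Global isotropic scale of the measured lattice relative to the ideal one.

    Element centroids of the two images are paired by nearest neighbour, and
    the scale is the robust median of the ratios of paired inter-centroid
    distances. Long baselines dominate the median, so centroid discretization
    noise cancels; pure rotations and translations leave the estimate at 1.
    """
    pts_i = find_centroids(np.asarray(ideal), pixel_spacing)
    pts_m = find_centroids(np.asarray(measured), pixel_spacing)
    if len(pts_i) < 2 or len(pts_m) < 2:
        raise ValueError("need at least two phantom elements to estimate scale")
    src, dst = _pair_centroids(pts_i, pts_m)
    iu, ju = np.triu_indices(len(src), k=1)
    d_ideal = np.linalg.norm(src[iu] - src[ju], axis=1)
    d_meas = np.linalg.norm(dst[iu] - dst[ju], axis=1)
    ok = d_ideal > 0
    return float(np.median(d_meas[ok] / d_ideal[ok]))


def _rigid_similarity_fit(src: np.ndarray, dst: np.ndarray, allow_scale: bool) -> tuple:
    """Least-squares (similarity) transform dst ~ s R src + t via SVD."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    a = src - mu_s
    b = dst - mu_d
    h = a.T @ b
    u, sv, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, d])
    rot = vt.T @ corr @ u.T
    scale = (sv * np.diag(corr)).sum() / (a**2).sum() if allow_scale else 1.0
    t = mu_d - scale * rot @ mu_s
    return scale, rot, t


def estimate_warp_field(
    measured: np.ndarray,
    ideal: np.ndarray,
    pixel_spacing: float,
    smoothing: float = 0.0,
) -> DeformationField:
    """Estimate the corrected->raw deformation field from a phantom pair.

    Stages: (1) global least-squares rigid alignment of the matched element
    centroids; (2) a smooth free-form residual field (thin-plate spline through
    the per-element residuals) rendered densely on the corrected grid. The
    Jacobian determinant of the composed mapping is computed by central
    differences; a fold (non-positive determinant) is flagged in the report.
    """
    measured = np.asarray(measured, dtype=float)
    ideal = np.asarray(ideal, dtype=float)
    if measured.shape != ideal.shape:
        raise ValueError("measured and ideal images must have the same shape")
    pts_i = find_centroids(ideal, pixel_spacing)
    pts_m = find_centroids(measured, pixel_spacing)
    src, dst = _pair_centroids(pts_i, pts_m)

    _, rot, t = _rigid_similarity_fit(src, dst, allow_scale=False)
    rigid_pred = src @ rot.T + t
    residual = dst - rigid_pred  # free-form part at the ideal centroids

    h, w = ideal.shape
    xs = (np.arange(w) + 0.5) * pixel_spacing
    ys = (np.arange(h) + 0.5) * pixel_spacing
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])

    if np.abs(residual).max() < 1e-9:
        freeform = np.zeros((h * w, 2))
    else:
        rbf = RBFInterpolator(src, residual, kernel="thin_plate_spline", smoothing=smoothing)
        freeform = rbf(grid)

    mapped = grid @ rot.T + t + freeform
    disp = (mapped - grid).reshape(h, w, 2)
    field_ = DeformationField(
        displacement=disp,
        pixel_spacing=pixel_spacing,
        provenance=("rigid", "freeform_tps"),
    )
    rms = float(np.sqrt((residual**2).sum(axis=1).mean()))
    field_.fit_report = {
        "n_elements": len(src),
        "rigid_rotation_rad": float(np.arctan2(rot[1, 0], rot[0, 0])),
        "rigid_translation_um": t.tolist(),
        "residual_rms_um": rms,
        "min_jacobian": float(field_.jacobian_det.min()),
        "folded": bool(field_.jacobian_det.min() <= 0),
    }
    return field_


def apply_correction(image: np.ndarray, def_field: DeformationField) -> np.ndarray:
    """Resample a raw image onto the corrected grid with intensity preservation.

    The corrected image is ``I_raw(p + displacement(p)) * jacobian_det(p)``:
    bilinear resampling followed by the per-pixel Jacobian factor, so that the
    total intensity of content mapped within the frame is conserved.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != def_field.shape:
        raise ValueError(
            f"image shape {image.shape} does not match field shape {def_field.shape}"
        )
    h, w = image.shape
    jj, ii = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # displacement is in micrometres; convert to pixel index offsets
    dcol = def_field.displacement[..., 0] / def_field.pixel_spacing
    drow = def_field.displacement[..., 1] / def_field.pixel_spacing
    sampled = ndimage.map_coordinates(
        image, [jj + drow, ii + dcol], order=1, mode="constant", cval=0.0
    )
    return sampled * def_field.jacobian_det


def displacement_magnitude_map(def_field: DeformationField) -> np.ndarray:
    """Per-pixel Euclidean norm of the displacement, micrometres."""
    return np.sqrt((def_field.displacement**2).sum(axis=2))
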