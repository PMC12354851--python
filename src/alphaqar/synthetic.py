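"""Synthetic data with known ground truth for every pipeline stage.

These generators emulate the study's inputs — Poisson list-mode decay events
from a known activity map, geometrically distorted lattice phantoms,
kidney-like sections with glomeruli/vessels and distance-structured uptake,
and serially sectioned tumor volumes with known inter-section misalignments —
and always emit the truth artifact (field, transform, mask, profile parameter)
alongside the data, so tests never re-derive truth from outputs.

Reproducibility contract: every generator is a pure function of (spec, seed)
using numpy's PCG64 generator; named substreams are derived from the base seed
with CRC32-hashed keys, so adding a consumer never perturbs the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .listmode import AcquisitionSchedule, EventList
from .quantify import AC225, ActivityImage, Isotope, decay_weight
from .segmentation import CompartmentMasks
from .warp import PhantomSpec, render_phantom, _render_elements

__all__ = [
    "substream",
    "simulate_listmode",
    "DistortionSpec",
    "generate_distorted_phantom",
    "KidneyPhantomSpec",
    "generate_kidney_phantom",
    "generate_slide_group",
    "TumorStackSpec",
    "generate_tumor_stack",
]


def substream(seed: int, *keys: str) -> np.random.Generator:
    """A named, reproducible PCG64 substream of the base seed."""
    hashed = [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *hashed]))


# ---------------------------------------------------------------------------
# list-mode events


def simulate_listmode(
    activity: ActivityImage,
    f: float,
    schedule: AcquisitionSchedule,
    seed: int = 0,
    isotope: Isotope | None = None,
) -> EventList:
    """Poisson list-mode events from a known activity map.

    Per pixel and acquisition window, the detected count is Poisson with mean
    f * N0 * (exp(-lambda t1) - exp(-lambda t2)), N0 = A0 / lambda. Event
    positions are uniform within their pixel; timestamps follow the truncated
    exponential decay density within their window.
    """
    if f <= 0:
        raise ValueError("f must be positive")
    iso = isotope or activity.isotope
    lam = iso.decay_constant
    rng = substream(seed, "listmode")
    a0 = activity.activity
    n0 = a0 / lam
    h, w = a0.shape
    xs_all, ys_all, ts_all, ws_all = [], [], [], []
    ox, oy = activity.origin
    sp = activity.pixel_spacing
    for wi, win in enumerate(schedule.windows):
        e1 = math.exp(-lam * win.t_start)
        e2 = math.exp(-lam * win.t_end)
        mean = f * n0 * (e1 - e2)
        counts = rng.poisson(mean)
        total = int(counts.sum())
        if total == 0:
            continue
        rows, cols = np.nonzero(counts)
        reps = counts[rows, cols]
        row_idx = np.repeat(rows, reps)
        col_idx = np.repeat(cols, reps)
        xs_all.append(ox + (col_idx + rng.random(total)) * sp)
        ys_all.append(oy + (row_idx + rng.random(total)) * sp)
        u = rng.random(total)
        t_abs = -np.log(e1 - u * (e1 - e2)) / lam
        ts_all.append(t_abs - win.t_start)
        ws_all.append(np.full(total, wi, dtype=np.intp))
    if not xs_all:
        empty = np.empty(0)
        return EventList(empty, empty.copy(), empty.copy(), np.empty(0, dtype=np.intp), schedule)
    return EventList(
        np.concatenate(xs_all),
        np.concatenate(ys_all),
        np.concatenate(ts_all),
        np.concatenate(ws_all),
        schedule,
    )


def expected_event_count(activity: ActivityImage, f: float, schedule: AcquisitionSchedule,
                         isotope: Isotope | None = None) -> float:
    """Expected total events: f * (sum A0 / lambda) * W."""
    iso = isotope or activity.isotope
    return f * activity.total_bq / iso.decay_constant * decay_weight(schedule, iso)


# ---------------------------------------------------------------------------
# distorted phantoms


@dataclass(frozen=True)
class DistortionSpec:
    """Analytic camera distortion: isotropic scale + radial (barrel) + local bumps.

    The mapping from corrected to raw coordinates about the image centre c is
    D(p) = c + s * (r + k1 |r|^2 r) + bumps(p), r = p - c. ``k1`` is in um^-2;
    positive values push corners outward (barrel-like residual).
    """

    isotropic_scale: float = 1.0
    k1_per_um2: float = 0.0
    bump_amplitude_um: float = 0.0
    bump_sigma_um: float = 400.0
    n_bumps: int = 0
    seed: int = 0


def _distortion_mapping(spec: DistortionSpec, center_um: np.ndarray, shape_um: tuple[float, float]):
    rng = substream(spec.seed, "distortion-bumps")
    if spec.n_bumps and spec.bump_amplitude_um > 0:
        centers = rng.random((spec.n_bumps, 2)) * np.asarray(shape_um)
        angles = rng.random(spec.n_bumps) * 2 * np.pi
        vecs = spec.bump_amplitude_um * np.column_stack([np.cos(angles), np.sin(angles)])
    else:
        centers = np.zeros((0, 2))
        vecs = np.zeros((0, 2))

    def mapping(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        r = points - center_um
        rad = spec.isotropic_scale * (1.0 + spec.k1_per_um2 * (r**2).sum(axis=1, keepdims=True))
        out = center_um + rad * r
        for c, v in zip(centers, vecs):
            d2 = ((points - c) ** 2).sum(axis=1, keepdims=True)
            out = out + v * np.exp(-0.5 * d2 / spec.bump_sigma_um**2)
        return out

    return mapping


def generate_distorted_phantom(
    spec: PhantomSpec, distortion: DistortionSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ideal image, distorted image, true corrected->raw displacement field).

    The distorted image renders each lattice element at its distorted centre
    D(u); the returned field holds D(p) - p (micrometres) densely on the
    corrected grid for recovery scoring. Specs whose distortion folds the grid
    are rejected.
    """
    ideal = render_phantom(spec)
    h, w = spec.image_shape
    shape_um = (w * spec.pixel_spacing, h * spec.pixel_spacing)
    center = np.array([0.5 * shape_um[0], 0.5 * shape_um[1]])
    mapping = _distortion_mapping(distortion, center, shape_um)

    moved = mapping(spec.lattice_um())
    distorted = _render_elements(spec, moved)

    xs = (np.arange(w) + 0.5) * spec.pixel_spacing
    ys = (np.arange(h) + 0.5) * spec.pixel_spacing
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    disp = (mapping(grid) - grid).reshape(h, w, 2)

    # fold check on the analytic field
    from .warp import jacobian_determinant

    if jacobian_determinant(disp, spec.pixel_spacing).min() <= 0:
        raise ValueError("distortion spec folds the grid; rejected")
    return ideal, distorted, disp


# ---------------------------------------------------------------------------
# kidney phantom


@dataclass(frozen=True)
class KidneyPhantomSpec:
    """Kidney-like section: elliptical tissue, cortical glomeruli, few vessels.

    ``enrichment_reference`` selects which compartment the annular uptake
    enrichment surrounds; amplitude is in multiples of the tissue baseline
    (1.0 = no enrichment). Anatomy grid is 4x finer than the camera grid by
    default, mirroring microscope vs autoradiography resolutions.
    """

    image_shape: tuple[int, int] = (320, 320)
    pixel_spacing_um: float = 6.625  # 26.5 / 4
    tissue_axes_um: tuple[float, float] = (950.0, 750.0)
    cortex_band_um: float = 300.0
    n_glomeruli: int = 20
    glomerulus_diameter_um: tuple[float, float] = (60.0, 120.0)
    n_vessels: int = 3
    vessel_width_um: float = 60.0
    vessel_length_um: float = 500.0
    enrichment_reference: str = "glomeruli"  # edge | glomeruli | vessels
    enrichment_annulus_um: tuple[float, float] = (50.0, 100.0)
    enrichment_amplitude: float = 1.0
    blood_pool_amplitude: float = 0.0
    noise_level: float = 0.0
    seed: int = 0


def _place_disks(rng, allowed: np.ndarray, n: int, radii_px: np.ndarray) -> list[tuple]:
    """Rejection-sample non-overlapping disk centres inside an allowed mask."""
    h, w = allowed.shape
    placed: list[tuple] = []
    tries = 0
    ys, xs = np.nonzero(allowed)
    if len(ys) == 0:
        raise ValueError("no allowed area for placement")
    while len(placed) < n:
        tries += 1
        if tries > 5000:
            raise ValueError("infeasible structure placement after max retries")
        k = rng.integers(len(ys))
        cy, cx = float(ys[k]), float(xs[k])
        r = radii_px[len(placed)]
        if cy - r < 3 or cy + r > h - 4 or cx - r < 3 or cx + r > w - 4:
            continue
        if any((cy - py) ** 2 + (cx - px) ** 2 < (r + pr + 2) ** 2 for py, px, pr in placed):
            continue
        yy, xx = np.mgrid[
            int(cy - r - 1) : int(cy + r + 2), int(cx - r - 1) : int(cx + r + 2)
        ]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if not allowed[yy[disk], xx[disk]].all():
            continue
        placed.append((cy, cx, r))
    return placed


def generate_kidney_phantom(
    spec: KidneyPhantomSpec,
) -> tuple[np.ndarray, ActivityImage, CompartmentMasks]:
    """(anatomy image, activity on the anatomy grid, truth compartment masks).

    Anatomy has stain-like contrast (bright tissue, dark lumina); activity is
    the tissue baseline plus the specified annular enrichment (triangular
    weight peaking at the annulus centre) and optional blood-pool term, with
    multiplicative Gaussian noise of relative width ``noise_level``.
    """
    h, w = spec.image_shape
    sp = spec.pixel_spacing_um
    rng = substream(spec.seed, "kidney")
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = spec.tissue_axes_um[1] / sp, spec.tissue_axes_um[0] / sp
    rho = np.sqrt(((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2)
    tissue = rho <= 1.0

    band_frac = spec.cortex_band_um / min(spec.tissue_axes_um)
    cortex = tissue & (rho >= 1.0 - band_frac)

    radii_g = (
        rng.uniform(*spec.glomerulus_diameter_um, size=spec.n_glomeruli) / 2.0 / sp
    )
    interior = ndimage.binary_erosion(cortex, iterations=2)
    glom_disks = _place_disks(rng, interior, spec.n_glomeruli, radii_g)
    glomeruli = np.zeros((h, w), dtype=bool)
    for gy, gx, r in glom_disks:
        glomeruli |= (yy - gy) ** 2 + (xx - gx) ** 2 <= r**2

    # vessels: elongated capsules in the medulla (inside tissue, away from glomeruli)
    vessels = np.zeros((h, w), dtype=bool)
    medulla = tissue & (rho < 1.0 - band_frac)
    half_w = spec.vessel_width_um / 2.0 / sp
    half_l = spec.vessel_length_um / 2.0 / sp
    placed = 0
    tries = 0
    while placed < spec.n_vessels:
        tries += 1
        if tries > 5000:
            raise ValueError("infeasible vessel placement after max retries")
        ys_m, xs_m = np.nonzero(ndimage.binary_erosion(medulla, iterations=3))
        k = rng.integers(len(ys_m))
        vy, vx = float(ys_m[k]), float(xs_m[k])
        theta = rng.uniform(0, np.pi)
        ux, uy = math.cos(theta), math.sin(theta)
        px_ = (xx - vx) * ux + (yy - vy) * uy  # along
        qx_ = -(xx - vx) * uy + (yy - vy) * ux  # across
        cap = (np.abs(px_) <= half_l) & (np.abs(qx_) <= half_w)
        if not (cap <= medulla).all() or (cap & glomeruli).any() or (cap & vessels).any():
            continue
        vessels |= cap
        placed += 1

    masks = CompartmentMasks(tissue, vessels, glomeruli, sp)

    # anatomy: bright tissue, dark lumina, mild texture
    anatomy = np.full((h, w), 0.03)
    anatomy[tissue] = 0.75
    anatomy[vessels | glomeruli] = 0.12
    anatomy += rng.normal(0, 0.02, size=(h, w))
    anatomy = np.clip(anatomy, 0, 1)

    # activity: baseline + annular enrichment + blood pool
    act = np.zeros((h, w))
    act[tissue] = 1.0
    if spec.enrichment_amplitude != 1.0:
        ref = {"edge": ~tissue, "glomeruli": glomeruli, "vessels": vessels}[
            spec.enrichment_reference
        ]
        dist = ndimage.distance_transform_edt(~ref) * sp
        lo, hi = spec.enrichment_annulus_um
        mid = 0.5 * (lo + hi)
        tri = np.clip(1.0 - np.abs(dist - mid) / (0.5 * (hi - lo)), 0.0, 1.0)
        act[tissue] *= 1.0 + (spec.enrichment_amplitude - 1.0) * tri[tissue]
    if spec.blood_pool_amplitude > 0:
        act[vessels] = spec.blood_pool_amplitude
    if spec.noise_level > 0:
        act *= np.clip(rng.normal(1.0, spec.noise_level, size=(h, w)), 0.0, None)
    activity = ActivityImage(activity=act, pixel_spacing=sp, isotope=AC225)
    return anatomy, activity, masks


# ---------------------------------------------------------------------------
# slide groups (multi-section coregistration)


def generate_slide_group(
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    pixel_spacing_um: float = 26.5,
    rotation_deg: float = 4.0,
    shift_um: tuple[float, float] = (60.0, -40.0),
    landmark_noise_um: float = 25.0,
    noise_level: float = 0.05,
):
    """Three-sections-on-a-slide fixture with a known whole-slide rigid offset.

    Section 0 is a near-symmetric ellipse (rotation is poorly constrained from
    it alone); sections 1-2 are lobed, asymmetric blobs. The anatomy composite
    is the activity composite's tissue content under a known rigid transform
    (rotation about the composite centre plus a shift); per-section landmarks
    carry annotation noise. Returns (sections, true_rotation_rad,
    true_shift_um) with sections ready for :class:`alphaqar.coreg.SlideGroup`.
    """
    from .coreg import Section

    rng = substream(seed, "slide-group")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    tiles = []
    for k in range(3):
        theta = np.arctan2(yy - cy, xx - cx)
        rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        if k == 0:  # near-symmetric: gentle ellipse
            radius = 0.38 * h * (1.0 + 0.04 * np.cos(2 * theta + rng.uniform(0, np.pi)))
        else:
            phases = rng.uniform(0, 2 * np.pi, 3)
            amps = rng.uniform(0.1, 0.22, 3)
            radius = 0.36 * h * (
                1.0 + sum(a * np.cos(m * theta + p) for m, (a, p) in enumerate(zip(amps, phases), start=2))
            )
        tissue = rr <= radius
        tex = ndimage.gaussian_filter(rng.normal(size=shape), 2.5)
        tiles.append(np.where(tissue, np.clip(0.6 + 0.3 * tex, 0.05, 1.0), 0.02))
    comp = np.hstack(tiles)  # anatomy content, unrotated
    hh, ww = comp.shape
    sp = pixel_spacing_um

    # activity: blurred tissue content + Poisson-like noise (sparse-ish)
    act_comp = ndimage.gaussian_filter(comp, 1.5)
    act_comp = np.clip(act_comp + rng.normal(0, noise_level, comp.shape), 0, None)

    # anatomy composite observed under the true rigid transform T (fixed->moving)
    rot = math.radians(rotation_deg)
    c_um = np.array([(ww - 1) / 2.0 * sp, (hh - 1) / 2.0 * sp])
    cth, sth = math.cos(rot), math.sin(rot)
    gy, gx = np.mgrid[0:hh, 0:ww]
    # content at q moves to T(q): sample original at T^{-1}(p)
    rx = gx * sp - c_um[0] - shift_um[0]
    ry = gy * sp - c_um[1] - shift_um[1]
    inv_x = c_um[0] + cth * rx + sth * ry
    inv_y = c_um[1] - sth * rx + cth * ry
    anat_obs = ndimage.map_coordinates(
        comp, [inv_y / sp, inv_x / sp], order=1, mode="constant", cval=0.02
    )
    anat_obs = np.clip(anat_obs + rng.normal(0, noise_level, comp.shape), 0, None)

    def t_true(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        r = points - c_um
        return np.column_stack(
            [c_um[0] + cth * r[:, 0] - sth * r[:, 1], c_um[1] + sth * r[:, 0] + cth * r[:, 1]]
        ) + np.asarray(shift_um)

    sections = []
    for k in range(3):
        sl = slice(k * w, (k + 1) * w)
        lm_act_comp = np.column_stack(
            [
                (k * w + rng.uniform(0.3, 0.7, 3) * w) * sp,
                rng.uniform(0.3, 0.7, 3) * h * sp,
            ]
        )
        lm_anat_comp = t_true(lm_act_comp) + rng.normal(0, landmark_noise_um, (3, 2))
        x_off = k * w * sp
        sections.append(
            Section(
                activity=act_comp[:, sl],
                anatomy=anat_obs[:, sl],
                activity_spacing=sp,
                anatomy_spacing=sp,
                landmarks_activity=lm_act_comp - [x_off, 0.0],
                landmarks_anatomy=lm_anat_comp - [x_off, 0.0],
            )
        )
    return sections, rot, np.asarray(shift_um)


# ---------------------------------------------------------------------------
# tumor stack


@dataclass(frozen=True)
class TumorStackSpec:
    """Serially sectioned tumor with known per-section misalignments.

    Anatomy carries rich boundary/texture structure; activity is sparse
    hot-spots, as is typical for antibody-delivered alpha emitters. Each
    non-reference section receives a known rigid perturbation (rotation,
    shift) plus an optional smooth warp, applied identically to both
    modalities.
    """

    image_shape: tuple[int, int] = (160, 160)
    pixel_spacing_um: float = 26.5
    n_sections: int = 3
    section_spacing_um: float = 28.0
    tumor_radius_um: float = 1600.0
    n_lobes: int = 4
    n_hotspots: int = 4
    hotspot_sigma_um: float = 140.0
    hotspot_contrast: float = 12.0
    max_rotation_deg: float = 6.0
    max_shift_um: float = 120.0
    warp_amplitude_um: float = 0.0
    warp_sigma_um: float = 900.0
    noise_level: float = 0.02
    seed: int = 0


@dataclass
class TumorStackTruth:
    """Ground truth accompanying a generated stack."""

    rotations_rad: np.ndarray  # per section, reference frame -> section frame
    shifts_um: np.ndarray  # (n, 2)
    landmarks_um: list[np.ndarray]  # per section, (3, 2) in that section's frame
    tissue_volume: np.ndarray  # unperturbed (n, h, w) tissue masks
    activity_volume: np.ndarray  # unperturbed (n, h, w) activity


def _smooth_warp(rng, shape, spacing, amplitude_um, sigma_um):
    if amplitude_um <= 0:
        return np.zeros(shape + (2,))
    sig_px = sigma_um / spacing
    comp = []
    for _ in range(2):
        noise = rng.normal(size=shape)
        sm = ndimage.gaussian_filter(noise, sig_px)
        sm *= amplitude_um / max(np.abs(sm).max(), 1e-12)
        comp.append(sm)
    return np.stack(comp, axis=-1)  # um, (h, w, 2) as (dx, dy)


def generate_tumor_stack(
    spec: TumorStackSpec,
) -> tuple[list[dict], TumorStackTruth]:
    """Generate perturbed serial sections plus ground truth.

    Returns ``sections``: one dict per section with keys ``anatomy``,
    ``activity`` (2D arrays, same grid), ``landmarks`` ((3, 2) um in the
    section frame), and the :class:`TumorStackTruth`. The middle section is
    the unperturbed reference.
    """
    h, w = spec.image_shape
    sp = spec.pixel_spacing_um
    n = spec.n_sections
    rng = substream(spec.seed, "tumor")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r_px = spec.tumor_radius_um / sp

    # continuous tumor shape: ellipsoid-ish blob with angular lobes, slowly varying in z
    theta = np.arctan2(yy - cy, xx - cx)
    lobe_phase = rng.uniform(0, 2 * np.pi, spec.n_lobes)
    lobe_amp = rng.uniform(0.05, 0.15, spec.n_lobes)
    z_positions = np.arange(n) * spec.section_spacing_um
    z_scale = 1.0 - 0.02 * np.abs(np.arange(n) - n // 2)  # gentle z taper

    # internal texture: fixed 3D-ish texture, drifting slightly with z
    base_tex = ndimage.gaussian_filter(rng.normal(size=(h, w)), 3.0)
    drift = ndimage.gaussian_filter(rng.normal(size=(h, w)), 6.0)

    # sparse hot-spots: 3D Gaussians shared across sections
    hot_y = rng.uniform(cy - 0.5 * r_px, cy + 0.5 * r_px, spec.n_hotspots)
    hot_x = rng.uniform(cx - 0.5 * r_px, cx + 0.5 * r_px, spec.n_hotspots)
    hot_z = rng.uniform(z_positions[0], z_positions[-1], spec.n_hotspots)
    sig_px = spec.hotspot_sigma_um / sp

    anatomy_planes = np.zeros((n, h, w))
    activity_planes = np.zeros((n, h, w))
    tissue_planes = np.zeros((n, h, w), dtype=bool)
    for k in range(n):
        radius = r_px * z_scale[k] * (
            1.0
            + sum(a * np.cos(m * theta + p) for m, (a, p) in enumerate(zip(lobe_amp, lobe_phase), start=2))
        )
        rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        tissue = rr <= radius
        tissue_planes[k] = tissue
        tex = base_tex + 0.15 * k * drift
        anat = np.where(tissue, 0.55 + 0.25 * tex, 0.02)
        anatomy_planes[k] = np.clip(anat, 0, 1)
        act = np.full((h, w), 0.02)
        for hy, hx, hz in zip(hot_y, hot_x, hot_z):
            dz = (z_positions[k] - hz) / spec.hotspot_sigma_um
            act += spec.hotspot_contrast * np.exp(
                -0.5 * (((yy - hy) ** 2 + (xx - hx) ** 2) / sig_px**2 + dz**2)
            )
        activity_planes[k] = np.where(tissue, act, 0.0)

    # landmarks: three well-separated tissue points in the reference frame, um
    lm_ref = np.array(
        [
            [cx * sp, (cy - 0.5 * r_px) * sp],
            [(cx - 0.5 * r_px) * sp, (cy + 0.35 * r_px) * sp],
            [(cx + 0.5 * r_px) * sp, (cy + 0.35 * r_px) * sp],
        ]
    )

    ref = n // 2
    rotations = np.zeros(n)
    shifts = np.zeros((n, 2))
    sections: list[dict] = []
    landmarks: list[np.ndarray] = []
    noise_rng = substream(spec.seed, "tumor-noise")
    for k in range(n):
        if k == ref:
            rot, shift = 0.0, np.zeros(2)
        else:
            rot = math.radians(noise_rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg))
            shift = noise_rng.uniform(-spec.max_shift_um, spec.max_shift_um, 2)
        rotations[k] = rot
        shifts[k] = shift
        warp = _smooth_warp(
            substream(spec.seed, "tumor-warp", str(k)),
            (h, w),
            sp,
            spec.warp_amplitude_um if k != ref else 0.0,
            spec.warp_sigma_um,
        )

        # sampling map: section-frame pixel p -> reference-frame position
        c_um = np.array([cx * sp, cy * sp])
        cth, sth = math.cos(rot), math.sin(rot)
        px_um = xx * sp
        py_um = yy * sp
        rx = px_um - c_um[0]
        ry = py_um - c_um[1]
        mx = c_um[0] + cth * rx - sth * ry + shift[0] + warp[..., 0]
        my = c_um[1] + sth * rx + cth * ry + shift[1] + warp[..., 1]
        coords = [my / sp, mx / sp]
        anat_k = ndimage.map_coordinates(anatomy_planes[k], coords, order=1, mode="nearest")
        act_k = ndimage.map_coordinates(activity_planes[k], coords, order=1, mode="constant")
        if spec.noise_level > 0:
            anat_k = np.clip(
                anat_k + noise_rng.normal(0, spec.noise_level, size=(h, w)), 0, 1
            )
            act_k = np.clip(
                act_k * noise_rng.normal(1.0, spec.noise_level, size=(h, w)), 0, None
            )

        # landmark in section frame: inverse of the rigid part (warp ~ 0 at landmarks scale)
        rx_l = lm_ref[:, 0] - c_um[0] - shift[0]
        ry_l = lm_ref[:, 1] - c_um[1] - shift[1]
        lm_k = np.column_stack(
            [
                c_um[0] + cth * rx_l + sth * ry_l,
                c_um[1] - sth * rx_l + cth * ry_l,
            ]
        )
        landmarks.append(lm_k)
        sections.append(
            {
                "anatomy": anat_k,
                "activity": act_k,
                "landmarks": lm_k,
                "pixel_spacing_um": sp,
                "z_um": float(z_positions[k]),
            }
        )
    truth = TumorStackTruth(
        rotations_rad=rotations,
        shifts_um=shifts,
        landmarks_um=landmarks,
        tissue_volume=tissue_planes,
        activity_volume=activity_planes,
    )
    return sections, truth
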