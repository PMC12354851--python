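"""Phantom rendering, distortion estimation and intensity-preserving correction."""

import numpy as np
import pytest
from scipy import ndimage

from alphaqar.synthetic import DistortionSpec, generate_distorted_phantom
from alphaqar.warp import (
    DeformationField,
    PhantomSpec,
    apply_correction,
    displacement_magnitude_map,
    estimate_isotropic_scale,
    estimate_warp_field,
    find_centroids,
    render_phantom,
)


def _truth_at_centroids(spec, field, truth):
    """Recovered vs true displacement sampled at the ideal dot centroids, px RMS."""
    cents = spec.lattice_um()
    rows = np.clip((cents[:, 1] / spec.pixel_spacing - 0.5).round().astype(int), 0, None)
    cols = np.clip((cents[:, 0] / spec.pixel_spacing - 0.5).round().astype(int), 0, None)
    diff = field.displacement[rows, cols] - truth[rows, cols]
    return np.sqrt((diff**2).sum(axis=1).mean()) / spec.pixel_spacing


class TestRenderPhantom:
    def test_element_count(self):
        spec = PhantomSpec("dots", 80, 300, 5, 7, (256, 256), 13.25)
        img = render_phantom(spec)
        assert ndimage.label(img)[1] == 35

    def test_lattice_pitch(self, dots_spec):
        img = render_phantom(dots_spec)
        pts = find_centroids(img, dots_spec.pixel_spacing)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        assert np.median(d[:, 1]) == pytest.approx(
            dots_spec.spacing, abs=0.5 * dots_spec.pixel_spacing
        )

    def test_centroids_match_lattice(self, dots_spec):
        """Center-of-mass oracle: rendered centroids sit on the spec lattice."""
        img = render_phantom(dots_spec)
        pts = find_centroids(img, dots_spec.pixel_spacing)
        lattice = dots_spec.lattice_um()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(lattice).query(pts)
        assert d.max() < 0.1 * dots_spec.pixel_spacing

    def test_out_of_bounds_elements_rejected(self):
        spec = PhantomSpec("dots", 80, 300, 20, 20, (128, 128), 13.25)
        with pytest.raises(ValueError, match="bounds"):
            render_phantom(spec)

    def test_values_are_unit_coverage(self, dots_spec):
        img = render_phantom(dots_spec)
        assert img.min() == 0.0 and img.max() == 1.0
        # anti-aliasing confined to element rims: interiors saturate at 1
        assert (img == 1.0).sum() > 0.5 * (img > 0).sum()


class TestIsotropicScale:
    def test_identity(self, dots_spec):
        img = render_phantom(dots_spec)
        assert estimate_isotropic_scale(img, img, dots_spec.pixel_spacing) == pytest.approx(1.0)

    def test_known_scale_recovered(self, dots_spec):
        # mirrors the published 1.6% global scaling scenario
        ideal, distorted, _ = generate_distorted_phantom(
            dots_spec, DistortionSpec(isotropic_scale=1.016)
        )
        s = estimate_isotropic_scale(distorted, ideal, dots_spec.pixel_spacing)
        assert s == pytest.approx(1.016, abs=1e-3)

    def test_rotation_invariance(self, dots_spec):
        ideal = render_phantom(dots_spec)
        rotated = ndimage.rotate(ideal.astype(float), 3.0, reshape=False, order=1)
        s = estimate_isotropic_scale(rotated, ideal, dots_spec.pixel_spacing)
        assert s == pytest.approx(1.0, abs=1e-3)


class TestWarpFieldEstimation:
    def test_identity_images_give_null_field(self, dots_spec):
        img = render_phantom(dots_spec)
        field = estimate_warp_field(img, img, dots_spec.pixel_spacing)
        assert np.abs(field.displacement).max() < 0.25 * dots_spec.pixel_spacing

    def test_barrel_distortion_recovered(self, dots_spec):
        ideal, distorted, truth = generate_distorted_phantom(
            dots_spec, DistortionSpec(k1_per_um2=2e-8)
        )
        field = estimate_warp_field(distorted, ideal, dots_spec.pixel_spacing)
        assert _truth_at_centroids(dots_spec, field, truth) < 0.5
        assert field.jacobian_det.min() > 0

    def test_shape_mismatch_rejected(self, dots_spec):
        img = render_phantom(dots_spec)
        with pytest.raises(ValueError, match="shape"):
            estimate_warp_field(img[:-10], img, dots_spec.pixel_spacing)


class TestApplyCorrection:
    @staticmethod
    def _smooth_field(shape, spacing, amplitude, seed=0):
        rng = np.random.default_rng(seed)
        disp = np.stack(
            [ndimage.gaussian_filter(rng.normal(size=shape), 12.0) for _ in range(2)], axis=-1
        )
        disp *= amplitude / np.abs(disp).max()
        return DeformationField(disp, spacing)

    def test_identity_field_is_noop(self):
        img = np.random.default_rng(0).random((64, 64))
        field = DeformationField(np.zeros((64, 64, 2)), 26.5)
        np.testing.assert_allclose(apply_correction(img, field), img, atol=1e-12)

    def test_uniform_areal_expansion_halves_intensity(self):
        # correction spreads content over twice the area: J = 1/2 everywhere
        h = w = 96
        sp = 26.5
        jj, ii = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        s = 1 / np.sqrt(2.0)
        disp = np.stack([(s - 1) * ii * sp, (s - 1) * jj * sp], axis=-1)
        field = DeformationField(disp, sp)
        out = apply_correction(np.ones((h, w)), field)
        assert out[20, 20] == pytest.approx(0.5, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_total_intensity_conserved_under_smooth_fields(self, seed):
        field = self._smooth_field((128, 128), 26.5, amplitude=30.0, seed=seed)
        img = np.zeros((128, 128))
        img[32:96, 32:96] = np.random.default_rng(seed).random((64, 64)) + 1.0
        out = apply_correction(img, field)
        assert abs(out.sum() - img.sum()) / img.sum() < 0.005

    def test_shape_mismatch_rejected(self):
        field = DeformationField(np.zeros((8, 8, 2)), 26.5)
        with pytest.raises(ValueError, match="shape"):
            apply_correction(np.zeros((9, 9)), field)


class TestSelfConsistency:
    def test_estimate_then_correct_restores_lattice(self, dots_spec):
        ideal, distorted, _ = generate_distorted_phantom(
            dots_spec, DistortionSpec(isotropic_scale=1.01, k1_per_um2=1.5e-8)
        )
        field = estimate_warp_field(distorted, ideal, dots_spec.pixel_spacing)
        corrected = apply_correction(distorted.astype(float), field)
        pts = find_centroids(corrected, dots_spec.pixel_spacing)
        lattice = dots_spec.lattice_um()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(lattice).query(pts)
        rms_px = np.sqrt((d**2).mean()) / dots_spec.pixel_spacing
        assert rms_px < 1.0


class TestDisplacementMagnitude:
    def test_zero_field(self):
        field = DeformationField(np.zeros((16, 16, 2)), 26.5)
        assert displacement_magnitude_map(field).max() == 0.0

    def test_pure_translation(self):
        disp = np.zeros((16, 16, 2))
        disp[..., 0] = 10.0
        field = DeformationField(disp, 26.5)
        np.testing.assert_allclose(displacement_magnitude_map(field), 10.0)

    def test_barrel_maximal_in_corners(self, dots_spec):
        _, _, truth = generate_distorted_phantom(dots_spec, DistortionSpec(k1_per_um2=2e-8))
        mag = np.sqrt((truth**2).sum(axis=2))
        h, w = mag.shape
        corners = [mag[0, 0], mag[0, -1], mag[-1, 0], mag[-1, -1]]
        interior = mag[h // 4 : -h // 4, w // 4 : -w // 4]
        assert min(corners) > interior.max()
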