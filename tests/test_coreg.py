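"""Landmark fits, slide-group registration, stacking and Dice comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from alphaqar.coreg import (
    SlideGroup,
    compare_stacking,
    dice,
    landmark_rigid_fit,
    register_histology_to_autoradiography,
    stack_sections,
)
from alphaqar.segmentation import largest_component_mask
from alphaqar.synthetic import generate_slide_group
from tests.conftest import sections_from_stack


class TestLandmarkRigidFit:
    def test_identity(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        tf = landmark_rigid_fit(pts, pts)
        assert tf.rotation == pytest.approx(0.0, abs=1e-12)
        assert tf.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_known_rotation_translation_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.random((5, 2)) * 1000
        th = math.radians(30)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        moved = pts @ rot.T + [5.0, -3.0]
        tf = landmark_rigid_fit(pts, moved)
        assert tf.rotation == pytest.approx(th, abs=1e-9)
        np.testing.assert_allclose(tf.apply(pts), moved, atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            landmark_rigid_fit(pts, pts)

    def test_too_few_points_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="3"):
            landmark_rigid_fit(pts, pts)

    def test_no_scale_absorbed(self):
        """A scaled point set must not be fit by scaling (determinant stays 1)."""
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [50.0, 50.0]])
        tf = landmark_rigid_fit(pts, pts * 1.3)
        assert np.linalg.det(tf.matrix()) == pytest.approx(1.0)
        assert tf.residual_rms > 1.0


class TestSlideGroupRegistration:
    def test_known_rigid_offset_recovered(self):
        sections, rot_true, shift_true = generate_slide_group(seed=0)
        group = SlideGroup(sections)
        tf, report = register_histology_to_autoradiography(group, iterations=200)
        assert abs(tf.rotation - rot_true) < math.radians(0.5)
        # evaluate as mapping error at probe points (pixel units, 26.5 um px)
        probes = np.array([[1000.0, 1000.0], [3000.0, 1500.0], [6000.0, 800.0]])
        c = np.array([(3 * 96 - 1) / 2 * 26.5, (96 - 1) / 2 * 26.5])
        th = rot_true
        r = probes - c
        truth = np.column_stack(
            [
                c[0] + math.cos(th) * r[:, 0] - math.sin(th) * r[:, 1],
                c[1] + math.sin(th) * r[:, 0] + math.cos(th) * r[:, 1],
            ]
        ) + shift_true
        err_px = np.linalg.norm(tf.apply(probes) - truth, axis=1) / 26.5
        assert err_px.max() < 0.5

    def test_group_constraint_needs_three_sections(self):
        sections, _, _ = generate_slide_group(seed=1)
        with pytest.raises(ValueError, match="3"):
            SlideGroup(sections[:2], group_constraint=True)

    def test_three_sections_beat_single_on_symmetric_tissue(self):
        """Fixed relative section positions resolve rotation ambiguity."""
        errs_group, errs_single = [], []
        for seed in range(4):
            sections, rot_true, _ = generate_slide_group(seed=seed)
            tf_g, _ = register_histology_to_autoradiography(
                SlideGroup(sections), iterations=200
            )
            tf_s, _ = register_histology_to_autoradiography(
                SlideGroup([sections[0]], group_constraint=False), iterations=200
            )
            errs_group.append(abs(tf_g.rotation - rot_true))
            errs_single.append(abs(tf_s.rotation - rot_true))
        assert np.median(errs_group) < np.median(errs_single)


class TestStacking:
    def test_aligned_stack_stays_aligned(self, tumor_stack_warped):
        from alphaqar.synthetic import TumorStackSpec, generate_tumor_stack

        spec = TumorStackSpec(
            seed=9, max_rotation_deg=0.0, max_shift_um=0.0, warp_amplitude_um=0.0,
            noise_level=0.0, image_shape=(96, 96),
        )
        raw, _ = generate_tumor_stack(spec)
        sections = sections_from_stack(raw)
        baseline = [largest_component_mask(s.anatomy) for s in sections]
        base_dsc = min(
            dice(baseline[i], baseline[i + 1]) for i in range(len(baseline) - 1)
        )
        stack = stack_sections(
            sections, "activity_only", rigid_iterations=100, similarity_iterations=100
        )
        masks = [largest_component_mask(a) for a in stack.anatomy]
        for i in range(len(masks) - 1):
            assert dice(masks[i], masks[i + 1]) >= base_dsc - 0.01

    def test_known_rotation_recovered(self):
        from alphaqar.synthetic import TumorStackSpec, generate_tumor_stack
        import SimpleITK as sitk

        spec = TumorStackSpec(
            seed=4, max_rotation_deg=10.0, max_shift_um=0.0, warp_amplitude_um=0.0,
            noise_level=0.01, image_shape=(96, 96),
        )
        raw, truth = generate_tumor_stack(spec)
        sections = sections_from_stack(raw)
        stack = stack_sections(
            sections, "activity_only", rigid_iterations=200, similarity_iterations=100
        )
        for i in (0, 2):
            # composed transform: the similarity stage holds the recovered rotation
            composite = sitk.CompositeTransform(stack.transforms[i])
            ang = None
            for k in range(composite.GetNumberOfTransforms()):
                t = composite.GetNthTransform(k)
                if t.GetName() == "Similarity2DTransform":
                    ang = sitk.Similarity2DTransform(t).GetAngle()
            assert ang is not None
            # generator maps section pixel -> reference via rotation by +rot, so
            # the fixed->moving (resampling) transform carries -rot
            assert abs(ang - (-truth.rotations_rad[i])) < math.radians(0.5)

    def test_anatomy_guided_at_least_matches_activity_only(self, tumor_stack_warped):
        _, sections, _ = tumor_stack_warped
        dscs = {}
        for method in ("activity_only", "anatomy_guided"):
            stack = stack_sections(
                sections, method,
                rigid_iterations=120, similarity_iterations=120, bspline_iterations=40,
            )
            masks = [largest_component_mask(a) for a in stack.anatomy]
            dscs[method] = np.mean(
                [dice(masks[i], masks[i + 1]) for i in range(len(masks) - 1)]
            )
        assert dscs["anatomy_guided"] >= dscs["activity_only"]

    def test_unknown_method_rejected(self, tumor_stack_warped):
        _, sections, _ = tumor_stack_warped
        with pytest.raises(ValueError, match="method"):
            stack_sections(sections, "hope")

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stack_sections([], "activity_only")


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:8, 2:8] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_hand_count(self):
        # two 10x10 squares overlapping in a 5x10 strip: 2*50/(100+100) = 0.5
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True
        b[0:10, 5:15] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_empty_empty_convention(self):
        e = np.zeros((5, 5), bool)
        assert dice(e, e) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestCompareStacking:
    def test_identical_pairs_degenerate(self):
        res = compare_stacking([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert res.mean_relative_improvement == 0.0
        assert res.t_statistic is None and res.p_value is None

    def test_t_matches_closed_form(self):
        a = np.array([0.70, 0.75, 0.80, 0.72, 0.68])
        b = np.array([0.78, 0.80, 0.82, 0.79, 0.75])
        res = compare_stacking(a, b)
        d = b - a
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.t_statistic == pytest.approx(t_expected, rel=1e-12)
        p_expected = 2 * stats.t.sf(abs(t_expected), len(d) - 1)
        assert res.p_value == pytest.approx(p_expected, rel=1e-12)

    def test_uniform_ten_percent_improvement(self):
        a = np.array([0.5, 0.6, 0.7])
        res = compare_stacking(a, a * 1.1)
        assert res.mean_relative_improvement == pytest.approx(0.10)

    def test_dsc_bounds_enforced(self):
        with pytest.raises(ValueError):
            compare_stacking([0.5, 1.5], [0.5, 0.5])
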