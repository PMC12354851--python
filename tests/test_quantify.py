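"""Decay-exact quantification: W weights, activity conversion, calibration fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from alphaqar.listmode import AcquisitionSchedule, CountsImage
from alphaqar.quantify import (
    AC225,
    CalibrationSample,
    Isotope,
    activity_at_reference,
    constant_activity_error,
    decay_weight,
    detector_efficiency,
    fit_sensitivity,
)

HOUR = 3600.0
DAY = 86400.0


class TestDecayWeight:
    def test_effectively_infinite_window_gives_one(self):
        sched = AcquisitionSchedule.from_pairs([(0.0, 1e6 * DAY)])
        assert decay_weight(sched, AC225) == pytest.approx(1.0)

    def test_one_half_life_gives_half(self):
        sched = AcquisitionSchedule.from_pairs([(0.0, AC225.half_life_s)])
        assert decay_weight(sched, AC225) == pytest.approx(0.5)

    def test_two_windows_match_quadrature_oracle(self):
        """W over (0,1d) and (2d,3d) equals the integral of lambda e^{-lambda t}."""
        sched = AcquisitionSchedule.from_pairs([(0.0, 1 * DAY), (2 * DAY, 3 * DAY)])
        lam = AC225.decay_constant
        oracle = sum(
            quad(lambda t: lam * math.exp(-lam * t), a, b)[0]
            for a, b in [(0, DAY), (2 * DAY, 3 * DAY)]
        )
        assert decay_weight(sched, AC225) == pytest.approx(oracle, rel=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        start=st.floats(0, 5 * DAY),
        dur=st.floats(1 * HOUR, 5 * DAY),
        split=st.floats(0.1, 0.9),
    )
    def test_splitting_window_preserves_weight(self, start, dur, split):
        whole = AcquisitionSchedule.from_pairs([(start, start + dur)])
        mid = start + split * dur
        parts = AcquisitionSchedule.from_pairs([(start, mid), (mid, start + dur)])
        assert decay_weight(parts, AC225) == pytest.approx(
            decay_weight(whole, AC225), rel=1e-12
        )


class TestActivityAtReference:
    def test_forward_model_inversion(self):
        """Counts constructed from N0 atoms recover A0 = lambda*N0 exactly."""
        n0 = 1e6
        f = 1.77
        lam = AC225.decay_constant
        sched = AcquisitionSchedule.from_pairs([(0.0, 60 * HOUR)])
        counts = f * n0 * (1 - math.exp(-lam * 60 * HOUR))
        a0 = activity_at_reference(counts, f, AC225, sched)
        assert a0 == pytest.approx(lam * n0, rel=1e-12)

    def test_limiting_form_total_decay(self):
        sched = AcquisitionSchedule.from_pairs([(0.0, 1e6 * DAY)])
        assert activity_at_reference(100.0, 1.0, AC225, sched) == pytest.approx(
            AC225.decay_constant * 100.0
        )

    def test_zero_counts_zero_activity(self, schedule_60h):
        assert activity_at_reference(0.0, 1.77, AC225, schedule_60h) == 0.0

    def test_image_in_image_out(self, schedule_60h):
        img = CountsImage(np.array([[0, 10], [20, 40]]), pixel_spacing=26.5)
        act = activity_at_reference(img, 1.77, AC225, schedule_60h)
        assert act.activity.shape == (2, 2)
        assert act.activity[0, 0] == 0.0
        assert act.activity[1, 1] == pytest.approx(2 * act.activity[1, 0])

    def test_degenerate_schedule_raises(self):
        short = Isotope("fast", half_life_s=1.0, alphas_per_primary=1, alpha_energies_mev=(6.0,))
        late = AcquisitionSchedule.from_pairs([(5000.0, 6000.0)])
        with pytest.raises(ValueError, match="degenerate"):
            activity_at_reference(10.0, 1.0, short, late)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(counts=st.floats(0, 1e6), f=st.floats(0.1, 5.0), scale=st.floats(0.5, 4.0))
    def test_linear_in_counts_inverse_in_f(self, counts, f, scale):
        sched = AcquisitionSchedule.from_pairs([(0.0, 60 * HOUR)])
        base = activity_at_reference(counts, f, AC225, sched)
        assert activity_at_reference(counts * scale, f, AC225, sched) == pytest.approx(
            base * scale, rel=1e-12
        )
        assert activity_at_reference(counts, f * scale, AC225, sched) == pytest.approx(
            base / scale, rel=1e-12
        )


class TestConstantActivityError:
    def test_matches_quadrature_oracle(self):
        """Trapezoid-of-endpoints vs exact exponential average, brute force."""
        lam = AC225.decay_constant
        for hours in (10.0, 60.0, 168.0, 336.0, 1000.0):
            T = hours * HOUR
            exact_mean = quad(lambda t: math.exp(-lam * t), 0, T)[0] / T
            trapezoid = 0.5 * (1 + math.exp(-lam * T))
            oracle = trapezoid / exact_mean - 1.0
            assert constant_activity_error(T, AC225) == pytest.approx(oracle, rel=1e-10)

    def test_vanishes_for_short_acquisitions(self):
        assert constant_activity_error(1.0, AC225) < 1e-12

    def test_strictly_increasing_in_duration(self):
        durations = np.linspace(1 * HOUR, 30 * DAY, 50)
        errs = [constant_activity_error(t, AC225) for t in durations]
        assert all(b > a for a, b in zip(errs, errs[1:]))

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            constant_activity_error(0.0, AC225)


class TestSensitivityFit:
    @staticmethod
    def _dilution_series(f, activities, hours=82.0, rng=None):
        sched = AcquisitionSchedule.from_pairs([(0.0, hours * HOUR)])
        samples = []
        for a in activities:
            n_primary = (a / AC225.decay_constant) * decay_weight(sched, AC225)
            counts = f * n_primary
            if rng is not None:
                counts = rng.poisson(counts)
            samples.append(CalibrationSample(a, counts, sched))
        return samples

    def test_noiseless_recovery(self):
        samples = self._dilution_series(1.77, [0.05, 0.5, 5.0, 50.0])
        res = fit_sensitivity(samples)
        assert res.sensitivity_factor == pytest.approx(1.77, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)
        assert not res.low_confidence

    def test_poisson_noise_within_three_se(self):
        rng = np.random.default_rng(11)
        estimates = []
        for _ in range(10):
            samples = self._dilution_series(1.77, [0.05, 0.2, 1.0, 5.0, 20.0], rng=rng)
            estimates.append(fit_sensitivity(samples).sensitivity_factor)
        est = np.asarray(estimates)
        se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - 1.77) < 3 * max(se, 1e-6)

    def test_single_sample_is_plain_ratio(self):
        samples = self._dilution_series(2.5, [1.0])
        res = fit_sensitivity(samples)
        assert res.sensitivity_factor == pytest.approx(2.5, rel=1e-12)
        assert res.low_confidence

    def test_all_zero_counts_rejected(self):
        sched = AcquisitionSchedule.from_pairs([(0.0, HOUR)])
        with pytest.raises(ValueError, match="zero"):
            fit_sensitivity([CalibrationSample(1.0, 0, sched)])

    def test_recovered_activity_on_identity_line(self):
        samples = self._dilution_series(1.77, [0.1, 1.0, 10.0])
        res = fit_sensitivity(samples)
        np.testing.assert_allclose(res.recovered_activity_bq, [0.1, 1.0, 10.0], rtol=1e-9)


class TestDetectorEfficiency:
    @pytest.mark.parametrize(
        "f,alphas,expected",
        [(1.77, 4, 0.885), (2.0, 4, 1.0), (0.5, 1, 1.0)],
    )
    def test_values(self, f, alphas, expected):
        assert detector_efficiency(f, alphas) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detector_efficiency(0.0, 4)
        with pytest.raises(ValueError):
            detector_efficiency(1.0, 0)
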