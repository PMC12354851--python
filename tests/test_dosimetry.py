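"""Alpha range model, dose-voxel kernel Monte Carlo, convolution and DVH."""

import numpy as np
import pytest

from alphaqar.dosimetry import (
    MEV_TO_J,
    ActivityVolume,
    DVHCurve,
    alpha_energy_from_range,
    alpha_range,
    cumulative_dvh,
    dose_rate_map,
    generate_dvk,
    stopping_power,
)
from alphaqar.quantify import AC225, SINGLE_ALPHA_TEST


class TestAlphaRange:
    def test_zero_energy_zero_range(self):
        assert alpha_range(0.0) == 0.0

    def test_strictly_increasing(self):
        es = np.linspace(0.1, 10.0, 50)
        rs = alpha_range(es)
        assert (np.diff(rs) > 0).all()

    def test_consistent_with_tabulated_water_ranges(self):
        # alpha CSDA ranges in liquid water: ~85-90 um at 8.4 MeV, ~45-50 um
        # at 5.8 MeV; all chain alphas stop within ~100 um
        assert 60.0 <= alpha_range(8.375) <= 100.0
        assert 40.0 <= alpha_range(5.83) <= 55.0
        assert alpha_range(max(AC225.alpha_energies_mev)) < 100.0

    def test_inverse_round_trip(self):
        es = np.array([1.0, 5.0, 8.375])
        np.testing.assert_allclose(alpha_energy_from_range(alpha_range(es)), es, rtol=1e-12)

    def test_stopping_power_is_range_derivative(self):
        e = 6.0
        h = 1e-5
        numeric = h / (alpha_range(e + h / 2) - alpha_range(e - h / 2))
        assert stopping_power(e) == pytest.approx(numeric, rel=1e-6)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            alpha_range(-1.0)


@pytest.fixture(scope="module")
def small_kernel():
    return generate_dvk(AC225, n_primaries=20_000, seed=1)


@pytest.fixture(scope="module")
def kernel():
    return generate_dvk(AC225, n_primaries=50_000, seed=2)


class TestGenerateDvk:
    def test_chain_multiplicity_logged(self, small_kernel):
        assert small_kernel.n_alphas_emitted == 4 * small_kernel.n_primaries

    def test_energy_conservation(self, small_kernel):
        total = small_kernel.total_energy_per_primary_mev()
        expected = sum(AC225.alpha_energies_mev)
        assert abs(total - expected) / expected < 0.01

    def test_central_voxel_is_maximum(self, small_kernel):
        assert small_kernel.central_is_max()

    def test_mirror_symmetry_within_mc_noise(self, small_kernel):
        d = small_kernel.dose
        for flipped in (d[::-1], d[:, ::-1], d[:, :, ::-1]):
            assert np.abs(d - flipped).max() / d.max() < 0.02

    def test_single_track_confined_to_range(self):
        kern = generate_dvk(
            SINGLE_ALPHA_TEST,
            voxel_dims_um=(28.0, 26.5, 26.5),
            n_primaries=1,
            seed=0,
            _fixed_direction=np.array([0.0, 0.0, 1.0]),  # +x
        )
        r = alpha_range(SINGLE_ALPHA_TEST.alpha_energies_mev[0])
        nz, ny, nx = kern.dose.shape
        cz, cy, cx = nz // 2, ny // 2, nx // 2
        hits = np.argwhere(kern.dose > 0)
        dists = np.linalg.norm(
            (hits - [cz, cy, cx]) * np.array(kern.voxel_dims_um), axis=1
        )
        diag = np.linalg.norm(kern.voxel_dims_um)
        assert dists.max() <= r + diag
        # track along +x: no deposition off the source row beyond one voxel
        assert set(hits[:, 0]) <= {cz} and set(hits[:, 1]) <= {cy}

    def test_too_small_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            generate_dvk(AC225, kernel_extent=1, n_primaries=10, seed=0)

    def test_seed_reproducibility(self):
        a = generate_dvk(AC225, n_primaries=2000, seed=7)
        b = generate_dvk(AC225, n_primaries=2000, seed=7)
        np.testing.assert_array_equal(a.dose, b.dose)


class TestDoseRateMap:
    def test_delta_input_reproduces_kernel(self, kernel):
        nz, ny, nx = 13, 21, 21
        act = np.zeros((nz, ny, nx))
        act[6, 10, 10] = 2.5
        vol = ActivityVolume(act, np.arange(nz) * 28.0, 26.5)
        rate = dose_rate_map(vol, kernel)
        kz, ky, kx = kernel.dose.shape
        sub = rate.dose_rate[
            6 - kz // 2 : 6 + kz // 2 + 1,
            10 - ky // 2 : 10 + ky // 2 + 1,
            10 - kx // 2 : 10 + kx // 2 + 1,
        ]
        ref = 2.5 * 3600.0 * kernel.dose
        np.testing.assert_allclose(sub, ref, rtol=1e-9, atol=1e-9 * ref.max())

    def test_equilibrium_closed_form(self, kernel):
        nz, ny, nx = 11, 31, 31
        a = 0.4
        vol = ActivityVolume(np.full((nz, ny, nx), a), np.arange(nz) * 28.0, 26.5)
        rate = dose_rate_map(vol, kernel)
        center = rate.dose_rate[nz // 2, ny // 2, nx // 2]
        closed = a * 3600.0 * sum(AC225.alpha_energies_mev) * MEV_TO_J / kernel.voxel_mass_kg
        assert abs(center - closed) / closed < 0.01

    def test_linearity_in_activity(self, kernel):
        rng = np.random.default_rng(3)
        act = rng.random((11, 15, 15))
        vol1 = ActivityVolume(act, np.arange(11) * 28.0, 26.5)
        vol2 = ActivityVolume(2 * act, np.arange(11) * 28.0, 26.5)
        r1 = dose_rate_map(vol1, kernel)
        r2 = dose_rate_map(vol2, kernel)
        np.testing.assert_allclose(r2.dose_rate, 2 * r1.dose_rate, rtol=1e-9, atol=1e-30)

    def test_grid_mismatch_rejected(self, kernel):
        vol = ActivityVolume(np.ones((5, 8, 8)), np.arange(5) * 14.0, 26.5)
        with pytest.raises(ValueError, match="mismatch"):
            dose_rate_map(vol, kernel)  # kernel dz is 28 um, stack is 14 um

    def test_edge_truncation_warned(self, kernel):
        vol = ActivityVolume(np.ones((3, 8, 8)), np.arange(3) * 28.0, 26.5)
        with pytest.warns(UserWarning, match="z-extent"):
            dose_rate_map(vol, kernel)


class TestCumulativeDvh:
    def test_uniform_dose_rate_is_step(self):
        rates = np.full((4, 4, 4), 2.0)
        curve = cumulative_dvh(rates, mask=np.ones((4, 4, 4), bool), n_thresholds=100)
        below = curve.thresholds <= 2.0
        np.testing.assert_allclose(curve.volume_fraction[below], 1.0)
        assert curve.volume_fraction[-1] == 0.0

    def test_two_level_hand_count(self):
        rates = np.concatenate([np.full(50, 1.0), np.full(50, 10.0)])
        curve = cumulative_dvh(rates, mask=np.ones(100, bool), n_thresholds=200)
        f = np.interp(0.5, curve.thresholds, curve.volume_fraction)
        assert f == pytest.approx(1.0)
        f5 = curve.volume_fraction[np.searchsorted(curve.thresholds, 5.0)]
        assert f5 == pytest.approx(0.5)

    def test_invariants_on_random_map(self):
        rng = np.random.default_rng(4)
        rates = rng.exponential(1.0, (6, 10, 10))
        curve = cumulative_dvh(rates, mask=rng.random((6, 10, 10)) > 0.3)
        assert curve.volume_fraction[0] == 1.0
        assert (np.diff(curve.volume_fraction) <= 1e-12).all()
        assert curve.volume_fraction[-1] == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cumulative_dvh(np.ones((3, 3)), mask=np.zeros((3, 3), bool))

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError, match="monotone"):
            DVHCurve(np.array([0.0, 1.0]), np.array([1.0, 1.1]))
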