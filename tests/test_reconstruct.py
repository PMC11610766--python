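"""Image reconstruction: Beer-Lambert reweighting, per-pixel estimators,
lens projection, binning, filtering, spectral interpolation."""
import numpy as np
import pytest

from cortexmc.reconstruct import (SensorGeometry, SpectralCube, denoise_nlm,
                                  interpolate_cube, mean_pathlength_image,
                                  photon_weight, pooled_spectra,
                                  project_through_lens, reflectance_image,
                                  spatial_binning)
from cortexmc.transport import PhotonBatch


def _toy_batch(exit_x, exit_y, ppl, n_launched, theta=None):
    n = len(exit_x)
    ppl = np.asarray(ppl, dtype=float)
    if theta is None:
        theta = np.zeros(n)
    return PhotonBatch(
        wavelength=500.0, n_launched=n_launched,
        exit_x=np.asarray(exit_x, dtype=float),
        exit_y=np.asarray(exit_y, dtype=float),
        theta_x=np.asarray(theta, dtype=float),
        theta_y=np.zeros(n),
        ppl=ppl, total_path=ppl.sum(axis=1),
        region_names=("grey_matter",) * ppl.shape[1], seed=0)


class TestPhotonWeight:
    def test_white_limit_is_unity(self):
        assert photon_weight(np.array([3.0, 4.0]), [0.0, 0.0]) == 1.0

    def test_closed_form_single_region(self):
        assert photon_weight(np.array([10.0]), [0.1]) == pytest.approx(
            np.exp(-1.0), rel=1e-12)

    def test_exponential_additivity(self):
        ppl = np.array([2.0, 5.0])
        a, b = np.array([0.1, 0.02]), np.array([0.3, 0.01])
        assert photon_weight(ppl, a) * photon_weight(ppl, b) == pytest.approx(
            photon_weight(ppl, a + b), rel=1e-12)

    def test_negative_mua_rejected(self):
        with pytest.raises(ValueError):
            photon_weight(np.array([1.0]), [-0.1])


class TestImagesAgainstBruteForce:
    """The vectorized estimators must equal explicit per-photon loops."""

    def _brute_force(self, batch, mua, geom):
        ny, nx = geom.shape
        wsum = np.zeros((ny, nx))
        pwsum = np.zeros((ny, nx))
        for j in range(batch.n_detected):
            w = 1.0
            for i in range(batch.ppl.shape[1]):
                w *= np.exp(-mua[i] * batch.ppl[j, i])
            row = int(np.floor(batch.exit_x[j] / geom.pitch_mm))
            col = int(np.floor(batch.exit_y[j] / geom.pitch_mm))
            if 0 <= col < nx and 0 <= row < ny:
                wsum[row, col] += w
                pwsum[row, col] += w * batch.ppl[j].sum()
        phi = wsum / (batch.n_launched * geom.pixel_area_mm2)
        L = np.divide(pwsum, wsum, out=np.zeros_like(wsum), where=wsum > 0)
        return phi, L

    def test_reflectance_and_pathlength_match_loops(self, slab_batch_500):
        vol, batch = slab_batch_500
        geom = SensorGeometry(shape=(8, 8), pitch_mm=1.0)
        mua = np.array([0.08])
        phi = reflectance_image(batch, mua, geom)
        L, valid = mean_pathlength_image(batch, mua, geom)
        phi_bf, L_bf = self._brute_force(batch, mua, geom)
        np.testing.assert_allclose(phi, phi_bf, rtol=1e-10)
        np.testing.assert_allclose(L, L_bf, rtol=1e-10)
        assert np.array_equal(valid, phi_bf > 0)

    def test_total_weight_equals_detected_fraction_in_white_limit(
            self, slab_batch_500):
        vol, batch = slab_batch_500
        geom = SensorGeometry(shape=(8, 8), pitch_mm=1.0)
        phi = reflectance_image(batch, [0.0], geom)
        total = phi.sum() * geom.pixel_area_mm2
        assert total == pytest.approx(batch.detected_fraction, rel=1e-10)


class TestToyImages:
    def test_single_photon_single_pixel(self):
        b = _toy_batch([0.5], [0.5], [[3.0]], n_launched=1)
        geom = SensorGeometry(shape=(2, 2), pitch_mm=1.0)
        phi = reflectance_image(b, [0.0], geom)
        assert phi[0, 0] == 1.0 and phi.sum() == 1.0

    def test_mean_path_equal_weights(self):
        b = _toy_batch([0.5, 0.5], [0.5, 0.5], [[1.0], [3.0]], n_launched=2)
        geom = SensorGeometry(shape=(1, 1), pitch_mm=1.0)
        L, valid = mean_pathlength_image(b, [0.0], geom)
        assert L[0, 0] == pytest.approx(2.0)
        assert valid[0, 0]

    def test_absorbing_the_long_path_lowers_mean_path(self):
        b = _toy_batch([0.5, 0.5], [0.5, 0.5], [[1.0], [3.0]], n_launched=2)
        geom = SensorGeometry(shape=(1, 1), pitch_mm=1.0)
        L0, _ = mean_pathlength_image(b, [0.0], geom)
        L1, _ = mean_pathlength_image(b, [0.5], geom)
        assert L1[0, 0] < L0[0, 0]

    def test_empty_pixels_flagged_invalid(self):
        b = _toy_batch([0.5], [0.5], [[1.0]], n_launched=1)
        geom = SensorGeometry(shape=(2, 2), pitch_mm=1.0)
        L, valid = mean_pathlength_image(b, [0.0], geom)
        assert valid.sum() == 1
        assert L[~valid].sum() == 0.0

    def test_doubling_pixel_area_halves_phi(self):
        b = _toy_batch([0.25], [0.25], [[1.0]], n_launched=4)
        phi1 = reflectance_image(b, [0.0],
                                 SensorGeometry(shape=(2, 2), pitch_mm=0.5))
        phi2 = reflectance_image(b, [0.0],
                                 SensorGeometry(shape=(1, 1),
                                                pitch_mm=0.5 * np.sqrt(2)))
        assert phi2.max() == pytest.approx(0.5 * phi1.max())


class TestLensProjection:
    def test_imaging_condition_gives_pure_magnification(self):
        # 1/d0 + 1/s = 1/f0 with f0=50, d0=75, s=150 -> magnification -2
        geom = SensorGeometry(shape=(4, 4), pitch_mm=1.0, mode="lens",
                              f0=50.0, d0=75.0, s=150.0)
        S = geom.system_matrix()
        assert S[0, 1] == pytest.approx(0.0, abs=1e-12)  # B vanishes
        assert S[0, 0] == pytest.approx(-2.0)            # A = -s/d0
        xs, _ = project_through_lens(1.0, 0.0, 0.0, 0.0, geom)
        assert xs == pytest.approx(-2.0)

    def test_angle_independence_at_imaging_condition(self):
        geom = SensorGeometry(shape=(4, 4), pitch_mm=1.0, mode="lens",
                              f0=50.0, d0=75.0, s=150.0)
        xs1, _ = project_through_lens(1.0, 0.0, 0.3, 0.0, geom)
        xs2, _ = project_through_lens(1.0, 0.0, -0.2, 0.0, geom)
        assert xs1 == pytest.approx(xs2)

    def test_surface_and_identity_lens_agree(self, slab_batch_500):
        """A degenerate lens (huge f0, tiny distances) reproduces the
        surface-mode image."""
        _, batch = slab_batch_500
        surf = SensorGeometry(shape=(8, 8), pitch_mm=1.0)
        lens = SensorGeometry(shape=(8, 8), pitch_mm=1.0, mode="lens",
                              f0=1e12, d0=1e-9, s=1e-9)
        phi_s = reflectance_image(batch, [0.05], surf)
        phi_l = reflectance_image(batch, [0.05], lens)
        np.testing.assert_allclose(phi_l, phi_s, rtol=1e-9)

    def test_lens_mode_requires_geometry(self):
        with pytest.raises(ValueError):
            SensorGeometry(shape=(4, 4), pitch_mm=1.0, mode="lens")


def _small_cube(seed=0, ny=10, nx=10, nl=3):
    rng = np.random.default_rng(seed)
    phi = rng.random((ny, nx, nl)) + 0.1
    L = rng.random((ny, nx, nl)) * 5 + 1
    return SpectralCube(phi=phi, pathlength=L,
                        valid=np.ones(phi.shape, dtype=bool),
                        wavelengths=np.array([500.0, 600.0, 700.0]),
                        pitch_mm=0.073)


class TestBinning:
    def test_factor_one_is_identity(self):
        cube = _small_cube()
        assert spatial_binning(cube, 1) is cube

    def test_five_by_five_binning_of_73um_pixels(self):
        cube = _small_cube()
        binned = spatial_binning(cube, 5)
        assert binned.pitch_mm == pytest.approx(0.365)  # 365 um
        assert binned.phi.shape[:2] == (2, 2)

    def test_binned_pathlength_equals_direct_coarse_estimate(
            self, slab_batch_500):
        """Binning the fine-grid images equals rebuilding on the coarse grid."""
        _, batch = slab_batch_500
        fine = SensorGeometry(shape=(8, 8), pitch_mm=1.0)
        coarse = SensorGeometry(shape=(2, 2), pitch_mm=4.0)
        mua = np.array([0.05])
        phi_f = reflectance_image(batch, mua, fine)
        L_f, valid_f = mean_pathlength_image(batch, mua, fine)
        cube = SpectralCube(phi=phi_f[:, :, None], pathlength=L_f[:, :, None],
                            valid=valid_f[:, :, None],
                            wavelengths=np.array([500.0]), pitch_mm=1.0)
        binned = spatial_binning(cube, 4)
        phi_c = reflectance_image(batch, mua, coarse)
        L_c, _ = mean_pathlength_image(batch, mua, coarse)
        np.testing.assert_allclose(binned.phi[:, :, 0], phi_c, rtol=1e-10)
        np.testing.assert_allclose(binned.pathlength[:, :, 0], L_c, rtol=1e-10)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            spatial_binning(_small_cube(), 0)


class TestDenoise:
    def test_constant_image_unchanged(self):
        cube = _small_cube()
        cube.phi[:] = 0.7
        cube.pathlength[:] = 2.0
        out = denoise_nlm(cube)
        np.testing.assert_allclose(out.phi, 0.7)
        np.testing.assert_allclose(out.pathlength, 2.0)

    def test_zero_strength_is_identity(self):
        cube = _small_cube()
        out = denoise_nlm(cube, h_factor=0.0)
        np.testing.assert_array_equal(out.phi, cube.phi)

    def test_noise_variance_reduced_on_homogeneous_region(self):
        rng = np.random.default_rng(3)
        base = np.full((24, 24, 1), 1.0)
        noisy = base + rng.normal(0, 0.1, base.shape)
        cube = SpectralCube(phi=np.abs(noisy), pathlength=np.abs(noisy),
                            valid=np.ones(base.shape, dtype=bool),
                            wavelengths=np.array([500.0]), pitch_mm=0.073)
        out = denoise_nlm(cube)
        assert out.phi.var() < cube.phi.var()


class TestSpectralInterpolation:
    def test_exact_at_simulated_wavelengths(self):
        cube = _small_cube()
        out = interpolate_cube(cube)
        assert out.wavelengths[0] == 500.0 and out.wavelengths[-1] == 700.0
        for lam in cube.wavelengths:
            k_in = int(np.where(cube.wavelengths == lam)[0][0])
            k_out = int(np.where(out.wavelengths == lam)[0][0])
            np.testing.assert_allclose(out.phi[:, :, k_out],
                                       cube.phi[:, :, k_in], rtol=1e-12)

    def test_linear_between_nodes(self):
        cube = _small_cube()
        out = interpolate_cube(cube)
        k = int(np.where(out.wavelengths == 550.0)[0][0])
        np.testing.assert_allclose(
            out.phi[:, :, k],
            0.5 * (cube.phi[:, :, 0] + cube.phi[:, :, 1]), rtol=1e-12)

    def test_extrapolation_rejected(self):
        with pytest.raises(ValueError):
            interpolate_cube(_small_cube(), np.array([400.0]))


def test_pooled_spectra_match_superpixel_definition():
    cube = _small_cube(seed=5)
    mask = np.zeros((10, 10), dtype=bool)
    mask[2:6, 3:8] = True
    phi, L = pooled_spectra(cube, mask)
    np.testing.assert_allclose(phi, cube.phi[mask].mean(axis=0))
    want_L = ((cube.phi[mask] * cube.pathlength[mask]).sum(axis=0)
              / cube.phi[mask].sum(axis=0))
    np.testing.assert_allclose(L, want_L)


def test_cube_hdf5_round_trip(tmp_path):
    cube = _small_cube(seed=9)
    path = tmp_path / "cube.h5"
    cube.to_hdf5(path)
    back = SpectralCube.from_hdf5(path)
    np.testing.assert_array_equal(back.phi, cube.phi)
    np.testing.assert_array_equal(back.pathlength, cube.pathlength)
    np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)
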