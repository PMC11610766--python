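"""Modified Beer-Lambert quantification: activation chemistry, noisy
attenuation changes, least-squares inversion, error summaries."""
import numpy as np
import pytest

from cortexmc.quantify import (ActivationModel,
                               MBLLSystem, NoiseModel, activated_composition,
                               attenuation_change, mbll_solve, quantify_noisy,
                               rmse)
from cortexmc.spectra import TissueComposition, absorption_coefficient


class TestActivationChemistry:
    def test_default_ground_truth_vector(self):
        act = ActivationModel()
        gt = act.ground_truth_M(("HbO2", "Hb", "oxCCO", "oxCytb", "oxCytc"))
        np.testing.assert_allclose(gt * 1e6, [5.0, -3.75, 0.5, 0.5, 0.5])

    def test_cytochrome_totals_conserved(self, compositions):
        rest = compositions["grey_matter"]
        act = activated_composition(rest, ActivationModel())
        assert act.c_oxcco_uM + act.c_redcco_uM == pytest.approx(
            rest.c_oxcco_uM + rest.c_redcco_uM)
        assert act.c_oxcytb_uM + act.c_redcytb_uM == pytest.approx(
            rest.c_oxcytb_uM + rest.c_redcytb_uM)
        assert act.c_oxcco_uM == pytest.approx(rest.c_oxcco_uM + 0.5)

    def test_hemoglobin_changes_change_total_and_saturation(self, compositions):
        rest = compositions["grey_matter"]
        act = activated_composition(rest, ActivationModel())
        assert act.c_hbo2_uM == pytest.approx(rest.c_hbo2_uM + 5.0)
        assert act.c_hb_uM == pytest.approx(rest.c_hb_uM - 3.75)

    def test_difference_spectra_equal_explicit_redox_bookkeeping(
            self, compositions, lib):
        """Applying +dC/-dC to the ox/red states changes mu_a by exactly
        ln(10) * eps_ox-red * dC."""
        rest = compositions["grey_matter"]
        act = activated_composition(
            rest, ActivationModel(dc_uM={"oxCCO": 0.5}))
        lam = np.arange(400.0, 1001.0, 50.0)
        d_mua = (absorption_coefficient(act, lib, lam)
                 - absorption_coefficient(rest, lib, lam))
        want = np.log(10) * lib.epsilon("ox-redCCO", lam) * 0.5e-6
        np.testing.assert_allclose(d_mua, want, rtol=1e-9, atol=1e-15)


class TestAttenuationChange:
    def test_noise_free_log_ratio(self):
        dA = attenuation_change(np.array([2.0]), np.array([1.0]), noise=None)
        assert dA[0, 0] == pytest.approx(np.log10(2.0))

    def test_no_change_no_noise_is_zero(self):
        dA = attenuation_change(np.array([1.5]), np.array([1.5]), noise=None)
        assert dA[0, 0] == 0.0

    def test_mean_over_draws_approaches_noise_free_value(self):
        noise = NoiseModel(snr=400, n_noise=4000, seed=1)
        phi_r = np.array([2.0, 1.0])
        phi_a = np.array([1.8, 0.9])
        dA = attenuation_change(phi_r, phi_a, noise)
        assert dA.shape == (4000, 2)
        exact = np.log10(phi_r / phi_a)
        se = dA.std(axis=0) / np.sqrt(noise.n_noise)
        assert np.all(np.abs(dA.mean(axis=0) - exact) < 4 * se + 1e-6)

    def test_shared_sigma_uses_mean_rest_reflectance(self):
        noise = NoiseModel(snr=100, shared_sigma=True)
        sig = noise.sigma(np.array([1.0, 3.0]))
        np.testing.assert_allclose(sig, [0.02, 0.02])
        per = NoiseModel(snr=100, shared_sigma=False).sigma(np.array([1.0, 3.0]))
        np.testing.assert_allclose(per, [0.01, 0.03])

    def test_reproducible_for_fixed_seed(self):
        noise = NoiseModel(seed=7, n_noise=10)
        a = attenuation_change(np.array([1.0]), np.array([0.9]), noise)
        b = attenuation_change(np.array([1.0]), np.array([0.9]), noise)
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_reflectance_rejected(self):
        with pytest.raises(ValueError):
            attenuation_change(np.array([0.0]), np.array([1.0]), None)


class TestMBLLSolve:
    def _system(self, lib, lam, chroms, L=None):
        lam = np.asarray(lam, dtype=float)
        if L is None:
            L = np.full(lam.shape, 3.0)
        return MBLLSystem.build(lam, L, lib, chroms)

    def test_square_system_recovers_exactly(self, lib):
        chroms = ("HbO2", "Hb", "oxCCO")
        sys3 = self._system(lib, [490, 600, 830], chroms)
        dc_true = np.array([5e-6, -3.75e-6, 0.5e-6])
        dA = sys3.matrix @ dc_true
        dc = mbll_solve(dA, sys3)[0]
        np.testing.assert_allclose(dc, dc_true, rtol=1e-9)

    def test_consistent_overdetermined_system_recovers_exactly(self, lib):
        chroms = ("HbO2", "Hb")
        sys2 = self._system(lib, np.arange(700.0, 901.0, 20.0), chroms)
        dc_true = np.array([5e-6, -3.75e-6])
        dA = sys2.matrix @ dc_true
        dc = mbll_solve(dA, sys2)[0]
        np.testing.assert_allclose(dc, dc_true, rtol=1e-9)

    def test_halving_pathlength_doubles_estimates(self, lib):
        chroms = ("HbO2", "Hb")
        lam = np.array([500.0, 560.0, 600.0])
        s_full = self._system(lib, lam, chroms, L=np.full(3, 4.0))
        s_half = self._system(lib, lam, chroms, L=np.full(3, 2.0))
        dA = s_full.matrix @ np.array([5e-6, -3.75e-6])
        np.testing.assert_allclose(mbll_solve(dA, s_half)[0],
                                   2 * mbll_solve(dA, s_full)[0], rtol=1e-9)

    def test_rank_deficient_design_names_wavelengths(self, lib):
        # duplicated wavelength rows cannot separate two chromophores
        sys_bad = self._system(lib, [800.0, 800.0], ("HbO2", "Hb"))
        with pytest.raises(np.linalg.LinAlgError, match="800"):
            mbll_solve(np.array([0.1, 0.1]), sys_bad)

    def test_fewer_wavelengths_than_chromophores_rejected(self, lib):
        with pytest.raises(ValueError):
            self._system(lib, [800.0], ("HbO2", "Hb"))


class TestRMSE:
    def test_perfect_estimates_have_zero_error(self):
        est = np.tile([1.0, 2.0], (10, 1))
        np.testing.assert_allclose(rmse(est, np.array([1.0, 2.0])), 0.0)

    def test_hand_computed_two_draws(self):
        est = np.array([[3.0], [4.0]])
        assert rmse(est, np.array([0.0]))[0] == pytest.approx(np.sqrt(12.5))

    def test_error_scales_inversely_with_snr(self, lib):
        """In the noise-dominated regime RMSE is proportional to 1/SNR."""
        lam = np.arange(760.0, 901.0, 20.0)
        L = np.full(lam.shape, 3.0)
        system = MBLLSystem.build(lam, L, lib, ("HbO2", "Hb"))
        phi_r = np.full(lam.shape, 1.0)
        dc_true = np.array([5e-6, -3.75e-6])
        phi_a = phi_r * 10 ** (-(system.matrix @ dc_true))
        out = {}
        for snr in (400.0, 800.0):
            noise = NoiseModel(snr=snr, n_noise=3000, seed=11)
            dA = attenuation_change(phi_r, phi_a, noise)
            dc = mbll_solve(dA, system)
            out[snr] = rmse(dc, dc_true)
        ratio = out[400.0] / out[800.0]
        np.testing.assert_allclose(ratio, 2.0, rtol=0.1)


class TestPipelineRecovery:
    def test_uniform_activation_recovered_in_linear_limit(
            self, uniform_sim_small_dc):
        """Whole-volume activation + small step: the inversion recovers the
        ground truth within ~1% for the 3-chromophore design."""
        ctx = uniform_sim_small_dc.context
        lam = np.array([440.0, 480.0, 520.0, 560.0, 600.0, 740.0, 800.0,
                        860.0])
        phi_r, phi_a, L = ctx.sample(lam)
        # every perturbed chromophore must be in the design, otherwise its
        # attenuation signal aliases into the others
        chroms = ("HbO2", "Hb", "oxCCO", "oxCytb", "oxCytc")
        res = quantify_noisy(phi_r, phi_a, L, lam, ctx.lib, chroms,
                             ctx.activation, noise=None)
        for c in ("HbO2", "Hb", "oxCCO"):
            gt = ctx.activation.dc_uM[c]
            assert res[c]["bias_uM"] == pytest.approx(0.0, abs=0.02 * abs(gt))

    def test_zero_activation_changes_nothing(self, compositions, lib):
        rest = compositions["grey_matter"]
        act = activated_composition(rest, ActivationModel(dc_uM={}))
        lam = np.arange(400.0, 1001.0, 100.0)
        np.testing.assert_allclose(absorption_coefficient(act, lib, lam),
                                   absorption_coefficient(rest, lib, lam),
                                   rtol=1e-12)

    def test_partial_volume_biases_noise_free_estimates(self, activation_sim):
        """With 50% lateral activation, NIR photons sample non-activated
        tissue: noise-free HbO2 estimates fall below the ground truth."""
        ctx = activation_sim.context
        lam = np.arange(780.0, 901.0, 10.0)
        phi_r, phi_a, L = ctx.sample(lam)
        res = quantify_noisy(phi_r, phi_a, L, lam, ctx.lib, ("HbO2", "Hb"),
                             ctx.activation, noise=None)
        est_hbo2 = res["HbO2"]["bias_uM"] + 5.0
        assert 0.0 < est_hbo2 < 5.0
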