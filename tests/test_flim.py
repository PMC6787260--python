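"""Decay fitting, FRET-fraction maps, E_D and K_D^eff estimation."""

import numpy as np
import pytest

from fcsflim import errors
from fcsflim.flim import (
    LifetimeModel,
    cell_fret_fraction,
    dimer_protomer_fraction,
    dimerisation_efficiency,
    estimate_kd_eff,
    fit_fret_fraction,
    fit_monoexp,
    fret_map,
)
from fcsflim.synthetic import (
    DimerPopulationConfig,
    FlimSimConfig,
    simulate_dimer_population,
    simulate_flim_cell,
)
from fcsflim.tcspc import DecayHistogram, FlimImage

from conftest import synthetic_decay


class TestMonoExp:
    def test_noiseless_histogram_recovers_tau(self, lifetime_model):
        decay = synthetic_decay(0.0, lifetime_model, n_photons=1e6, bg_fraction=0.0)
        fit = fit_monoexp(decay, lifetime_model)
        assert fit.tau == pytest.approx(2.4, rel=1e-3)

    def test_poisson_recovery_is_unbiased(self, lifetime_model):
        """Mean fitted tau over 20 seeds within 2.4 +/- 0.02 ns at 1e5 photons."""
        taus = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            decay = synthetic_decay(0.0, lifetime_model, n_photons=1e5, rng=rng)
            taus.append(fit_monoexp(decay, lifetime_model).tau)
        assert abs(np.mean(taus) - 2.4) < 0.02

    def test_empty_histogram_raises(self, lifetime_model):
        with pytest.raises(errors.InsufficientDataError):
            fit_monoexp(DecayHistogram(counts=np.zeros(256), bin_width=12.5 / 256),
                        lifetime_model)

    def test_residuals_are_white(self, lifetime_model):
        """Wald-Wolfowitz runs test on fit residuals passes >= 90% of fits."""
        from fcsflim.flim import decay_shape, _deviance_residuals

        passes = 0
        n_fits = 30
        for seed in range(n_fits):
            rng = np.random.default_rng(300 + seed)
            decay = synthetic_decay(0.0, lifetime_model, n_photons=1e5, rng=rng)
            fit = fit_monoexp(decay, lifetime_model)
            model = fit.background + fit.amplitude * decay_shape(
                decay.times, fit.tau, lifetime_model.irf_sigma, lifetime_model.irf_t0)
            r = _deviance_residuals(np.asarray(decay.counts, float), model)
            signs = r > 0
            n1, n2 = signs.sum(), (~signs).sum()
            runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
            mu = 1 + 2 * n1 * n2 / (n1 + n2)
            var = (mu - 1) * (mu - 2) / (n1 + n2 - 1)
            if abs(runs - mu) / np.sqrt(var) < 1.96:
                passes += 1
        assert passes / n_fits >= 0.9


class TestFretFraction:
    @pytest.mark.parametrize("f_true,bound", [(0.0, 0.02), (1.0, 0.98)])
    def test_limits(self, lifetime_model, f_true, bound, rng):
        decay = synthetic_decay(f_true, lifetime_model, n_photons=1e5, rng=rng)
        f = fit_fret_fraction(decay, lifetime_model)
        if f_true == 0.0:
            assert f <= 0.02
        else:
            assert f >= 0.98

    def test_recovery_at_intermediate_fraction(self, lifetime_model):
        fs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            decay = synthetic_decay(0.4, lifetime_model, n_photons=1e5, rng=rng)
            fs.append(fit_fret_fraction(decay, lifetime_model))
        assert abs(np.mean(fs) - 0.40) < 0.02

    def test_low_counts_rejected(self, lifetime_model):
        decay = DecayHistogram(counts=np.ones(256), bin_width=12.5 / 256)
        with pytest.raises(errors.InsufficientDataError):
            fit_fret_fraction(decay, lifetime_model, min_photons=1000)

    def test_requires_tau_da(self):
        model = LifetimeModel(tau_d=2.4)
        decay = DecayHistogram(counts=np.full(256, 10.0), bin_width=12.5 / 256)
        with pytest.raises(ValueError):
            fit_fret_fraction(decay, model)


class TestFretMap:
    def _uniform_image(self, f, per_pixel, shape=(12, 12), rng=None,
                       model=None):
        decay = np.stack([
            synthetic_decay(f, model, n_photons=per_pixel, rng=rng).counts
            for _ in range(shape[0] * shape[1])
        ]).reshape(shape + (-1,))
        return FlimImage(decay=decay, pixel_size=0.275, bin_width=12.5 / 256)

    def test_uniform_truth_recovered(self, lifetime_model, rng):
        img = self._uniform_image(0.3, 1500, rng=rng, model=lifetime_model)
        fmap = fret_map(img, lifetime_model, min_photons=300)
        assert fmap.valid_mask.all()
        assert abs(np.nanmean(fmap.f_d) - 0.30) < 0.02
        assert np.nanmax(fmap.f_d) <= 1.0 and np.nanmin(fmap.f_d) >= 0.0

    def test_threshold_above_brightest_pixel_warns_empty(self, lifetime_model, rng):
        img = self._uniform_image(0.3, 200, shape=(4, 4), rng=rng, model=lifetime_model)
        with pytest.warns(errors.EmptyMapWarning):
            fmap = fret_map(img, lifetime_model, min_photons=10_000)
        assert not fmap.valid_mask.any()
        assert np.isnan(fmap.f_d).all()

    def test_two_region_cell_ordered_and_accurate(self, lifetime_model):
        cfg = FlimSimConfig(image_size=(48, 48), cell_axes=(5.0, 3.5),
                            fret_fraction={"cytoplasm": 0.1, "membrane": 0.5},
                            total_photon_budget=3e6, rng_seed=6)
        img, truth = simulate_flim_cell(cfg)
        fmap = fret_map(img, lifetime_model, min_photons=300)
        cyt = truth.extras["cytoplasm_mask"] & fmap.valid_mask
        # keep membrane pixels whose truth is not PSF-diluted by the cytoplasm
        mem = truth.extras["membrane_mask"] & fmap.valid_mask & (
            truth.extras["f_map"] > 0.45)
        f_cyt = np.nanmean(fmap.f_d[cyt])
        f_mem = np.nanmean(fmap.f_d[mem])
        assert f_mem > f_cyt
        assert abs(f_cyt - np.nanmean(truth.extras["f_map"][cyt])) < 0.03
        assert abs(f_mem - np.nanmean(truth.extras["f_map"][mem])) < 0.03

    def test_pooled_cell_fit_matches_truth(self, lifetime_model):
        cfg = FlimSimConfig(fret_fraction={"cytoplasm": 0.25, "membrane": 0.25},
                            total_photon_budget=2e5, rng_seed=2)
        img, _ = simulate_flim_cell(cfg)
        assert cell_fret_fraction(img, lifetime_model) == pytest.approx(0.25, abs=0.02)


class TestDimerisationEfficiency:
    def test_equal_concentrations_double_the_fraction(self):
        assert dimerisation_efficiency(0.25, 10.0, 10.0) == pytest.approx(0.5)

    def test_acceptor_excess_limit(self):
        e = dimerisation_efficiency(0.3, 1e-6, 100.0)
        assert e == pytest.approx(0.3, rel=1e-4)

    def test_zero_acceptor_raises(self):
        with pytest.raises(errors.UndefinedEfficiencyError):
            dimerisation_efficiency(0.2, 5.0, 0.0)

    def test_clipped_to_unit_interval(self):
        assert dimerisation_efficiency(0.9, 100.0, 1.0) == 1.0

    def test_invariant_to_donor_acceptor_ratio(self):
        """E_D at fixed dimer fraction is the same whatever the donor share."""
        means = []
        for x_d in (0.25, 0.5, 0.75):
            cfg = DimerPopulationConfig(
                kd_eff=49.0, total_conc_range=(49.0, 49.0 * 1.0001),
                donor_fraction_range=(x_d, x_d + 1e-6),
                measurement_noise_sd=0.01, n_cells=60, rng_seed=13)
            cells, _ = simulate_dimer_population(cfg)
            means.append(np.mean([
                dimerisation_efficiency(c["f_D_eff_observed"], c["C_D"], c["C_A"])
                for c in cells]))
        assert max(means) / min(means) - 1 < 0.05
        assert np.allclose(means, 0.5, atol=0.03)


class TestKdEstimation:
    def test_recovery_single_population(self):
        cells, _ = simulate_dimer_population(DimerPopulationConfig(kd_eff=49.0, rng_seed=0))
        fit = estimate_kd_eff(cells, n_boot=100, seed=0)
        assert fit.kd_eff == pytest.approx(49.0, rel=0.2)
        assert fit.kd_stderr > 0
        assert fit.n_cells == 50

    def test_too_few_cells_rejected(self):
        cells, _ = simulate_dimer_population(DimerPopulationConfig(n_cells=5, rng_seed=0))
        with pytest.raises(ValueError):
            estimate_kd_eff(cells)

    def test_narrow_concentration_range_warns(self):
        cfg = DimerPopulationConfig(total_conc_range=(40.0, 60.0), rng_seed=0)
        cells, _ = simulate_dimer_population(cfg)
        with pytest.warns(errors.IllConditionedWarning):
            estimate_kd_eff(cells, n_boot=10)

    def test_more_dimers_at_fixed_concentration_means_lower_kd(self):
        """Monotonicity: raising the simulated dimer fraction lowers K-hat."""
        fits = []
        for kd_true in (100.0, 10.0):  # lower K -> more dimers
            cells, _ = simulate_dimer_population(DimerPopulationConfig(
                kd_eff=kd_true, rng_seed=7))
            fits.append(estimate_kd_eff(cells, n_boot=10, seed=1).kd_eff)
        assert fits[1] < fits[0]

    def test_accepts_precomputed_e_d(self):
        c_t = np.geomspace(2, 200, 20)
        cells = [{"C_D": ct / 2, "C_A": ct / 2,
                  "E_D": float(dimer_protomer_fraction(ct, 30.0))} for ct in c_t]
        fit = estimate_kd_eff(cells, n_boot=10)
        assert fit.kd_eff == pytest.approx(30.0, rel=1e-3)
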