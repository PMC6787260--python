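"""Correlator, diffusion models, drift alignment and fits."""

import numpy as np
import pytest

from fcsflim import errors
from fcsflim.sfcs import (
    CorrelationCurve,
    FocusCalibration,
    MembraneTrace,
    align_membrane,
    autocorrelate,
    bin_photon_stream,
    calibrate_focus,
    direct_autocorrelation,
    fit_diffusion,
    model_g2d,
    model_g3d,
)
from fcsflim.synthetic import SfcsSimConfig, simulate_membrane_fcs, simulate_point_fcs
from fcsflim.tcspc import LineScanMatrix, decode_linescan


class TestModels:
    @pytest.mark.parametrize("tau,n,tau_d,s,expected", [
        (0.0, 2.0, 1.0, 5.0, 0.5),          # zero lag -> 1/N
        (1.0, 1.0, 1.0, 1e12, 2 ** -0.5),   # S -> inf limit
        (1.0, 1.0, 1.0, 1.0, 0.5),          # S = 1
    ])
    def test_g2d_closed_forms(self, tau, n, tau_d, s, expected):
        assert model_g2d(tau, n, tau_d, s) == pytest.approx(expected, rel=1e-9)

    def test_g3d_zero_lag_is_amplitude(self):
        assert model_g3d(0.0, 4.0, 1e-3, 5.0) == pytest.approx(0.25)

    def test_g2d_strictly_decreasing_in_lag(self):
        tau = np.linspace(0, 50e-3, 400)
        g = model_g2d(tau, 3.0, 1.9e-3, 5.0)
        assert np.all(np.diff(g) < 0)

    @pytest.mark.parametrize("bad", [(-1, 1, 5), (1, 0, 5), (1, 1, -2)])
    def test_nonpositive_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            model_g2d(1e-3, *bad)


class TestCorrelator:
    def test_constant_trace_gives_zero_everywhere(self):
        trace = MembraneTrace(intensity=np.full(4096, 7.0), dt=1e-3)
        curve = autocorrelate(trace)
        assert np.allclose(curve.G, 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_multitau_equals_direct_sum_on_first_octave(self, seed):
        """Multi-tau must agree with the brute-force correlator to 1e-12."""
        rng = np.random.default_rng(seed)
        x = rng.poisson(4.0, 10_000).astype(float)
        trace = MembraneTrace(intensity=x, dt=1.0)
        curve = autocorrelate(trace, m=8, n_segments=2)
        seg = x.size // 2
        for k in range(16):  # first octave: lags 1..2m unbinned
            lag_samples = int(round(curve.lags[k]))
            oracle = np.mean([
                direct_autocorrelation(x[s * seg:(s + 1) * seg], 16)[1][lag_samples - 1]
                for s in range(2)])
            assert curve.G[k] == pytest.approx(oracle, rel=1e-12, abs=1e-13)

    def test_iid_poisson_trace_is_statistically_flat(self):
        """Null check: a memoryless photon trace has no correlation signal."""
        n_seeds, viol, total, gsum = 60, 0, 0, 0.0
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            trace = MembraneTrace(intensity=rng.poisson(5.0, 4096).astype(float), dt=1e-3)
            curve = autocorrelate(trace, m=8, n_segments=8)
            sd = np.where(curve.G_sd > 0, curve.G_sd, np.inf)
            viol += int(np.sum(np.abs(curve.G) > 3 * sd))
            total += curve.G.size
            gsum += curve.G[:16].mean()
        # 3-sigma exceedances should be rare and the mean level ~0
        assert viol / total < 0.03
        assert abs(gsum / n_seeds) < 5e-4

    def test_zero_mean_trace_raises(self):
        with pytest.raises(errors.NormalizationError):
            autocorrelate(MembraneTrace(intensity=np.zeros(1024), dt=1e-3))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            autocorrelate(MembraneTrace(intensity=np.ones(32), dt=1e-3), m=8)

    def test_first_lag_equals_sampling_interval(self):
        trace = MembraneTrace(intensity=np.random.default_rng(0).poisson(3, 2048).astype(float),
                              dt=1 / 1400)
        curve = autocorrelate(trace)
        assert curve.lags[0] == pytest.approx(1 / 1400)
        assert np.all(np.diff(curve.lags) > 0)


def _matrix_with_peak(center, n_lines=2000, n_pixels=64, amp=30.0, bg=0.5, seed=0):
    rng = np.random.default_rng(seed)
    x = np.arange(n_pixels)
    center = np.broadcast_to(np.asarray(center, dtype=float), (n_lines,))
    lam = bg + amp * np.exp(-0.5 * ((x[None, :] - center[:, None]) / 1.8) ** 2)
    return LineScanMatrix(counts=rng.poisson(lam), line_period=1 / 1400, pixel_size=0.26)


class TestAlignment:
    def test_static_membrane_center_recovered(self):
        m = _matrix_with_peak(20.0)
        trace = align_membrane(m)
        assert abs(trace.center_trajectory.mean() - 20.0) < 0.5
        assert trace.intensity.size == m.n_lines

    def test_linear_drift_slope_recovered_within_10pct(self):
        # 2 px/min across a 2000-line (1.43 s) matrix is tiny; use a
        # visible but realistic drift of 4 px across the record instead
        n_lines = 7000
        true_slope = 4.0 / n_lines  # px per line
        centers = 25.0 + true_slope * np.arange(n_lines)
        m = _matrix_with_peak(centers, n_lines=n_lines)
        trace = align_membrane(m)
        slope = np.polyfit(np.arange(n_lines), trace.center_trajectory, 1)[0]
        assert slope == pytest.approx(true_slope, rel=0.10)

    def test_featureless_matrix_raises(self):
        rng = np.random.default_rng(0)
        m = LineScanMatrix(counts=rng.poisson(2.0, (2000, 64)),
                           line_period=1 / 1400, pixel_size=0.26)
        with pytest.raises(errors.MembraneNotFoundError):
            align_membrane(m)

    def test_peak_at_edge_raises_edge_clipping(self):
        m = _matrix_with_peak(1.0)
        with pytest.raises(errors.EdgeClippingError):
            align_membrane(m)


def _curve_from_model(model_fn, n, tau_d, s, dt=1 / 1400, n_lags=48):
    lags = dt * np.unique(np.round(np.geomspace(1, 600, n_lags))).astype(float)
    g = model_fn(lags, n, tau_d, s)
    return CorrelationCurve(lags=lags, G=g, G_sd=np.zeros_like(g), n_segments=1)


class TestDiffusionFit:
    def test_noiseless_self_consistency(self):
        curve = _curve_from_model(model_g2d, 5.0, 1.9e-3, 5.0)
        fit = fit_diffusion(curve, FocusCalibration(0.25, 1.25))
        assert fit.n == pytest.approx(5.0, rel=1e-6)
        assert fit.tau_d == pytest.approx(1.9e-3, rel=1e-6)
        assert fit.converged and not fit.at_bound

    def test_diffusion_coefficient_arithmetic(self):
        # w_o = 0.25 µm and tau_D = 1.883 ms print as D = 8.30 µm²/s
        curve = _curve_from_model(model_g2d, 3.0, 1.883e-3, 5.0)
        fit = fit_diffusion(curve, FocusCalibration(0.25, 1.25))
        assert fit.d == pytest.approx(0.25 ** 2 / (4 * 1.883e-3), rel=1e-6)
        assert round(fit.d, 1) == 8.3

    def test_too_few_lags_rejected(self):
        curve = _curve_from_model(model_g2d, 3.0, 2e-3, 5.0, n_lags=6)
        with pytest.raises(ValueError):
            fit_diffusion(curve, FocusCalibration(0.25, 1.25))


class TestCalibration:
    def test_waist_from_reference_dye_tau(self):
        # tau_D = 36.3 µs at D_ref = 430 µm²/s -> w_o = 0.250 µm
        curve = _curve_from_model(model_g3d, 2.0, 36.3e-6, 5.0, dt=5e-6)
        cal = calibrate_focus(curve, 430.0)
        assert cal.beam_waist == pytest.approx(np.sqrt(4 * 430 * 36.3e-6), rel=1e-6)
        assert abs(cal.beam_waist - 0.250) < 1e-3
        assert cal.aspect == pytest.approx(5.0, rel=1e-4)

    def test_implausible_aspect_warns(self):
        curve = _curve_from_model(model_g3d, 2.0, 36.3e-6, 0.7, dt=5e-6)
        with pytest.warns(errors.ImplausibleGeometryWarning):
            calibrate_focus(curve, 430.0)


class TestStreamBinning:
    def test_binning_conserves_photons(self):
        stream = simulate_point_fcs(430.0, FocusCalibration(0.25, 1.25),
                                    0.25, 3e4, 2.0, seed=1)
        trace = bin_photon_stream(stream, 5e-6)
        assert trace.intensity.sum() == stream.n_photons
        assert trace.dt == 5e-6


class TestAmplitudeLaw:
    def test_fitted_n_scales_with_density(self):
        """G(0) follows 1/N: doubling the density halves the amplitude."""
        fits = []
        for density in (1.0, 2.0):
            cfg = SfcsSimConfig(particle_density=density, duration=40.0,
                                rng_seed=77, background_rate=0.0)
            stream, _ = simulate_membrane_fcs(cfg)
            xt = decode_linescan(stream, cfg.n_pixels)
            curve = autocorrelate(align_membrane(xt))
            fits.append(fit_diffusion(curve, FocusCalibration(0.25, 1.25)))
        ratio = fits[1].n / fits[0].n
        assert ratio == pytest.approx(2.0, rel=0.2)
        # absolute level matches the focal-area prediction density*pi*w*zo
        expected = 1.0 * np.pi * 0.25 * 1.25
        assert fits[0].n == pytest.approx(expected, rel=0.2)
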