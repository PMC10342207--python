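import numpy as np
import pytest

from flimpheno import BiexpParams, FitConfig, IRFCurve, TCSPCImage, TimeGrid, make_irf
from flimpheno.decay_model import mean_lifetime, model_curve, wrapped_biexp
from flimpheno.fitting import fit_image, fit_pixel
from flimpheno.synthetic import simulate_decay


class TestMeanLifetime:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (BiexpParams(0.7, 0.5, 3.0), 1.25),
            (BiexpParams(1.0, 0.8, 5.0), 0.8),
            (BiexpParams(0.5, 1.0, 3.0), 2.0),
        ],
    )
    def test_weighted_average(self, params, expected):
        assert mean_lifetime(params) == pytest.approx(expected)


class TestModelCurve:
    def test_delta_irf_is_shifted_wrapped_decay(self, grid):
        """Convolution with a point-mass IRF only rotates the decay."""
        k = 20
        delta = np.zeros(grid.n_channels)
        delta[k] = 1.0
        irf = IRFCurve(counts=delta, grid=grid)
        p = BiexpParams(0.6, 0.5, 3.0)
        curve = model_curve(p, irf, grid, amplitude=1e5)
        expected = 1e5 * np.roll(wrapped_biexp(p, grid), k)
        assert np.allclose(curve, expected, rtol=1e-9, atol=1e-6)

    def test_zero_amplitude_is_flat_background(self, grid, irf):
        p = BiexpParams(0.6, 0.5, 3.0, background=2.5)
        assert np.allclose(model_curve(p, irf, grid, amplitude=0.0), 2.5)

    def test_collapse_to_mono_exponential(self, grid, irf):
        """Equal lifetimes reduce the model to a single exponential."""
        tau = 1.7
        nearly_mono = model_curve(BiexpParams(0.3, tau, tau + 1e-9), irf, grid, 1e5)
        mono = model_curve(BiexpParams(1.0, tau, tau + 1.0), irf, grid, 1e5)
        assert np.allclose(nearly_mono, mono, rtol=1e-6)

    def test_grid_mismatch_rejected(self, grid):
        other = TimeGrid(n_channels=128, period=12.5)
        irf_other = make_irf(other)
        with pytest.raises(ValueError):
            model_curve(BiexpParams(0.6, 0.5, 3.0), irf_other, grid, 1.0)

    def test_wrap_around_carries_tail(self, grid, irf):
        """Long lifetimes leave a periodic tail: counts just before t=0 rise."""
        p = BiexpParams(0.0 + 1e-12, 0.5, 3.0)  # essentially mono tau=3
        curve = model_curve(p, irf, grid, amplitude=1.0)
        assert curve[0] > 0  # channel before the IRF peak is not empty


class TestFitPixel:
    @pytest.mark.parametrize(
        "truth",
        [
            BiexpParams(0.6, 0.4, 2.8),
            BiexpParams(0.8, 0.3, 2.0),
            BiexpParams(0.5, 0.8, 4.0),
            BiexpParams(0.9, 0.2, 3.5),
            BiexpParams(0.3, 0.6, 1.8),
        ],
    )
    @pytest.mark.parametrize("objective", ["mle", "neyman"])
    def test_noise_free_round_trip(self, grid, irf, truth, objective):
        """Noise-free curves are recovered to 0.5% across the parameter range."""
        curve = model_curve(truth, irf, grid, amplitude=1e6)
        fit = fit_pixel(curve, irf, grid, FitConfig(objective=objective))
        assert fit.valid
        assert fit.params.alpha1 == pytest.approx(truth.alpha1, rel=5e-3, abs=5e-3)
        assert fit.params.tau1 == pytest.approx(truth.tau1, rel=5e-3)
        assert fit.params.tau2 == pytest.approx(truth.tau2, rel=5e-3)
        assert fit.chi2_reduced < 0.01

    def test_monte_carlo_tau_m_recovery(self, grid, irf):
        """Median fitted tau_m at 5,000 photons stays within 5% of 1.25 ns."""
        truth = BiexpParams(0.7, 0.5, 3.0)
        rng = np.random.default_rng(77)
        tau_ms = []
        for _ in range(200):
            hist = simulate_decay(truth, irf, 5000, grid, seed=rng)
            fit = fit_pixel(hist, irf, grid)
            assert fit.valid
            tau_ms.append(fit.tau_m)
        assert np.median(tau_ms) == pytest.approx(1.25, rel=0.05)

    def test_below_threshold_marked_invalid(self, grid, irf):
        fit = fit_pixel(np.zeros(grid.n_channels), irf, grid, FitConfig(min_photons=100))
        assert not fit.valid
        assert fit.params is None
        assert "threshold" in fit.message

    def test_background_recovered(self, grid, irf):
        """The offset is identifiable only up to its near-degeneracy with the
        wrapped long-lifetime plateau; shape parameters stay accurate."""
        truth = BiexpParams(0.7, 0.5, 3.0, background=3.0)
        curve = model_curve(truth, irf, grid, amplitude=1e6)
        fit = fit_pixel(curve, irf, grid)
        assert fit.params.background == pytest.approx(3.0, rel=0.15)
        assert fit.params.tau2 == pytest.approx(3.0, rel=5e-3)

    def test_ordering_enforced(self, grid, irf):
        """tau1 < tau2 always holds on output, whatever the optimizer found."""
        truth = BiexpParams(0.25, 1.2, 1.6)  # both components near the bound overlap
        curve = model_curve(truth, irf, grid, amplitude=1e6)
        fit = fit_pixel(curve, irf, grid)
        assert fit.params.tau1 < fit.params.tau2


class TestFitImage:
    def _constant_image(self, grid, irf, params, photons, shape=(8, 8), seed=0):
        expected = model_curve(params, irf, grid, amplitude=photons)
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected, size=shape + (grid.n_channels,))
        return TCSPCImage(counts=counts, grid=grid, channel_name="NADPH")

    def test_constant_field_recovery(self, grid, irf):
        truth = BiexpParams(0.7, 0.5, 3.0)
        image = self._constant_image(grid, irf, truth, 20000)
        result = fit_image(image, irf, FitConfig(spatial_bin=1))
        assert result.valid.all()
        assert np.nanmedian(result.tau_m) == pytest.approx(truth.tau_m, rel=0.02)
        ok = result.valid
        assert np.allclose(
            result.tau_m[ok],
            result.alpha1[ok] * result.tau1[ok] + (1 - result.alpha1[ok]) * result.tau2[ok],
            atol=1e-9,
        )

    def test_binning_equals_fitting_summed_histogram(self, grid, irf):
        """3x3 of identical pixels: the binned center fit equals one 9-pixel fit."""
        truth = BiexpParams(0.7, 0.5, 3.0)
        hist = simulate_decay(truth, irf, 2000, grid, seed=5)
        counts = np.tile(hist, (3, 3, 1))
        image = TCSPCImage(counts=counts, grid=grid)
        result = fit_image(image, irf, FitConfig(spatial_bin=1))
        single = fit_pixel(9.0 * hist, irf, grid)
        assert result.tau_m[1, 1] == pytest.approx(single.tau_m, abs=1e-9)

    def test_photon_threshold_selects_bright_pixels(self, grid, irf):
        truth = BiexpParams(0.7, 0.5, 3.0)
        counts = np.zeros((5, 5, grid.n_channels), dtype=np.int64)
        counts[2, 2] = simulate_decay(truth, irf, 50000, grid, seed=6)
        image = TCSPCImage(counts=counts, grid=grid)
        result = fit_image(image, irf, FitConfig(spatial_bin=0, min_photons=1000))
        assert result.valid[2, 2]
        assert result.valid.sum() == 1
        assert np.isnan(result.tau_m[0, 0])

    def test_grid_mismatch_rejected(self, grid, irf):
        other = TimeGrid(n_channels=128, period=12.5)
        image = TCSPCImage(np.zeros((2, 2, 128), dtype=int), other)
        with pytest.raises(ValueError):
            fit_image(image, irf)


class TestConsistency:
    def test_tau_m_monotone_in_alpha1(self, grid, irf):
        """Lower free fraction -> longer fitted mean lifetime (tau1 < tau2)."""
        fitted = []
        for a1 in (0.8, 0.6, 0.4):
            hist = simulate_decay(BiexpParams(a1, 0.5, 3.0), irf, 50000, grid, seed=11)
            fitted.append(fit_pixel(hist, irf, grid).tau_m)
        assert fitted[0] < fitted[1] < fitted[2]
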