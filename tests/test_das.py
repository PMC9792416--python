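"""Global lifetime analysis: kernel accuracy, variable-projection fits,
DAS normalisation and the average-lifetime statistic."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import least_squares

from photospec.das import (DASComponent, DASFitResult, GlobalDASFit,
                           StreakImage, average_lifetime, bin_wavelengths,
                           das_lambda_max, emg_kernel, global_fit,
                           normalize_das, read_streak, write_streak)
from photospec.lineshapes import BandModel
from photospec.spectra import Spectrum
from photospec.synthetic import make_streak

GRID = np.arange(620.0, 800.0, 1.0)


def das_pair():
    bulk = Spectrum(GRID, BandModel(685.0, 24.0)(GRID))
    red = Spectrum(GRID, BandModel(727.0, 30.0)(GRID))
    return bulk, red


class TestEmgKernel:
    def test_plain_exponential_limit(self):
        t = np.linspace(0.0, 500.0, 200)
        small = emg_kernel(t, 50.0, 1e-3, 0.0)
        plain = np.exp(-t / 50.0)
        mask = t >= 5e-3
        assert np.max(np.abs(small[mask] - plain[mask])) < 1e-9

    def test_half_peak_at_time_zero(self):
        # erfc(0) = 1: at t = t0 the kernel is half the sigma->0 peak
        assert emg_kernel(30.0, 40.0, 0.01, 30.0) == pytest.approx(0.5,
                                                                   abs=1e-3)

    def test_against_quadrature_convolution_oracle(self):
        """Closed form vs adaptive quadrature of the defining convolution
        exp(-u/tau) * Gaussian(t - t0 - u)."""
        tau, fwhm, t0 = 40.0, 16.0, 30.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        t = np.linspace(0.0, 400.0, 41)

        def integrand(u, ti):
            g = np.exp(-0.5 * ((ti - t0 - u) / sigma) ** 2)
            return np.exp(-u / tau) * g / (sigma * np.sqrt(2 * np.pi))

        oracle = np.array([
            quad(integrand, 0, np.inf, args=(ti,), epsabs=1e-14,
                 epsrel=1e-12, limit=200)[0]
            for ti in t
        ])
        mine = emg_kernel(t, tau, fwhm, t0)
        mask = oracle > 1e-12
        rel = np.abs(mine[mask] - oracle[mask]) / oracle[mask]
        assert rel.max() < 1e-6

    def test_no_overflow_far_from_t0(self):
        vals = emg_kernel(np.array([0.0, 5000.0]), 5.0, 16.0, 30.0)
        assert np.all(np.isfinite(vals))


class TestStreakImage:
    def test_shape_and_negativity_validation(self):
        with pytest.raises(ValueError, match="shape"):
            StreakImage([0.0, 1.0], [700.0, 705.0], np.ones((3, 2)), 16.0)
        with pytest.raises(ValueError, match="non-negative"):
            StreakImage([0.0, 1.0], [700.0, 705.0], -np.ones((2, 2)), 16.0)

    def test_tsv_roundtrip(self, tmp_path):
        bulk, red = das_pair()
        img = make_streak([(30.0, bulk), (120.0, red)], counts_scale=100.0,
                          seed=5)
        p = tmp_path / "streak.tsv"
        write_streak(img, p)
        back = read_streak(p)
        assert np.array_equal(back.counts, img.counts)
        assert back.irf_fwhm_ps == img.irf_fwhm_ps
        assert back.irf_t0_ps == img.irf_t0_ps

    def test_wavelength_binning_means_columns(self):
        times = np.arange(0.0, 10.0)
        wl = np.arange(700.0, 710.0)  # 1-nm columns
        counts = np.tile(np.arange(10.0), (10, 1))
        img = StreakImage(times, wl, counts, 16.0)
        binned = bin_wavelengths(img, 5.0)
        assert binned.counts.shape[1] == 2
        assert np.allclose(binned.counts[0], [2.0, 7.0])


class TestGlobalFit:
    def test_noiseless_two_component_recovery(self):
        bulk, red = das_pair()
        img = make_streak([(30.0, bulk), (120.0, red)], poisson_noise=False)
        fit = GlobalDASFit(n_components=2, tau_init_ps=[15.0, 300.0]).fit(img)
        assert np.allclose(fit.lifetimes_, [30.0, 120.0], rtol=1e-6)
        # DAS recovered up to the single global count scaling
        for comp, truth in zip(fit.result_.components, (bulk, red)):
            das_true = np.interp(comp.wavelengths_nm, truth.wavelengths_nm,
                                 truth.intensities)
            scale = comp.amplitudes.max() / das_true.max()
            assert np.max(np.abs(comp.amplitudes - scale * das_true)) \
                < 1e-6 * comp.amplitudes.max()

    def test_single_component_residual_at_noise_floor(self):
        bulk, _ = das_pair()
        img = make_streak([(80.0, bulk)], counts_scale=1e4, seed=11)
        fit = GlobalDASFit(n_components=1, tau_init_ps=[40.0]).fit(img)
        # Poisson shot noise: RMS residual close to sqrt(mean counts)
        shot = np.sqrt(img.counts.mean())
        assert fit.residual_rms_ < 2.0 * shot
        assert fit.lifetimes_[0] == pytest.approx(80.0, rel=0.02)

    def test_variable_projection_equals_joint_fit(self):
        """On a small instance the varpro optimum coincides with a
        brute-force joint optimisation of lifetimes and amplitudes."""
        wl = np.array([690.0, 710.0, 730.0])
        spec_a = Spectrum(np.array([680.0, 700.0, 740.0]), [1.0, 0.7, 0.1])
        spec_b = Spectrum(np.array([680.0, 700.0, 740.0]), [0.2, 0.6, 1.0])
        img = make_streak([(25.0, spec_a), (110.0, spec_b)], bin_nm=20.0,
                          dt_ps=4.0, poisson_noise=False)
        varpro = GlobalDASFit(n_components=2, tau_init_ps=[40.0, 200.0],
                              fit_t0=False).fit(img)

        times, counts = img.times_ps, img.counts
        nlam = counts.shape[1]

        def joint_residual(theta):
            taus = np.exp(theta[:2])
            A = theta[2:].reshape(2, nlam)
            C = np.column_stack([emg_kernel(times, tau, img.irf_fwhm_ps,
                                            img.irf_t0_ps) for tau in taus])
            return (counts - C @ A).ravel()

        # warm-start the joint amplitudes by linear least squares at the
        # initial lifetimes, as any sane joint optimiser would
        tau0 = np.array([20.0, 130.0])
        C0 = np.column_stack([emg_kernel(times, tau, img.irf_fwhm_ps,
                                         img.irf_t0_ps) for tau in tau0])
        A0, *_ = np.linalg.lstsq(C0, counts, rcond=None)
        theta0 = np.concatenate([np.log(tau0), A0.ravel()])
        sol = least_squares(joint_residual, theta0, xtol=1e-15, ftol=1e-15,
                            gtol=1e-15)
        joint_taus = np.sort(np.exp(sol.x[:2]))
        assert np.allclose(varpro.lifetimes_, joint_taus, rtol=1e-6)

    def test_role_assignment_heuristic(self):
        bulk, red = das_pair()
        transfer = Spectrum(GRID, BandModel(685, 24)(GRID)
                            - 0.5 * BandModel(730, 30)(GRID))
        contam = Spectrum(GRID, 0.3 * BandModel(683, 18)(GRID))
        img = make_streak([(10.0, transfer), (35.0, bulk), (120.0, red),
                           (400.0, contam)], counts_scale=2e4, seed=2)
        result = global_fit(img, n_components=4,
                            tau_init_ps=[6.0, 25.0, 90.0, 700.0])
        roles = [c.role for c in result.components]
        assert roles == ["transfer", "bulk_decay", "red_decay",
                         "contamination"]
        assert result.average_lifetime_ps is not None

    def test_explicit_role_override(self):
        bulk, red = das_pair()
        img = make_streak([(30.0, bulk), (120.0, red)], poisson_noise=False)
        result = global_fit(img, n_components=2, tau_init_ps=[15.0, 300.0],
                            roles={0: "bulk_decay", 1: "red_decay"})
        assert [c.role for c in result.components] == ["bulk_decay",
                                                       "red_decay"]

    def test_bad_initial_lifetimes_rejected(self):
        bulk, _ = das_pair()
        img = make_streak([(30.0, bulk)], poisson_noise=False)
        with pytest.raises(ValueError, match="distinct"):
            GlobalDASFit(n_components=2, tau_init_ps=[30.0, 30.0]).fit(img)


class TestNormalizeAndAverageLifetime:
    def make_result(self):
        bulk, red = das_pair()
        img = make_streak([(35.0, bulk), (120.0, red)], poisson_noise=False)
        return global_fit(img, n_components=2, tau_init_ps=[20.0, 200.0],
                          roles={0: "bulk_decay", 1: "red_decay"})

    def test_total_absolute_area_one(self):
        result = normalize_das(self.make_result())
        assert sum(abs(c.area) for c in result.components) == pytest.approx(
            1.0, rel=1e-12)

    def test_average_lifetime_invariant_under_normalization(self):
        result = self.make_result()
        before = average_lifetime(result)
        after = average_lifetime(normalize_das(result))
        assert after == pytest.approx(before, rel=1e-12)

    def test_per_component_mode(self):
        result = normalize_das(self.make_result(), per_component=True)
        for c in result.components:
            assert abs(c.area) == pytest.approx(1.0, rel=1e-12)

    def test_count_scale_invariance_of_normalized_das(self):
        bulk, red = das_pair()
        img1 = make_streak([(35.0, bulk), (120.0, red)], poisson_noise=False,
                           counts_scale=1e4)
        img2 = make_streak([(35.0, bulk), (120.0, red)], poisson_noise=False,
                           counts_scale=2e4)
        r1 = normalize_das(global_fit(img1, 2, [20.0, 200.0]))
        r2 = normalize_das(global_fit(img2, 2, [20.0, 200.0]))
        for c1, c2 in zip(r1.components, r2.components):
            assert np.allclose(c1.amplitudes, c2.amplitudes, rtol=1e-6,
                               atol=1e-9)

    def test_average_lifetime_arithmetic(self):
        wl = np.array([700.0, 710.0])
        # areas 0.6 and 0.4 via constant amplitude over a 10-nm span
        c2 = DASComponent(40.0, wl, np.full(2, 0.06), role="bulk_decay")
        c3 = DASComponent(120.0, wl, np.full(2, 0.04), role="red_decay")
        result = DASFitResult((c2, c3), 0.0, 0.0, 16.0)
        assert average_lifetime(result) == pytest.approx(72.0, rel=1e-12)

    def test_degenerate_single_area(self):
        wl = np.array([700.0, 710.0])
        c2 = DASComponent(40.0, wl, np.full(2, 0.06), role="bulk_decay")
        c3 = DASComponent(120.0, wl, np.full(2, 1e-15), role="red_decay")
        result = DASFitResult((c2, c3), 0.0, 0.0, 16.0)
        assert average_lifetime(result) == pytest.approx(40.0, rel=1e-6)

    def test_non_positive_area_rejected(self):
        wl = np.array([700.0, 710.0])
        c2 = DASComponent(40.0, wl, np.full(2, 0.06), role="bulk_decay")
        c3 = DASComponent(120.0, wl, np.full(2, -0.04), role="red_decay")
        result = DASFitResult((c2, c3), 0.0, 0.0, 16.0)
        with pytest.raises(ValueError, match="positive areas"):
            average_lifetime(result)


class TestDasLambdaMax:
    def test_window_excludes_bulk_feature(self):
        amps = BandModel(685.0, 15.0, 2.0)(GRID) + BandModel(729.0, 25.0)(GRID)
        comp = DASComponent(120.0, GRID, amps)
        pk = das_lambda_max(comp)
        assert pk.lambda_max_nm == pytest.approx(729.0, abs=0.5)

    def test_fitted_red_das_maximum(self):
        bulk, _ = das_pair()
        red = Spectrum(GRID, BandModel(727.0, 30.0)(GRID))
        img = make_streak([(35.0, bulk), (120.0, red)], counts_scale=3e4,
                          seed=9)
        result = global_fit(img, 2, [20.0, 200.0])
        pk = das_lambda_max(result.components[1])
        assert pk.lambda_max_nm == pytest.approx(727.0, abs=0.5)
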