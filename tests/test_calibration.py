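"""Regression-based parameter extraction and the cross-wavelength conversion."""

import numpy as np
import pandas as pd
import pytest

from soedkit.calibration import (
    BleachingCalibration,
    WavelengthConversionFit,
    convert_523_to_630,
    fit_delta_sigma,
    fit_quencher_rates,
    fit_sold_soed_line,
    photobleaching_rate,
    wavelength_conversion_study,
)
from soedkit.kinetics import KineticsState, simulate_invitro
from soedkit.photophysics import tau_delta_from_rates
from soedkit.synthetic_data import (
    OpticsScenario,
    PhantomScenario,
    generate_optics_table,
    generate_phantom_timeseries,
)


class TestPhotobleachingRate:
    def test_linear_decay(self):
        t = np.arange(0.0, 100.0, 10.0)
        rate = photobleaching_rate(t, 100.0 - t)
        assert np.allclose(rate, 1.0)

    def test_constant_concentration(self):
        t = np.arange(0.0, 100.0, 10.0)
        assert np.allclose(photobleaching_rate(t, np.full(t.size, 42.0)), 0.0)

    def test_exponential_decay_matches_analytic_derivative(self):
        t = np.arange(0.0, 400.0, 10.0)
        y = np.exp(-t / 100.0)
        rate = photobleaching_rate(t, y)
        analytic = y / 100.0
        mid = slice(5, -5)
        rel = np.abs(rate[mid] - analytic[mid]) / analytic[mid]
        # the centred 5-point window at 10 s spacing has an exact curvature
        # bias of [20 sinh(0.2) + 10 sinh(0.1)] / 10 - 1 = +0.55% on a 100 s
        # exponential; anything beyond that indicates an estimator defect
        assert np.max(rel) < 0.006

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            photobleaching_rate([0.0, 1.0], [1.0, 0.9])


class TestBleachingLine:
    def test_printed_line_arithmetic(self):
        """Intercept/slope and slope/xi from a fitted bleaching line."""
        cal = BleachingCalibration.from_line(6.86e-7, 1.78e-5, 10.3e-3)
        assert cal.delta == pytest.approx(25.0, abs=1.0)
        assert cal.sigma == pytest.approx(6.6e-5, rel=0.02)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            BleachingCalibration.from_line(-1e-7, 1e-5, 1e-2)

    def test_noiseless_recovery_within_two_percent(self, invitro_params):
        """A simulated phantom series hands back the generating (delta, sigma)."""
        runs = []
        for c, phi in [(27.0, 45.0), (50.0, 38.0), (167.0, 42.0)]:
            sc = PhantomScenario(S0_initial=c, phi0=phi,
                                 o2_noise_sd=0.0, s0_noise_rel_sd=0.0, seed=0)
            runs.append(generate_phantom_timeseries(sc, invitro_params)[0])
        cal = fit_delta_sigma(runs, invitro_params)
        assert cal.delta == pytest.approx(invitro_params.delta, rel=0.02)
        assert cal.sigma == pytest.approx(invitro_params.sigma, rel=0.02)

    def test_simulated_series_accepted_directly(self, invitro_params):
        t = np.arange(0.0, 901.0, 10.0)
        series = simulate_invitro(invitro_params, 38.0,
                                  KineticsState(50.0, 160.4), t)
        cal = fit_delta_sigma(series, invitro_params)
        assert cal.delta == pytest.approx(invitro_params.delta, rel=0.05)

    def test_noisy_recovery_within_reported_uncertainty(self, invitro_params):
        """Across 100 seeded replicates of the three-phantom experiment the
        recovered delta lands within the +-4.3 uM band at least 90% of the
        time and sigma within a factor of two."""
        hits_delta = hits_sigma = 0
        n_rep = 100
        for rep in range(n_rep):
            runs = []
            for c, phi in [(27.0, 45.0), (50.0, 38.0), (167.0, 42.0)]:
                sc = PhantomScenario(S0_initial=c, phi0=phi, seed=rep * 10 + int(c))
                runs.append(generate_phantom_timeseries(sc, invitro_params)[0])
            cal = fit_delta_sigma(runs, invitro_params)
            hits_delta += abs(cal.delta - invitro_params.delta) < 4.3
            hits_sigma += (invitro_params.sigma / 2 < cal.sigma
                           < invitro_params.sigma * 2)
        assert hits_delta >= 0.9 * n_rep
        assert hits_sigma >= 0.9 * n_rep


class TestQuencherLine:
    def test_exact_recovery_on_noiseless_points(self):
        k6, k7 = 1.14e5, 235.0
        pts = [(A, tau_delta_from_rates(k6, k7, A)) for A in (0.0, 50.0, 200.0, 1000.0)]
        cal = fit_quencher_rates(pts)
        assert cal.k6 == pytest.approx(k6, rel=1e-9)
        assert cal.k7 == pytest.approx(k7, rel=1e-9)

    def test_zero_quencher_point_fixes_k6(self):
        assert 1.0 / tau_delta_from_rates(1.14e5, 235.0, 0.0) == pytest.approx(1.14e5)

    def test_recovery_within_literature_band(self):
        """Lifetimes generated with k7 in the reported 300-400 range are
        recovered inside that band despite measurement noise."""
        rng = np.random.default_rng(17)
        k6, k7 = 1.14e5, 350.0
        A = np.array([0.0, 100.0, 300.0, 600.0, 1000.0, 2000.0])
        ok = 0
        for _ in range(20):
            tau = tau_delta_from_rates(k6, k7, 0.0) * np.ones(A.size)
            tau = np.array([tau_delta_from_rates(k6, k7, a) for a in A])
            tau_meas = tau * (1 + rng.normal(0.0, 0.01, tau.size))
            cal = fit_quencher_rates(list(zip(A, tau_meas)))
            ok += 300.0 < cal.k7 < 400.0
        assert ok >= 18

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError):
            fit_quencher_rates([(0.0, 1e-5), (0.0, 1e-5), (0.0, 1e-5)])


class TestSoldSoedLine:
    def test_collinear_points_give_unit_r_squared(self):
        pairs = [(x, 2.0 * x + 1.0) for x in (1.0, 2.0, 3.0, 4.0)]
        fit = fit_sold_soed_line(pairs)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.factor == pytest.approx(2.0)
        assert fit.offset == pytest.approx(1.0)

    def test_dropping_intercept_on_offset_data_reduces_r_squared(self):
        rng = np.random.default_rng(3)
        x = np.linspace(1.0, 10.0, 20)
        y = 2.0 * x + 5.0 + rng.normal(0.0, 0.05, x.size)
        fit = fit_sold_soed_line(list(zip(x, y)))
        assert fit.r_squared_no_intercept < fit.r_squared

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_sold_soed_line([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])


class TestWavelengthConversion:
    def test_paper_style_coefficient_evaluation(self):
        """Affine conversion arithmetic on a known coefficient set."""
        fit = WavelengthConversionFit(
            a_slope=0.05814, a_intercept=1.922,
            b_c_coeff=0.000618, b_const=-0.000033,
            c_range=(0.21, 21.0), fluence_range=(10.0, 120.0),
        )
        assert fit.a(21.0) == pytest.approx(3.143, abs=1e-3)
        assert fit.b(2.1, 120.0) == pytest.approx(0.152, abs=1e-3)
        res = convert_523_to_630(1.0, 2.1, 120.0, fit)
        assert res.rx630 == pytest.approx(2.196, abs=2e-3)
        assert not res.extrapolated

    def test_zero_input_returns_offset_and_affinity(self):
        fit = WavelengthConversionFit(0.05814, 1.922, 0.000618, -0.000033,
                                      (0.21, 21.0), (10.0, 120.0))
        b = convert_523_to_630(0.0, 2.1, 120.0, fit).rx630
        r1 = convert_523_to_630(1.0, 2.1, 120.0, fit).rx630
        r2 = convert_523_to_630(2.0, 2.1, 120.0, fit).rx630
        r3 = convert_523_to_630(3.0, 2.1, 120.0, fit).rx630
        assert b == pytest.approx(fit.b(2.1, 120.0))
        # affine map: conversion of a sum equals sum of conversions minus one offset
        assert r3 == pytest.approx(r1 + r2 - b, rel=1e-12)

    def test_extrapolation_flagged(self):
        fit = WavelengthConversionFit(0.05, 1.9, 6e-4, 0.0, (0.21, 21.0), (10.0, 120.0))
        assert convert_523_to_630(1.0, 100.0, 60.0, fit).extrapolated

    def test_identical_optics_and_parameters_give_identity(self, invivo_params):
        """Same optics and photophysics at both wavelengths: a = 1, b = 0."""
        table = pd.DataFrame({
            "site": ["a", "b", "c"],
            "mu_a_523": [0.3, 0.6, 1.0], "mu_s_prime_523": [10.0, 15.0, 20.0],
            "mu_a_630": [0.3, 0.6, 1.0], "mu_s_prime_630": [10.0, 15.0, 20.0],
        })
        fit = wavelength_conversion_study(
            table, c_values=(2.0, 8.0), fluence_rates=(50.0,),
            total_fluences=(10.0, 30.0),
            params_523=invivo_params, params_630=invivo_params,
            fluence_model="diffusion",
        )
        assert fit.a(2.0) == pytest.approx(1.0, abs=1e-6)
        assert fit.a(8.0) == pytest.approx(1.0, abs=1e-6)
        assert abs(fit.b(2.0, 30.0)) < 1e-9

    def test_mpm_study_structure(self, invivo_params, invivo_params_523):
        """On the patient optics spread, the 630 nm treatment beam produces
        more reacted singlet oxygen than 523 nm at equal incident fluence
        (a > 1, growing with concentration) and the per-group regressions
        are strongly linear."""
        table = generate_optics_table(OpticsScenario(n_sites=5, seed=42))
        fit = wavelength_conversion_study(
            table, c_values=(0.21, 2.1, 21.0), fluence_rates=(25.0, 75.0),
            total_fluences=(10.0, 120.0),
            params_523=invivo_params_523, params_630=invivo_params,
            fluence_model="mc", mc_photons=100_000,
        )
        for c in (0.21, 2.1, 21.0):
            assert fit.a(c) > 1.0
        assert fit.a_slope > 0.0          # a grows with concentration
        assert fit.table.r_squared.min() > 0.8
        assert np.all(fit.table.b_mM >= 0.0)

    def test_insufficient_grid_rejected(self, invivo_params):
        table = pd.DataFrame({
            "mu_a_523": [0.3], "mu_s_prime_523": [10.0],
            "mu_a_630": [0.3], "mu_s_prime_630": [10.0],
        })
        with pytest.raises(ValueError):
            wavelength_conversion_study(
                table, c_values=(2.0,), fluence_rates=(50.0,),
                total_fluences=(10.0,),
                params_523=invivo_params, params_630=invivo_params,
            )
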