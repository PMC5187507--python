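"""Luminescence pulse response, histogram handling, and lifetime fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from soedkit.sold import (
    SoldCumulative,
    SoldFitError,
    SoldHistogram,
    cumulative_counts,
    fit_pulse_response,
    pulse_response,
    pulse_response_peak_time,
    subtract_background,
)

TAU_D, TAU_T = 9.4e-6, 0.43e-6


def _piecewise_quad(f, breakpoints=(0.0, 2e-6, 2e-5, 1e-4, 5e-4)):
    """Adaptive quadrature in segments (the pulse occupies a sliver of the range)."""
    return sum(quad(f, a, b, limit=200)[0]
               for a, b in zip(breakpoints, breakpoints[1:]))


def _expected_histogram(params, S0, N, n_pulses, bin_width=32e-9, t_max=60e-6):
    edges = np.arange(0.0, t_max + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lam = (pulse_response(centers, N, params.sigma_A(), S0, params.Phi_Delta,
                          params.tau_Delta, params.tau_t)
           / params.tau_R * bin_width * n_pulses)
    return edges, lam


class TestPulseResponse:
    def test_zero_at_time_zero_and_nonnegative(self):
        t = np.linspace(0.0, 60e-6, 500)
        y = pulse_response(t, 1e12, 1.5e-17, 50.0, 0.64, TAU_D, TAU_T)
        assert y[0] == 0.0
        assert np.all(y >= 0.0)

    def test_peak_location(self):
        t_star = pulse_response_peak_time(TAU_D, TAU_T)
        assert t_star == pytest.approx(1.39e-6, rel=1e-2)
        t = np.linspace(0.0, 20e-6, 20001)
        y = pulse_response(t, 1.0, 1.0, 1.0, 1.0, TAU_D, TAU_T)
        assert t[np.argmax(y)] == pytest.approx(t_star, abs=2e-9)

    def test_integral_identity(self):
        """int_0^inf of the pulse response equals N sigma_A S0 Phi_Delta tau_Delta."""
        amp = 1e12 * 1.5e-17 * 50.0 * 0.64
        val = _piecewise_quad(
            lambda t: pulse_response(t, 1e12, 1.5e-17, 50.0, 0.64, TAU_D, TAU_T)
        )
        assert val == pytest.approx(amp * TAU_D, rel=1e-6)

    def test_degenerate_lifetimes_rejected(self):
        with pytest.raises(ValueError):
            pulse_response(1e-6, 1.0, 1.0, 1.0, 1.0, TAU_D, TAU_D)

    @given(st.floats(1e-7, 1e-4), st.floats(1.1, 100.0))
    @settings(max_examples=40, derandomize=True)
    def test_shape_degenerate_under_labelled_swap(self, tau_fast, ratio):
        """Swapping the two lifetimes while rescaling the amplitude by their
        ratio leaves the curve unchanged — the degeneracy behind the fitter's
        tau_Delta > tau_t labelling convention."""
        tau_slow = tau_fast * ratio
        t = np.linspace(0.0, 5 * tau_slow, 50)
        a = pulse_response(t, 1.0, 1.0, 1.0, 1.0, tau_slow, tau_fast)
        b = pulse_response(t, tau_slow / tau_fast, 1.0, 1.0, 1.0, tau_fast, tau_slow)
        assert np.allclose(a, b, rtol=1e-9)


class TestCumulativeCounts:
    def test_no_quencher_ratio_is_one(self):
        assert cumulative_counts(2.0, 3.0, 5.0, 0.5, 7e-6, 7e-6) == pytest.approx(
            2.0 * 3.0 * 5.0 * 0.5
        )

    def test_linear_in_concentration(self):
        one = cumulative_counts(1e12, 1.5e-17, 50.0, 0.64, TAU_D, 8.77e-6)
        two = cumulative_counts(1e12, 1.5e-17, 100.0, 0.64, TAU_D, 8.77e-6)
        assert two == pytest.approx(2 * one)

    def test_equals_quadrature_of_pulse_response(self):
        tau_R = 8.77e-6
        expected = cumulative_counts(1e12, 1.5e-17, 50.0, 0.64, TAU_D, tau_R)
        val = _piecewise_quad(
            lambda t: pulse_response(t, 1e12, 1.5e-17, 50.0, 0.64, TAU_D, TAU_T) / tau_R
        )
        assert val == pytest.approx(expected, rel=1e-6)


class TestHistograms:
    def _pair(self, rng, lam_signal, lam_bg, edges):
        n = edges.size - 1
        g = np.ones(n, dtype=bool)
        h1270 = SoldHistogram(edges, rng.poisson(lam_signal + lam_bg, n), "1270", g)
        h1210 = SoldHistogram(edges, rng.poisson(lam_bg, n), "1210", g)
        return h1270, h1210

    def test_identical_histograms_cancel(self):
        edges = np.arange(0.0, 1e-5, 32e-9)
        counts = np.arange(edges.size - 1, dtype=float)
        a = SoldHistogram(edges, counts, "1270")
        b = SoldHistogram(edges, counts, "1210")
        assert np.all(subtract_background(a, b).counts == 0.0)

    def test_zero_background_passthrough(self):
        edges = np.arange(0.0, 1e-5, 32e-9)
        counts = np.linspace(0, 50, edges.size - 1)
        a = SoldHistogram(edges, counts, "1270")
        b = SoldHistogram(edges, np.zeros(edges.size - 1), "1210")
        assert np.allclose(subtract_background(a, b).counts, counts)

    def test_poisson_pair_mean_and_variance(self):
        """Net = signal in expectation, variance = 2 lambda_b + s."""
        rng = np.random.default_rng(11)
        edges = np.arange(2001) * 32e-9
        s, lb = 40.0, 25.0
        nets = []
        for _ in range(200):
            h1270, h1210 = self._pair(rng, s, lb, edges)
            nets.append(subtract_background(h1270, h1210).counts)
        nets = np.asarray(nets)
        assert nets.mean() == pytest.approx(s, rel=0.01)
        assert nets.var() == pytest.approx(2 * lb + s, rel=0.05)

    def test_mismatched_binning_rejected(self):
        a = SoldHistogram(np.arange(0.0, 1e-5, 32e-9),
                          np.zeros(len(np.arange(0.0, 1e-5, 32e-9)) - 1), "1270")
        b = SoldHistogram(np.arange(0.0, 1e-5, 64e-9),
                          np.zeros(len(np.arange(0.0, 1e-5, 64e-9)) - 1), "1210")
        with pytest.raises(ValueError):
            subtract_background(a, b)

    def test_negative_raw_counts_rejected(self):
        edges = np.arange(0.0, 1e-5, 32e-9)
        with pytest.raises(ValueError):
            SoldHistogram(edges, np.full(edges.size - 1, -1.0), "1270")

    def test_cumulative_counts_must_be_monotone(self):
        with pytest.raises(ValueError):
            SoldCumulative(np.array([1.0, 1.0]), np.array([2.0, 1.0]), 600.0)

    def test_csv_round_trip(self, meoh_params, tmp_path):
        from soedkit.synthetic_data import generate_sold_histograms

        h1270, _ = generate_sold_histograms(meoh_params, 50.0, 1e12, 1_000_000,
                                            background_rate=5.0, seed=3)
        path = tmp_path / "h.csv"
        h1270.to_csv(path)
        back = SoldHistogram.from_csv(path)
        assert np.array_equal(back.counts, h1270.counts)
        assert back.filter_label == "1270"
        assert back.bin_width == pytest.approx(h1270.bin_width)


class TestLifetimeFit:
    def test_noiseless_recovery(self, meoh_params):
        edges, lam = _expected_histogram(meoh_params, 50.0, 1e12, 2e8)
        net = SoldHistogram(edges, lam, "net")
        fit = fit_pulse_response(net)
        assert fit.tau_Delta == pytest.approx(meoh_params.tau_Delta, rel=1e-3)
        assert fit.tau_t == pytest.approx(meoh_params.tau_t, rel=1e-3)

    def test_amplitude_lifetime_identity(self, meoh_params):
        """amplitude * tau_Delta equals the quadrature integral of the fitted
        curve with the offset removed."""
        edges, lam = _expected_histogram(meoh_params, 50.0, 1e12, 2e8)
        fit = fit_pulse_response(SoldHistogram(edges, lam, "net"))
        integral = _piecewise_quad(lambda t: fit.curve(t) - fit.offset)
        assert integral == pytest.approx(fit.amplitude * fit.tau_Delta, rel=1e-6)

    def test_gate_mask_does_not_perturb_noiseless_fit(self, meoh_params):
        edges, lam = _expected_histogram(meoh_params, 50.0, 1e12, 2e8)
        full = fit_pulse_response(SoldHistogram(edges, lam, "net"))
        gate = np.ones(lam.size, dtype=bool)
        gate[::7] = False  # drop a comb of bins
        gated = fit_pulse_response(SoldHistogram(edges, lam, "net", gate))
        assert gated.tau_Delta == pytest.approx(full.tau_Delta, rel=1e-6)

    def test_offset_only_histogram_refused(self):
        rng = np.random.default_rng(5)
        edges = np.arange(0.0, 60e-6, 32e-9)
        counts = rng.poisson(30.0, edges.size - 1).astype(float)
        with pytest.raises(SoldFitError):
            fit_pulse_response(SoldHistogram(edges, counts, "net"))

    def test_too_few_bins_rejected(self):
        edges = np.arange(0.0, 33 * 32e-9, 32e-9)
        with pytest.raises(ValueError):
            fit_pulse_response(SoldHistogram(edges, np.ones(edges.size - 1), "net"))

    def test_bias_shrinks_with_total_counts(self, meoh_params):
        """Median tau_Delta error decreases as counts grow 1e3 -> 1e5."""
        from soedkit.synthetic_data import (
            expected_total_signal_counts,
            generate_sold_histograms,
        )

        per_pulse = expected_total_signal_counts(meoh_params, 50.0, 1e12, 1)
        errors = {}
        for target in (1e3, 1e5):
            n_pulses = int(np.ceil(target / per_pulse))
            errs = []
            for seed in range(30):
                h1270, h1210 = generate_sold_histograms(
                    meoh_params, 50.0, 1e12, n_pulses,
                    background_rate=0.5, seed=1000 + seed,
                )
                net = subtract_background(h1270, h1210)
                try:
                    fit = fit_pulse_response(net, variance=h1270.counts + h1210.counts)
                except SoldFitError:
                    continue
                errs.append(abs(fit.tau_Delta - meoh_params.tau_Delta))
            errors[target] = np.median(errs)
        assert errors[1e5] < errors[1e3]
        assert errors[1e5] < 0.1e-6
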