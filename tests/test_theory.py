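"""Closed-form spectral theory: moments, kernels, spectra, information rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stpfilter import (SignalSpec, SynapseParams, depression_kernel, gain,
                       linear_information_rate, noise_intensities,
                       population_spectra, signal_transfer_spectra,
                       single_synapse_spectra, steady_state)

FREQ = np.geomspace(0.01, 200.0, 200)

param_sets = st.builds(
    SynapseParams,
    n_sites=st.integers(1, 50),
    p_release=st.floats(0.05, 1.0),
    tau_rec=st.floats(0.02, 2.0),
)


class TestSteadyState:
    def test_no_depletion_without_release_or_input(self, params):
        for ss in (steady_state(params.with_(p_release=0.0), 20.0),
                   steady_state(params, 0.0)):
            assert ss.v_mean == params.n_sites
            assert ss.release_rate == 0.0

    def test_mean_pool_closed_form_value(self):
        params = SynapseParams(n_sites=10, p_release=0.5, tau_rec=0.2)
        assert steady_state(params, 10.0).v_mean == pytest.approx(5.0)

    def test_event_driven_simulation_oracle(self):
        # 500 s event-driven run reproduces the closed-form mean
        from stpfilter import simulate_poisson, simulate_stochastic

        params = SynapseParams(n_sites=10, p_release=0.5, tau_rec=0.2)
        _, traj = simulate_stochastic(params, simulate_poisson(10, 500, seed=0),
                                      seed=1)
        assert traj.values.mean() == pytest.approx(5.0, rel=0.03)

    def test_mean_pool_strictly_decreasing_in_rate(self, params):
        rates = np.linspace(1, 100, 50)
        v = [steady_state(params, r).v_mean for r in rates]
        assert np.all(np.diff(v) < 0)

    def test_second_moment_dominates_squared_mean(self, params):
        ss = steady_state(params, 20.0)
        assert ss.v_second >= ss.v_mean**2
        assert ss.tau_eff <= params.tau_rec


class TestGainAndKernel:
    def test_gain_matches_finite_difference_of_mean_conductance(self, params):
        h = 1e-4
        for r in (5.0, 40.0):
            fd = (steady_state(params, r + h).g_mean
                  - steady_state(params, r - h).g_mean) / (2 * h)
            assert gain(params, r) == pytest.approx(fd, rel=1e-6)
        fd0 = (steady_state(params, h).g_mean
               - steady_state(params, 0.0).g_mean) / h
        assert gain(params, 0.0) == pytest.approx(fd0, rel=1e-3)

    def test_gain_at_zero_rate_is_full_pool_release(self, params):
        assert gain(params, 0.0) == params.p_release * params.n_sites

    def test_gain_decreases_with_rate(self, params):
        assert gain(params, 100.0) < gain(params, 10.0)
        assert gain(params.with_(p_release=0.0), 20.0) == 0.0

    def test_kernel_magnitude_is_high_pass(self, params):
        a = np.abs(depression_kernel(params, 20.0, FREQ))
        assert np.all(np.diff(a) >= -1e-12)
        assert a[0] <= a[-1]

    def test_kernel_plateau_equals_mean_release_per_spike(self, params):
        ss = steady_state(params, 20.0)
        a_inf = abs(depression_kernel(params, 20.0, np.array([1e6]))[0])
        assert a_inf == pytest.approx(params.p_release * ss.v_mean, rel=1e-6)

    def test_kernel_zero_frequency_equals_gain(self, params):
        a0 = abs(depression_kernel(params, 20.0, np.array([0.0]))[0])
        assert a0 == pytest.approx(gain(params, 20.0), rel=1e-12)

    def test_depleted_zero_frequency_transfer_vanishes(self, params):
        # p r tau >> 1: the cross-spectrum at 0 Hz is tiny relative to plateau
        a = depression_kernel(params, 2000.0, np.array([0.0, 1e6]))
        assert abs(a[0]) / abs(a[1]) < 0.01
        # and |A(0)| r -> 0 as the synapse saturates
        a0 = [abs(depression_kernel(params, r, np.array([0.0]))[0]) * r
              for r in (100.0, 400.0, 1600.0)]
        assert a0[0] > a0[1] > a0[2]


class TestNoiseIntensities:
    def test_deterministic_model_has_no_intrinsic_noise(self, params):
        ni = noise_intensities(params, 20.0, "deterministic")
        assert ni.D_recovery == 0.0 and ni.D_release == 0.0
        assert ni.D_input > 0.0

    def test_stochastic_intensities_positive(self, params):
        ni = noise_intensities(params, 20.0, "stochastic")
        assert ni.D_recovery > 0 and ni.D_release > 0

    def test_certain_release_kills_binomial_variance(self, params):
        ni = noise_intensities(params.with_(p_release=1.0), 20.0, "stochastic")
        assert ni.D_release == 0.0

    def test_depleted_release_power_approaches_recovery_rate(self, params):
        # zero-frequency release power -> n/tau_rec when strongly depleted
        c = noise_intensities(params, 2000.0, "stochastic").covariance_coeffs
        s0 = c["delta_area"] + 2 * c["exp_amplitude"] * c["tau_eff"]
        assert s0 == pytest.approx(params.n_sites / params.tau_rec, rel=0.05)


class TestSingleSynapseSpectra:
    def test_deterministic_coherence_exactly_flat(self, params):
        th = single_synapse_spectra(params, 20.0, FREQ, "deterministic")
        assert th.coherence.max() / th.coherence.min() == pytest.approx(
            1.0, abs=1e-12)

    def test_stochastic_coherence_high_pass_and_near_zero_at_dc(self, params):
        th = single_synapse_spectra(params, 20.0, FREQ, "stochastic")
        assert th.coherence[0] < 0.01
        assert np.all(np.diff(th.coherence) >= -1e-12)

    def test_cross_spectrum_identical_between_models(self, params):
        a = single_synapse_spectra(params, 20.0, FREQ, "stochastic").S_xg
        b = single_synapse_spectra(params, 20.0, FREQ, "deterministic").S_xg
        assert np.allclose(a, b, rtol=1e-12)

    def test_conductance_kernel_suppresses_high_frequencies(self, params):
        for model in ("stochastic", "deterministic"):
            th = single_synapse_spectra(params, 20.0, np.array([1.0, 100.0]),
                                        model)
            assert th.S_gg[1] < 0.5 * th.S_gg[0]

    def test_cross_spectrum_band_pass_with_interior_peak(self, params):
        # |S_xg| peaks between the depression and kernel corner frequencies
        ss = steady_state(params, 20.0)
        f_lo = 1 / (2 * np.pi * ss.tau_eff)
        f_hi = 1 / (2 * np.pi * params.kernel.tau_syn)
        th = single_synapse_spectra(params, 20.0, FREQ, "stochastic")
        f_peak = FREQ[np.argmax(np.abs(th.S_xg))]
        assert f_lo < f_peak < f_hi

    @given(params=param_sets, rate=st.floats(1.0, 200.0))
    @settings(max_examples=40, deadline=None)
    def test_cauchy_schwarz_and_model_ordering(self, params, rate):
        sto = single_synapse_spectra(params, rate, FREQ, "stochastic")
        det = single_synapse_spectra(params, rate, FREQ, "deterministic")
        for th in (sto, det):
            assert np.all(np.abs(th.S_xg) ** 2
                          <= th.S_xx * th.S_gg * (1 + 1e-9))
            assert np.all(th.S_gg >= -1e-12)
            assert np.all((th.coherence >= 0) & (th.coherence <= 1))
        assert np.all(sto.S_gg >= det.S_gg * (1 - 1e-9))
        assert np.all(sto.coherence <= det.coherence * (1 + 1e-9))


class TestPopulation:
    def test_single_member_reduces_to_single_synapse(self, params):
        one = single_synapse_spectra(params, 20.0, FREQ, "stochastic")
        pop = population_spectra(params, 20.0, 0.0, 1, FREQ, "stochastic")
        assert np.allclose(pop.S_xg, one.S_xg)
        assert np.allclose(pop.coherence, one.coherence)

    @pytest.mark.parametrize("n", [1, 10, 100])
    def test_uncorrelated_population_coherence_is_single_synapse(self, params, n):
        one = single_synapse_spectra(params, 20.0, FREQ, "stochastic").coherence
        pop = population_spectra(params, 20.0, 0.0, n, FREQ,
                                 "stochastic").coherence
        assert np.allclose(pop, one, rtol=1e-10)

    def test_models_converge_for_large_correlated_population(self, params):
        f = np.array([1.0])
        cs = population_spectra(params, 20.0, 0.1, 10_000, f,
                                "stochastic").coherence[0]
        cd = population_spectra(params, 20.0, 0.1, 10_000, f,
                                "deterministic").coherence[0]
        assert cs / cd == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("model", ["stochastic", "deterministic"])
    def test_correlated_population_conductance_power_has_interior_peak(
            self, params, model):
        # Poisson inputs are white, yet the population conductance power
        # is band-pass: depression suppresses slow fluctuations, the
        # conductance kernel fast ones, leaving an interior rhythm-like
        # peak between the two corner frequencies.
        f = np.linspace(0.1, 100.0, 2000)
        th = population_spectra(params, 20.0, 0.1, 100, f, model)
        i_peak = np.argmax(th.S_gg)
        f_lo = 1 / (2 * np.pi * steady_state(params, 20.0).tau_eff)
        f_hi = 1 / (2 * np.pi * params.kernel.tau_syn)
        assert f_lo < f[i_peak] < f_hi
        assert th.S_gg[i_peak] > 1.5 * th.S_gg[0]
        assert th.S_gg[i_peak] > 1.5 * th.S_gg[-1]


class TestSignalTransfer:
    def test_zero_signal_reduces_to_population(self, params):
        pop = population_spectra(params, 20.0, 0.1, 10, FREQ, "stochastic")
        sig = signal_transfer_spectra(params, 20.0,
                                      SignalSpec(peak_power=0.0), 0.1, 10,
                                      FREQ, "stochastic")
        assert np.allclose(sig.S_gg, pop.S_gg)
        assert np.allclose(sig.coherence, pop.coherence)
        assert not sig.coherence_signal.any()

    def test_deterministic_peak_signal_coherence_shift_invariant(self, params):
        offsets = np.linspace(-2.0, 2.0, 2001)
        peaks = []
        for fc in (10.0, 45.0):
            spec = SignalSpec(bandwidth=0.1, central_frequency=fc,
                              peak_power=20.0)
            th = signal_transfer_spectra(params, 20.0, spec, 0.0, 1,
                                         fc + offsets, "deterministic")
            peaks.append(th.coherence_signal.max())
        assert peaks[0] == pytest.approx(peaks[1], rel=1e-9)

    def test_stochastic_transfers_fast_signals_more_reliably(self, params):
        peaks = []
        for fc in (1.0, 45.0):
            f = np.linspace(max(fc - 2, 0.01), fc + 2, 2001)
            spec = SignalSpec(bandwidth=0.1, central_frequency=fc,
                              peak_power=20.0)
            th = signal_transfer_spectra(params, 20.0, spec, 0.0, 1, f,
                                         "stochastic")
            peaks.append(th.coherence_signal.max())
        assert peaks[1] > peaks[0]

    def test_large_signal_triggers_linearization_warning(self, params):
        spec = SignalSpec(bandwidth=1.0, central_frequency=5.0,
                          peak_power=100.0)
        with pytest.warns(UserWarning, match="peak power"):
            signal_transfer_spectra(params, 20.0, spec, 0.0, 1, FREQ,
                                    "stochastic")


class TestInformationRate:
    def test_zero_coherence_carries_no_information(self):
        f = np.linspace(0, 100, 1001)
        assert linear_information_rate(f, np.zeros_like(f)) == 0.0

    def test_half_coherence_band_closed_form(self):
        # C = 1/2 on [0, 10] Hz -> -10 log2(1/2) = 10 bits/s
        f = np.linspace(0, 10, 100_001)
        assert linear_information_rate(f, np.full_like(f, 0.5)) == \
            pytest.approx(10.0, rel=1e-9)

    def test_perfect_coherence_diverges(self):
        f = np.linspace(0, 10, 11)
        with pytest.raises(ValueError, match="diverges"):
            linear_information_rate(f, np.ones_like(f))

    def test_monotone_in_pointwise_coherence(self):
        f = np.linspace(0, 50, 501)
        lo = linear_information_rate(f, np.full_like(f, 0.2))
        hi = linear_information_rate(f, np.full_like(f, 0.4))
        assert hi > lo

    def test_stochastic_rate_below_deterministic_at_every_frequency(
            self, params):
        f = np.arange(0.0, 100.0, 0.01) + 0.005
        for fc in np.linspace(1, 50, 8):
            spec = SignalSpec(bandwidth=0.1, central_frequency=fc,
                              peak_power=20.0)
            rates = {}
            for model in ("stochastic", "deterministic"):
                th = signal_transfer_spectra(params, 20.0, spec, 0.0, 1, f,
                                             model)
                rates[model] = linear_information_rate(f, th.coherence_signal)
            assert rates["stochastic"] < rates["deterministic"]
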