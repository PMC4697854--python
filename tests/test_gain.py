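"""Stationary rate, dynamic gain cascade, shape taxonomy, step response."""

import math
import warnings

import numpy as np
import pytest

from gifgain import (
    InputModel,
    NeuronParameters,
    classify_shape,
    critical_rate,
    descriptors,
    dynamic_gain,
    f_limit,
    is_voltage_resonant,
    linear_response,
    sigma_I_for_rate,
    stationary_rate,
    step_response,
    tau_c,
    tau_s,
    to_implicit,
    voltage_moments,
)
from gifgain.gain import critical_rate_closed_form, linear_response_biquad, max_rate

from conftest import TAU_I, random_stable_neurons


class TestStationaryRate:
    def test_saturation_of_spikes_per_correlation_window(self, default_neuron):
        # nu0 * tau_s -> 1/(2 pi) as the noise dominates the threshold
        inp = InputModel(tau_I=TAU_I, sigma_I=1e9)
        val = stationary_rate(default_neuron, inp) * tau_s(default_neuron, inp)
        assert val == pytest.approx(1.0 / (2 * math.pi), rel=1e-9)

    def test_unit_relative_fluctuations(self, default_neuron):
        # sigma_V = theta gives nu0 tau_s = exp(-1/2)/(2 pi)
        st = voltage_moments(default_neuron, InputModel(tau_I=TAU_I, sigma_I=1.0))
        inp = InputModel(tau_I=TAU_I, sigma_I=1.0 / st.sigma_V)
        val = stationary_rate(default_neuron, inp) * tau_s(default_neuron, inp)
        assert val == pytest.approx(math.exp(-0.5) / (2 * math.pi), rel=1e-10)

    def test_zero_noise_is_silent(self, default_neuron):
        assert stationary_rate(default_neuron, InputModel(tau_I=TAU_I, sigma_I=0.0)) == 0.0

    def test_monotone_in_noise_and_bounded(self, default_neuron):
        sigmas = np.linspace(0.1, 20.0, 40)
        rates = [stationary_rate(default_neuron, InputModel(tau_I=TAU_I, sigma_I=s))
                 for s in sigmas]
        assert np.all(np.diff(rates) > 0)
        assert rates[-1] < max_rate(default_neuron, TAU_I)


class TestRateCalibration:
    def test_round_trip_on_random_parameter_sets(self):
        rng = np.random.default_rng(41)
        for p in random_stable_neurons(rng, 100):
            tau_i = 10 ** rng.uniform(-0.5, 0.5)
            bound = max_rate(p, tau_i)
            target = bound * rng.uniform(0.01, 0.9)
            sig = sigma_I_for_rate(p, tau_i, target)
            achieved = stationary_rate(p, InputModel(tau_I=tau_i, sigma_I=sig))
            assert achieved == pytest.approx(target, rel=1e-8)

    def test_forbidden_rate_diagnostic(self, default_neuron):
        bound = max_rate(default_neuron, TAU_I)
        with pytest.raises(ValueError, match="forbidden rate"):
            sigma_I_for_rate(default_neuron, TAU_I, bound * 1.01)
        with pytest.raises(ValueError, match="forbidden rate"):
            sigma_I_for_rate(default_neuron, TAU_I, 0.0)

    def test_divergence_near_the_bound(self, default_neuron):
        bound = max_rate(default_neuron, TAU_I)
        s1 = sigma_I_for_rate(default_neuron, TAU_I, bound * (1 - 1e-4))
        s2 = sigma_I_for_rate(default_neuron, TAU_I, bound * (1 - 1e-8))
        assert s2 > 50 * s1  # sigma_I diverges as the rate approaches 1/(2 pi tau_s)

    def test_running_example_noise_level(self, default_neuron, default_drive):
        # nu0 tau_s = 0.01 corresponds to sigma_V = 0.4251
        st = voltage_moments(default_neuron, default_drive)
        assert st.sigma_rel == pytest.approx(
            math.sqrt(0.5 / math.log(1 / (2 * math.pi * 0.01))), rel=1e-10
        )
        assert st.sigma_rel == pytest.approx(0.42507, rel=1e-4)


class TestSpikingFilterTime:
    def test_proportionality_constant(self, default_neuron):
        st = voltage_moments(default_neuron, InputModel(tau_I=TAU_I, sigma_I=1.0))
        inp = InputModel(tau_I=TAU_I, sigma_I=1.0 / st.sigma_V)  # sigma = 1
        ts = tau_s(default_neuron, inp)
        assert tau_c(default_neuron, inp) == pytest.approx(math.sqrt(math.pi / 2) * ts,
                                                           rel=1e-10)

    def test_running_example_value(self, default_neuron, default_drive):
        assert tau_c(default_neuron, default_drive) == pytest.approx(1.372, rel=1e-3)

    def test_vanishes_with_rate(self, default_neuron):
        # tau_c -> 0 as nu0 -> 0, though only as 1/sqrt(log) in the rate
        tcs = [
            tau_c(default_neuron,
                  InputModel(tau_I=TAU_I, sigma_I=sigma_I_for_rate(default_neuron, TAU_I, nu)))
            for nu in (1e-3, 1e-12, 1e-60, 1e-250)
        ]
        assert np.all(np.diff(tcs) < 0)
        assert tcs[-1] < 0.15

    def test_increases_with_rate(self, default_neuron):
        bound = max_rate(default_neuron, TAU_I)
        tcs = [
            tau_c(default_neuron,
                  InputModel(tau_I=TAU_I, sigma_I=sigma_I_for_rate(default_neuron, TAU_I,
                                                                   f * bound)))
            for f in (0.01, 0.1, 0.5, 0.9)
        ]
        assert np.all(np.diff(tcs) > 0)


class TestLinearResponse:
    def test_zero_frequency_value(self, default_neuron, default_drive):
        st = voltage_moments(default_neuron, default_drive)
        expected = 0.25 / (st.sigma_rel**2 * default_neuron.theta)
        assert linear_response(default_neuron, default_drive, 0.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_lif_reduces_to_single_order_filter(self):
        p = NeuronParameters(tau_V=10.0, g=0.0, tau_w=20.0)
        inp = InputModel(tau_I=1.0, sigma_I=0.5)
        st = voltage_moments(p, inp)
        tc = tau_c(p, inp)
        w = np.logspace(-3, 2, 30)
        expected = (1 + 1j * w * tc) / (1 + 1j * w * p.tau_V) / st.sigma_rel**2
        assert np.allclose(linear_response(p, inp, w), expected, rtol=1e-12)

    def test_biquad_cascade_form_identical(self):
        rng = np.random.default_rng(43)
        for p in random_stable_neurons(rng, 30):
            tau_i = 10 ** rng.uniform(-0.5, 0.5)
            sig = sigma_I_for_rate(p, tau_i, max_rate(p, tau_i) * rng.uniform(0.05, 0.8))
            inp = InputModel(tau_I=tau_i, sigma_I=sig)
            w = 10.0 ** rng.uniform(-3, 2, 7)
            a = linear_response(p, inp, w)
            b = linear_response_biquad(p, inp, w)
            assert np.max(np.abs(a - b) / np.abs(a)) < 1e-12

    def test_limit_consistency_chain(self, default_neuron, default_drive):
        d = descriptors(default_neuron, default_drive)
        lo = abs(linear_response(default_neuron, default_drive, 1e-5 / d.tau_s))
        hi = abs(linear_response(default_neuron, default_drive, 1e5 / d.tau_s))
        assert lo == pytest.approx(d.nu_low, rel=1e-6)
        assert hi == pytest.approx(d.nu_high, rel=1e-6)
        assert d.nu_inf == pytest.approx(d.nu_high / d.nu_low, rel=1e-12)
        assert d.nu_inf == pytest.approx(d.tau_c / default_neuron.tau_eff, rel=1e-12)

    def test_running_example_descriptors(self, default_neuron, default_drive):
        d = descriptors(default_neuron, default_drive)
        assert d.nu_inf == pytest.approx(0.549, rel=1e-3)
        assert d.nu_omegaL == pytest.approx(2.881, rel=1e-3)

    def test_dynamic_gain_curve(self, default_neuron, default_drive):
        freq = np.logspace(-1, 3, 120)
        curve = dynamic_gain(default_neuron, default_drive, freq)
        assert np.all(np.isfinite(curve.gain))
        assert np.all((curve.phase > -math.pi) & (curve.phase <= math.pi))
        # gain peaks near the center frequency for this resonant example
        f_peak = freq[np.argmax(curve.gain)]
        f_center = curve.descriptors.omega_L / (2 * math.pi) * 1000
        assert f_peak == pytest.approx(f_center, rel=0.2)

    def test_rejects_bad_grid(self, default_neuron, default_drive):
        with pytest.raises(ValueError):
            dynamic_gain(default_neuron, default_drive, np.array([10.0, 5.0]))


class TestCriticalRate:
    def test_defining_identity(self, default_neuron):
        nu_crit = critical_rate(default_neuron, TAU_I)
        sig = sigma_I_for_rate(default_neuron, TAU_I, nu_crit)
        d = descriptors(default_neuron, InputModel(tau_I=TAU_I, sigma_I=sig))
        assert d.nu_inf == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_agrees(self):
        rng = np.random.default_rng(47)
        for p in random_stable_neurons(rng, 25):
            assert critical_rate(p, 1.0) == pytest.approx(
                critical_rate_closed_form(p, 1.0), rel=1e-10
            )

    def test_lif_reduction(self):
        # g = 0: tau_eff = tau_V and the closed form uses tau_s = sqrt(tau_I tau_V)
        p = NeuronParameters(tau_V=10.0, g=0.0, tau_w=20.0)
        ts = math.sqrt(10.0)
        expected = math.exp(-(math.pi / 4) * ts**2 / 100.0) / (2 * math.pi * ts)
        assert critical_rate(p, 1.0) == pytest.approx(expected, rel=1e-10)

    def test_diverges_for_fast_voltage_correlations(self):
        # tau_s << tau_eff: critical rate approaches the 1/(2 pi tau_s) scale
        p = NeuronParameters(tau_V=100.0, g=0.2, tau_w=50.0)
        tau_i = 1e-3
        nu_crit = critical_rate(p, tau_i)
        ts = tau_s(p, InputModel(tau_I=tau_i, sigma_I=1.0))
        assert ts < 0.05 * p.tau_eff
        assert nu_crit == pytest.approx(1 / (2 * math.pi * ts), rel=0.01)

    def test_low_pass_below_high_pass_above(self, default_neuron):
        nu_crit = critical_rate(default_neuron, TAU_I)
        for frac, expect_high in ((0.5, False), (1.5, True)):
            sig = sigma_I_for_rate(default_neuron, TAU_I, frac * nu_crit)
            d = descriptors(default_neuron, InputModel(tau_I=TAU_I, sigma_I=sig))
            assert (d.nu_inf > 1) == expect_high


class TestShapeTaxonomy:
    def test_running_example_is_resonant_low_pass(self, default_neuron, default_drive):
        d = descriptors(default_neuron, default_drive)
        s = classify_shape(d, default_neuron)
        assert s.region == (1, -1, 1)
        assert s.spiking_resonant and s.pass_type == "low" and s.accessible

    def test_only_six_patterns_occur(self):
        rng = np.random.default_rng(53)
        seen = set()
        impossible = {(1, -1, -1), (-1, 1, 1)}
        for p in random_stable_neurons(rng, 3000):
            tau_i = 10 ** rng.uniform(-1, 1)
            nu = max_rate(p, tau_i) * rng.uniform(1e-4, 0.999)
            inp = InputModel(tau_I=tau_i, sigma_I=sigma_I_for_rate(p, tau_i, nu))
            s = classify_shape(descriptors(p, inp), p)
            assert s.region not in impossible
            seen.add(s.region)
        assert len(seen) == 6

    def test_amgm_lower_bound_with_equality_at_xi_one(self):
        rng = np.random.default_rng(59)
        for p in random_stable_neurons(rng, 10_000):
            tau_i = 10 ** rng.uniform(-1, 1)
            nu = max_rate(p, tau_i) * rng.uniform(1e-4, 0.999)
            d = descriptors(p, InputModel(tau_I=tau_i,
                                          sigma_I=sigma_I_for_rate(p, tau_i, nu)))
            assert d.nu_omegaL >= d.Q_L * (1 + d.nu_inf) * (1 - 1e-12)
        # equality exactly when tau_w = tau_c: calibrate sigma so tau_c = tau_w
        p = NeuronParameters(tau_V=10.0, g=1.0, tau_w=3.0)
        st = voltage_moments(p, InputModel(tau_I=1.0, sigma_I=1.0))
        sigma_rel = p.tau_w / (math.sqrt(math.pi / 2) * st.tau_s)
        inp = InputModel(tau_I=1.0, sigma_I=sigma_rel / st.sigma_V)
        d = descriptors(p, inp)
        assert d.xi == pytest.approx(1.0, rel=1e-10)
        assert d.nu_omegaL == pytest.approx(d.Q_L * (1 + d.nu_inf), rel=1e-10)

    def test_center_response_approaches_quality_factor(self, default_neuron):
        # nu_omegaL -> Q_L as nu_inf -> 0 at fixed xi
        d = descriptors(default_neuron,
                        InputModel(tau_I=TAU_I,
                                   sigma_I=sigma_I_for_rate(default_neuron, TAU_I, 1e-18)))
        # directly check the identity at small nu_inf
        nu_inf = 1e-6
        xi = d.xi
        val = d.Q_L * math.sqrt((1 + nu_inf * xi) * (1 + nu_inf / xi))
        assert val == pytest.approx(d.Q_L, rel=1e-4)

    def test_double_dissociation_of_resonances(self):
        # all four combinations of voltage/spiking resonance are realizable
        tau_i = 1.0

        def flags(p, sigma_rel):
            st = voltage_moments(p, InputModel(tau_I=tau_i, sigma_I=1.0))
            inp = InputModel(tau_I=tau_i, sigma_I=sigma_rel / st.sigma_V)
            s = classify_shape(descriptors(p, inp), p)
            return is_voltage_resonant(p), s.spiking_resonant

        # resonator driven sparsely: both resonances
        assert flags(NeuronParameters(tau_V=10.0, g=3.0, tau_w=20.0), 0.425) == (True, True)
        # slow adaptation, strong drive: voltage resonance masked in spiking
        assert flags(NeuronParameters(tau_V=10.0, g=1.2, tau_w=100.0), 5.0) == (True, False)
        # fast intrinsic current, strong drive: spiking resonance without
        # voltage resonance (low-frequency attenuation by the spiking filter)
        assert flags(NeuronParameters(tau_V=10.0, g=0.5, tau_w=5.0), 1.761) == (False, True)
        # same neuron, weak drive: neither
        assert flags(NeuronParameters(tau_V=10.0, g=0.5, tau_w=5.0), 0.3) == (False, False)


class TestStepResponse:
    def test_causality(self, default_neuron, default_drive):
        t = np.linspace(-40.0, -0.1, 20)
        assert np.all(step_response(default_neuron, default_drive, 0.1, t) == 0.0)

    def test_jump_and_asymptote_identities(self, default_neuron, default_drive):
        d = descriptors(default_neuron, default_drive)
        A = 0.1
        jump = A * d.nu_low * d.nu_inf  # = A theta tau_c / (sigma_V^2 tau_V)
        r0 = float(step_response(default_neuron, default_drive, A, np.array([1e-12]))[0])
        assert r0 == pytest.approx(jump, rel=1e-9)
        r_inf = float(step_response(default_neuron, default_drive, A, np.array([1e7]))[0])
        assert r_inf == pytest.approx(A * d.nu_low, rel=1e-10)

    def test_matches_inverse_transform_oracle(self, default_neuron, default_drive):
        # independent oracle: numerical inverse transform of the linear
        # response times the step spectrum; the principal-value part and the
        # slowly decaying tail are carried by analytic bridge filters
        p, inp = default_neuron, default_drive
        A = 0.1
        d = descriptors(p, inp)
        wmax, N = 2000.0, 2**23
        wg = np.linspace(0.0, wmax, N // 2 + 1)
        resp = linear_response(p, inp, wg)
        c0 = d.nu_low * d.nu_inf  # high-frequency plateau
        G2 = resp - c0
        G20 = float(np.real(G2[0]))
        b1 = float(np.real(1j * wg[-1] * G2[-1]))  # 1/omega tail coefficient
        tau_a, tau_b = 5.0, 20.0
        c1 = (b1 - G20 / tau_b) / (1 / tau_a - 1 / tau_b)
        c2 = G20 - c1
        bridge = c1 / (1 + 1j * wg * tau_a) + c2 / (1 + 1j * wg * tau_b)
        H = np.empty_like(G2)
        H[1:] = (G2[1:] - bridge[1:]) / (1j * wg[1:])
        H[0] = 2 * H[1] - H[2]
        dw = wg[1] - wg[0]
        smooth = np.fft.irfft(H, n=N) * (N * dw / (2 * math.pi))
        t = np.arange(N) * (2 * math.pi / (N * dw))
        oracle = A * (c0 + c1 * (1 - np.exp(-t / tau_a)) + c2 * (1 - np.exp(-t / tau_b))
                      + smooth)
        mask = (t > 0.02) & (t < 300.0)
        closed = step_response(p, inp, A, t[mask])
        jump = A * c0
        assert np.max(np.abs(oracle[mask] - closed)) < 1e-6 * jump

    def test_rings_at_intrinsic_frequency(self, default_neuron, default_drive):
        imp = to_implicit(default_neuron)
        A = 0.1
        t = np.linspace(0.5, 200.0, 200001)
        r = step_response(default_neuron, default_drive, A, t)
        asym = float(step_response(default_neuron, default_drive, A, np.array([1e7]))[0])
        dev = r - asym
        crossings = t[np.nonzero(np.diff(np.sign(dev)))[0]]
        gaps = np.diff(crossings)
        assert np.allclose(gaps, math.pi / imp.Omega, rtol=0.05)
        # envelope decays with the relaxation time
        peaks = np.abs(dev)
        k1 = np.argmin(np.abs(t - 20.0))
        k2 = np.argmin(np.abs(t - 20.0 - imp.tau_r))
        assert peaks[k2] < peaks[k1]


class TestEifCutoff:
    def test_inverse_scaling_with_slope_factor(self, default_neuron, default_drive):
        f1 = f_limit(default_neuron, default_drive, 0.35)
        f2 = f_limit(default_neuron, default_drive, 0.035)
        assert f2 / f1 == pytest.approx(10.0, rel=1e-10)

    def test_unprotected_resonance_warns(self, default_neuron, default_drive):
        with pytest.warns(UserWarning, match="resonance not protected"):
            f_limit(default_neuron, default_drive, 1e3)

    def test_protected_resonance_is_silent(self, default_neuron, default_drive):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            f_limit(default_neuron, default_drive, 0.035)
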