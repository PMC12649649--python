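"""Single-neuron E-GLIF dynamics: exact propagation, escape noise, resets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respicpg import eglif
from respicpg.eglif import (
    EGLIFParameters,
    NeuronState,
    apply_spike_reset,
    calibrate_to_rate,
    draw_spike,
    escape_rate,
    fixed_point,
    pattern_parameters,
    propagate,
    rhythm_parameters,
    spike_probability,
    subthreshold_eigenvalues,
)


@pytest.fixture(scope="module")
def rhythm():
    return rhythm_parameters()


@pytest.fixture(scope="module")
def pattern():
    return pattern_parameters()


from helpers import rk4_oracle


class TestPropagate:
    def test_pure_leak_closed_form(self):
        p = EGLIFParameters(C_m=100, tau_m=30, E_L=-65, I_e=0, V_th=-50,
                            V_r=-60, t_ref=2, lambda_0=1e-4, tau_V=1.7,
                            k_adap=0.0, k_2=0.0331, k_1=0.007, A_2=5, A_1=0)
        s = NeuronState(V_m=p.E_L + 10.0)
        out = propagate(s, p, 12.5)
        assert out.V_m == pytest.approx(p.E_L + 10.0 * math.exp(-12.5 / 30.0),
                                        abs=1e-12)

    @given(st.floats(-80, -40), st.floats(-50, 50), st.floats(0, 100),
           st.floats(0.05, 20.0))
    @settings(max_examples=100, deadline=None)
    def test_semigroup_property(self, v, ia, idp, dt):
        """Two half steps equal one full step for the exact propagator."""
        p = rhythm_parameters()
        s = NeuronState(V_m=v, I_adap=ia, I_dep=idp)
        once = propagate(s, p, dt)
        twice = propagate(propagate(s, p, dt / 2), p, dt / 2)
        assert twice.V_m == pytest.approx(once.V_m, abs=1e-9)
        assert twice.I_adap == pytest.approx(once.I_adap, abs=1e-9)
        assert twice.I_dep == pytest.approx(once.I_dep, abs=1e-9)

    @pytest.mark.parametrize("factory", [rhythm_parameters, pattern_parameters])
    def test_matches_dense_rk4_oracle(self, factory):
        """500 ms trajectory agrees with brute-force RK4 at dt=1 us."""
        p = factory()
        s = NeuronState(V_m=-60.0, I_adap=10.0, I_dep=5.0)
        # exact propagation in 0.1 ms steps
        cur = s
        for _ in range(5000):
            cur = propagate(cur, p, 0.1)
        ref = rk4_oracle(s, p, 500.0)
        assert cur.V_m == pytest.approx(ref[0], abs=1e-5)
        assert cur.I_adap == pytest.approx(ref[1], abs=1e-5)

    def test_refractory_clamps_voltage_but_not_currents(self, rhythm):
        s = NeuronState(V_m=rhythm.V_r, I_adap=20.0, I_dep=3.0,
                        refractory_remaining=1.0)
        out = propagate(s, rhythm, 0.4)
        assert out.V_m == rhythm.V_r
        assert out.refractory_remaining == pytest.approx(0.6)
        assert out.I_adap != s.I_adap  # currents keep evolving
        assert out.I_dep == pytest.approx(3.0 * math.exp(-rhythm.k_1 * 0.4))

    def test_refractory_clock_floors_at_zero(self, rhythm):
        s = NeuronState(V_m=rhythm.V_r, refractory_remaining=0.3)
        assert propagate(s, rhythm, 5.0).refractory_remaining == 0.0

    def test_invalid_arguments_rejected(self, rhythm):
        with pytest.raises(ValueError):
            propagate(NeuronState(V_m=-60.0), rhythm, 0.0)
        with pytest.raises(ValueError):
            propagate(NeuronState(V_m=float("nan")), rhythm, 0.1)

    def test_converges_to_fixed_point_without_noise(self):
        p = rhythm_parameters(lambda_0=0.0)
        star = fixed_point(p)
        cur = NeuronState(V_m=-60.0)
        for _ in range(400):  # the slow relaxation mode needs tens of seconds
            cur = propagate(cur, p, 100.0)
        assert cur.V_m == pytest.approx(star.V_m, abs=1e-6)
        assert cur.I_adap == pytest.approx(star.I_adap, abs=1e-6)


class TestEscapeRate:
    def test_threshold_and_one_width_above(self, rhythm):
        assert escape_rate(rhythm.V_th, rhythm) == pytest.approx(rhythm.lambda_0)
        assert escape_rate(rhythm.V_th + rhythm.tau_V, rhythm) == pytest.approx(
            rhythm.lambda_0 * math.e)

    def test_zero_scale_is_identically_zero(self):
        p = rhythm_parameters(lambda_0=0.0)
        for v in (-80.0, -50.0, 0.0):
            assert escape_rate(v, p) == 0.0

    @given(st.floats(-80, -30), st.floats(0.01, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_voltage(self, v, dv):
        p = rhythm_parameters()
        assert escape_rate(v + dv, p) > escape_rate(v, p)


class TestDrawSpike:
    def test_never_spikes_with_zero_scale(self):
        p = rhythm_parameters(lambda_0=0.0)
        rng = np.random.default_rng(0)
        s = NeuronState(V_m=0.0)  # far above threshold
        assert not any(draw_spike(s, p, 0.1, rng) for _ in range(1000))

    def test_monte_carlo_matches_closed_form(self, rhythm):
        """Spike fraction over 1e6 draws within 3 binomial SD of 1-exp(-lam dt)."""
        # choose V so that lambda * dt = 0.01
        lam = 0.1  # per ms
        v = rhythm.V_th + rhythm.tau_V * math.log(lam / rhythm.lambda_0)
        s = NeuronState(V_m=v)
        dt = 0.1
        p_true = -math.expm1(-lam * dt)
        rng = np.random.default_rng(12345)
        n = 1_000_000
        draws = rng.random(n)  # same stream draw_spike would consume
        hits = int(np.sum(draws < spike_probability(v, rhythm, dt)))
        sd = math.sqrt(n * p_true * (1 - p_true))
        assert abs(hits - n * p_true) < 3 * sd

    def test_refractory_neuron_rejected(self, rhythm):
        s = NeuronState(V_m=-50.0, refractory_remaining=1.0)
        with pytest.raises(RuntimeError):
            draw_spike(s, rhythm, 0.1, np.random.default_rng(0))

    def test_consumes_exactly_one_draw(self, rhythm):
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        s = NeuronState(V_m=-50.0)
        draw_spike(s, rhythm, 0.1, rng1)
        rng2.random()
        assert rng1.random() == rng2.random()


class TestSpikeReset:
    def test_reset_updates_set_mode(self):
        p = rhythm_parameters(dep_increment=False)
        s = NeuronState(V_m=-45.0, I_adap=2.0, I_dep=1.0)
        out = apply_spike_reset(s, p, t=123.4)
        assert out.V_m == p.V_r
        assert out.I_adap == pytest.approx(2.0 + p.A_2)
        assert out.I_dep == p.A_1  # set, not incremented
        assert out.refractory_remaining == p.t_ref
        assert out.last_spike_time == 123.4

    def test_adaptation_increment_is_cumulative(self):
        p = rhythm_parameters(dep_increment=False)
        s = NeuronState(V_m=-45.0, I_adap=2.0)
        twice = apply_spike_reset(apply_spike_reset(s, p, 0.0), p, 0.0)
        assert twice.I_adap == pytest.approx(2.0 + 2 * p.A_2)
        assert twice.I_dep == p.A_1  # still set, not incremented

    def test_spike_current_accumulates_in_increment_mode(self, rhythm):
        assert rhythm.dep_increment
        s = NeuronState(V_m=-45.0, I_dep=-10.0)
        twice = apply_spike_reset(apply_spike_reset(s, rhythm, 0.0), rhythm, 0.0)
        assert twice.I_dep == pytest.approx(-10.0 + 2 * rhythm.A_1)

    def test_zero_a1_clears_depolarizing_current(self):
        p = rhythm_parameters(A_1=0.0, dep_increment=False)
        out = apply_spike_reset(NeuronState(V_m=-45.0, I_dep=50.0), p, 0.0)
        assert out.I_dep == 0.0


class TestEigenvalues:
    def test_uncoupled_gives_pure_decay_rates(self):
        p = rhythm_parameters(k_adap=0.0)
        ev = sorted(subthreshold_eigenvalues(p), key=lambda z: z.real)
        assert ev[0].imag == 0 and ev[1].imag == 0
        assert {round(-e.real, 6) for e in ev} == {
            round(1 / p.tau_m, 6), round(p.k_2, 6)}

    def test_resonant_case_hand_algebra(self):
        """k_2 = 1/tau_m gives eigenvalues -1/tau_m +- i sqrt(k_adap/C_m)."""
        p = rhythm_parameters(k_2=1.0 / 30.0, tau_m=30.0)
        ev = subthreshold_eigenvalues(p)
        for z in ev:
            assert z.real == pytest.approx(-1.0 / 30.0, abs=1e-12)
        omega = math.sqrt(p.k_adap / p.C_m)
        assert sorted(z.imag for z in ev) == pytest.approx([-omega, omega])

    def test_pattern_is_oscillatory_rhythm_has_slow_mode(self):
        """Pattern rings (k_2 = 1/tau_m, non-damping); rhythm is overdamped
        with a relaxation mode slower than one second."""
        pat = subthreshold_eigenvalues(pattern_parameters())
        assert all(abs(z.imag) > 0 for z in pat)
        rhy = subthreshold_eigenvalues(rhythm_parameters())
        assert all(z.imag == 0 for z in rhy)
        slowest = max(rhy, key=lambda z: z.real)
        assert -1.0 / slowest.real > 500.0  # ms
        # cross-check against the characteristic polynomial
        for p, ev in ((pattern_parameters(), pat), (rhythm_parameters(), rhy)):
            a, b = -1 / p.tau_m, -1 / p.C_m
            c, d = p.k_adap, -p.k_2
            for z in ev:
                assert abs((z - a) * (z - d) - b * c) < 1e-9


class TestCalibration:
    def test_fixed_point_placed_at_threshold_for_target_rate(self):
        p = calibrate_to_rate(rhythm_parameters(), 0.1)
        # lambda_0 = 1e-4 / ms = 0.1 Hz, so the fixed point sits at V_th
        assert fixed_point(p).V_m == pytest.approx(p.V_th, abs=1e-9)

    def test_other_targets_shift_rest_by_log_rate(self):
        p0 = rhythm_parameters()
        lo = calibrate_to_rate(p0, 0.05)
        hi = calibrate_to_rate(p0, 0.2)
        shift = fixed_point(hi).V_m - fixed_point(lo).V_m
        assert shift == pytest.approx(p0.tau_V * math.log(4), abs=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            EGLIFParameters(C_m=-1, tau_m=30, E_L=-65, I_e=0, V_th=-50,
                            V_r=-60, t_ref=2, lambda_0=1e-4, tau_V=1.7,
                            k_adap=0.5, k_2=0.03, k_1=0.007, A_2=5, A_1=0)
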