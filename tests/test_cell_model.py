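"""Unit and property tests of the ionic cell model."""

import math

import numpy as np
import pytest

from canatrial import cell_model as cm


def make_state_at(v, params, ca_i=1e-4):
    """State with every gate at its steady state for the given voltage.

    JSR Ca2+ is pinned to cytosolic Ca2+ so the release flux vanishes and the
    flux signal driving the SR release gates is independent of those gates.
    """
    y = cm.default_state(params).y.copy()
    y[cm.S_V] = v
    y[cm.S_CAI] = ca_i
    y[cm.S_CAREL] = ca_i
    inf, _ = cm.gate_steady_states(v, ca_i=ca_i, fn=0.0)
    y[cm.GATE_SLICE] = inf
    state = cm.CellState(y)
    fn = cm.currents(state, params)["fn"]
    inf, _ = cm.gate_steady_states(v, ca_i=ca_i, fn=fn)
    y[cm.GATE_SLICE] = inf
    return cm.CellState(y)


class TestGateKinetics:
    def test_gates_at_steady_state_have_zero_derivative(self, control_params, rng):
        """Relaxation kinetics have a fixed point at x = x_inf(V)."""
        for v in rng.uniform(-90.0, 40.0, size=100):
            state = make_state_at(v, control_params)
            dy = cm.compute_derivatives(state, control_params)
            assert np.allclose(dy[cm.GATE_SLICE], 0.0, atol=1e-9), f"V={v}"

    def test_steady_states_and_time_constants_finite_and_bounded(self, rng):
        for v in rng.uniform(-150.0, 80.0, size=200):
            inf, tau = cm.gate_steady_states(v)
            assert np.all((inf >= 0.0) & (inf <= 1.0))
            assert np.all(tau > 0.0)
            assert np.all(np.isfinite(tau))

    def test_singular_voltages_have_finite_limits(self):
        # removable singularities of the rate expressions
        for v in (-47.13, -14.1, 3.3328, 19.9, -10.0, 7.9):
            inf_lo, tau_lo = cm.gate_steady_states(v - 1e-7)
            inf_at, tau_at = cm.gate_steady_states(v)
            assert np.allclose(inf_lo, inf_at, rtol=1e-4)
            assert np.allclose(tau_lo, tau_at, rtol=1e-4)


class TestNCX:
    def test_matches_independent_evaluation(self, control_params):
        """Straight-line evaluation of the exchanger equations (oracle)."""
        p = control_params
        v, na_i, ca_i = 0.0, 10.0, 2e-4
        ef = math.exp(p.ncx_eta * v / p.rt_over_f)
        efm = math.exp((p.ncx_eta - 1.0) * v / p.rt_over_f)
        num = ef * na_i**3 * p.ca_o - efm * p.na_o**3 * ca_i
        den = (p.ncx_km_ca_i * p.na_o**3 * (1 + (na_i / p.ncx_km_na_i) ** 3)
               + p.ncx_km_na_o**3 * ca_i * (1 + ca_i / p.ncx_km_ca_i)
               + p.ncx_km_ca_o * na_i**3
               + na_i**3 * p.ca_o + p.na_o**3 * ca_i)
        allo = 1.0 / (1.0 + (p.ncx_kd_act / ca_i) ** 2)
        expected = p.ncx_v_max * allo * num / (den * (1 + p.ncx_k_sat * efm))
        assert cm.ncx_current(v, na_i, ca_i, p) == pytest.approx(expected,
                                                                rel=1e-12)

    def test_zero_at_reversal(self, control_params):
        """Current vanishes when the thermodynamic driving term vanishes."""
        p = control_params
        v, na_i = -30.0, 10.0
        ca_i = na_i**3 * p.ca_o * math.exp(v / p.rt_over_f) / p.na_o**3
        assert cm.ncx_current(v, na_i, ca_i, p) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_maximal_rate(self, control_params):
        doubled = control_params.replace(ncx_v_max=2 * control_params.ncx_v_max)
        base = cm.ncx_current(-40.0, 11.0, 3e-4, control_params)
        assert cm.ncx_current(-40.0, 11.0, 3e-4, doubled) == pytest.approx(
            2 * base, rel=1e-12)

    def test_rejects_nonpositive_concentrations(self, control_params):
        with pytest.raises(ValueError):
            cm.ncx_current(0.0, -1.0, 1e-4, control_params)


class TestEulerStep:
    def test_single_step_advances_v_by_dt_times_rate(self, control_params):
        state = cm.default_state(control_params)
        dy = cm.compute_derivatives(state, control_params, i_stim=5.0)
        new = cm.step_euler(state, control_params, dt=0.02, i_stim=5.0)
        assert new.v == pytest.approx(state.v + 0.02 * dy[cm.S_V], abs=1e-12)

    def test_rejects_nonpositive_dt(self, control_params):
        with pytest.raises(ValueError):
            cm.step_euler(cm.default_state(control_params), control_params,
                          dt=0.0)

    def test_gate_escape_raises_named_instability(self, control_params):
        """A gate driven out of [0, 1] is an error, never a silent clip."""
        state = cm.default_state(control_params)
        # depolarize without letting the gates follow: the fast Na+ gates are
        # now far from steady state and a long Euler step overshoots [0, 1]
        state.y[cm.S_V] = -20.0
        with pytest.raises(cm.NumericalInstabilityError) as exc:
            cm.step_euler(state, control_params, dt=5.0)
        assert exc.value.variable in cm.STATE_NAMES

    def test_single_step_richardson_error_is_second_order(self, control_params,
                                                          control_stimulus):
        """One Euler step vs two half steps differ by O(dt^2) on a smooth
        segment (the local error ratio quarters when dt halves)."""
        # advance 40 ms into a beat to sit on the smooth plateau
        state, _, _ = cm.integrate(
            cm.default_state(control_params), control_params, 40.0,
            stimulus=cm.Stimulus(control_stimulus.amplitude, 2.0, (5.0,)))

        def local_error(dt):
            one = cm.step_euler(state, control_params, dt=dt)
            half = cm.step_euler(state, control_params, dt=dt / 2)
            two = cm.step_euler(half, control_params, dt=dt / 2)
            return abs(one.v - two.v)

        e_coarse, e_fine = local_error(0.04), local_error(0.02)
        assert e_fine < 0.35 * e_coarse

    def test_refining_dt_converges_on_one_paced_beat(self, control_params,
                                                     control_stimulus):
        """APD90 converges monotonically as dt is refined 0.02 -> 0.002 ms."""
        from canatrial.biomarkers import apd
        apds = {}
        for dt in (0.02, 0.01, 0.002):
            _, t, rec = cm.integrate(cm.default_state(control_params),
                                     control_params, 500.0, dt=dt,
                                     stimulus=cm.Stimulus(
                                         control_stimulus.amplitude, 2.0,
                                         onsets=(5.0,)),
                                     record_stride=0.1)
            apds[dt], _, _, _ = apd(t, rec[:, cm.S_V], 5.0)
        err_coarse = abs(apds[0.02] - apds[0.002])
        err_half = abs(apds[0.01] - apds[0.002])
        assert err_coarse < 3.0  # first beat from rest, worst case
        assert err_half < 0.75 * err_coarse  # first-order shrinkage


class TestRestingState:
    def test_default_state_is_reproducible_and_valid(self, control_params):
        s1 = cm.default_state(control_params)
        s2 = cm.default_state(control_params)
        assert np.array_equal(s1.y, s2.y)
        assert -85.0 <= s1.v <= -75.0
        assert np.all((s1.gates >= 0.0) & (s1.gates <= 1.0))
        occ = s1.buffer_occupancies(control_params)
        assert all(0.0 <= f <= 1.0 for f in occ.values())

    def test_ten_second_quiescence_is_stable(self, control_params):
        """Stimulus-free integration drifts V < 1 mV, concentrations < 1%."""
        s0 = cm.default_state(control_params)
        s = cm.equilibrate(control_params, duration=10_000.0)
        assert abs(s.v - s0.v) < 1.0
        for idx in (cm.S_NAI, cm.S_KI, cm.S_CAI, cm.S_CAUP, cm.S_CAREL):
            assert abs(s.y[idx] / s0.y[idx] - 1.0) < 0.01

    def test_runaway_stimulus_raises_with_context(self, control_params):
        with pytest.raises(cm.NumericalInstabilityError) as exc:
            cm.integrate(cm.default_state(control_params), control_params,
                         50.0, stimulus=cm.Stimulus(-4000.0, 10.0, (1.0,)))
        assert exc.value.variable == "v"
        assert exc.value.t_ms >= 0.0


class TestParameters:
    def test_roundtrip_through_dict_and_array(self, control_params):
        d = control_params.to_dict()
        assert cm.CellParameters.from_dict(d) == control_params
        arr = control_params.to_array()
        assert cm.CellParameters.from_array(arr) == control_params

    def test_validation_rejects_bad_values(self):
        with pytest.raises(ValueError):
            cm.CellParameters(g_na=-1.0)
        with pytest.raises(ValueError):
            cm.CellParameters(ncx_eta=1.5)
        with pytest.raises(ValueError):
            cm.CellParameters.from_dict({"not_a_parameter": 1.0})

    def test_stimulus_validation(self):
        with pytest.raises(ValueError):
            cm.Stimulus(amplitude=10.0, duration=0.0)
        with pytest.raises(ValueError):
            cm.Stimulus(amplitude=10.0, onsets=(5.0, 4.0))
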