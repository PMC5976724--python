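"""Single-neuron vector field: temperature scaling, gating kinetics,
current definitions and their analytic limits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import fsolve

from chaosnet.model import (NeuronParameters, NeuronState, derivatives,
                            ionic_currents, params_to_matrix, resting_state,
                            steady_state_activation, temperature_factors,
                            PARAM_COLUMNS)


@pytest.mark.parametrize("T, rho, phi", [
    (25.0, 1.0, 1.0),
    (35.0, 1.3, 3.0),
    (36.0, 1.3 ** 1.1, 3.0 ** 1.1),
])
def test_temperature_factors(T, rho, phi):
    r, p = temperature_factors(T)
    assert r == pytest.approx(rho, rel=1e-12)
    assert p == pytest.approx(phi, rel=1e-12)


def test_temperature_factors_reject_nonfinite():
    with pytest.raises(ValueError):
        temperature_factors(float("nan"))


def test_activation_midpoint_and_limits():
    assert steady_state_activation(-40.0, 0.11, -40.0) == pytest.approx(0.5)
    assert steady_state_activation(1e4, 0.25, -25.0) == pytest.approx(1.0)
    assert steady_state_activation(-1e4, 0.25, -25.0) == pytest.approx(0.0)
    # h-current activates under hyperpolarization (negative slope)
    assert (steady_state_activation(-100.0, -0.14, -85.0)
            > steady_state_activation(-60.0, -0.14, -85.0))


@given(st.floats(-100, 40), st.floats(-100, 40))
def test_activation_monotone(v1, v2):
    lo, hi = sorted((v1, v2))
    up = steady_state_activation(np.array([lo, hi]), 0.25, -25.0)
    dn = steady_state_activation(np.array([lo, hi]), -0.14, -85.0)
    assert up[0] <= up[1]
    assert dn[0] >= dn[1]
    assert np.all((up > 0) & (up < 1)) and np.all((dn > 0) & (dn < 1))


def test_zero_driving_force_kills_each_current(default_params):
    p = default_params
    for name, E in [("I_d", p.E_d), ("I_r", p.E_r), ("I_sd", p.E_sd),
                    ("I_sr", p.E_sr), ("I_h", p.E_h), ("I_l", p.E_l)]:
        st_ = NeuronState(V=E, a_r=0.3, a_sd=0.4, a_sr=0.2, a_h=0.5)
        assert ionic_currents(st_, p)[name] == pytest.approx(0.0, abs=1e-12)


def test_calcium_gate(default_params):
    p = default_params
    half = ionic_currents(NeuronState(V=0.0, a_sr=0.4), p)["I_sr"]
    rho, _ = temperature_factors(p.T)
    assert half == pytest.approx(rho * p.g_sr * 0.5 * (0.0 - p.E_sr))
    assert ionic_currents(NeuronState(V=0.0, a_sr=0.0), p)["I_sr"] == 0.0


def test_gating_nullclines(default_params):
    p = default_params
    V = -52.0
    s = NeuronState(
        V=V,
        a_r=float(steady_state_activation(V, p.s_r, p.V0_r)),
        a_sd=float(steady_state_activation(V, p.s_sd, p.V0_sd)),
        a_sr=0.2,
        a_h=float(steady_state_activation(V, p.s_h, p.V0_h)))
    d = derivatives(s, p)
    assert d[1] == pytest.approx(0.0, abs=1e-14)   # a_r
    assert d[2] == pytest.approx(0.0, abs=1e-14)   # a_sd
    assert d[4] == pytest.approx(0.0, abs=1e-14)   # a_h
    # calcium nullcline: a_sr = -eta I_sd / kappa, positive for inward I_sd
    I_sd = ionic_currents(s, p)["I_sd"]
    s2 = NeuronState(V=V, a_r=s.a_r, a_sd=s.a_sd,
                     a_sr=-p.eta * I_sd / p.kappa, a_h=s.a_h)
    assert I_sd < 0 and s2.a_sr > 0
    assert derivatives(s2, p)[3] == pytest.approx(0.0, abs=1e-14)


def test_full_equilibrium_is_a_fixed_point(default_params):
    p = default_params

    def f(x):
        return derivatives(NeuronState.from_array(x), p)

    x0 = resting_state(p).as_array()
    xeq = fsolve(f, x0, full_output=False)
    assert np.allclose(f(xeq), 0.0, atol=1e-9)


def test_derivatives_reject_nonfinite_state(default_params):
    with pytest.raises(FloatingPointError):
        derivatives(NeuronState(V=float("inf")), default_params)


def test_parameter_validation():
    with pytest.raises(ValueError):
        NeuronParameters(g_sd=-0.1)
    with pytest.raises(ValueError):
        NeuronParameters(tau_r=0.0)
    with pytest.raises(ValueError):
        NeuronParameters(C_m=-1.0)


def test_text_round_trip_and_packaged_defaults(default_params):
    again = NeuronParameters.from_text(default_params.to_text())
    assert again == default_params
    assert NeuronParameters.from_packaged_defaults() == default_params


def test_param_matrix_layout(default_params):
    M = params_to_matrix([default_params, default_params.with_(g_sd=0.3)])
    assert M.shape == (2, len(PARAM_COLUMNS))
    assert M[0, PARAM_COLUMNS.index("g_sd")] == default_params.g_sd
    assert M[1, PARAM_COLUMNS.index("g_sd")] == 0.3
    rho, phi = temperature_factors(default_params.T)
    assert M[0, PARAM_COLUMNS.index("rho")] == pytest.approx(rho)


def test_gating_variables_stay_in_unit_interval(default_params):
    """a_r, a_sd, a_h live in the attracting interval [0, 1]."""
    from chaosnet import integrate
    state = None
    for _ in range(10):
        rec = integrate(default_params, t_transient=2000.0, t_record=0.0,
                        state0=state)
        state = rec.final_state
        gates = state[[1, 2, 4], :]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)
        assert state[3, 0] >= 0.0   # calcium stays non-negative


def test_noih_model_decouples_ah(default_params):
    """With g_h = 0 the h-gate cannot influence V: runs differing only in
    the initial a_h give bit-identical voltage traces (4-variable
    reduction)."""
    from chaosnet import integrate
    from chaosnet.simulate import initial_state
    p = default_params.with_(g_h=0.0)
    s1 = initial_state([p])
    s2 = s1.copy()
    s2[4, 0] = 0.93
    r1 = integrate(p, t_transient=0.0, t_record=4000.0, state0=s1)
    r2 = integrate(p, t_transient=0.0, t_record=4000.0, state0=s2)
    assert np.array_equal(r1.V_traces, r2.V_traces)


def test_default_neuron_oscillates(default_record):
    """The reference parameter set is an oscillatory (spiking) neuron."""
    assert default_record.spikes[0].size > 10
    assert np.ptp(default_record.V_traces) > 40.0
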