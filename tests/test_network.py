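"""Newman-Watts topology construction and gap-junction coupling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chaosnet.model import NeuronParameters
from chaosnet.network import (InvalidTopologyError, NetworkSpec,
                              adjacency_to_csr, gap_junction_current,
                              load_edge_list, network_rhs, newman_watts,
                              save_edge_list)


def test_ring_lattice_degrees():
    C = newman_watts(250, 5, 0.0, seed=0)
    assert np.all(C.sum(axis=1) == 10)
    assert np.array_equal(C, C.T)
    assert np.all(np.diag(C) == 0)


def test_k1_p0_is_cycle_graph():
    C = newman_watts(6, 1, 0.0, seed=0)
    expect = np.zeros((6, 6), dtype=int)
    for i in range(6):
        expect[i, (i + 1) % 6] = expect[(i + 1) % 6, i] = 1
    assert np.array_equal(C, expect)


def test_p1_mean_degree():
    """Each node adds exactly one shortcut at p = 1; every shortcut raises
    two degrees, so the mean degree is 2K + 2 = 12 (up to rare collisions
    resolved by redrawing)."""
    means = [newman_watts(250, 5, 1.0, seed=s).sum(axis=1).mean()
             for s in range(100)]
    assert np.mean(means) == pytest.approx(12.0, abs=3 * np.std(means) / 10 + 1e-9)


@given(st.integers(0, 10_000))
def test_newman_watts_structure(seed):
    C = newman_watts(40, 3, 0.3, seed=seed)
    assert np.array_equal(C, C.T)
    assert np.all(np.diag(C) == 0)
    deg = C.sum(axis=1)
    assert np.all(deg >= 6)                       # ring backbone intact
    for k in range(1, 4):
        idx = np.arange(40)
        assert np.all(C[idx, (idx + k) % 40] == 1)
    assert np.array_equal(C, newman_watts(40, 3, 0.3, seed=seed))  # determinism


def test_invalid_topology_rejected():
    with pytest.raises(InvalidTopologyError):
        newman_watts(10, 5, 0.1, seed=0)
    with pytest.raises(InvalidTopologyError):
        newman_watts(10, 2, 1.5, seed=0)


def test_gap_junction_current_values():
    assert gap_junction_current(-60.0, -60.0, 0.5) == 0.0
    assert gap_junction_current(-70.0, -50.0, 0.5) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        gap_junction_current(0.0, 0.0, -1.0)


def _random_spec(N, g, seed):
    rng = np.random.default_rng(seed)
    C = newman_watts(N, 2, 0.4, seed=seed)
    params = [NeuronParameters(g_sd=float(x)) for x in rng.uniform(0.18, 0.3, N)]
    return NetworkSpec(C=C, g=g, params=params)


def _syn_currents(states, spec):
    """I_syn per node, recovered as the coupled-minus-uncoupled dV/dt."""
    coupled = network_rhs(states, spec)
    free = network_rhs(states, NetworkSpec(C=spec.C * 0, g=0.0, params=spec.params))
    C_m = spec.params[0].C_m
    return (coupled[0] - free[0]) * C_m


def test_identical_states_give_zero_coupling():
    spec = _random_spec(8, 0.7, seed=1)
    states = np.tile(np.array([-55.0, 0.2, 0.3, 0.15, 0.4])[:, None], (1, 8))
    assert np.allclose(_syn_currents(states, spec), 0.0, atol=1e-12)


def test_two_neuron_antisymmetry():
    C = np.array([[0, 1], [1, 0]], dtype=np.int8)
    spec = NetworkSpec(C=C, g=0.3, params=[NeuronParameters()] * 2)
    states = np.array([[-70.0, -40.0], [0.2, 0.3], [0.1, 0.4],
                       [0.2, 0.1], [0.3, 0.2]])
    I = _syn_currents(states, spec)
    assert I[0] == pytest.approx(-I[1], rel=1e-12)
    assert I[0] == pytest.approx(0.3 * (-40.0 - -70.0))


def test_total_coupling_conserved():
    """sum_k I_syn,k = 0 for symmetric C; oracle is an explicit pair loop."""
    rng = np.random.default_rng(7)
    spec = _random_spec(12, 0.9, seed=3)
    states = np.vstack([rng.uniform(-80, -20, 12), rng.uniform(0, 1, (4, 12))])
    I = _syn_currents(states, spec)
    oracle = np.zeros(12)
    for k in range(12):
        for l in range(12):
            if spec.C[k, l]:
                oracle[k] += spec.g * (states[0, l] - states[0, k])
    assert np.allclose(I, oracle, atol=1e-10)
    assert abs(I.sum()) < 1e-10


def test_g_zero_matches_isolated_runs():
    from chaosnet import integrate
    spec = _random_spec(6, 0.0, seed=5)
    rec = integrate(spec, t_transient=500.0, t_record=2000.0)
    for n, p in enumerate(spec.params):
        solo = integrate(p, t_transient=500.0, t_record=2000.0)
        assert np.array_equal(rec.V_traces[n], solo.V_traces[0])


def test_strong_coupling_contracts_voltage_difference():
    from chaosnet import integrate
    from chaosnet.simulate import initial_state
    p = NeuronParameters()
    C = np.array([[0, 1], [1, 0]], dtype=np.int8)
    spec = NetworkSpec(C=C, g=1.0, params=[p, p])
    s0 = initial_state([p, p])
    s0[0, 1] = -50.0
    rec = integrate(spec, t_transient=0.0, t_record=3000.0, state0=s0)
    assert abs(rec.V_traces[0, -1] - rec.V_traces[1, -1]) < 1e-3


def test_edge_list_round_trip(tmp_path):
    C = newman_watts(30, 2, 0.5, seed=9)
    path = tmp_path / "edges.txt"
    save_edge_list(C, path)
    assert np.array_equal(load_edge_list(path, 30), C)


def test_csr_matches_dense():
    C = newman_watts(20, 2, 0.3, seed=4)
    indptr, indices = adjacency_to_csr(C)
    for k in range(20):
        assert np.array_equal(np.sort(indices[indptr[k]:indptr[k + 1]]),
                              np.flatnonzero(C[k]))


def test_spec_validation():
    with pytest.raises(InvalidTopologyError):
        NetworkSpec(C=np.array([[0, 1], [0, 0]]), g=0.1,
                    params=[NeuronParameters()] * 2)
    with pytest.raises(InvalidTopologyError):
        NetworkSpec(C=np.array([[1, 1], [1, 0]]), g=0.1,
                    params=[NeuronParameters()] * 2)
    with pytest.raises(ValueError):
        NetworkSpec(C=np.zeros((3, 3), dtype=int), g=0.1,
                    params=[NeuronParameters()] * 2)
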