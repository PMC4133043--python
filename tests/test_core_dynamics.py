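"""Single-neuron and single-synapse oracle tests.

The resting-state oracle re-derives the quiescent fixed point with an
independent root-finder over independently transcribed steady-state
equations; integrator checks compare against closed forms.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from shuntnet.core_dynamics import (
    IntegrationDivergedError,
    NeuronParams,
    NeuronState,
    SynapseParams,
    SynapseState,
    gating_steady_state,
    membrane_derivatives,
    resting_state,
    step_neuron,
    synaptic_current,
    update_synaptic_gating,
)


# --------------------------------------------------------------------------
# independent resting-state oracle (transcribed from docs/parameters.md,
# kept separate from the package implementation on purpose)
# --------------------------------------------------------------------------

def _oracle_rest(g_l: float) -> float:
    def am(v): return 0.32 * (v + 50.0) / (1.0 - np.exp(-(v + 50.0) / 4.0))
    def bm(v): return 0.28 * (v + 23.0) / (np.exp((v + 23.0) / 5.0) - 1.0)
    def ah(v): return 0.128 * np.exp(-(v + 50.0) / 18.0)
    def bh(v): return 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    def an(v): return 0.032 * (v + 52.0) / (1.0 - np.exp(-(v + 52.0) / 5.0))
    def bn(v): return 0.5 * np.exp(-(v + 57.0) / 40.0)
    def mca(v): return 1.0 / (1.0 + np.exp(-(v + 10.0) / 5.0))

    def f(v):
        m = am(v) / (am(v) + bm(v))
        h = ah(v) / (ah(v) + bh(v))
        n = an(v) / (an(v) + bn(v))
        return (
            g_l * (v + 65.0)
            + 100.0 * m ** 3 * h * (v - 55.0)
            + 40.0 * n ** 4 * (v + 80.0)
            + 0.9 * mca(v) * (v - 120.0)
        )

    return brentq(f, -70.0, -62.0)


def _simulate(params, current, duration, dt=0.025, state=None):
    state = state or resting_state(params)
    spikes = []
    t = 0.0
    prev = state.last_spike_time
    trace = []
    for _ in range(int(round(duration / dt))):
        state = step_neuron(state, params, 0.0, current, dt, t)
        t += dt
        if state.last_spike_time is not None and state.last_spike_time != prev:
            spikes.append(state.last_spike_time)
            prev = state.last_spike_time
        trace.append(state.membrane_potential)
    return state, np.array(spikes), np.array(trace)


class TestRestingState:
    def test_matches_independent_root_finder(self):
        for params in (NeuronParams.excitatory(), NeuronParams.inhibitory()):
            oracle = _oracle_rest(params.leak_conductance)
            assert resting_state(params).membrane_potential == pytest.approx(oracle, abs=1e-6)

    def test_rest_close_to_leak_reversal(self):
        assert abs(resting_state(NeuronParams.excitatory()).membrane_potential + 65.0) < 5.0

    def test_membrane_stays_at_rest_without_input(self):
        params = NeuronParams.excitatory()
        _, spikes, trace = _simulate(params, 0.0, 500.0)
        assert spikes.size == 0
        assert np.all(np.abs(trace + 65.0) < 5.0)


class TestFiringPatterns:
    def test_excitatory_adaptation(self):
        _, spikes, _ = _simulate(NeuronParams.excitatory(), 1.0, 1000.0)
        isis = np.diff(spikes)
        assert len(spikes) > 10
        # instantaneous rate decreases: first five ISIs increase monotonically
        assert np.all(np.diff(isis[:5]) > 0)
        assert isis[-1] > isis[0]

    def test_inhibitory_no_adaptation(self):
        _, spikes, _ = _simulate(NeuronParams.inhibitory(), 1.0, 1000.0)
        isis = np.diff(spikes)
        assert len(spikes) > 10
        # ISIs converge to constant within 5% after 5 spikes
        late = isis[5:]
        assert np.all(np.abs(late - late.mean()) / late.mean() < 0.05)

    def test_inhibitory_membrane_twice_as_fast(self):
        e, i = NeuronParams.excitatory(), NeuronParams.inhibitory()
        assert i.leak_conductance == pytest.approx(2.0 * e.leak_conductance)
        assert not i.has_ahp and e.has_ahp

    def test_dt_halving_shifts_spikes_less_than_one_dt(self):
        params = NeuronParams.excitatory()
        _, s1, _ = _simulate(params, 1.0, 200.0, dt=0.025)
        _, s2, _ = _simulate(params, 1.0, 200.0, dt=0.0125)
        n = min(len(s1), len(s2))
        assert n >= 5
        # less than one coarse dt of drift per 100 ms of simulation
        assert np.max(np.abs(s1[:n] - s2[:n])) < 0.025 * (200.0 / 100.0)


class TestPassiveLimit:
    def test_exponential_step_response(self):
        params = NeuronParams(
            sodium_conductance=0.0,
            potassium_conductance=0.0,
            calcium_conductance=0.0,
            ahp_conductance=0.0,
            has_ahp=False,
        )
        g_l, v_l, i0, dt = params.leak_conductance, params.leak_reversal, 0.2, 0.01
        state = NeuronState(v_l, 0.0, 1.0, 0.0, 0.0)
        ts, vs = [], []
        t = 0.0
        for _ in range(int(200.0 / dt)):
            state = step_neuron(state, params, 0.0, i0, dt, t)
            t += dt
            ts.append(t)
            vs.append(state.membrane_potential)
        ts, vs = np.array(ts), np.array(vs)
        tau = 1.0 / g_l
        analytic = v_l + (i0 / g_l) * (1.0 - np.exp(-ts / tau))
        assert np.max(np.abs(vs - analytic)) < 0.01 * (i0 / g_l)


class TestErrors:
    def test_non_finite_current_raises(self):
        params = NeuronParams.excitatory()
        with pytest.raises(IntegrationDivergedError):
            step_neuron(resting_state(params), params, np.nan, 0.0, 0.025)

    def test_non_finite_state_raises(self):
        params = NeuronParams.excitatory()
        bad = NeuronState(np.inf, 0.1, 0.9, 0.1, 0.0)
        with pytest.raises(IntegrationDivergedError):
            step_neuron(bad, params, 0.0, 0.0, 0.025)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(sodium_conductance=-1.0)
        with pytest.raises(ValueError):
            NeuronParams(potassium_reversal=-60.0)  # breaks V_K < V_L


@settings(max_examples=25, deadline=None)
@given(
    current=st.floats(min_value=-1.0, max_value=4.0),
    v0=st.floats(min_value=-80.0, max_value=-50.0),
)
def test_gating_variables_bounded(current, v0):
    params = NeuronParams.excitatory()
    m, h, n = gating_steady_state(v0)
    state = NeuronState(v0, m, h, n, 0.0)
    t = 0.0
    for _ in range(400):
        state = step_neuron(state, params, 0.0, current, 0.025, t)
        t += 0.025
        for x in (state.gating_m, state.gating_h, state.gating_n):
            assert 0.0 <= x <= 1.0
        assert state.calcium >= 0.0


class TestSynapticGating:
    def test_exponential_decay_closed_form(self):
        state = SynapseState(gating_s_e=np.array([1.0]), gating_s_i=np.array([0.0]))
        dt = 0.025
        for _ in range(int(2.0 / dt)):
            state = update_synaptic_gating(state, dt=dt)
        assert state.gating_s_e[0] == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_zero_is_fixed_point(self):
        state = SynapseState(gating_s_e=np.zeros(2), gating_s_i=np.zeros(2))
        for _ in range(100):
            state = update_synaptic_gating(state, dt=0.1)
        assert np.all(state.gating_s_e == 0.0)
        assert np.all(state.gating_s_i == 0.0)

    def test_monotone_decay_after_spike(self):
        def after(silence_ms):
            s = SynapseState(gating_s_e=np.zeros(1), gating_s_i=np.zeros(1))
            s = update_synaptic_gating(s, presynaptic_spikes_e=np.ones(1), dt=0.025)
            for _ in range(int(silence_ms / 0.025)):
                s = update_synaptic_gating(s, dt=0.025)
            return s.gating_s_e[0]

        assert after(10.0) < after(2.0)

    def test_spike_increments_by_one(self):
        s = SynapseState(gating_s_e=np.array([0.25]), gating_s_i=np.zeros(1))
        s2 = update_synaptic_gating(s, presynaptic_spikes_e=np.ones(1), dt=1e-9)
        assert s2.gating_s_e[0] == pytest.approx(1.25, rel=1e-6)

    def test_negative_gating_rejected(self):
        s = SynapseState(gating_s_e=np.array([-0.1]), gating_s_i=np.zeros(1))
        with pytest.raises(ValueError):
            update_synaptic_gating(s, dt=0.025)


class TestSynapticCurrent:
    def test_zero_gating_gives_zero(self):
        g = SynapseState(gating_s_e=np.zeros(3), gating_s_i=np.zeros(2))
        exc, inh = synaptic_current("E", -65.0, g, np.ones(3), np.ones(2))
        assert exc == 0.0 and inh == 0.0

    def test_zero_driving_force_excitatory(self):
        g = SynapseState(gating_s_e=np.ones(3), gating_s_i=np.zeros(2))
        exc, _ = synaptic_current("E", 0.0, g, np.ones(3), np.ones(2))
        assert exc == pytest.approx(0.0, abs=1e-12)

    def test_zero_driving_force_inhibitory(self):
        g = SynapseState(gating_s_e=np.zeros(2), gating_s_i=np.ones(2))
        _, inh = synaptic_current("E", -80.0, g, np.ones(2), np.ones(2))
        assert inh == pytest.approx(0.0, abs=1e-12)

    def test_components_sum_to_total(self):
        rng = np.random.default_rng(0)
        g = SynapseState(gating_s_e=rng.random(5), gating_s_i=rng.random(4))
        w_e, w_i = rng.random(5), rng.random(4)
        v = -58.3
        exc, inh = synaptic_current("E", v, g, w_e, w_i)
        p = SynapseParams()
        total = -float(w_e @ g.gating_s_e) * v - float(w_i @ g.gating_s_i) * (
            v - p.inhibitory_reversal
        )
        assert exc + inh == pytest.approx(total, rel=1e-12)

    def test_signs_at_rest(self):
        g = SynapseState(gating_s_e=np.ones(1), gating_s_i=np.ones(1))
        exc, inh = synaptic_current("E", -65.0, g, np.ones(1), np.ones(1))
        assert exc > 0 > inh

    def test_dimension_mismatch(self):
        g = SynapseState(gating_s_e=np.ones(3), gating_s_i=np.ones(2))
        with pytest.raises(ValueError):
            synaptic_current("E", -65.0, g, np.ones(4), np.ones(2))

    def test_no_inhibitory_weights_means_zero_component(self):
        g = SynapseState(gating_s_e=np.ones(2), gating_s_i=np.ones(3))
        _, inh = synaptic_current("I", -65.0, g, np.ones(2), None)
        assert inh == 0.0


def test_current_decomposition_consistent_with_step():
    """The summed components drive step_neuron identically to the total."""
    params = NeuronParams.excitatory()
    state = resting_state(params)
    g = SynapseState(gating_s_e=np.array([0.5]), gating_s_i=np.array([0.4]))
    exc, inh = synaptic_current("E", state.membrane_potential, g, np.array([0.01]), np.array([0.02]))
    s1 = step_neuron(state, params, exc + inh, 0.0, 0.025)
    s2 = step_neuron(state, params, 0.0, exc + inh, 0.025)
    assert s1.membrane_potential == pytest.approx(s2.membrane_potential, abs=1e-12)
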