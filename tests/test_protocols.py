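"""Protocol tests on the small fixture network."""

import numpy as np
import pytest

from shuntnet.engine import Simulator
from shuntnet.plasticity import PlasticityParams
from shuntnet.protocols import (
    Presentation,
    Protocol,
    StimulusSpec,
    decompose_currents,
    make_oriented_input,
    measure_tuning,
    probe_fi_curve,
    run_protocol,
    run_training,
)


class TestOrientedInput:
    def test_peak_at_center_neuron(self, small_network):
        spec = StimulusSpec(90.0, 2.0, 2.0, 100.0)
        i_e, _ = make_oriented_input(spec, small_network)
        center = small_network.orientation_to_index(90.0)
        assert i_e[center] == pytest.approx(2.0)
        assert i_e.argmax() == center

    def test_one_sd_falloff(self, small_network):
        spec = StimulusSpec(90.0, 2.0, 2.0, 100.0)
        i_e, _ = make_oriented_input(spec, small_network)
        center = small_network.orientation_to_index(90.0)
        # 2 neurons away = one s.d.
        assert i_e[(center + 2) % 10] == pytest.approx(2.0 * np.exp(-0.5), rel=1e-9)

    def test_translation(self, small_network):
        deg = small_network.degrees_per_neuron
        a, _ = make_oriented_input(StimulusSpec(90.0, 2.0, 2.0, 100.0), small_network)
        b, _ = make_oriented_input(StimulusSpec(90.0 + 3 * deg, 2.0, 2.0, 100.0), small_network)
        np.testing.assert_allclose(np.roll(a, 3), b, atol=1e-12)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            StimulusSpec(peak_amplitude=-1.0)
        with pytest.raises(ValueError):
            StimulusSpec(profile_width=0.0)


class TestTraining:
    def test_zero_repetitions_is_identity(self, small_network, small_stimulus):
        tr = run_training(small_network, small_stimulus, 0,
                          PlasticityParams(), calcium_target=0.01)
        np.testing.assert_array_equal(tr.network.w_ff, small_network.w_ff)
        np.testing.assert_array_equal(tr.network.w_fb, small_network.w_fb)

    def test_feedforward_growth_is_stimulus_specific(self, small_network):
        stim = StimulusSpec(90.0, 2.0, 1.5, 300.0)
        pl = PlasticityParams(hebbian_rate=0.01, feedback_rate=0.0, update_stride=4)
        tr = run_training(small_network, stim, 3, pl, calcium_target=1e9)
        dw = tr.network.w_ff - small_network.w_ff
        center = small_network.orientation_to_index(90.0)
        near = [(center + d) % 10 for d in (-1, 0, 1)]
        far = [(center + 5) % 10]
        mask = small_network.ff_mask
        near_growth = dw[np.ix_(near, near)][mask[np.ix_(near, near)]]
        far_growth = dw[np.ix_(far, far)][mask[np.ix_(far, far)]]
        assert near_growth.size and near_growth.mean() > 0
        if far_growth.size:
            assert far_growth.mean() <= 0.01 * max(near_growth.mean(), 1e-12)

    def test_weight_trajectories_monotone(self, small_network):
        stim = StimulusSpec(90.0, 2.0, 1.5, 300.0)
        pl = PlasticityParams(hebbian_rate=0.01, feedback_rate=0.0, update_stride=4)
        tr = run_training(small_network, stim, 3, pl, calcium_target=1e9)
        assert np.all(np.diff(tr.w_ff_mean) >= 0)


class TestMeasureTuning:
    def test_probe_neutrality_and_determinism(self, small_network):
        probes = np.arange(0.0, 180.0, 18.0)
        spec = StimulusSpec(90.0, 2.0, 1.5, 200.0)
        s1 = measure_tuning(small_network, probes, spec)
        s2 = measure_tuning(small_network, probes, spec)
        np.testing.assert_array_equal(s1["rates_v1e"], s2["rates_v1e"])
        np.testing.assert_array_equal(s1["feedback_drive"], s2["feedback_drive"])

    def test_naive_peak_near_own_position(self, small_network):
        probes = np.arange(0.0, 180.0, 18.0)
        spec = StimulusSpec(90.0, 2.0, 1.5, 300.0)
        sweep = measure_tuning(small_network, probes, spec)
        rates = sweep["rates_v1e"]
        for nid in range(10):
            if rates[:, nid].max() < 5.0:
                continue
            best = probes[rates[:, nid].argmax()]
            own = small_network.position_of_neuron(nid)
            d = min(abs(best - own), 180.0 - abs(best - own))
            assert d <= 18.0  # within one probe step of its own position

    def test_zero_amplitude_probe_silent(self, small_network):
        probes = [0.0, 90.0]
        spec = StimulusSpec(90.0, 1e-9, 1.5, 150.0)
        sweep = measure_tuning(small_network, probes, spec)
        assert sweep["rates_v1e"].max() == 0.0  # spontaneous rate is zero

    def test_empty_probe_list_rejected(self, small_network):
        with pytest.raises(ValueError):
            measure_tuning(small_network, [], StimulusSpec())


class TestFICurve:
    def test_monotone_in_current(self, small_network):
        fi = probe_fi_curve(small_network, 5, [0.0, 0.5, 1.0, 2.0], None, duration=300.0)
        assert np.all(np.diff(fi.rates) >= 0)

    def test_zero_current_no_background_is_spontaneous(self, small_network):
        fi = probe_fi_curve(small_network, 5, [0.0], None, duration=200.0)
        assert fi.rates[0] == 0.0


class TestDecompose:
    def test_zero_weights_zero_currents(self, small_config, small_stimulus):
        from shuntnet.network_builder import build_network

        net = build_network(small_config)
        net.w_ee *= 0.0
        net.w_ie *= 0.0
        net.w_fb *= 0.0
        dec = decompose_currents(net, 0, small_stimulus)
        assert np.all(dec.excitatory == 0.0)
        assert np.all(dec.inhibitory == 0.0)

    def test_component_signs(self, small_network, small_stimulus):
        center = small_network.orientation_to_index(90.0)
        dec = decompose_currents(small_network, center, small_stimulus)
        assert dec.mean_excitatory >= 0.0
        assert dec.mean_inhibitory <= 0.0

    def test_window_out_of_range_rejected(self, small_network, small_stimulus):
        with pytest.raises(ValueError):
            decompose_currents(small_network, 0, small_stimulus,
                               window=(0.0, small_stimulus.duration + 100.0))


class TestRunProtocol:
    def test_seed_reproducibility(self, small_network):
        proto = Protocol(
            presentations=[Presentation(StimulusSpec(90.0, 2.0, 1.5, 150.0), 50.0, False)],
            repetitions=2,
            random_seed=11,
        )
        r1 = run_protocol(small_network, proto)
        r2 = run_protocol(small_network, proto)
        for a, b in zip(r1.spikes_v1e, r2.spikes_v1e):
            np.testing.assert_array_equal(a, b)

    def test_spike_times_strictly_increasing(self, small_network):
        proto = Protocol(
            presentations=[Presentation(StimulusSpec(90.0, 2.0, 1.5, 150.0), 50.0, False)],
            repetitions=3,
        )
        res = run_protocol(small_network, proto)
        for train in res.spikes_v1e + res.spikes_v1i + res.spikes_v2:
            if len(train) > 1:
                assert np.all(np.diff(train) > 0)

    def test_recorded_currents_collected(self, small_network):
        proto = Protocol(
            presentations=[Presentation(StimulusSpec(90.0, 2.0, 1.5, 150.0), 0.0, False)],
            record_currents=(0,),
        )
        res = run_protocol(small_network, proto)
        assert 0 in res.currents
        assert res.currents[0].shape[1] == 2


class TestSimulatorContract:
    def test_reset_restores_rest(self, small_network):
        sim = Simulator(small_network.copy())
        i_e = np.full(10, 1.5)
        sim.run(100.0, i_ext_e=i_e, record=False)
        sim.reset()
        v0 = sim.v_e.copy()
        rec = sim.run(100.0, record=False)
        assert np.all(np.abs(sim.v_e - v0) < 1.0)
        assert sum(len(s) for s in rec.spikes_v1e) == 0

    def test_shape_validation(self, small_network):
        sim = Simulator(small_network.copy())
        with pytest.raises(ValueError):
            sim.run(10.0, i_ext_e=np.zeros(7))

    def test_non_finite_current_raises(self, small_network):
        from shuntnet.core_dynamics import IntegrationDivergedError

        sim = Simulator(small_network.copy())
        bad = np.zeros(10)
        bad[0] = np.nan
        with pytest.raises(IntegrationDivergedError):
            sim.run(10.0, i_ext_e=bad)

    def test_divergence_reported_with_time(self, small_network):
        from shuntnet.core_dynamics import IntegrationDivergedError

        net = small_network.copy()
        sim = Simulator(net)
        with pytest.raises(IntegrationDivergedError):
            sim.run(50.0, i_ext_e=np.full(10, 1e7))

    def test_translation_symmetry_small_ring(self, small_config):
        """Shifting the stimulus by k neurons shifts the response by k."""
        from shuntnet.network_builder import build_network

        net = build_network(small_config)
        deg = net.degrees_per_neuron
        rates = []
        for k in (0, 3):
            sim = Simulator(net.copy())
            spec = StimulusSpec(90.0 + k * deg, 2.0, 1.5, 300.0)
            i_e, i_i = make_oriented_input(spec, net)
            rec = sim.run(300.0, i_ext_e=i_e, i_ext_i=i_i, record=False)
            rates.append(rec.rates("v1e", 60.0, 300.0))
        # responses are index-shifted copies up to feedforward-sampling noise
        assert np.corrcoef(np.roll(rates[0], 3), rates[1])[0, 1] > 0.9
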