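"""Experimental procedures: oriented-stimulus construction, training by
repeated presentation, tuning-curve measurement, f-I probing by current
injection, synaptic-current decomposition, and input-resistance probing.

All measurement protocols run with plasticity frozen and re-initialize the
network at rest before every presentation, so probing never trains and
successive sweeps are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from shuntnet.engine import Simulator, RunRecord
from shuntnet.network_builder import NetworkArchitecture
from shuntnet.plasticity import PlasticityParams, update_calcium_target

__all__ = [
    "StimulusSpec",
    "Protocol",
    "SimulationResult",
    "TrainingResult",
    "FICurve",
    "DecomposedCurrents",
    "make_oriented_input",
    "compute_calcium_setpoint",
    "run_training",
    "run_protocol",
    "measure_tuning",
    "probe_fi_curve",
    "decompose_currents",
    "measure_input_resistance",
    "rate_from_spikes",
]

# fraction of the stimulus window discarded as onset transient when
# estimating firing rates
RATE_TRANSIENT_FRACTION = 0.2


@dataclass(frozen=True)
class StimulusSpec:
    """Bell-shaped oriented input: a Gaussian current profile on the ring."""

    center_orientation: float = 90.0  # degrees
    peak_amplitude: float = 1.5  # current units (per unit area)
    profile_width: float = 8.0  # Gaussian s.d. in neuron units
    duration: float = 500.0  # ms
    onset_ramp: float = 50.0  # ms of linear ramp-in (avoids a synchronized onset burst)

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if self.profile_width <= 0:
            raise ValueError("profile_width must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    def shifted(self, orientation: float) -> "StimulusSpec":
        """Same stimulus centered at a different orientation."""
        return StimulusSpec(
            center_orientation=orientation,
            peak_amplitude=self.peak_amplitude,
            profile_width=self.profile_width,
            duration=self.duration,
            onset_ramp=self.onset_ramp,
        )


@dataclass(frozen=True)
class Presentation:
    """One entry of a protocol schedule."""

    stimulus: StimulusSpec
    inter_stimulus_interval: float = 500.0
    plasticity_on: bool = False


@dataclass
class Protocol:
    """Ordered presentation schedule with recording flags."""

    presentations: list = field(default_factory=list)
    repetitions: int = 1
    random_seed: int = 0
    record_spikes: bool = True
    record_states: bool = False
    record_currents: tuple = ()
    record_weights: bool = True

    @property
    def total_time(self) -> float:
        return self.repetitions * sum(
            p.stimulus.duration + p.inter_stimulus_interval for p in self.presentations
        )


@dataclass
class SimulationResult:
    """Spike trains, optional traces, current decompositions and weight
    snapshots from one protocol run, with the seed echoed."""

    spikes_v1e: list = field(default_factory=list)
    spikes_v1i: list = field(default_factory=list)
    spikes_v2: list = field(default_factory=list)
    times: np.ndarray | None = None
    v_traces: dict = field(default_factory=dict)
    currents: dict = field(default_factory=dict)  # neuron -> (T, 2) exc/inh
    weight_snapshots: list = field(default_factory=list)
    seed: int = 0
    config_echo: dict = field(default_factory=dict)


@dataclass
class TrainingResult:
    """Trained architecture plus per-presentation weight summaries."""

    network: NetworkArchitecture
    calcium_target: float
    w_ff_mean: np.ndarray  # (repetitions + 1,) mean over existing connections
    w_fb_history: np.ndarray  # (repetitions + 1, n_v2)
    v2_calcium_mean: np.ndarray  # (repetitions,) presentation-averaged active-subset calcium


@dataclass
class FICurve:
    """Firing rate vs injected current for one neuron."""

    currents: np.ndarray
    rates: np.ndarray
    neuron_id: int
    condition: str = ""


@dataclass
class DecomposedCurrents:
    """Separately recorded excitatory and inhibitory synaptic current traces
    (evaluated at the resting potential of the monitored neuron)."""

    times: np.ndarray
    excitatory: np.ndarray
    inhibitory: np.ndarray
    neuron_id: int

    @property
    def mean_excitatory(self) -> float:
        return float(np.mean(self.excitatory))

    @property
    def mean_inhibitory(self) -> float:
        return float(np.mean(self.inhibitory))


def make_oriented_input(
    spec: StimulusSpec, architecture: NetworkArchitecture, stimulus_gain_i: float | None = None
):
    """Per-neuron input currents for a bell-shaped oriented stimulus.

    Returns ``(i_e, i_i)``: Gaussian profiles of injected current over the
    layer-one excitatory ring and (scaled by the configured gain) over the
    interleaved inhibitory cells.  On the circular topology the profile wraps.
    """
    ne, ni = architecture.n_v1_excitatory, architecture.n_v1_inhibitory
    deg = architecture.degrees_per_neuron
    center = (spec.center_orientation % 180.0) / deg
    if architecture.topology == "bounded" and not (
        0.0 <= spec.center_orientation <= 180.0
    ):
        raise ValueError("stimulus center outside the bounded orientation domain")
    if stimulus_gain_i is None:
        stimulus_gain_i = (
            architecture.config.stimulus_gain_i if architecture.config is not None else 1.0
        )
    from shuntnet.network_builder import ring_distance

    pos_e = np.arange(ne, dtype=float)
    stride = ne / ni
    pos_i = (np.arange(ni, dtype=float) + 0.5) * stride
    d_e = ring_distance(pos_e, center, ne, architecture.topology)
    d_i = ring_distance(pos_i, center, ne, architecture.topology)
    i_e = spec.peak_amplitude * np.exp(-np.square(d_e) / (2.0 * spec.profile_width ** 2))
    i_i = stimulus_gain_i * spec.peak_amplitude * np.exp(
        -np.square(d_i) / (2.0 * spec.profile_width ** 2)
    )
    return i_e, i_i


def rate_from_spikes(spikes: list, t_start: float, t_stop: float) -> np.ndarray:
    """Mean rate (Hz) per neuron from spike-time arrays over a window."""
    out = np.empty(len(spikes))
    for k, st in enumerate(spikes):
        out[k] = np.count_nonzero((np.asarray(st) >= t_start) & (np.asarray(st) < t_stop))
    return out * 1000.0 / (t_stop - t_start)


def _active_v2_subset(ca_v2: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Indices of layer-two neurons whose time-averaged calcium exceeds
    ``fraction`` of the population maximum."""
    mean_ca = ca_v2.mean(axis=0)
    return np.flatnonzero(mean_ca > fraction * mean_ca.max())


def compute_calcium_setpoint(
    network: NetworkArchitecture,
    stimulus: StimulusSpec,
    plasticity: PlasticityParams | None = None,
    dt: float = 0.025,
):
    """Baseline homeostatic calcium set-point of the layer-two population.

    Presents the stimulus once to the naive network (plasticity off) and
    averages the calcium of the stimulus-activated layer-two subset over the
    trailing set-point window.  Returns ``(ca0, active_indices)``; the
    set-point is then held fixed throughout training.
    """
    plasticity = plasticity or PlasticityParams()
    sim = Simulator(network.copy(), dt=dt)
    rec = sim.run(
        stimulus.duration,
        *make_oriented_input(stimulus, network),
        rec_stride=20,
        ramp=stimulus.onset_ramp,
    )
    active = _active_v2_subset(rec.ca_v2)
    if active.size == 0:
        raise RuntimeError("stimulus evoked no layer-two calcium; cannot set a target")
    trace = rec.ca_v2[:, active].mean(axis=1)
    sample_dt = dt * 20
    ca0 = update_calcium_target(trace, plasticity.setpoint_window, sample_dt)
    return ca0, active


def run_training(
    network: NetworkArchitecture,
    stimulus: StimulusSpec,
    repetitions: int,
    plasticity: PlasticityParams | None = None,
    calcium_target: float | None = None,
    dt: float = 0.025,
    record_presentations: bool = True,
) -> TrainingResult:
    """Repeatedly present one stimulus with both plasticity rules active.

    Each presentation starts from rest (the inter-stimulus blank is long
    relative to every synaptic and calcium time constant, so carry-over state
    is negligible and is not simulated).  Only the feedforward magnitudes and
    feedback scalars change; a copy of the input architecture is trained and
    returned, the original is untouched.
    """
    plasticity = plasticity or PlasticityParams()
    trained = network.copy()
    if calcium_target is None:
        calcium_target, _ = compute_calcium_setpoint(network, stimulus, plasticity, dt=dt)
    sim = Simulator(trained, dt=dt)
    i_e, i_i = make_oriented_input(stimulus, trained)
    mask = trained.ff_mask
    w_ff_mean = [float(trained.w_ff[mask].mean()) if mask.any() else 0.0]
    w_fb_hist = [trained.w_fb.copy()]
    ca_mean = []
    for _ in range(int(repetitions)):
        sim.reset()
        rec = sim.run(
            stimulus.duration,
            i_ext_e=i_e,
            i_ext_i=i_i,
            plasticity=plasticity,
            calcium_target=calcium_target,
            rec_stride=20 if record_presentations else 0,
            record=record_presentations,
            ramp=stimulus.onset_ramp,
        )
        if record_presentations:
            active = _active_v2_subset(rec.ca_v2)
            ca_mean.append(
                float(rec.ca_v2[:, active].mean()) if active.size else 0.0
            )
        w_ff_mean.append(float(trained.w_ff[mask].mean()) if mask.any() else 0.0)
        w_fb_hist.append(trained.w_fb.copy())
    sim.reset()
    return TrainingResult(
        network=trained,
        calcium_target=calcium_target,
        w_ff_mean=np.array(w_ff_mean),
        w_fb_history=np.array(w_fb_hist),
        v2_calcium_mean=np.array(ca_mean),
    )


def measure_tuning(
    network: NetworkArchitecture,
    probe_orientations,
    probe_spec: StimulusSpec,
    neuron_ids=None,
    dt: float = 0.025,
    condition: str = "",
):
    """Orientation sweep with plasticity frozen.

    For each probe orientation the network is re-initialized at rest, driven
    for the probe duration, and time-averaged rates are computed over the
    final 80% of the window.  Returns a dict with the probe grid, the full
    layer-one excitatory rate matrix, the layer-two rate matrix, the total
    feedback drive per probe, and :class:`~shuntnet.analysis.TuningCurve`
    objects for the requested neurons.
    """
    from shuntnet.analysis import TuningCurve

    probe_orientations = np.asarray(list(probe_orientations), float)
    if probe_orientations.size == 0:
        raise ValueError("probe orientation list is empty")
    sim = Simulator(network.copy(), dt=dt)
    ne = network.n_v1_excitatory
    rates_e = np.zeros((probe_orientations.size, ne))
    rates_2 = np.zeros((probe_orientations.size, network.n_v2_excitatory))
    fb_drive = np.zeros(probe_orientations.size)
    t_on = RATE_TRANSIENT_FRACTION * probe_spec.duration
    for k, ori in enumerate(probe_orientations):
        sim.reset()
        spec = probe_spec.shifted(float(ori))
        rec = sim.run(
            probe_spec.duration,
            *make_oriented_input(spec, network),
            rec_stride=20,
            ramp=probe_spec.onset_ramp,
        )
        rates_e[k] = rec.rates("v1e", t_on, probe_spec.duration)
        rates_2[k] = rec.rates("v2", t_on, probe_spec.duration)
        sel = rec.times >= t_on
        fb_drive[k] = float(rec.fb_drive[sel].mean())
    if neuron_ids is None:
        neuron_ids = range(ne)
    curves = {
        int(i): TuningCurve(
            orientations=probe_orientations.copy(),
            rates=rates_e[:, int(i)].copy(),
            neuron_id=int(i),
            condition=condition,
        )
        for i in neuron_ids
    }
    return {
        "orientations": probe_orientations,
        "rates_v1e": rates_e,
        "rates_v2": rates_2,
        "feedback_drive": fb_drive,
        "curves": curves,
    }


def probe_fi_curve(
    network: NetworkArchitecture,
    neuron_id: int,
    current_values,
    background_stimulus: StimulusSpec | None = None,
    duration: float = 500.0,
    dt: float = 0.025,
    condition: str = "",
) -> FICurve:
    """f-I curve of one layer-one excitatory neuron by direct current
    injection, with the network optionally driven by a background stimulus
    (so recurrent and feedback pathways are engaged)."""
    current_values = np.asarray(list(current_values), float)
    sim = Simulator(network.copy(), dt=dt)
    if background_stimulus is not None:
        i_e_bg, i_i_bg = make_oriented_input(background_stimulus, network)
    else:
        i_e_bg = np.zeros(network.n_v1_excitatory)
        i_i_bg = np.zeros(network.n_v1_inhibitory)
    rates = np.zeros(current_values.size)
    t_on = RATE_TRANSIENT_FRACTION * duration
    for k, amp in enumerate(current_values):
        sim.reset()
        i_e = i_e_bg.copy()
        i_e[neuron_id] += amp
        ramp = background_stimulus.onset_ramp if background_stimulus is not None else 50.0
        rec = sim.run(duration, i_ext_e=i_e, i_ext_i=i_i_bg, record=False, ramp=ramp)
        rates[k] = rate_from_spikes([rec.spikes_v1e[neuron_id]], t_on, duration)[0]
    return FICurve(currents=current_values, rates=rates, neuron_id=neuron_id, condition=condition)


def decompose_currents(
    network: NetworkArchitecture,
    neuron_id: int,
    stimulus: StimulusSpec,
    window: tuple | None = None,
    dt: float = 0.025,
) -> DecomposedCurrents:
    """Separately recorded excitatory (recurrent + feedback) and inhibitory
    synaptic currents onto one layer-one excitatory neuron during a stimulus.

    Currents are evaluated at the neuron's resting potential (voltage-clamp
    readout of the recorded conductances), matching the balance-at-rest
    protocol.
    """
    sim = Simulator(network.copy(), dt=dt)
    rec = sim.run(
        stimulus.duration,
        *make_oriented_input(stimulus, network),
        monitor_conductance=(neuron_id,),
        rec_stride=10,
        ramp=stimulus.onset_ramp,
    )
    if window is None:
        window = (RATE_TRANSIENT_FRACTION * stimulus.duration, stimulus.duration)
    t0, t1 = window
    if t0 < 0 or t1 > stimulus.duration + 1e-9 or t1 <= t0:
        raise ValueError(f"window {window} outside simulated time [0, {stimulus.duration}]")
    sel = (rec.times >= t0) & (rec.times < t1)
    g = rec.g_monitored[neuron_id]
    v_rest = sim.resting_potential_e
    i_exc = -(g[sel, 0] + g[sel, 1]) * (v_rest - 0.0)
    i_inh = -g[sel, 2] * (v_rest - sim.synapse.inhibitory_reversal)
    return DecomposedCurrents(
        times=rec.times[sel].copy(),
        excitatory=i_exc,
        inhibitory=i_inh,
        neuron_id=neuron_id,
    )


def measure_input_resistance(
    network: NetworkArchitecture,
    neuron_id: int,
    background_stimulus: StimulusSpec | None = None,
    duration: float = 500.0,
    dt: float = 0.025,
) -> float:
    """Effective input resistance of one layer-one excitatory neuron at rest.

    The inverse of the total membrane conductance load: leak plus the
    time-averaged synaptic conductances recorded while the background
    stimulus drives the network.  (Probing with an injected current step
    measures the same slope for a passive membrane but is confounded by the
    recurrent network's response to the probe current itself.)
    """
    sim = Simulator(network.copy(), dt=dt)
    if background_stimulus is not None:
        i_e, i_i = make_oriented_input(background_stimulus, network)
        ramp = background_stimulus.onset_ramp
        duration = background_stimulus.duration
    else:
        i_e = np.zeros(network.n_v1_excitatory)
        i_i = np.zeros(network.n_v1_inhibitory)
        ramp = 0.0
    rec = sim.run(
        duration,
        i_ext_e=i_e,
        i_ext_i=i_i,
        monitor_conductance=(neuron_id,),
        rec_stride=10,
        ramp=ramp,
    )
    g = rec.g_monitored[neuron_id]
    sel = rec.times >= rec.t0 + 0.4 * duration
    g_syn = float(np.mean(g[sel].sum(axis=1)))
    return 1.0 / (sim.neuron_e.leak_conductance + g_syn)


def run_protocol(
    network: NetworkArchitecture,
    protocol: Protocol,
    plasticity: PlasticityParams | None = None,
    calcium_target: float = 0.0,
    dt: float = 0.025,
) -> SimulationResult:
    """Execute an ordered presentation schedule and collect results.

    Plasticity is applied only during presentations flagged ``plasticity_on``.
    The network copy is mutated across the schedule (so training
    presentations accumulate); measurement presentations still start from a
    rest state.
    """
    net = network.copy()
    sim = Simulator(net, dt=dt)
    result = SimulationResult(seed=protocol.random_seed)
    offset = 0.0
    for _ in range(int(protocol.repetitions)):
        for pres in protocol.presentations:
            sim.reset()
            rec = sim.run(
                pres.stimulus.duration,
                *make_oriented_input(pres.stimulus, net),
                plasticity=plasticity if pres.plasticity_on else None,
                calcium_target=calcium_target,
                monitor_conductance=protocol.record_currents,
                record_v=3 if protocol.record_states else 0,
                rec_stride=20,
                ramp=pres.stimulus.onset_ramp,
            )
            for pop, store in (
                ("spikes_v1e", result.spikes_v1e),
                ("spikes_v1i", result.spikes_v1i),
                ("spikes_v2", result.spikes_v2),
            ):
                trains = getattr(rec, pop)
                if not store:
                    store.extend([st + offset for st in trains])
                else:
                    for k, st in enumerate(trains):
                        store[k] = np.concatenate([store[k], st + offset])
            if protocol.record_currents and rec.g_monitored:
                v_rest = sim.resting_potential_e
                for idx, g in rec.g_monitored.items():
                    tr = np.column_stack(
                        [
                            -(g[:, 0] + g[:, 1]) * v_rest,
                            -g[:, 2] * (v_rest - sim.synapse.inhibitory_reversal),
                        ]
                    )
                    if idx in result.currents:
                        result.currents[idx] = np.vstack([result.currents[idx], tr])
                    else:
                        result.currents[idx] = tr
            if protocol.record_weights:
                result.weight_snapshots.append(
                    {
                        "w_ff_mean": float(net.w_ff[net.ff_mask].mean()),
                        "w_fb": net.w_fb.copy(),
                    }
                )
            offset += pres.stimulus.duration + pres.inter_stimulus_interval
    result.config_echo = {"dt": dt, "repetitions": protocol.repetitions}
    return result
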