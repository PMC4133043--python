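"""Architecture construction: populations, distance-dependent recurrent
weights, probabilistic convergent feedforward connectivity, uniform feedback.

Layer-one excitatory neurons tile 180 degrees of orientation on a ring (1.8
degrees per neuron at the default size of 100); inhibitory neurons interleave
at one per four excitatory cells.  Recurrent weights are deterministic
Gaussian-of-distance profiles; feedforward connections are Bernoulli-sampled
with Gaussian-of-distance probability; feedback is one scalar per layer-two
neuron fanning out uniformly to every layer-one cell.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConnectivityConfig",
    "NetworkArchitecture",
    "ring_distance",
    "build_v1_recurrent",
    "build_feedforward",
    "build_feedback",
    "build_network",
    "calibrate_ei_balance",
    "measure_rest_balance",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """No inhibitory scaling in the search bracket balances the currents."""


@dataclass(frozen=True)
class ConnectivityConfig:
    """Connectivity parameters (sizes, widths, peak weights, seed)."""

    n_v1_excitatory: int = 100
    n_v1_inhibitory: int = 25
    n_v2_excitatory: int = 100
    recurrent_sd: float = 10.0
    feedforward_sd: float = 5.0
    w_ee_peak: float = 0.002
    w_ei_peak: float = 0.004
    w_ie_peak: float = 0.045
    w_ii_peak: float = 0.03
    ff_peak_probability: float = 0.8
    ff_initial_weight: float = 0.008
    feedback_initial: float = 1.0
    feedback_gain_e: float = 0.01
    feedback_gain_i: float = 0.02
    stimulus_gain_i: float = 1.0
    background_current_e: float = 0.0
    background_current_i: float = 0.0
    topology: str = "circular"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.recurrent_sd <= 0 or self.feedforward_sd <= 0:
            raise ValueError("connectivity s.d. values must be > 0")
        if self.topology not in ("circular", "bounded"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (0.0 <= self.ff_peak_probability <= 1.0):
            raise ValueError("ff_peak_probability must be in [0, 1]")
        for name in ("w_ee_peak", "w_ei_peak", "w_ie_peak", "w_ii_peak", "ff_initial_weight",
                     "feedback_initial", "feedback_gain_e", "feedback_gain_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class NetworkArchitecture:
    """Weight structures and population geometry of the two-layer network.

    Weight matrices are (source, target) with non-negative entries; the sign
    of each pathway is carried by the synapse type.  ``w_fb`` holds one
    scalar per layer-two neuron, applied identically (times the class gain)
    to every layer-one target.
    """

    n_v1_excitatory: int
    n_v1_inhibitory: int
    n_v2_excitatory: int
    w_ee: np.ndarray
    w_ei: np.ndarray
    w_ie: np.ndarray
    w_ii: np.ndarray
    w_ff: np.ndarray
    ff_mask: np.ndarray
    w_fb: np.ndarray
    feedback_gain_e: float
    feedback_gain_i: float
    topology: str = "circular"
    config: ConnectivityConfig | None = None
    ei_scale: float = 1.0  # I->E scaling found by calibration

    @property
    def degrees_per_neuron(self) -> float:
        return 180.0 / self.n_v1_excitatory

    def position_of_neuron(self, index: int, population: str = "v1e") -> float:
        """Preferred orientation (degrees) of a neuron, by ring position."""
        if population in ("v1e", "v2"):
            return (index % self.n_v1_excitatory) * self.degrees_per_neuron
        if population == "v1i":
            stride = self.n_v1_excitatory / self.n_v1_inhibitory
            return ((index + 0.5) * stride) * self.degrees_per_neuron
        raise ValueError(f"unknown population {population!r}")

    def orientation_to_index(self, orientation_deg: float) -> int:
        """Nearest excitatory-ring index for an orientation in degrees."""
        idx = int(round((orientation_deg % 180.0) / self.degrees_per_neuron))
        return idx % self.n_v1_excitatory

    def copy(self) -> "NetworkArchitecture":
        return _copy.deepcopy(self)


def ring_distance(i, j, n: int, topology: str = "circular"):
    """Distance between ring positions ``i`` and ``j`` (in neuron units)."""
    d = np.abs(np.asarray(i, float) - np.asarray(j, float))
    if topology == "circular":
        d = np.minimum(d, n - d)
    return d


def _gaussian_profile(dist, peak: float, sd: float):
    return peak * np.exp(-np.square(dist) / (2.0 * sd * sd))


def build_v1_recurrent(config: ConnectivityConfig):
    """Deterministic Gaussian-of-distance recurrent weights (E->E, E->I, I->E).

    These pathways are frozen: no learning rule ever touches them.
    """
    ne, ni = config.n_v1_excitatory, config.n_v1_inhibitory
    sd = config.recurrent_sd
    pos_e = np.arange(ne, dtype=float)
    stride = ne / ni
    pos_i = (np.arange(ni, dtype=float) + 0.5) * stride
    d_ee = ring_distance(pos_e[:, None], pos_e[None, :], ne, config.topology)
    d_ei = ring_distance(pos_e[:, None], pos_i[None, :], ne, config.topology)
    d_ie = ring_distance(pos_i[:, None], pos_e[None, :], ne, config.topology)
    d_ii = ring_distance(pos_i[:, None], pos_i[None, :], ne, config.topology)
    w_ee = _gaussian_profile(d_ee, config.w_ee_peak, sd)
    w_ei = _gaussian_profile(d_ei, config.w_ei_peak, sd)
    w_ie = _gaussian_profile(d_ie, config.w_ie_peak, sd)
    w_ii = _gaussian_profile(d_ii, config.w_ii_peak, sd)
    return w_ee, w_ei, w_ie, w_ii


def build_feedforward(config: ConnectivityConfig, rng: np.random.Generator):
    """Bernoulli-sampled convergent feedforward connectivity (V1E -> V2E).

    Connection probability falls off as a Gaussian of ring distance between
    corresponding positions (s.d. ``feedforward_sd``); existing connections
    start at a uniform magnitude.  The sparsity pattern is frozen; only
    magnitudes learn.
    """
    ne, nv = config.n_v1_excitatory, config.n_v2_excitatory
    pos_e = np.arange(ne, dtype=float)
    pos_v = np.arange(nv, dtype=float) * (ne / nv)
    d = ring_distance(pos_e[:, None], pos_v[None, :], ne, config.topology)
    prob = _gaussian_profile(d, config.ff_peak_probability, config.feedforward_sd)
    mask = rng.random((ne, nv)) < prob
    w_ff = np.where(mask, config.ff_initial_weight, 0.0)
    return w_ff, mask


def build_feedback(config: ConnectivityConfig) -> np.ndarray:
    """Uniform naive feedback weights, one scalar per layer-two neuron."""
    return np.full(config.n_v2_excitatory, float(config.feedback_initial))


def build_network(config: ConnectivityConfig) -> NetworkArchitecture:
    """Assemble the full architecture from one seeded configuration.

    Identical configuration (including seed) yields a bit-identical
    architecture.
    """
    rng = np.random.default_rng(config.random_seed)
    w_ee, w_ei, w_ie, w_ii = build_v1_recurrent(config)
    w_ff, mask = build_feedforward(config, rng)
    w_fb = build_feedback(config)
    return NetworkArchitecture(
        n_v1_excitatory=config.n_v1_excitatory,
        n_v1_inhibitory=config.n_v1_inhibitory,
        n_v2_excitatory=config.n_v2_excitatory,
        w_ee=w_ee,
        w_ei=w_ei,
        w_ie=w_ie,
        w_ii=w_ii,
        w_ff=w_ff,
        ff_mask=mask,
        w_fb=w_fb,
        feedback_gain_e=config.feedback_gain_e,
        feedback_gain_i=config.feedback_gain_i,
        topology=config.topology,
        config=config,
    )


def measure_rest_balance(
    architecture: NetworkArchitecture,
    probe_stimulus,
    probe_neuron: int | None = None,
    duration: float = 500.0,
    dt: float = 0.025,
    v_rest: float | None = None,
):
    """Time-averaged excitatory and inhibitory synaptic currents seen by a
    quiescent layer-one neuron at its resting potential.

    The probe neuron defaults to the cell diametrically opposite the stimulus
    center (it does not respond to the stimulus); conductances are measured
    over the last 60% of the stimulus window and converted to currents at the
    resting potential.  Returns ``(i_exc, i_inh)`` with the membrane-current
    sign convention (excitatory > 0, inhibitory < 0 at rest).
    """
    from shuntnet.engine import Simulator
    from shuntnet.protocols import make_oriented_input

    sim = Simulator(architecture, dt=dt)
    if v_rest is None:
        v_rest = sim.resting_potential_e
    ne = architecture.n_v1_excitatory
    if probe_neuron is None:
        center = architecture.orientation_to_index(probe_stimulus.center_orientation)
        # average over a small group of quiescent cells opposite the
        # stimulus; a single cell's local inhibition is too granular (few
        # inhibitory neurons within reach) for a stable calibration target
        probes = tuple(
            (center + ne // 2 + off) % ne for off in (-6, -3, 0, 3, 6)
        )
    else:
        probes = (int(probe_neuron),)
    i_e, i_i = make_oriented_input(probe_stimulus, architecture)
    rec = sim.run(
        duration,
        i_ext_e=i_e,
        i_ext_i=i_i,
        monitor_conductance=probes,
        rec_stride=10,
        ramp=probe_stimulus.onset_ramp,
    )
    sel = rec.times >= rec.t0 + 0.4 * duration
    g_exc = float(np.mean([np.mean(rec.g_monitored[p][sel, 0] + rec.g_monitored[p][sel, 1]) for p in probes]))
    g_inh = float(np.mean([np.mean(rec.g_monitored[p][sel, 2]) for p in probes]))
    i_exc = -g_exc * (v_rest - 0.0)
    i_inh = -g_inh * (v_rest - sim.synapse.inhibitory_reversal)
    return i_exc, i_inh


def calibrate_ei_balance(
    architecture: NetworkArchitecture,
    probe_stimulus,
    tolerance: float = 0.1,
    target_fraction: float = -0.05,
    scale_bracket: tuple = (0.05, 8.0),
    max_iter: int = 60,
    probe_neuron: int | None = None,
    duration: float = 500.0,
    dt: float = 0.025,
    apply: bool = True,
) -> float:
    """Scale I->E weights so excitation and inhibition cancel at rest.

    Bisection on a multiplicative factor applied to the I->E matrix until the
    time-averaged excitatory and inhibitory currents onto the probed neurons
    (evaluated at the resting potential) cancel within ``tolerance`` of the
    excitatory component.  ``target_fraction`` aims the net current at a
    small fraction of the excitatory component rather than exactly zero; the
    slightly inhibition-dominant default (still well inside the balance
    tolerance) buys the trained feedback loop a stability margin.  Returns
    the factor; with ``apply`` it is folded into ``architecture.w_ie`` and
    recorded as ``ei_scale``.

    Raises
    ------
    CalibrationError
        If no factor inside ``scale_bracket`` achieves balance.
    """
    if not np.any(architecture.w_ee) and not np.any(architecture.w_fb):
        return 0.0

    base_w_ie = architecture.w_ie.copy()

    def net_at(scale: float):
        trial = architecture.copy()
        trial.w_ie = base_w_ie * scale
        i_exc, i_inh = measure_rest_balance(
            trial, probe_stimulus, probe_neuron=probe_neuron, duration=duration, dt=dt
        )
        return i_exc + i_inh - target_fraction * i_exc, i_exc

    lo, hi = scale_bracket
    f_lo, exc_lo = net_at(lo)
    if exc_lo <= 0.0:
        # degenerate: no excitatory drive reaches the probe; nothing to balance
        return 0.0
    f_hi, exc_hi = net_at(hi)
    if abs(f_hi) <= 0.3 * tolerance * abs(exc_hi):
        if apply:
            architecture.w_ie = base_w_ie * hi
            architecture.ei_scale = hi
        return hi
    if f_lo < 0 or f_hi > 0:
        raise CalibrationError(
            f"balance not bracketed: net current {f_lo:.4g} at scale {lo}, "
            f"{f_hi:.4g} at scale {hi}"
        )
    scale, best_frac = None, np.inf
    blo, bhi = lo, hi
    for _ in range(max_iter):
        mid = 0.5 * (blo + bhi)
        f_mid, exc_mid = net_at(mid)
        frac = abs(f_mid) / abs(exc_mid) if exc_mid > 0 else np.inf
        if frac < best_frac:
            scale, best_frac = mid, frac
        if frac <= 0.3 * tolerance:
            break
        if f_mid > 0:
            blo = mid
        else:
            bhi = mid
    # the balance fraction is steep and locally non-monotone in the scale,
    # which can strand a blind bisection on the wrong branch; rescue with a
    # coarse geometric scan refined around its lowest sign crossing
    if scale is None or best_frac > tolerance - abs(target_fraction):
        grid = np.geomspace(lo, hi, 12)
        nets = np.zeros(grid.size)
        for k, g in enumerate(grid):
            f_k, exc_k = net_at(float(g))
            nets[k] = f_k
            frac = abs(f_k) / exc_k if exc_k > 0 else np.inf
            if frac < best_frac:
                scale, best_frac = float(g), frac
        for k in range(grid.size - 1):
            if nets[k] > 0 > nets[k + 1]:
                blo, bhi = float(grid[k]), float(grid[k + 1])
                for _ in range(12):
                    mid = 0.5 * (blo + bhi)
                    f_mid, exc_mid = net_at(mid)
                    frac = abs(f_mid) / abs(exc_mid) if exc_mid > 0 else np.inf
                    if frac < best_frac:
                        scale, best_frac = mid, frac
                    if frac <= 0.3 * tolerance:
                        break
                    if f_mid > 0:
                        blo = mid
                    else:
                        bhi = mid
                break
    if scale is None or best_frac > tolerance - abs(target_fraction):
        raise CalibrationError(
            f"no scaling in {scale_bracket} balances the currents within "
            f"{tolerance:.0%} (best deviation {best_frac:.1%} at scale {scale})"
        )
    if apply:
        architecture.w_ie = base_w_ie * scale
        architecture.ei_scale = scale
    return scale
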