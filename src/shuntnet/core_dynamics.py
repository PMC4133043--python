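"""Single-neuron and single-synapse dynamics.

Hodgkin-Huxley regular-spiking neurons with a high-threshold calcium current,
a calcium-dependent after-hyperpolarization (AHP) potassium current on
excitatory cells, intracellular-calcium dynamics, and first-order AMPA /
GABAa synaptic gating.

Conventions
-----------
* voltages in mV, time in ms, conductances in mS/cm^2, currents in uA/cm^2,
  membrane capacitance fixed at 1 uF/cm^2;
* intracellular calcium is a dimensionless activity variable driven by the
  spike-associated calcium current and decaying with ``tau_ca``;
* ionic currents are written ``g * x * (V - E)`` and enter the membrane
  equation with a minus sign, so synaptic currents returned by
  :func:`synaptic_current` are *membrane* currents: positive = depolarizing.

The exact gating-kinetics rate functions are listed in
``docs/parameters.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IntegrationDivergedError",
    "NeuronParams",
    "NeuronState",
    "SynapseParams",
    "SynapseState",
    "alpha_m",
    "beta_m",
    "alpha_h",
    "beta_h",
    "alpha_n",
    "beta_n",
    "mca_inf",
    "gating_steady_state",
    "membrane_derivatives",
    "step_neuron",
    "update_synaptic_gating",
    "synaptic_current",
]

# Threshold used to detect spikes (upward crossing) and minimum separation
# between detected spikes.
SPIKE_THRESHOLD = 0.0  # mV
SPIKE_REFRACTORY = 2.0  # ms


class IntegrationDivergedError(RuntimeError):
    """Raised when a neuron state or input stops being finite."""


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical parameters of one cell class (per-unit-area units)."""

    leak_conductance: float = 0.05
    sodium_conductance: float = 100.0
    potassium_conductance: float = 40.0
    calcium_conductance: float = 0.9
    ahp_conductance: float = 0.05
    leak_reversal: float = -65.0
    sodium_reversal: float = 55.0
    potassium_reversal: float = -80.0
    calcium_reversal: float = 120.0
    calcium_time_constant: float = 100.0
    calcium_influx_gain: float = 0.002
    has_ahp: bool = True

    def __post_init__(self) -> None:
        for name in (
            "leak_conductance",
            "sodium_conductance",
            "potassium_conductance",
            "calcium_conductance",
            "ahp_conductance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (self.potassium_reversal < self.leak_reversal < self.sodium_reversal):
            raise ValueError("require V_K < V_L < V_Na")
        if self.calcium_time_constant <= 0:
            raise ValueError("calcium_time_constant must be > 0")

    @classmethod
    def excitatory(cls, **overrides) -> "NeuronParams":
        """Regular-spiking excitatory cell (g_L = 0.05, AHP present)."""
        return cls(**overrides)

    @classmethod
    def inhibitory(cls, **overrides) -> "NeuronParams":
        """Fast inhibitory cell: leak doubled (g_L = 0.1), no AHP current."""
        overrides.setdefault("leak_conductance", 0.1)
        overrides.setdefault("ahp_conductance", 0.0)
        overrides.setdefault("has_ahp", False)
        return cls(**overrides)


@dataclass
class NeuronState:
    """Dynamic state of one neuron."""

    membrane_potential: float = -65.0
    gating_m: float = 0.0
    gating_h: float = 1.0
    gating_n: float = 0.0
    calcium: float = 0.0
    last_spike_time: float | None = None

    def is_finite(self) -> bool:
        return bool(
            np.isfinite(self.membrane_potential)
            and np.isfinite(self.gating_m)
            and np.isfinite(self.gating_h)
            and np.isfinite(self.gating_n)
            and np.isfinite(self.calcium)
        )


@dataclass(frozen=True)
class SynapseParams:
    """AMPA / GABAa kinetic constants and reversal potentials.

    The inhibitory reversal is stored with its physiological sign (-80 mV,
    equal to the potassium reversal); the source text quotes the magnitude.
    """

    ampa_time_constant: float = 2.0
    gabaa_time_constant: float = 2.0
    excitatory_reversal_onto_E: float = 0.0
    excitatory_reversal_onto_I: float = 0.0
    inhibitory_reversal: float = -80.0

    def __post_init__(self) -> None:
        if self.ampa_time_constant <= 0 or self.gabaa_time_constant <= 0:
            raise ValueError("synaptic time constants must be > 0")


@dataclass
class SynapseState:
    """Outgoing gating variables, one per presynaptic source neuron."""

    gating_s_e: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gating_s_i: np.ndarray = field(default_factory=lambda: np.zeros(0))
    depression_factor_f_e: float = 1.0
    depression_factor_f_i: float = 1.0


# --------------------------------------------------------------------------
# gating kinetics (rate functions in 1/ms, voltages in mV)
# --------------------------------------------------------------------------


def _vtrap(x: np.ndarray | float, y: float) -> np.ndarray | float:
    """x / (exp(x/y) - 1), continuous at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, y * (1.0 - x / (2.0 * y)), safe / np.expm1(safe / y))
    return out if out.shape else float(out)


def alpha_m(v):
    return 0.32 * _vtrap(-(np.asarray(v, float) + 50.0), 4.0)


def beta_m(v):
    return 0.28 * _vtrap(np.asarray(v, float) + 23.0, 5.0)


def alpha_h(v):
    return 0.128 * np.exp(-(np.asarray(v, float) + 50.0) / 18.0)


def beta_h(v):
    return 4.0 / (1.0 + np.exp(-(np.asarray(v, float) + 27.0) / 5.0))


def alpha_n(v):
    return 0.032 * _vtrap(-(np.asarray(v, float) + 52.0), 5.0)


def beta_n(v):
    return 0.5 * np.exp(-(np.asarray(v, float) + 57.0) / 40.0)


def mca_inf(v):
    """Instantaneous activation of the high-threshold calcium current."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) + 10.0) / 5.0))


def gating_steady_state(v: float) -> tuple[float, float, float]:
    """Voltage-clamp fixed point (m_inf, h_inf, n_inf) at potential ``v``."""
    am, bm = float(alpha_m(v)), float(beta_m(v))
    ah, bh = float(alpha_h(v)), float(beta_h(v))
    an, bn = float(alpha_n(v)), float(beta_n(v))
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


# --------------------------------------------------------------------------
# membrane equation
# --------------------------------------------------------------------------


def resting_state(params: NeuronParams, v_lo: float = -80.0, v_hi: float = -50.0) -> NeuronState:
    """Quiescent fixed point of the membrane equation (zero input, zero calcium).

    Solves dV/dt = 0 with gating variables at their voltage-clamp steady
    state; of the up-to-three fixed points the lowest (stable rest) is
    returned.  Used to initialize simulations at rest.
    """
    from scipy.optimize import brentq

    def dv(v):
        m, h, n = gating_steady_state(v)
        return membrane_derivatives(v, m, h, n, 0.0, params, 0.0)[0]

    # bracket the lowest downward crossing on a coarse grid
    grid = np.linspace(v_lo, v_hi, 121)
    vals = [dv(v) for v in grid]
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa > 0 >= fb:
            v_lo, v_hi = a, b
            break
    else:
        raise ValueError("no stable resting point found in bracket")
    v_rest = brentq(dv, v_lo, v_hi)
    m, h, n = gating_steady_state(v_rest)
    return NeuronState(float(v_rest), m, h, n, 0.0, None)


def membrane_derivatives(
    v: float,
    m: float,
    h: float,
    n: float,
    ca: float,
    params: NeuronParams,
    total_current: float,
) -> tuple[float, float, float, float, float]:
    """Time derivatives (dV, dm, dh, dn, dCa) of the point-neuron ODE.

    ``total_current`` is the sum of synaptic and injected membrane currents
    (positive depolarizes).
    """
    p = params
    i_leak = p.leak_conductance * (v - p.leak_reversal)
    i_na = p.sodium_conductance * m * m * m * h * (v - p.sodium_reversal)
    i_k = p.potassium_conductance * n ** 4 * (v - p.potassium_reversal)
    i_ca = p.calcium_conductance * mca_inf(v) * (v - p.calcium_reversal)
    i_ahp = 0.0
    if p.has_ahp:
        i_ahp = p.ahp_conductance * ca * (v - p.potassium_reversal)
    dv = -(i_leak + i_na + i_k + i_ca + i_ahp) + total_current
    dm = alpha_m(v) * (1.0 - m) - beta_m(v) * m
    dh = alpha_h(v) * (1.0 - h) - beta_h(v) * h
    dn = alpha_n(v) * (1.0 - n) - beta_n(v) * n
    # calcium influx follows the (inward, negative) calcium current
    dca = -p.calcium_influx_gain * i_ca - ca / p.calcium_time_constant
    return dv, dm, dh, dn, float(dca)


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    synaptic_current: float,
    injected_current: float,
    dt: float,
    t: float = 0.0,
) -> NeuronState:
    """Advance one neuron by ``dt`` with a classical RK4 step.

    Currents are held constant across the step.  A spike is registered on an
    upward crossing of 0 mV (with a 2 ms refractory window) and recorded in
    ``last_spike_time``.

    Raises
    ------
    IntegrationDivergedError
        If the state or the inputs are non-finite.
    """
    if not state.is_finite() or not np.isfinite(synaptic_current + injected_current):
        raise IntegrationDivergedError(
            f"non-finite neuron state or input at t={t:.3f} ms: {state}"
        )
    i_total = synaptic_current + injected_current
    y = np.array(
        [
            state.membrane_potential,
            state.gating_m,
            state.gating_h,
            state.gating_n,
            state.calcium,
        ]
    )

    def f(yv):
        return np.array(membrane_derivatives(*yv, params, i_total))

    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    y_new = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    y_new[4] = max(y_new[4], 0.0)

    last = state.last_spike_time
    crossed = state.membrane_potential < SPIKE_THRESHOLD <= y_new[0]
    if crossed and (last is None or (t + dt) - last >= SPIKE_REFRACTORY):
        last = t + dt
    new = replace(
        state,
        membrane_potential=float(y_new[0]),
        gating_m=float(np.clip(y_new[1], 0.0, 1.0)),
        gating_h=float(np.clip(y_new[2], 0.0, 1.0)),
        gating_n=float(np.clip(y_new[3], 0.0, 1.0)),
        calcium=float(y_new[4]),
        last_spike_time=last,
    )
    if not new.is_finite():
        raise IntegrationDivergedError(f"integration diverged at t={t + dt:.3f} ms")
    return new


# --------------------------------------------------------------------------
# synapses
# --------------------------------------------------------------------------


def update_synaptic_gating(
    state: SynapseState,
    presynaptic_spikes_e: np.ndarray | None = None,
    presynaptic_spikes_i: np.ndarray | None = None,
    dt: float = 0.025,
    params: SynapseParams = SynapseParams(),
) -> SynapseState:
    """Exponential decay of all gating variables plus unit spike increments.

    Each gating variable obeys ``ds/dt = -s/tau`` between spikes and jumps by
    one on a presynaptic spike (spike indicators are 0/1 vectors aligned with
    the source populations).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    s_e = np.asarray(state.gating_s_e, dtype=float)
    s_i = np.asarray(state.gating_s_i, dtype=float)
    if np.any(s_e < 0) or np.any(s_i < 0):
        raise ValueError("gating variables must be non-negative")
    s_e = s_e * np.exp(-dt / params.ampa_time_constant)
    s_i = s_i * np.exp(-dt / params.gabaa_time_constant)
    if presynaptic_spikes_e is not None:
        spikes = np.asarray(presynaptic_spikes_e, dtype=float)
        if spikes.shape != s_e.shape:
            raise ValueError("spike vector shape mismatch (excitatory)")
        s_e = s_e + spikes
    if presynaptic_spikes_i is not None:
        spikes = np.asarray(presynaptic_spikes_i, dtype=float)
        if spikes.shape != s_i.shape:
            raise ValueError("spike vector shape mismatch (inhibitory)")
        s_i = s_i + spikes
    return replace(state, gating_s_e=s_e, gating_s_i=s_i)


def synaptic_current(
    target_class: str,
    target_v: float,
    gatings: SynapseState,
    weights_e: np.ndarray,
    weights_i: np.ndarray | None = None,
    params: SynapseParams = SynapseParams(),
) -> tuple[float, float]:
    """Excitatory and inhibitory membrane currents onto one target neuron.

    Returns the two components separately (their sum is the total synaptic
    current used by the membrane equation).  ``target_class`` selects the
    excitatory reversal used for AMPA currents ('E' or 'I').  The inhibitory
    component is zero when no inhibitory weights are supplied (e.g. no
    I->I coupling is configured).
    """
    if target_class not in ("E", "I"):
        raise ValueError("target_class must be 'E' or 'I'")
    w_e = np.asarray(weights_e, dtype=float)
    s_e = np.asarray(gatings.gating_s_e, dtype=float)
    if w_e.shape != s_e.shape:
        raise ValueError("excitatory weight/gating dimension mismatch")
    v_exc = (
        params.excitatory_reversal_onto_E
        if target_class == "E"
        else params.excitatory_reversal_onto_I
    )
    i_exc = -gatings.depression_factor_f_e * float(w_e @ s_e) * (target_v - v_exc)
    i_inh = 0.0
    if weights_i is not None:
        w_i = np.asarray(weights_i, dtype=float)
        s_i = np.asarray(gatings.gating_s_i, dtype=float)
        if w_i.shape != s_i.shape:
            raise ValueError("inhibitory weight/gating dimension mismatch")
        i_inh = -gatings.depression_factor_f_i * float(w_i @ s_i) * (
            target_v - params.inhibitory_reversal
        )
    return i_exc, i_inh
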