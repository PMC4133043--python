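"""Learning rules.

Two rules operate on the inter-layer pathways only (recurrent weights are
frozen):

* calcium-product Hebbian growth of feedforward weights,
  ``dW_ij/dt = (eta / tau_Hebb) * Ca_pre_j * Ca_post_i`` on existing
  connections, hard-clipped at a ceiling;
* homeostatic adjustment of the per-neuron feedback scalars toward a calcium
  set-point, ``dw_i/dt = (eta / tau_FB) * (Ca_i - Ca0)``, clipped to
  ``[0, ceiling]`` and gated by presynaptic calcium (silent layer-two
  neurons keep their naive feedback weight).

Above-target layer-two activity therefore strengthens feedback, which
suppresses layer one — and hence layer two — closing a negative feedback
loop around the set-point.

The same formulas are integrated online by the simulation kernel; the
functions here are the rule definitions used directly by tests and by
coarse-grained (per-sample) updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams",
    "hebbian_update",
    "feedback_update",
    "update_calcium_target",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Time scales, rates, ceilings and gates of both rules."""

    hebbian_time_constant: float = 100.0
    feedback_time_constant: float = 500.0
    hebbian_rate: float = 0.0006
    feedback_rate: float = 0.3
    feedforward_ceiling: float = 0.010
    feedback_ceiling: float = 2.0
    calcium_gate: float = 0.75  # fraction of the set-point gating the feedback rule
    setpoint_window: float = 300.0  # ms of baseline used for the calcium target
    feedforward_enabled: bool = True
    feedback_enabled: bool = True
    update_stride: int = 8  # dynamics steps between online weight updates

    def __post_init__(self) -> None:
        if self.hebbian_time_constant <= 0 or self.feedback_time_constant <= 0:
            raise ValueError("plasticity time constants must be > 0")
        if self.feedforward_ceiling < 0 or self.feedback_ceiling < 0:
            raise ValueError("weight ceilings must be >= 0")


def hebbian_update(
    w_ff: np.ndarray,
    ca_v1: np.ndarray,
    ca_v2: np.ndarray,
    dt: float,
    params: PlasticityParams,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """One Euler step of the calcium-product Hebbian rule.

    ``w_ff`` is (n_v1e, n_v2); connections absent from ``mask`` never grow.
    Returns a new array; inputs are not modified.
    """
    ca_v1 = np.asarray(ca_v1, float)
    ca_v2 = np.asarray(ca_v2, float)
    if np.any(ca_v1 < 0) or np.any(ca_v2 < 0):
        raise ValueError("calcium concentrations must be non-negative")
    if w_ff.shape != (ca_v1.size, ca_v2.size):
        raise ValueError("weight/calcium shape mismatch")
    if not params.feedforward_enabled:
        return w_ff.copy()
    growth = (params.hebbian_rate / params.hebbian_time_constant) * dt * np.outer(
        ca_v1, ca_v2
    )
    if mask is None:
        mask = w_ff > 0
    out = np.where(mask, w_ff + growth, w_ff)
    return np.minimum(out, params.feedforward_ceiling)


def feedback_update(
    w_fb: np.ndarray,
    ca_v2: np.ndarray,
    calcium_target: float,
    dt: float,
    params: PlasticityParams,
) -> np.ndarray:
    """One Euler step of the homeostatic feedback rule.

    Each layer-two neuron whose calcium exceeds the gate moves its feedback
    scalar proportionally to ``Ca - Ca0``; the result is clipped to
    ``[0, ceiling]``.  Returns a new array.
    """
    ca_v2 = np.asarray(ca_v2, float)
    if np.any(ca_v2 < 0):
        raise ValueError("calcium concentrations must be non-negative")
    if w_fb.shape != ca_v2.shape:
        raise ValueError("weight/calcium shape mismatch")
    if calcium_target < 0:
        raise ValueError("calcium_target must be >= 0")
    if not params.feedback_enabled:
        return w_fb.copy()
    active = ca_v2 > params.calcium_gate * calcium_target
    delta = (params.feedback_rate / params.feedback_time_constant) * dt * (
        ca_v2 - calcium_target
    )
    out = np.where(active, w_fb + delta, w_fb)
    return np.clip(out, 0.0, params.feedback_ceiling)


def update_calcium_target(history: np.ndarray, window: float, dt: float) -> float:
    """Running time-average of a calcium trace over the trailing ``window`` ms.

    ``history`` is sampled every ``dt`` ms; the set-point is the mean of the
    most recent ``window / dt`` samples (all samples if the trace is
    shorter).
    """
    history = np.asarray(history, float)
    if history.size == 0:
        raise ValueError("calcium history is empty")
    if window <= 0 or dt <= 0:
        raise ValueError("window and dt must be > 0")
    n = max(int(round(window / dt)), 1)
    return float(np.mean(history[-n:]))
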