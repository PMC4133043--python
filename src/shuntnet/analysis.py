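"""Quantification of tuning curves and population responses.

Width is reported as full width at half maximum (FWHM) above the spontaneous
rate; the amplitude-to-width ratio R is amplitude divided by that width.
Slopes are central finite differences on the probe grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningCurve",
    "TuningMetrics",
    "IOFunction",
    "tuning_metrics",
    "classify_change",
    "preference_stability",
    "io_function",
    "feedback_strength_profile",
]

ORIENTATION_PERIOD = 180.0


@dataclass
class TuningCurve:
    """Orientation -> firing-rate mapping for one neuron."""

    orientations: np.ndarray
    rates: np.ndarray
    neuron_id: int = -1
    condition: str = ""

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, float)
        self.rates = np.asarray(self.rates, float)
        if self.orientations.shape != self.rates.shape:
            raise ValueError("orientation and rate grids differ in length")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class TuningMetrics:
    """Derived quantities of one tuning curve.

    ``defined`` is False for flat (non-responsive) curves, in which case the
    other fields are NaN rather than zero-divided.
    """

    amplitude: float
    width: float
    ratio_R: float
    preferred_orientation: float
    slope_at_reference: float
    slope_scale: float = np.nan  # max |slope| over the whole curve, for comparisons
    defined: bool = True


@dataclass
class IOFunction:
    """Input-strength -> output-rate mapping of the probed neuron."""

    inputs: np.ndarray
    rates: np.ndarray
    recurrence: str  # 'with' | 'without'


def circular_difference(a: float, b: float, period: float = ORIENTATION_PERIOD) -> float:
    """Signed smallest difference a - b on a circle of the given period."""
    d = (a - b) % period
    return d - period if d > period / 2 else d


def _interp_crossing(x0, y0, x1, y1, level):
    if y1 == y0:
        return x1
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def tuning_metrics(
    curve: TuningCurve,
    reference_orientation: float,
    spontaneous_rate: float = 0.0,
    response_threshold: float = 1.0,
) -> TuningMetrics:
    """Amplitude, FWHM width, ratio R, preferred orientation and slope.

    The spontaneous rate is subtracted before amplitude/width computation.
    The curve is unwrapped around its peak (circular orientation domain), the
    width is measured where the response crosses half its peak on either
    flank (linear interpolation), and the slope is a central finite
    difference at the grid point nearest ``reference_orientation``.
    Curves whose peak response stays below ``response_threshold`` (Hz above
    spontaneous) are flagged undefined.
    """
    ori = curve.orientations
    resp = curve.rates - spontaneous_rate
    n = ori.size
    if n < 3:
        raise ValueError("need at least 3 probe orientations")
    k_peak = int(np.argmax(resp))
    amplitude = float(resp[k_peak])
    if amplitude < response_threshold:
        return TuningMetrics(np.nan, np.nan, np.nan, np.nan, np.nan, defined=False)

    # unwrap the grid around the peak so the curve is a single bump on a line
    rel = np.array([circular_difference(o, ori[k_peak]) for o in ori])
    order = np.argsort(rel)
    x = rel[order]
    y = resp[order]
    j_peak = int(np.argmax(y))

    # interpolated peak location: centroid of the response above half height
    # (robust to flat-topped curves where a 3-point parabola jitters)
    top = y >= 0.5 * amplitude
    offset = float(np.sum(x[top] * y[top]) / np.sum(y[top]))
    preferred = (ori[k_peak] + offset) % ORIENTATION_PERIOD

    # full width at half maximum, interpolated on both flanks
    half = amplitude / 2.0
    left = x[0]
    for j in range(j_peak, 0, -1):
        if y[j - 1] < half <= y[j]:
            left = _interp_crossing(x[j - 1], y[j - 1], x[j], y[j], half)
            break
    right = x[-1]
    for j in range(j_peak, n - 1):
        if y[j + 1] < half <= y[j]:
            right = _interp_crossing(x[j], y[j], x[j + 1], y[j + 1], half)
            break
    width = float(right - left)
    if width <= 0:
        return TuningMetrics(amplitude, np.nan, np.nan, preferred, np.nan, defined=False)

    # central finite difference at the grid point nearest the reference
    k_ref = int(np.argmin(np.abs([circular_difference(o, reference_orientation) for o in ori])))

    def _central_slope(k):
        k_lo = (k - 1) % n
        k_hi = (k + 1) % n
        d_ori = circular_difference(ori[k_hi], ori[k_lo])
        return (resp[k_hi] - resp[k_lo]) / d_ori if d_ori != 0 else np.nan

    slope = float(_central_slope(k_ref))
    slope_scale = float(np.nanmax(np.abs([_central_slope(k) for k in range(n)])))

    return TuningMetrics(
        amplitude=amplitude,
        width=width,
        ratio_R=amplitude / width,
        preferred_orientation=float(preferred),
        slope_at_reference=slope,
        slope_scale=slope_scale,
        defined=True,
    )


def classify_change(
    before: TuningMetrics,
    after: TuningMetrics,
    slope_tolerance: float = 0.15,
) -> str:
    """Label the before/after change of one neuron's tuning curve.

    * ``'reduction'``: amplitude and width both decreased while the slope
      magnitude at the reference orientation changed by at most
      ``slope_tolerance`` (relative);
    * ``'sharpening'``: width shrank proportionally more than amplitude and
      the slope magnitude increased beyond tolerance;
    * ``'none'``: anything else;
    * ``'undefined'``: either metric set is undefined (flat curve).
    """
    if not (before.defined and after.defined):
        return "undefined"
    amp_change = (after.amplitude - before.amplitude) / before.amplitude
    width_change = (after.width - before.width) / before.width
    # slope changes are normalized by the steepest slope of the before-curve,
    # so flat-topped reference points (slope ~ 0) do not blow up the ratio
    scale = before.slope_scale
    if not np.isfinite(scale) or scale <= 0:
        scale = before.amplitude / before.width
    slope_change = (abs(after.slope_at_reference) - abs(before.slope_at_reference)) / scale
    if width_change < 0 and width_change < amp_change and slope_change > slope_tolerance:
        return "sharpening"
    if amp_change < 0 and width_change < 0 and abs(slope_change) <= slope_tolerance:
        return "reduction"
    return "none"


def preference_stability(
    before: dict,
    after: dict,
    tolerance_degrees: float,
    reference_orientation: float = 0.0,
    spontaneous_rate: float = 0.0,
):
    """Per-neuron orientation-preference stability between two curve sets.

    ``before`` and ``after`` map neuron id -> :class:`TuningCurve` on matched
    grids.  A responsive neuron is stable when its preferred orientation
    moved by at most ``tolerance_degrees`` (circular distance).  Returns
    ``(per_neuron, fraction_stable)`` where ``per_neuron`` maps neuron id to
    True/False (non-responsive neurons are omitted).
    """
    if set(before) != set(after):
        raise ValueError("before/after neuron sets differ")
    per_neuron = {}
    for nid in before:
        mb = tuning_metrics(before[nid], reference_orientation, spontaneous_rate)
        ma = tuning_metrics(after[nid], reference_orientation, spontaneous_rate)
        if not (mb.defined and ma.defined):
            continue
        shift = abs(circular_difference(ma.preferred_orientation, mb.preferred_orientation))
        per_neuron[nid] = bool(shift <= tolerance_degrees)
    fraction = (
        sum(per_neuron.values()) / len(per_neuron) if per_neuron else float("nan")
    )
    return per_neuron, fraction


def io_function(
    network,
    input_amplitudes,
    with_recurrence: bool,
    stimulus_template=None,
    neuron_id: int | None = None,
    dt: float = 0.025,
) -> IOFunction:
    """Rate of the stimulus-center neuron as a function of input strength.

    The without-recurrence condition zeroes every recurrent weight in layer
    one and the feedback scalars (without inhibition the excitatory feedback
    loop has no counterweight and diverges); plasticity is always frozen.
    """
    from shuntnet.protocols import (
        StimulusSpec,
        make_oriented_input,
        rate_from_spikes,
        RATE_TRANSIENT_FRACTION,
    )
    from shuntnet.engine import Simulator

    if stimulus_template is None:
        stimulus_template = StimulusSpec()
    net = network.copy()
    if not with_recurrence:
        net.w_ee = np.zeros_like(net.w_ee)
        net.w_ei = np.zeros_like(net.w_ei)
        net.w_ie = np.zeros_like(net.w_ie)
        net.w_ii = np.zeros_like(net.w_ii)
        # feedback is excitatory and unopposed once inhibition is removed;
        # the open-loop condition must silence it or the comparison diverges
        net.w_fb = np.zeros_like(net.w_fb)
    if neuron_id is None:
        neuron_id = net.orientation_to_index(stimulus_template.center_orientation)
    sim = Simulator(net, dt=dt)
    amps = np.asarray(list(input_amplitudes), float)
    rates = np.zeros(amps.size)
    t_on = RATE_TRANSIENT_FRACTION * stimulus_template.duration
    for k, amp in enumerate(amps):
        sim.reset()
        spec = StimulusSpec(
            center_orientation=stimulus_template.center_orientation,
            peak_amplitude=float(amp) if amp > 0 else 1e-12,
            profile_width=stimulus_template.profile_width,
            duration=stimulus_template.duration,
        )
        rec = sim.run(
            stimulus_template.duration, *make_oriented_input(spec, net), record=False,
            ramp=spec.onset_ramp,
        )
        rates[k] = rate_from_spikes(
            [rec.spikes_v1e[neuron_id]], t_on, stimulus_template.duration
        )[0]
    return IOFunction(inputs=amps, rates=rates, recurrence="with" if with_recurrence else "without")


def feedback_strength_profile(
    network,
    probe_orientations,
    probe_spec=None,
    dt: float = 0.025,
) -> np.ndarray:
    """Total feedback drive delivered to layer one per probe orientation.

    The drive is the time-averaged sum of feedback-weighted layer-two
    synaptic activity (the quantity fanned out uniformly to every layer-one
    cell).  Naive networks give a flat profile; trained networks peak at the
    trained orientation.
    """
    from shuntnet.protocols import StimulusSpec, measure_tuning

    if probe_spec is None:
        probe_spec = StimulusSpec()
    sweep = measure_tuning(network, probe_orientations, probe_spec, neuron_ids=(), dt=dt)
    return sweep["feedback_drive"]
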