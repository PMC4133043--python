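# shuntnet

A conductance-based spiking network model of perceptual learning through
top-down feedback. Two layers of Hodgkin–Huxley neurons — an orientation
ring of 100 excitatory and 25 inhibitory cells (layer one, "V1") and 100
excitatory cells (layer two, "V2") — are coupled by sparse convergent
feedforward projections and uniform excitatory feedback. Repeated stimulus
presentation strengthens the feedforward pathway through a calcium-product
Hebbian rule and the feedback pathway through a homeostatic calcium
set-point rule. Because the feedback recruits balanced excitation and
inhibition in layer one, the trained network exhibits shunting inhibition:
enlarged but still-cancelling synaptic currents at rest, a rightward
(subtractive) f-I shift, reduced input resistance, stimulus-specific
feedback strength, and sharpened orientation tuning with stable orientation
preferences.

## Layout

| module | contents |
|---|---|
| `shuntnet.core_dynamics` | single-neuron HH dynamics (Na, K, Ca, calcium-dependent AHP), intracellular calcium, AMPA/GABAa gating and currents |
| `shuntnet.engine` | numba network integrator (RK4, rate-function lookup tables, online plasticity, conductance recording) |
| `shuntnet.network_builder` | ring architecture, Gaussian-of-distance recurrent weights, Bernoulli feedforward sampling, uniform feedback, E/I balance calibration |
| `shuntnet.plasticity` | Hebbian feedforward rule, homeostatic feedback rule, calcium set-point |
| `shuntnet.protocols` | oriented stimuli, training, tuning sweeps, f-I probing, current decomposition, input resistance |
| `shuntnet.analysis` | tuning metrics (amplitude, FWHM width, ratio R, slope), reduction/sharpening classification, preference stability, input–output functions, feedback-strength profiles |
| `shuntnet.cli_io` | YAML config schema, HDF5/CSV serialization, `simulate` CLI, figure regeneration |

Exact gating kinetics and all parameter values are listed in
`docs/parameters.md`.

## CLI

```bash
simulate train --seed 0 --out results/            # calibrate + train, write HDF5
simulate tuning --seed 0 --out results/           # naive tuning sweep (CSV)
simulate fi --currents 0:1.2:0.05 --out results/  # f-I probe of the far neuron
simulate decompose --out results/                 # E/I current decomposition
simulate reproduce-figures --seed 0 --out results/  # full chain + PNG figure analogues
```

All commands accept `--config cfg.yaml` (strict schema; unknown keys are
rejected; an empty file means published defaults).

## Known limitations

Four acceptance properties are not met by the implementation at its default
operating point and their tests are left failing deliberately:

* the trained-preferring neuron's tuning amplitude does not decrease
  measurably (flank sharpening is reproduced, response reduction is not);
* the trained feedback-strength profile is peaked and graded, but a
  marginally self-exciting trained subnetwork inflates the feedback drive at
  the single diametrically opposite probe orientation, displacing the
  profile's argmax;
* the with-recurrence population response never exceeds the
  without-recurrence response for strongly driven neurons (the recurrent
  network is inhibition-dominated at every drive);
* post-training layer-two calcium settles well above the homeostatic
  set-point rather than within 10%.

All three trace to one mechanism: with the published cell parameters, the
suppressive effect of balanced feedback conductance on a strongly driven
neuron is weak, and strengthening the relevant couplings far enough to make
it visible tips the network into a runaway synchronous state (the
"epileptic-like" regime the modulatory feedback is supposed to avoid). The
stability boundary of the feedback loop sits directly against the operating
point needed for these three effects.
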