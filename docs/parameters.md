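# Model parameters

All quantities are per-unit-area: conductances in mS/cm², currents in
µA/cm², capacitance fixed at 1 µF/cm², voltages in mV, time in ms.

## Membrane equation

For every neuron,

    C dV/dt = -I_L - I_Na - I_K - I_Ca - I_AHP + I_syn + I_inj

    I_L   = g_L (V - V_L)
    I_Na  = g_Na m³ h (V - V_Na)
    I_K   = g_K n⁴ (V - V_K)
    I_Ca  = g_Ca mCa∞(V) (V - V_Ca)
    I_AHP = g_AHP [Ca] (V - V_K)          (excitatory cells only)

with published constants

| symbol | value | notes |
|---|---|---|
| g_Le | 0.05 | excitatory leak |
| g_Li | 0.1 | inhibitory leak (2x -> membrane twice as fast) |
| g_Na | 100 | |
| g_K | 40 | |
| g_Ca | 0.9 | high-threshold calcium current |
| g_AHP | 0.05 | calcium-dependent K current, excitatory only |
| V_L | -65 | |
| V_Na | 55 | |
| V_K | -80 | |
| V_Ca | 120 | |
| tau_Ca | 100 ms | calcium decay |

## Gating kinetics

Regular-spiking cortical parameterization: Traub–Miles-type rate functions
with the sodium activation curve shifted +4 mV (required for a stable rest
near −65 mV at the small leak conductance above; without the shift the
sodium window current makes the cell fire spontaneously).

    alpha_m = 0.32 (V + 50) / (1 - exp(-(V + 50)/4))
    beta_m  = 0.28 (V + 23) / (exp((V + 23)/5) - 1)
    alpha_h = 0.128 exp(-(V + 50)/18)
    beta_h  = 4 / (1 + exp(-(V + 27)/5))
    alpha_n = 0.032 (V + 52) / (1 - exp(-(V + 52)/5))
    beta_n  = 0.5 exp(-(V + 57)/40)

Calcium-current activation (instantaneous):

    mCa∞(V) = 1 / (1 + exp(-(V + 10)/5))

Intracellular calcium follows the calcium current:

    d[Ca]/dt = -gamma I_Ca - [Ca]/tau_Ca,   gamma = 0.002

With these kinetics the excitatory cell rests at −64.79 mV, fires tonically
with spike-frequency adaptation (monotonically lengthening inter-spike
intervals via I_AHP); the inhibitory cell rests at −64.90 mV and fires at
constant inter-spike intervals.

## Synapses

First-order gating: ds/dt = −s/tau, s += 1 on each presynaptic spike;
tau_AMPA = tau_GABAa = 2 ms.  Currents are I = −g s f (V − E) with
E_AMPA = 0, E_GABAa = −80 (the printed magnitude 80 interpreted with the
physiological sign), and depression factors f fixed at 1.

## Plasticity

    Feedforward (Hebbian):   dW_ij/dt = (eta_H / tau_Hebb) [Ca]_j^V1 [Ca]_i^V2,  tau_Hebb = 100 ms
    Feedback (homeostatic):  dw_i/dt  = (eta_F / tau_FB) ([Ca]_i^V2 - Ca0),      tau_FB  = 500 ms

Both are clipped to [0, ceiling]; the feedback rule is gated by presynaptic
calcium (silent layer-two cells keep their naive weight).  Ca0 is the
time-averaged calcium of the stimulus-activated layer-two subset during one
pre-training baseline presentation, then frozen.
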