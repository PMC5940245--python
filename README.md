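# slowswitch

Conductance-based excitatory–inhibitory network model with a **switchable
slow negative conductance** — and the experiment battery that shows why it
matters.

## The problem

Brain states switch fast and reliably between an *active* regime
(asynchronous spiking, flat mean field) and an *oscillatory* regime
(synchronized slow rhythms), even though the underlying populations are
heterogeneous down to every cell and synapse. This package models the
cellular mechanism that makes such network switches robust: the **slow
activation of T-type calcium channels**, which endows each neuron with a
slow negative conductance that hyperpolarization turns on and depolarization
turns off. The mechanism is tested by ablation — an otherwise identical
model in which T-type activation is instantaneous shares every steady state
but loses the switch completely.

It is aimed at computational neuroscientists who want to reproduce, ablate,
or build on this mechanism: every figure-level experiment is a library call
returning tidy tables, and every parameter of the model is exposed.

## The model

Single-compartment neurons,

```
C_m dV/dt = −(I_leak + I_Na + I_Kd + I_CaT + I_KCa + I_H) − I_syn + I_app
d[Ca]/dt  = −k1·I_CaT − k2·[Ca]
```

with Boltzmann gating `x_∞(V) = 1/(1+exp((V−V_half)/V_slope))`,
`τ_x(V) = A − B/(1+exp((V−D)/E))`, and the T-type current
`I_CaT = ḡ_CaT · m_CaT³ h_CaT · (V − V_Ca)` whose activation variable is
either dynamical (*slow* mode) or evaluated as `m_CaT,∞(V)` and removed from
the state (*instantaneous* mode). Networks are bipartite E–I motifs: AMPA
from E to I, kinetic GABA_A and GABA_B from I to E, all-to-all with weak
random weights, no intra-population connections; GABA_B is ~50× slower than
GABA_A. Every maximal conductance is drawn uniformly from its physiological
range, so no two cells are alike. See `docs/methods.md` for the full
parameter tables and every numerical choice.

## Worked example

`python examples/two_cell_switch.py` — the reference two-cell circuit under
the canonical protocol (2.5 s spontaneous activity, 6 s of −2.6 µA/cm²
applied to the inhibitory cell, release):

```
T-type activation: slow
  pre    : tonic_spiking
  during : bursting_sync
  post   : tonic_spiking
  switched: True
  rhythm : period 214 ms, 3.5 spikes/burst, intraburst 66 Hz, duty cycle 0.16

T-type activation: instantaneous
  pre    : tonic_spiking
  during : tonic_spiking
  post   : tonic_spiking
  switched: False
```

The slow model switches from tonic spiking into a ~5 Hz alternating E–I
rebound rhythm (bursting period 214 ms) whose intraburst frequency (66 Hz)
far exceeds the tonic rate, and reverts on release; the instantaneous model
— same parameters, same steady states — never leaves the tonic regime.

Other examples, one per capability (each prints its own interpretation):

| script | what it shows |
|---|---|
| `examples/ensemble_robustness.py` | 56/60 random circuits switch; 0/60 without slow activation |
| `examples/neuromodulation_robustness.py` | 11/11 neuromodulated circuits keep the switch, each with a retuned rhythm |
| `examples/voltage_clamp_signature.py` | two inward-current phases from −90 mV holding, one from −60 |
| `examples/single_cell_modes.py` | PIR survives the kinetics ablation, rebound bursting does not |
| `examples/mean_field_scaling.py` | LFP peak-frequency spread shrinks as networks grow 10 → 40 cells |
| `examples/pathway_control.py` | clustered GABA_B makes the switch spatially addressable |
| `examples/transfer_modes.py` | GABA_A:GABA_B ratio turns E cells from relays into detectors |

A thin CLI wraps the same calls: `slowswitch simulate --n-e 1 --n-i 1
--seed 3` or `slowswitch run ensemble_switch --n 200 --out out/`.

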