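# Methods

## The model

`slowswitch` simulates bipartite excitatory–inhibitory (E–I) networks of
single-compartment conductance-based neurons and asks one question of them:
what lets a global hyperpolarizing input switch the whole population between
an *active* state (asynchronous tonic spiking, flat mean field) and an
*oscillatory* state (synchronized rebound bursting, a marked slow LFP band) —
robustly, across widely heterogeneous cells and synapses?

The answer the model embodies: a **switchable slow negative conductance**
supplied by the slow activation of T-type calcium channels. Hyperpolarization
deinactivates the channels and moves the cell into a slow excitability mode
prone to bursting; depolarization turns that mode off. Because the mechanism
is cellular and shared by the whole population, the network state can be
switched without touching connectivity — and because it is only a *switch*,
every other conductance remains free to *tune* the rhythm, which is what
makes the mechanism compatible with heterogeneity, neuromodulation and
plasticity.

### Membrane equation

Each cell follows

```
C_m dV/dt = −(I_leak + I_Na + I_Kd + I_CaT + I_KCa + I_H) − I_syn + I_app
```

with six currents (conductances in mS/cm², potentials in mV, time in ms):

| current | form | reversal |
|---|---|---|
| leak | g_leak (V − V_leak) | −59 |
| transient Na | g_Na m_Na³ h_Na (V − V_Na) | +50 |
| delayed-rectifier K | g_Kd m_Kd⁴ (V − V_K) | −85 |
| T-type Ca | g_CaT m_CaT³ h_CaT (V − V_Ca) | +120 |
| Ca-activated K | g_KCa m_KCa([Ca]) (V − V_K) | −85 |
| H-current | g_H m_H (V − V_H) | −20 |

Gating variables relax as `τ_x(V) dx/dt = x_∞(V) − x` with Boltzmann steady
states `x_∞ = 1/(1+exp((V−V_half)/V_slope))` and sigmoid time constants
`τ_x = A − B/(1+exp((V−D)/E))`; the constants ship as packaged data
(`slowswitch/data/gating_table.json`). The Na inactivation time constant uses
the dedicated bell-shaped product
`τ_hNa = 0.67/(1+exp(−(V+62.9)/10)) · (1.5 + 1/(1+exp((V+34.9)/3.6)))`,
the standard reading of this Traub-style expression: positive, bounded, and
with the correct high- and low-voltage limits.

Calcium dynamics: `d[Ca]/dt = −k1·I_CaT − k2·[Ca]` — the T current is
negative when inward, so influx raises [Ca]; [Ca] is clamped at zero from
below to absorb solver undershoot. The K–Ca activation is
`m_KCa = ([Ca]/([Ca]+K_D))²`.

Two deliberate readings of ambiguous definitions, both exposed as options:

* **I_KCa driving force.** A calcium-activated *potassium* current must
  reverse at V_K; the variant with a +120 mV (calcium) reversal would be
  depolarizing and non-physiological. The package defaults to V_K and keeps
  the other variant behind `NeuronParams(kca_reversal="VCa")`.
* **Leak conductance range.** The leak is sampled from a tight ±10 % band,
  g_leak ∈ [0.0475, 0.0575] mS/cm². A weak leak is structurally necessary
  for everything this model does: it lets cells fire tonically at I_app = 0
  (the documented baseline state — no ad-hoc depolarizing drive is needed),
  and it lets the slow T-type negative conductance (≈0.2 mS/cm² near −70 mV)
  dominate the passive conductance so that hyperpolarized cells enter the
  bursting-prone slow mode. With a leak an order of magnitude larger, cells
  rest silent, hyperpolarized cells sit at a stable equilibrium, and no
  circuit switches — the phenomenology collapses. The band's ±10 % width
  matches the style of the H-conductance band.

### The kinetics ablation

The control model differs in exactly one respect: T-type activation is
instantaneous, `I_CaT = g_CaT m_CaT,∞(V)³ h_CaT (V−V_Ca)`, and m_CaT leaves
the state vector (it is *not* simulated with a tiny time constant, which
would only add stiffness without changing the point). The ablation preserves
every steady state — both models share the same I/V curve, verified to 1e−9
relative — and destroys only the slow dynamics. That makes it a clean test
that the network switch is a *dynamical* consequence of slow activation.

### Synapses

Each presynaptic cell carries one gating variable per receptor type,
`ds/dt = α·T_m(V_pre)(1−s) − β·s`, driven by the release sigmoid
`T_m = 1/(1+exp(−(V_pre−2)/5))`. Rates (ms⁻¹) and reversals: AMPA
(1.1, 0.19, 0 mV), GABA_A (0.53, 0.19, −70 mV), GABA_B (0.016, 0.0047,
−85 mV) — GABA_B is the slow integrator, roughly fifty-fold slower than
GABA_A. Topology is bipartite and all-to-all: E→I carries AMPA, I→E carries
GABA_A and GABA_B, no intra-population connections. The postsynaptic current
into cell i is `Σ_j w_ij s_j (V_i − E_rev)`, outward positive.

### Randomization — the synthetic study conditions

`sample_neuron_params` draws every maximal conductance and both Ca rates
uniformly from their physiological ranges (g_Na ∈ [135, 205],
g_Kd ∈ [20, 60], g_CaT ∈ [0.375, 0.725], g_KCa ∈ [3, 5],
g_H ∈ [0.0095, 0.0105] mS/cm²; k1 ∈ [0.075, 0.125], k2 ∈ [0.0075, 0.0125]);
synaptic weights are drawn per connection from ±1/8 around their central
value. E and I cells share the same intrinsic ranges — only their synapses
differ. A master seed is split into per-circuit substreams
(`numpy.random.SeedSequence.spawn`), so ensembles are reproducible and any
member can be rebuilt in isolation.

This generator emulates the biological situation the model targets —
populations whose every cell and synapse is quantitatively different — and
nothing more. It does not emulate channel noise, synaptic failure,
conduction delays, or structured topology; passing ensemble tests therefore
demonstrates robustness to *parametric* heterogeneity, not to stochastic
dynamics.

### Calibrated values

Three quantities the model description leaves open were calibrated **once**
against the reference phenomenology (the two-cell switch) and then frozen;
they are ordinary package defaults, marked implementation-chosen:

* `K_D_ca = 250 µM` — K–Ca half-activation. Much lower values make the AHP
  so strong that cells burst spontaneously in the active state; much higher
  values remove burst termination.
* Central synaptic conductances `AMPA 0.15, GABA_A 2.5, GABA_B 0.8 mS/cm²`,
  expressed as the *total* incoming conductance per postsynaptic cell and
  divided by the presynaptic count per connection, so aggregate drive is
  independent of network size. The GABA_A-dominant ratio (≈3:1) is the
  reference ("high-ratio") regime: tonic inhibitory firing holds E cells
  just below threshold without pushing them into the slow mode.
* The five-level applied-current grid {−1.0, −1.8, −2.6, −3.4, −4.2}
  µA/cm², spanning the reference level −2.6.

### The switch mechanism, concretely

In the active state every cell is intrinsically tonic; I cells fire and
their sustained GABA holds E cells mostly silent. The hyperpolarizing step
(−2.6 µA/cm² onto I cells only) silences the I cells and deinactivates
their T channels; as their GABA_B decays (~200 ms), the E cells —
themselves primed by the inhibition they were under — escape and fire a
rebound burst; the AMPA volley lands on primed I cells and triggers a
T-type burst; its GABA pulse re-primes the E cells. The result is an
alternating (anti-phase) E–I rebound rhythm at 2–8 Hz that terminates the
moment the step ends. With instantaneous T activation the I cells simply
follow their input and the loop never ignites.

## Numerics

* **Integration.** Exponential Euler for gating variables *and* for V in
  conductance form: every ionic and synaptic term is a conductance times a
  driving force, so for frozen gating the membrane equation is linear in V
  and admits an exact exponential step. This matters: during the spike
  upstroke the total membrane conductance exceeds 2/dt for any practical dt
  (g_Na alone reaches ~40 mS/cm²), so plain forward Euler diverges. Ca and
  synaptic s use forward Euler (their rates are far below 1/dt). Default
  dt = 0.05 ms, validated by a convergence test under dt halving (spike
  counts within 5 %, first-spike times within 1 ms, mean rates within 2 %;
  pointwise late-spike times in the coupled rebound rhythm are
  trajectory-sensitive and are not a convergence criterion).
* **Initial conditions.** V₀ = −60 mV (or the clamp/hold value), gating at
  x_∞(V₀), Ca at its fixed point; a 500 ms settle period precedes every
  analysis window, and the first second of the during-epoch is excluded as
  rhythm ignition transient.
* **Guards.** |V| > 200 mV marks a batch member as blown up (NaN-poisoned,
  reported, not fatal to the batch). Exponential-Euler gating is confined to
  [0, 1] by construction and Ca is clamped at 0; both bounds are tracked at
  runtime and reported in `SimulationResult.meta`.
* **Vectorization.** A batch of B same-topology networks advances as (B, N)
  arrays; 1000 two-cell circuits integrate in one pass (~2 min for the full
  switch protocol on one core). Batch results are bit-identical to
  sequential runs.

## Analysis definitions

* **Spikes**: upward crossings of 0 mV with a 1 ms lockout (model spikes
  overshoot +20 mV; any threshold in [−20, +10] gives the same trains).
* **Bursts**: ISI-threshold segmentation — intra-burst ISI < 60 ms, flanking
  gaps > 120 ms, ≥ 2 spikes. The wide separation between intraburst
  intervals (tens of ms) and burst periods (hundreds of ms) makes the
  defaults insensitive. Rebound-burst *detection in the release protocol*
  uses a 15 ms intra-burst threshold instead: a genuine T-type rebound burst
  is a high-frequency cluster, and the instantaneous model's decelerating
  fast-tonic rebound (ISIs ≥ 17 ms) must not be mistaken for one.
* **Rhythm metrics**: PER = mean burst-onset interval; SPB = mean spikes per
  burst; IBF = mean (SPB−1)/duration; DC = mean duration/PER.
* **Cell labels**: silent; slow_spiking (< 5 Hz, no bursts); tonic_spiking;
  bursting (≥ 2 bursts in the window).
* **Circuit label, two-cell**: `bursting_sync` requires bursting cells on
  both sides with period ratio in (2/3, 3/2) **and** a stable relative phase
  of burst onsets, measured as circular concentration R ≥ 0.7 of the E→I
  onset lags. The rebound rhythm locks anti-phase (lag ≈ half a period), so
  lag *consistency*, not onset coincidence, is the right test; distance
  thresholds misclassify cleanly locked rhythms whose lag sits exactly at
  the tolerance.
* **Network state**: for populations beyond a few cells the cellular rhythms
  are deliberately heterogeneous and pairwise phase tests are meaningless;
  the network state is a mean-field property. A network counts as
  oscillatory when its slow-band (1–20 Hz) LFP power is ≥ 10× the
  active-state level (`lfp.is_oscillatory`).
* **Switch**: pre-epoch label ∈ {tonic_spiking, spiking_slowly} and
  during-epoch label = bursting_sync.

## LFP and spectra

The LFP of a population is the sum of postsynaptic currents into its cells
divided by the cell count — 1/N normalization is what makes the mean field
converge with size — sampled at F_s = 1 kHz and low-pass filtered at 100 Hz
with a 4th-order Butterworth filter, applied forward–backward (zero phase)
so LFP features stay aligned with spike times. Spectrograms are Hann-tapered
STFTs (1024 ms windows, 90 % overlap, log₁₀ power); peak frequency is the
argmax of the periodogram with the DC bin excluded.

## Spatial clustering

Clustered receptors get the Gaussian profile
`exp(−(x_j − x_i)²/(2c²))` with positions in **cell-index units** and
c = 0.8, then each postsynaptic row is renormalized to its unclustered
total. Index units are the only reading under which spatial control works
at all: normalized to the array length, c = 0.8 blurs the profile across
the entire population and one modulated pathway perturbs every cluster
equally. With index units each cell's strong GABA_B inputs come from its
~2 nearest neighbours, and hyperpolarizing one pathway switches exactly the
corresponding E cluster. Spatial control additionally requires the clustered
receptor to carry the dominant inhibition, so the clustered layout defaults
to the GABA_B-dominant configuration {GABA_A 0.5, GABA_B 1.6}; with
GABA_A-dominant weights the unclustered GABA_A from non-modulated pathways
keeps every E cell silent and no cluster can ignite.

## Problem sizes

The test suite runs the ensembles at desk scale: 400 slow-mode and 200
instantaneous-mode circuits (acceptance bands widened by twice the binomial
standard error, which keeps the checks equivalent to the full-size bounds),
20 networks per size for the mean-field shrinkage test, and single networks
for the pathway and transfer experiments. `scripts/acceptance.py` runs the
full 1000-circuit ensemble.

## Limitations

* Single-compartment cells; no morphology, temperature dependence or channel
  noise. Ca concentration is in internal units fixed only through k1, k2.
* The burst segmentation thresholds and the synchrony criterion are
  explicit, documented choices; ensemble counts carry a (small) classifier
  dependence, which is why they are compared with tolerance.
* The fixed-step integrator trades pointwise late-time accuracy in chaotic
  rhythms for speed and determinism; all reported statistics are
  rate/label-level observables that converge under dt refinement.
* Epoch durations (2.5 s pre, 6 s during) are long enough for ≥ 10 burst
  cycles, not for asymptotic statistics; lengthening them sharpens labels
  slightly but does not move the ensemble fractions beyond their sampling
  noise.
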