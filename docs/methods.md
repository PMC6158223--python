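# Methods

This note records the modelling choices behind `nemasim`: the equations,
the units, the provenance of every default constant, the numerical scheme,
and what the built-in tests do and do not demonstrate.

## Units

All quantities use one self-consistent system: mV, ms, nS, pA, pF, µM.
Because nS·mV = pA and pA/pF = mV/ms, no conversion factors appear in any
equation; parameter files and CSV/JSON outputs are in these units too.

## Cell models

**LIF (levels A, B).** `C_m dV/dt = -g_leak (V - E_leak) + I_total`, with
threshold-and-reset spiking and an absolute refractory period during which
the membrane is clamped at `V_reset`. Level B adds a per-cell activity
variable `a` (decay constant `tau_activity`, increment per spike) as a
low-pass proxy of firing rate. It is a *readout only*: it does not feed
back on the dynamics. That choice was genuinely open — an activity variable
could plausibly gate adaptation currents — and the readout interpretation
is the most conservative one; anything stronger would have invented
physiology.

**Conductance-based (levels C, C1).** Single compartments with

```
C_m dV/dt = -g_leak (V - E_leak) - Σ_c gbar_c a_c^p h_c (V - E_c) + I_total
dx/dt     = (x_inf(V) - x) / tau_x,   x_inf(V) = 1 / (1 + exp((V_half - V)/k))
d[Ca]/dt  = -rho * I_Ca - [Ca] / tau_Ca
```

Gates use Boltzmann steady states with *voltage-independent* time
constants — the simplest form of the Hodgkin–Huxley formalism that still
has closed-form relaxation solutions to test against. Outward current is
positive; `I_Ca` is the summed current of calcium-carrying channels, so
inward calcium current raises the pool. The pool is linear (no buffering or
saturation). Muscles carry three channels — fast K⁺ (activation exponent 4,
inactivating), slow K⁺, and an inactivating Ca²⁺ current (the calcium
carrier) — the current complement known from voltage-clamp work on the
body-wall muscle. Spikes in conductance cells are *detected* (upward
crossing of a threshold, default −20 mV, with a 1 ms minimum inter-event
interval) rather than imposed; detection matters only where level C uses
spike-triggered synapses.

## Synapse models

**Spike-triggered** (levels A–C): conductance `g` jumps by the connection
weight at each presynaptic spike and decays with `tau_decay` (single
exponential); `I = g (E_syn - V_post)`.

**Graded/analogue** (level C1): transmission is a sigmoid of presynaptic
voltage with first-order kinetics, in the style of the stomatogastric
pyloric-network models:

```
s_inf = 1 / (1 + exp((V_th_pre - V_pre)/delta)),  ds/dt = (s_inf - s)/tau_s
I = w s (E_syn - V_post)
```

`tau_s` is constant. The source models scale the timescale by
`(1 - s_inf)`, which makes release faster than recovery; the constant
form was chosen deliberately because it has an exact exponential solution,
and the asymmetry is not needed for any behaviour modelled here.

**Gap junctions**: ohmic, `I_into_a = w (V_b - V_a)`, charge-conserving by
construction. Under level A every connection — gap junctions included — is
represented as a spike-triggered excitatory synapse; the conductance is
carried over unchanged (identity mapping, one synapse per direction), since
no principled conversion factor exists between a coupling conductance and a
synaptic weight at that level of abstraction.

Defaults: excitatory `E_syn = 0 mV`, inhibitory `E_syn = -70 mV`, both
overridable per parameter set. All synaptic and gap currents are computed
as currents *into* the postsynaptic cell, depolarising positive.

## Weight and polarity rules

Chemical weight = per-contact baseline conductance × anatomical contact
count (default baseline 0.01 nS for both chemical and electrical
connections). Polarity: inhibitory iff the presynaptic neurotransmitter is
GABA (case-insensitive), excitatory otherwise including unknown. This is a
first approximation — it ignores receptor identity, so e.g. glutamatergic
inhibition through GluCl channels is misclassified by design.

## Parameter provenance

The shipped level defaults (JSON files under `nemasim/data/parameters/`)
are *model* constants, not measurements. Membrane scales (pF-range
capacitances, 10–100 ms membrane time constants, −60 mV rest) are in the
physiological range for *C. elegans* neurons and muscles. The channel
half-activations and conductance densities at levels C/C1 were set so that

- neurons behave as excitable relay units: a low-threshold inactivating
  Ca²⁺ current (ignition near −40 mV) regenerates chain activity, a slow
  K⁺ current adapts it, and Ca²⁺ inactivation self-terminates plateaus;
- muscles are quiescent at rest but fire a regenerative calcium response
  once synaptic drive exceeds a few pA, with the fast/slow K⁺ currents
  shaping repolarisation.

The initial state places every cell at `E_leak` with gates at their
steady state for that voltage. For the shipped channel sets a small
fraction of the slow K⁺ conductance is open at −60 mV, so cells settle
within ~1 mV of `E_leak` over the first tens of ms; the equilibrium-start
property (no drift at all) holds exactly for passive configurations.

## The forward-locomotion circuit

Cell complement: AVBL/AVBR, DB1–DB7, VB1–VB11, DD1–DD6, VD1–VD13, and 96
muscles (MDL/MDR/MVL/MVR 01–24). Class-level connectivity: AVB gap
junctions onto every B neuron; chain gap junctions between consecutive B
neurons; B → ipsilateral-side muscles excitatory, D → muscles inhibitory;
DB → VD excitatory, DB → DD inhibitory, VB → DD excitatory, VB → VD
inhibitory; all wired connections share one uniform weight. Proprioception
is a static feed-forward graded excitation DBi → DBi+1 and VBi → VBi+1 —
a deliberate stand-in for stretch-receptor signalling, not a mechanics
model.

**Innervation fixture.** The real neuron→muscle table is not publicly
deposited, so the default map is synthetic: each motor-neuron class covers
muscle indices 8–24 with contiguous, anatomically ordered blocks
(consecutive neurons share one boundary muscle; dorsal neurons project to
both dorsal rows, ventral to both ventral rows). MVL24 is excluded, so
exactly 95 of the 96 muscles receive input and MVL24 stays silent. Head
muscles (indices 1–7 of each quadrant) receive direct synchronized current
pulses because their presynaptic neurons are outside the circuit. A real
innervation table can be supplied as a two-column CSV (neuron, muscle).

**Drive constants.** None of the stimulation amplitudes, the uniform
weight, the proprioceptive gain or the drive period is reported in the
literature for this reduced circuit; they are package defaults, chosen
once so that the default 5 s run expresses the qualitative pattern the
circuit is meant to produce — a head-to-tail calcium wave in all four
quadrants at the drive frequency, near-synchronous dorsal left/right
activation, and dorsoventral alternation — and documented here as
non-literature values. Defaults: CPG period 1250 ms (four body waves in
5 s, ~0.8 Hz), pulse width 300 ms, 25 pA into DB1/VB1 with the ventral
pulse delayed by half a period, 5 pA tonic into AVB, 20 pA head-muscle
pulses, uniform weight 0.1 nS, proprioceptive gain 0.7 nS.

Two mechanisms had to be balanced here, and the balance is worth recording.
AVB's gap junctions couple the two antiphase B chains through a common hub,
so any regenerative excitability in the *neurons* must ignite above the
voltage to which hub coupling can drag an off-phase chain (about −50 mV)
and below the voltage that proprioceptive drive produces (about −30 mV);
the neuron Ca²⁺ ignition threshold sits between them. Muscles face the
analogous discrimination between off-phase synaptic crosstalk (~1 pA) and
on-phase block drive (~5 pA), which the sharper muscle Ca²⁺ activation
(k = 3 mV) provides.

## Wave analysis

Activation events are local maxima of muscle [Ca²⁺] after a settle period
(default one drive period), with prominence at least 20% of the trace
range; traces with range below 10⁻⁶ µM are reported as having no peaks
rather than yielding spurious maxima. Per quadrant, the propagation slope
is the least-squares slope of first post-settle peak time against muscle
index — positive means head-to-tail. Frequency is 1000 / median inter-peak
interval (ms) of a reference muscle (the midpoint of the first quadrant
list). Phase relations are circular means of per-index first-peak offsets
between paired quadrants, reported as fractions of a period in [0, 1);
for "synchrony" comparisons the distance to the nearer of 0 and 1 is the
meaningful quantity.

## Numerical scheme

Forward Euler throughout, fixed step (default 0.05 ms), synchronous
(Jacobi-style) update: all synaptic, gap and stimulus currents are
evaluated from the previous step's state, then every cell advances. Spike
events detected on one step increment spike-triggered conductances so
that their current first flows on the following step. Consequences:
results are independent of cell ordering and bit-reproducible, coupling
has a one-step latency, and convergence is first order in dt (halving dt
halves the error — verified numerically). Gate and synaptic gating
variables are clipped to [0, 1] after each step; the clip is inactive at
the default step for the shipped time constants (the smallest tau is
2 ms = 40 steps) and exists to keep pathological user parameters from
leaving the invariant domain. Non-finite membrane potentials abort the run
with the offending cell and time. The default step is stable for all
shipped time constants; exponential-Euler gate updates were considered and
rejected to keep a single, uniformly testable scheme.

Problem sizes used in the shipped verification runs: the locomotion
demonstration integrates 135 cells for 5 s at dt = 0.05 ms (100 000
steps, ~10 s wall time); closed-form checks use single cells or pairs for
100–500 ms; structural oracles use 20 seeded synthetic connectomes of ~50
cells.

## Synthetic connectomes

The generator emulates the statistical texture of the real wiring —
Bernoulli connectivity, geometric contact counts (minimum 1, mean ~3), a
GABAergic subpopulation, muscles strictly postsynaptic — and is fully
reproducible per seed. It does **not** reproduce the real network's
degree distribution, spatial organisation, left/right symmetry or
class-specific wiring motifs. Tests that pass on synthetic connectomes
therefore validate the *machinery* (parsing, subsetting, weight
resolution, simulation) on realistic input shapes; they say nothing about
the behaviour of the real connectome beyond the locomotion circuit, whose
wiring is constructed explicitly.

## Known limitations

- Polarity by the GABA rule only; no receptor-level annotation.
- Constant gate and synapse time constants; no kinetic-scheme channels;
  no plastic (activity-dependent) synapses.
- Single compartments only; no morphologies, no cable effects.
- The NeuroML export is structural (populations, projections with weights,
  inputs); it does not emit executable dynamics definitions, and periodic
  pulse trains use a `period`/`number` attribute extension on
  `pulseGenerator`.
- The locomotion circuit's drive constants are calibrated to the
  qualitative target pattern, not fitted to recordings; the wave's
  quantitative speed and phase values should be read as model properties,
  not predictions.
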