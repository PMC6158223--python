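# nemasim

Connectome-driven modelling of the *Caenorhabditis elegans* nervous system:
generate neural-circuit models from wiring diagrams at selectable levels of
biophysical detail, simulate them with a built-in deterministic integrator,
and analyse the traveling-wave muscle activity of a forward-locomotion
circuit.

## Who this is for

*C. elegans* is the only animal with a fully mapped nervous system: 302
neurons whose chemical synapses and gap junctions are catalogued cell by
cell. That makes it the natural testbed for the question *how much
biophysical detail does a network model need before it reproduces
behaviour?* `nemasim` is built for researchers who want to ask that question
quantitatively: the same wiring diagram can be instantiated as a network of
leaky integrate-and-fire points or of conductance-based cells with calcium
dynamics and graded synapses, and the two can be compared on identical
stimulation protocols.

## The model

**Wiring.** A `Connectome` holds cells plus chemical and electrical
connection lists with anatomical contact counts, read from CSV wiring tables
in either of the two public spreadsheet layouts (Varshney/WormAtlas or
WormWiring), or produced by a seeded synthetic generator. Two rules turn
anatomy into physiology:

- polarity: a connection is **inhibitory iff the presynaptic
  neurotransmitter is GABA**, excitatory otherwise (unknown included);
- weight: synaptic conductance `g = n_contacts x g_baseline`, so at the
  default 0.01 nS baseline a 13-contact pair carries 0.13 nS and a
  single-contact pair 0.01 nS. Individual weights can be overridden.

**Detail levels.** A `ParameterSet` (shipped as versioned JSON) fixes one of
four levels:

| level | cells | chemical synapses | gap junctions |
|-------|-------|-------------------|----------------|
| A | LIF | spike-triggered (all connections) | converted to excitatory synapses |
| B | LIF + firing-rate proxy | spike-triggered | electrical |
| C | conductance-based | spike-triggered | electrical |
| C1 | conductance-based | graded (analogue) | electrical |

Conductance-based cells are single compartments in the Hodgkin–Huxley
formalism with Boltzmann steady-state gates `x_inf(V) = 1/(1 +
exp((V_half - V)/k))`, fixed gate time constants, and a linear intracellular
calcium pool `d[Ca]/dt = -rho * I_Ca - [Ca]/tau_Ca` fed by the
calcium-carrying channels. Muscles carry fast and slow K⁺ currents and an
inactivating Ca²⁺ current. Graded synapses transmit continuously as a
sigmoid of presynaptic voltage — the appropriate approximation for
*C. elegans*, whose neurons mostly signal without classical action
potentials: `ds/dt = (s_inf(V_pre) - s)/tau_s`,
`I = w s (E_syn - V_post)`.

**Simulation.** `simulate` integrates any built network with synchronous
forward Euler at a fixed step (default 0.05 ms), records voltage, calcium
and spike times, and is bit-reproducible. Network structure exports to a
NeuroML v2 structural subset (populations, projections, inputs) and to
diffable JSON.

**Locomotion demonstration.** `build_forward_locomotion` assembles the
classic forward-crawling circuit — AVB command interneurons, 18 B-type
(cholinergic, excitatory) and 19 D-type (GABAergic, inhibitory) motor
neurons, 96 body-wall muscles in four quadrants — driven by periodic
current pulses into DB1/VB1 standing in for a central pattern generator,
with feed-forward proprioceptive coupling along the B chains.
`wave_metrics` measures the resulting muscle-calcium pattern: head-to-tail
peak-time slope per quadrant, oscillation frequency, and dorsoventral and
left-right phase relations.

## Worked example

```python
import nemasim as ns

# weight rule: 13 anatomical contacts at the 0.01 nS per-contact baseline
print("13 contacts ->", ns.connection_weight(13, 0.01), "nS")

# build and run the forward-locomotion circuit for 5 s (level C1)
params = ns.ParameterSet.from_level("C1")
config = ns.LocomotionConfig()
net = ns.build_forward_locomotion(params, config)
print(f"{len(net.neuron_names)} neurons, {len(net.muscle_names)} muscles, "
      f"{len(net.synapses)} connections")

result = ns.simulate(net, ns.SimulationSpec(duration=5000, dt=0.05, record_every=10))
metrics = ns.wave_metrics(result, settle_time=config.cpg_period)
print(f"muscle wave frequency: {metrics.frequency:.2f} Hz")
print("head-to-tail slope (ms per muscle index):",
      {q: round(s, 1) for q, s in metrics.propagation_slope.items()})
print(f"dorsoventral phase: {metrics.dorsoventral_phase:.2f} of a period")
print(f"dorsal left-right phase: {metrics.left_right_phase:.2f}")
```

prints

```
13 contacts -> 0.13 nS
39 neurons, 96 muscles, 356 connections
muscle wave frequency: 0.80 Hz
head-to-tail slope (ms per muscle index): {'MDL': 14.8, 'MDR': 14.8, 'MVL': 19.1, 'MVR': 19.5}
dorsoventral phase: 0.52 of a period
dorsal left-right phase: 0.00
```

Read it as: the 5 s simulation expresses a calcium wave that travels from
head to tail in all four muscle quadrants (positive slope: each successive
muscle peaks ~15–20 ms later), the muscles oscillate at the 0.8 Hz drive
frequency, the two dorsal quadrants activate synchronously, and dorsal and
ventral sides alternate in antiphase — the activation pattern required to
push the worm forward.

The same pipelines are available from a shell:

```bash
nemasim generate --circuit locomotion --params C1 -o out/
nemasim simulate --circuit four-pair --params C --duration 1000 -o out/
nemasim analyze --results out/results.csv -o out/
```

## Scope

The package deliberately stops at single-compartment cells: no
multicompartmental morphologies, no export of executable LEMS dynamics (the
built-in simulator is the executable semantics), no body-mechanics
coupling, and no live access to online connectome databases — wiring comes
from local CSV files or the synthetic generator. See `docs/methods.md` for
the modelling assumptions and parameter provenance.
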