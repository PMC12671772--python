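# tmsplast

Multi-scale simulation of long-term synaptic plasticity induced by
repetitive magnetic stimulation (rMS) in a reduced CA1 pyramidal neuron.

Repetitive transcranial magnetic stimulation changes synaptic strength,
but which synapses change, and by how much, depends on where they sit on
the dendritic tree and on the temporal pattern of stimulation. This
package is for computational neuroscientists who want to simulate those
layer- and distance-resolved effects in a single biophysical cell: it
couples a compartmental CA1 pyramidal-cell model (Hodgkin–Huxley channels,
myelinated axon) to uniform-field extracellular stimulation and to a
four-pathway voltage-dependent plasticity rule on 128 excitatory synapses,
and provides the stimulation protocols (pulse trains, theta-burst,
local electrical afferent stimulation, pre/post pairing), in-silico
pharmacology, and distance-profile analyses used to study them.

## The model in brief

* **Cable model.** Reduced CA1 morphology (soma, tapered apical trunk with
  three obliques and a two-branch tuft, two basal subtrees, myelinated
  axon with 5 nodes of Ranvier). Implicit Crank–Nicolson integration on
  the tree (Hines solver), dt = 0.025 ms, compiled with numba.
* **Field coupling.** Each compartment receives the quasipotential
  `Ve = −E·r` of a uniform field **E**, scaled by the pulse waveform
  s(t); the field drives axial currents through differences of (v + Ve).
* **Plasticity.** Synaptic weight is the product `w_pre · w_post`.
  Postsynaptic LTP/LTD follow a calcium-like signal
  `C ← C_gain · sat(G) · rect(u − θuC)` (NMDA-trace G, local voltage u,
  thresholds θC± = 8.0/8.2) integrated with τ_C = 120 ms; presynaptic LTD
  follows a low-pass depolarisation trace T at each release; presynaptic
  LTP is a slow chain (Nα → Nβ → X → K) that engages only for sustained
  (burst-like) depolarisation. See `docs/methods.md` for the equations,
  defaults and calibration.

## Worked example

A scaled 10 Hz rMS session (90 pulses at 275 V/m, monophasic, all-synapse
co-activation delayed 1 ms, 3 Hz Poisson background):

```
$ tmsplast run-protocol --frequency 10 --n-pulses 90 --seed 0
{
  "all": 0.989,
  "schaffer": 1.055,
  "proximal_sr": 2.877,
  "distal_sr": -0.0,
  "oriens": -0.0,
  "radiatum": 1.734,
  "tuft": -0.0
}
```

The numbers are mean percentage changes of effective synaptic weight per
group after the 90 pulses: proximal stratum-radiatum synapses potentiate
(+2.9% here, i.e. ≈ +29% when extrapolated to the full 900-pulse
protocol), distal radiatum and tuft synapses do not change, and the
Schaffer-collateral mean (+1.1%) is diluted by the unchanged distal and
basal groups. Outcomes vary substantially between synapse placements;
the headline quantities below average over a fixed set of four seeded
placements.

The same entry points are available as library calls:

```python
from tmsplast import build_model, standard_protocol, SimConfig

model = build_model(placement_seed=0)
proto = standard_protocol("rms_train", frequency=10.0, n_pulses=90)
result = model.run(proto, SimConfig(settle_time=1000.0))
print(result.percent_change().mean())
```

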