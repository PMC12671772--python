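# Methods

## The model

`tmsplast` simulates long-term plasticity of excitatory synapses on a
reduced CA1 pyramidal neuron driven by repetitive magnetic stimulation
(rMS) and by classical electrical afferent stimulation. Three coupled
components make up the model.

**Compartmental cell.** The morphology is a reduced CA1 pyramidal cell:
a 20 µm soma; a 400 µm apical trunk (tapering 4 → 2 µm) carrying three
oblique branches at 100/200/300 µm and two tuft branches beyond 400 µm;
two basal subtrees (150 µm primary, two 200 µm children each); and a
myelinated axon (30 µm initial segment, six 60 µm internodes alternating
with five 1 µm nodes of Ranvier, 30 µm unmyelinated terminal). Section
dimensions are package defaults (the reference morphology prints only the
topology and relative diameters) and are configurable in
`morphology.GeometryConfig`. Layers follow labels: basal → stratum oriens,
trunk + obliques → stratum radiatum, tuft → stratum lacunosum-moleculare.

Membrane biophysics follow a fixed region × channel conductance table
(Na, K_A, KDR, K_M, two Ca-gated K, Ca_T/L/N, Ih, leak) with three
distance-dependent rules: Ih grows linearly with somatic distance,
dendritic K_A rises sigmoidally beyond ~300 µm, and the leak reversal
hyperpolarises distally (−65.73 − 5d/150 mV). Channel *kinetics* are not
part of that table; they are Hodgkin–Huxley-style sigmoidal steady states
with bell-shaped time constants, collected in `membrane.KineticsConfig`
and calibrated against behavioural anchors (below). Axonal compartments
use a fast-repolarising kinetics variant (fast KDR, fast Na recovery) so
the axon can follow high-frequency trains while the somatodendritic
membrane repolarises slowly; axonal Na activation is left-shifted
(Nav1.6-like) and basal-dendrite Na activation right-shifted (no local
regeneration in the basal tree — back-propagating spikes are decremental
there).

**Field coupling.** A magnetic pulse is a uniform field E with a short
waveform s(t); every compartment receives the quasipotential
Ve = −E·r (coordinates at compartment centres), scaled by amplitude×s(t).
Only spatial differences of Ve enter the cable equation (through axial
currents on v+Ve), so uniform offsets are electrically silent. The default
monophasic pulse is a damped half-sine of 0.2 ms; the biphasic pulse is a
0.15 ms positive lobe followed by a 0.3 ms equal-area negative lobe.

**Plastic synapses.** 128 excitatory synapses (AMPA/NMDA, weight =
w_pre·w_post) and 18 non-plastic inhibitory synapses (double exponential,
E = −75 mV) are placed across the layers in the proportions 47/73/8
(oriens/radiatum/SLM; inhibitory 2/5/8/3 with a perisomatic group).
Within a layer, placement is stratified: per-section counts follow
membrane-area shares, positions are uniform in arc. Initial weights use a
uniform multiplier m ∈ [0.22, 0.44] applied to the default factors 0.5
(pre) and 2.0 (post); the weight draw is independent of placement so the
total input is identical across placements.

Four pathways change the weights continuously as a function of the local
membrane potential u (all constants in `synapses.PlasticSynapseParams`):

* Postsynaptic LTP/LTD are driven by C, a calcium-like proxy that relaxes
  (τ_C = 120 ms) toward `C_gain · sat(G) · rect(u − θuC)`, where G tracks
  recent presynaptic release with NMDA kinetics (2/50 ms). LTP engages for
  C > θC+ (8.2), LTD for C > θC− (8.0) gated by the release trace Z.
  Because C integrates over ~120 ms, isolated pulses (1 Hz) leave it below
  threshold while 10–20 Hz trains accumulate it past threshold — this is
  the source of the frequency dependence of the postsynaptic pathways.
* Presynaptic LTD subtracts A_pre−·T at each release, with T a low-pass
  (10 ms) of depolarisation above −60 mV.
* Presynaptic LTP integrates a slow chain Nα → Nβ → X → Kα → Kβ → Kγ that
  only engages for sustained depolarisation of ≳15–40 ms (theta bursts,
  postsynaptic spike bursts, ≥15 Hz trains with residual Nβ); isolated
  spikes never cross the X threshold.

Weights are clipped to hard bounds (w_pre ∈ [0,1], w_post ∈ [0,4]).

## Numerical scheme

The tree is discretised into ≤20 µm compartments; axial conductances use
the cylindrical formula on half-compartment resistances. Voltages advance
by an implicit θ-scheme (Crank–Nicolson default, backward Euler optional)
solved exactly on the tree by Hines elimination at dt = 0.025 ms; channel
gates use unconditionally stable exponential-Euler steps through
voltage-indexed lookup tables; synaptic traces decay analytically. The
whole inner loop is one compiled (numba) kernel; a vectorised/scalar
reference implementation of the membrane and synapse dynamics exists in
plain Python and the test suite asserts agreement between the two routes.
Every protocol is preceded by a 1000 ms settling period with stimulation
off and plastic weights frozen; baselines are taken at the end of
settling. Runs are bit-reproducible given the seeds.

Convergence checks: the passive cable matches the analytic sealed-end
cosh profile within 1%; halving dt moves somatic spike times by <0.1 ms;
spatially uniform quasipotentials leave trajectories unchanged.

## Calibration

The conductance table and the synapse constants are fixed; the published
account of this model class leaves the channel kinetics and the four
pathway amplitudes as hand-tuned free parameters, and this package does
the same. The calibrated profile (in `model.CALIBRATED_AMPLITUDES` plus
the `KineticsConfig` defaults) was set, in order, against:

1. **Firing threshold.** The single-pulse monophasic field threshold is
   calibrated to ≈210 V/m (axonal Na activation shift −16 mV; node and
   internode diameters 1.5 µm — thinner axons initiate but fail to invade
   the soma antidromically). The biphasic pulse shape puts its threshold
   just above 275 V/m, so 10 Hz biphasic trains fire rarely while
   theta-burst volley summation still recruits spikes.
2. **Subthreshold silence.** g_base = 0.01 µS keeps the compound
   all-synapse volley (with co-activated 20 nS inhibitory synapses)
   subthreshold, so below-threshold field amplitudes produce no firing
   and no weight change.
3. **Distance profile at 10 Hz.** Back-propagating spikes boosted by the
   co-activated volley produce long (~10 ms) suprathreshold-C events on
   the proximal trunk and obliques; the trunk's high K_A and low Na kill
   the bAP by ~300 µm (distal radiatum and tuft silent), and the basal Na
   shift keeps oriens changes small.
4. **Magnitudes.** A_post+ (1.2e-5) and C_gain (1.8) centre the
   proximal-radiatum change at +65% and the Schaffer mean near +30% for
   the 900-pulse 10 Hz protocol, averaged over the four-placement model
   set; A_pre+ (5.5e-5) sets the burst-driven presynaptic component.

The placement spread of these outcomes is substantial (the threshold
nonlinearity of C amplifies arc-position and weight-draw differences);
reported group numbers are means over the fixed set of four seeded
placements, mirroring the fixed model set of the study design.

## What the generator emulates — and what it does not

Synthetic inputs are the built-in morphology, the seeded placements and
weight draws, and homogeneous 3 Hz Poisson background on every synapse.
This stands in for spontaneously active slice cultures; it does not model
correlated presynaptic activity, synaptic failures or stochastic delays,
feed-forward/feedback inhibitory circuits, metaplasticity, or non-uniform
fields. Passing tests therefore demonstrate the behaviour of the model
under these idealised conditions, not quantitative predictions for any
particular slice preparation.

## Design choices on open points

* The initial-weight sentence is read per-factor (w_pre = 0.5 m,
  w_post = 2 m, effective weight m²); a config switch selects the
  product reading.
* "Schaffer collateral" synapses are those in strata oriens + radiatum;
  the radiatum-only mask is also computed and reported.
* Theta-burst "100 ms separation" is read as the silent gap after the
  last stimulus of a burst (140 ms burst period); a flag selects the
  onset-to-onset reading.
* C is treated as a dynamic state (relaxation toward its drive) rather
  than an instantaneous function; the instantaneous form is recovered
  with τ_C → 0. The drive saturates at C_usat (inactive in the calibrated
  profile).
* Pairing paradigms use 2 ms / 2 nA somatic injections, 100 Hz within
  bursts, pairs at 1 Hz.

## Known limitations

* With the inhibitory strength required to make the inhibited electrical
  tuft TBS negligible, co-activated inhibition also suppresses the distal
  burst summation that the uniform-field TBS needs, so the model does not
  reproduce tuft LTP under field TBS *with* inhibition intact (it does
  without inhibition).
* Distal TBS plasticity has a sodium-independent component here (NMDA and
  passive summation), so dendritic TTX attenuates rather than abolishes
  it in the electrical TBS case.
* Blocking L-type calcium channels only clamps the presynaptic-LTP
  variable Nα; at 10 Hz that chain is silent, so the block leaves the
  10 Hz outcome essentially unchanged rather than halving it. Within this
  pathway wiring, a 10 Hz-active/1 Hz-silent Nα contribution is not
  attainable with the published time constants.
* Weight trajectories are linear only while weights stay away from the
  hard bounds; no metaplasticity or inhibitory plasticity is modelled.
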