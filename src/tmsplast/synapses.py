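"""Synapse models: plastic excitatory AMPA/NMDA synapses and static inhibition.

The excitatory synapse is a combined AMPA/NMDA conductance whose strength is
the product of a presynaptic and a postsynaptic weight factor.  Four
pathways modify the weights continuously as a function of the *local*
membrane potential u at the synapse:

* postsynaptic LTP / LTD are driven by ``C = sat(G) * rect(u - θuC)``, a
  proxy for calcium entry through NMDA receptors (``G`` tracks recent
  presynaptic activity with NMDA kinetics); LTP engages above ``θC+``, LTD
  above ``θC-`` and gated by the presynaptic trace ``Z``;
* presynaptic LTD is gated by ``T``, a low-threshold filtered depolarisation
  standing in for voltage-gated calcium channels, and applied at each
  presynaptic release;
* presynaptic LTP is carried by the slow chain ``Nα → Nβ → X → Kα → Kβ → Kγ``
  linking strong sustained depolarisation (L-type calcium / nitric-oxide
  like signalling) to a slowly accumulating weight gain.

``rect(x) = max(x, 0)`` and ``sat(x; M) = M x / (1 + M x)`` (slope M at 0,
asymptote 1).  All rate constants and thresholds live in
:class:`PlasticSynapseParams`; the defaults are the tuned hippocampal
parameter set of the model being reproduced.  The scalar functions in this
module are the reference dynamics; the compiled kernel in
:mod:`tmsplast._kernels` implements the identical update for whole
populations and is tested against these functions.

Inhibitory synapses are non-plastic double-exponential conductances with a
-75 mV reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .morphology import (
    CellLocation,
    LAYER_OF_LABEL,
    Morphology,
    RegionLabel,
    path_distance,
)

__all__ = [
    "PlasticSynapseParams",
    "PlasticSynapseState",
    "InhibitorySynapse",
    "SynapsePopulation",
    "place_synapses",
    "init_weights",
    "synaptic_current",
    "plasticity_step",
    "effective_weight",
    "inhibitory_current",
    "mg_block",
    "sat",
    "rect",
    "dexp_peak_time",
    "dexp_norm",
]


def rect(x):
    return np.maximum(x, 0.0)


def sat(x, m):
    """Saturation ``M x / (1 + M x)``: slope M at 0, asymptote 1."""
    return m * x / (1.0 + m * x)


def mg_block(u, mg: float = 1.0):
    """Sigmoidal magnesium block of the NMDA conductance (1 mM Mg default)."""
    return 1.0 / (1.0 + 0.28 * mg * np.exp(-0.062 * u))


def dexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Peak time of ``exp(-t/tau_decay) - exp(-t/tau_rise)``."""
    return (
        math.log(tau_decay / tau_rise)
        * tau_rise * tau_decay / (tau_decay - tau_rise)
    )


def dexp_norm(tau_rise: float, tau_decay: float) -> float:
    """Peak value of the raw double exponential (used to normalise to 1)."""
    tp = dexp_peak_time(tau_rise, tau_decay)
    return math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)


@dataclass
class PlasticSynapseParams:
    """Parameters of the four-pathway plastic synapse.

    Defaults are the tuned hippocampal set (weight-scale interval, AMPA/NMDA
    kinetics, pathway amplitudes and thresholds).  ``g_base`` (µS), the hard
    weight bounds and the initial-weight convention are implementation
    parameters, not part of that set; the four pathway amplitudes and
    ``g_base`` are the calibration-eligible knobs.
    """

    WMIN: float = 0.22
    WMAX: float = 0.44
    tau_A: float = 0.2          # ms, AMPA rise
    tau_B: float = 2.0          # ms, AMPA decay
    e_rev: float = 0.0          # mV (e_Na in the synapse model)
    S_AMPA: float = 0.5
    S_NMDA: float = 0.5
    tau_GA: float = 2.0         # ms, NMDA / G rise
    tau_GB: float = 50.0        # ms, NMDA / G decay
    w_pre_init: float = 0.5
    w_post_init: float = 2.0
    M_G: float = 10.0
    A_pre_plus: float = 1.4e-5
    A_pre_minus: float = 2.25e-4
    A_post_plus: float = 1.6e-2
    A_post_minus: float = 45e-5
    tau_uT: float = 10.0
    theta_uT: float = -60.0
    M_T: float = 1.7
    theta_uN: float = -55.0
    tau_ZA: float = 1.0
    tau_ZB: float = 15.0
    M_Z: float = 6.0
    tau_Nalpha: float = 7.5
    tau_Nbeta: float = 20.0
    M_Nalpha: float = 2.0
    M_Nbeta: float = 10.0
    theta_NX: float = 0.3
    theta_uC: float = -63.5
    theta_C_minus: float = 8.0
    theta_C_plus: float = 8.2
    tau_Kalpha: float = 10.0
    tau_Kgamma: float = 25.0
    M_Kalpha: float = 1.5
    M_Kbeta: float = 1.7
    S_Kbeta: float = 100.0
    # implementation parameters
    g_base: float = 0.015       # µS at unit effective weight
    #: gain on the postsynaptic-calcium proxy drive, C = C_gain * sat(G) *
    #: rect(u - theta_uC).  Sets where typical depolarisation events sit
    #: relative to the fixed LTP/LTD thresholds; calibration-eligible
    #: together with the pathway amplitudes.
    C_gain: float = 1.0
    #: integration time constant (ms) of C.  C relaxes toward
    #: ``C_gain * sat(G) * rect(u - theta_uC)``; a long tau_C makes C a
    #: calcium-pool-like signal that accumulates over pulse trains (the
    #: source of the frequency dependence of the postsynaptic pathways).
    tau_C: float = 120.0
    #: saturation (mV) of the voltage overshoot feeding C: the drive uses
    #: min(rect(u - theta_uC), C_usat), so full dendritic spikes and large
    #: subthreshold events contribute comparably (calcium-proxy saturation).
    C_usat: float = 25.0
    w_pre_min: float = 0.0
    w_pre_max: float = 1.0
    w_post_min: float = 0.0
    w_post_max: float = 4.0
    #: if True, the uniform multiplier m scales each factor (w_pre = 0.5 m,
    #: w_post = 2 m, effective weight m²); if False it scales the product.
    multiplier_per_factor: bool = True

    def __post_init__(self):
        if self.theta_C_minus >= self.theta_C_plus:
            raise ValueError("theta_C_minus must be < theta_C_plus")
        for name in ("tau_A", "tau_B", "tau_GA", "tau_GB", "tau_uT", "tau_ZA",
                     "tau_ZB", "tau_Nalpha", "tau_Nbeta", "tau_Kalpha",
                     "tau_Kgamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def pack(self) -> np.ndarray:
        """Flat parameter vector in the kernel's fixed layout."""
        return np.array([
            self.tau_A, self.tau_B, self.e_rev, self.S_AMPA, self.S_NMDA,
            self.tau_GA, self.tau_GB, self.M_G,
            self.A_pre_plus, self.A_pre_minus, self.A_post_plus, self.A_post_minus,
            self.tau_uT, self.theta_uT, self.M_T, self.theta_uN,
            self.tau_ZA, self.tau_ZB, self.M_Z,
            self.tau_Nalpha, self.tau_Nbeta, self.M_Nalpha, self.M_Nbeta,
            self.theta_NX, self.theta_uC, self.theta_C_minus, self.theta_C_plus,
            self.tau_Kalpha, self.tau_Kgamma, self.M_Kalpha, self.M_Kbeta,
            self.S_Kbeta, self.g_base, self.C_gain, self.tau_C, self.C_usat,
            self.w_pre_min, self.w_pre_max, self.w_post_min, self.w_post_max,
            dexp_norm(self.tau_A, self.tau_B),
            dexp_norm(self.tau_GA, self.tau_GB),
            dexp_norm(self.tau_ZA, self.tau_ZB),
        ], dtype=float)


@dataclass
class PlasticSynapseState:
    """Dynamic state of one plastic synapse.

    Double-exponential traces are stored as (rise, decay) exponential pairs;
    the normalised trace is ``(decay - rise) / norm`` so a single event
    peaks at 1.
    """

    location: CellLocation
    a_rise: float = 0.0
    a_decay: float = 0.0
    g_rise: float = 0.0
    g_decay: float = 0.0
    z_rise: float = 0.0
    z_decay: float = 0.0
    T: float = 0.0
    N_alpha: float = 0.0
    N_beta: float = 0.0
    K_alpha: float = 0.0
    K_gamma: float = 0.0
    C: float = 0.0
    w_pre: float = 0.5
    w_post: float = 2.0

    def ampa_trace(self, p: PlasticSynapseParams) -> float:
        return (self.a_decay - self.a_rise) / dexp_norm(p.tau_A, p.tau_B)

    def nmda_trace(self, p: PlasticSynapseParams) -> float:
        return (self.g_decay - self.g_rise) / dexp_norm(p.tau_GA, p.tau_GB)

    def z_trace(self, p: PlasticSynapseParams) -> float:
        return (self.z_decay - self.z_rise) / dexp_norm(p.tau_ZA, p.tau_ZB)


@dataclass
class InhibitorySynapse:
    """Non-plastic double-exponential synapse, reversal -75 mV."""

    location: CellLocation
    tau_rise: float = 0.5
    tau_decay: float = 8.0
    e_rev: float = -75.0
    weight: float = 20e-3       # µS
    g_rise: float = 0.0
    g_decay: float = 0.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("inhibitory weight must be >= 0")


@dataclass
class SynapsePopulation:
    excitatory: list[PlasticSynapseState]
    inhibitory: list[InhibitorySynapse]
    placement_seed: int = 0
    weight_seed: int = 0

    def layers(self, morph: Morphology) -> list[str]:
        """Layer name per excitatory synapse."""
        out = []
        for s in self.excitatory:
            label = morph.sections[s.location.section_id].label
            out.append(LAYER_OF_LABEL[label])
        return out

    def path_distances(self, morph: Morphology) -> np.ndarray:
        return np.array([path_distance(morph, s.location) for s in self.excitatory])

    def to_dataframe(self, morph: Morphology):
        """Population dump: id, section, arc, path distance, layer, weights."""
        import pandas as pd

        rows = []
        for i, s in enumerate(self.excitatory):
            rows.append({
                "synapse_id": i,
                "section_id": s.location.section_id,
                "arc_fraction": s.location.arc_fraction,
                "path_distance_um": path_distance(morph, s.location),
                "layer": LAYER_OF_LABEL[
                    morph.sections[s.location.section_id].label
                ],
                "w_pre": s.w_pre,
                "w_post": s.w_post,
            })
        return pd.DataFrame(rows)


#: excitatory layer allocation (counts follow the hippocampal synapse census
#: of Megias et al. scaled to 128; inhibitory counts include perisomatic)
EXC_LAYER_FRACTIONS = {
    "stratum_oriens": 0.37,
    "stratum_radiatum": 0.57,
    "stratum_lacunosum_moleculare": 0.06,
}
INH_LAYER_FRACTIONS = {
    "soma": 2 / 18,
    "stratum_oriens": 5 / 18,
    "stratum_radiatum": 8 / 18,
    "stratum_lacunosum_moleculare": 3 / 18,
}

_LAYER_LABELS = {
    "stratum_oriens": (RegionLabel.BASAL,),
    "stratum_radiatum": (RegionLabel.APICAL_TRUNK, RegionLabel.OBLIQUE),
    "stratum_lacunosum_moleculare": (RegionLabel.TUFT,),
    "soma": (RegionLabel.SOMA,),
}


def _largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    keys = list(fractions)
    raw = np.array([fractions[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = raw - base
    for i in np.argsort(-rem)[: n - int(base.sum())]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def _sample_locations(
    morph: Morphology, labels, count: int, rng: np.random.Generator
) -> list[CellLocation]:
    """Area-stratified placement: per-section counts follow membrane-area
    shares (largest remainder, seeded tie-breaking), positions uniform in
    arc within each section.  Keeps the layer-uniform density while
    avoiding chance clusters of many synapses on one thin branch."""
    secs = [s for lab in labels for s in morph.by_label(lab)]
    if not secs:
        raise ValueError(f"no sections with labels {labels}")
    areas = np.array([s.lateral_area() for s in secs])
    raw = areas / areas.sum() * count
    base = np.floor(raw).astype(int)
    rem = raw - base
    n_extra = count - int(base.sum())
    order = np.argsort(-(rem + 1e-9 * rng.random(len(secs))))
    for i in order[:n_extra]:
        base[i] += 1
    out = []
    for sec, k in zip(secs, base):
        for _ in range(int(k)):
            out.append(CellLocation(sec.id, float(rng.uniform())))
    return out


def place_synapses(
    morph: Morphology,
    n_exc: int = 128,
    n_inh: int = 18,
    placement_seed: int = 0,
    weight_seed: int = 0,
    params: PlasticSynapseParams | None = None,
) -> SynapsePopulation:
    """Randomised layer-respecting synapse placement.

    Excitatory synapses are split across the three layers by fixed
    proportions and placed uniformly over the membrane within each layer
    (never on soma or axon); inhibitory synapses additionally target the
    soma.  Placement depends only on ``placement_seed``; initial weights
    only on ``weight_seed``, so re-placing with a new seed keeps the total
    synaptic input identical.
    """
    if n_exc < len(EXC_LAYER_FRACTIONS):
        raise ValueError(f"n_exc must be >= {len(EXC_LAYER_FRACTIONS)}")
    if n_inh < len(INH_LAYER_FRACTIONS):
        raise ValueError(f"n_inh must be >= {len(INH_LAYER_FRACTIONS)}")
    p = params or PlasticSynapseParams()
    rng = np.random.default_rng(placement_seed)

    exc_locs: list[CellLocation] = []
    for layer, cnt in _largest_remainder(n_exc, EXC_LAYER_FRACTIONS).items():
        exc_locs += _sample_locations(morph, _LAYER_LABELS[layer], cnt, rng)

    inh_locs: list[CellLocation] = []
    for layer, cnt in _largest_remainder(n_inh, INH_LAYER_FRACTIONS).items():
        inh_locs += _sample_locations(morph, _LAYER_LABELS[layer], cnt, rng)

    w_pre, w_post = init_weights(n_exc, weight_seed, p)
    excitatory = [
        PlasticSynapseState(location=loc, w_pre=w_pre[i], w_post=w_post[i])
        for i, loc in enumerate(exc_locs)
    ]
    inhibitory = [InhibitorySynapse(location=loc) for loc in inh_locs]
    return SynapsePopulation(
        excitatory=excitatory,
        inhibitory=inhibitory,
        placement_seed=placement_seed,
        weight_seed=weight_seed,
    )


def init_weights(
    n: int, weight_seed: int, params: PlasticSynapseParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Initial weights: ``m_i ~ U[WMIN, WMAX]`` applied to the default factors.

    With the per-factor convention (default), ``w_pre = 0.5 m`` and
    ``w_post = 2 m`` so the effective initial weight is ``m²``.
    """
    p = params or PlasticSynapseParams()
    if p.WMIN > p.WMAX:
        raise ValueError("WMIN must be <= WMAX")
    rng = np.random.default_rng(weight_seed)
    m = rng.uniform(p.WMIN, p.WMAX, size=n)
    if p.multiplier_per_factor:
        return p.w_pre_init * m, p.w_post_init * m
    return p.w_pre_init * np.ones(n), p.w_post_init * m


def effective_weight(state: PlasticSynapseState) -> float:
    """Total synaptic weight: the product of pre- and postsynaptic factors."""
    return state.w_pre * state.w_post


def _decay_dexp(state, rise_attr, decay_attr, tau_r, tau_d, dt, event):
    r = getattr(state, rise_attr) * math.exp(-dt / tau_r)
    d = getattr(state, decay_attr) * math.exp(-dt / tau_d)
    if event:
        r += 1.0
        d += 1.0
    setattr(state, rise_attr, r)
    setattr(state, decay_attr, d)


def synaptic_current(
    state: PlasticSynapseState,
    u: float,
    dt: float,
    params: PlasticSynapseParams | None = None,
    pre_event: bool = False,
    s_nmda_scale: float = 1.0,
) -> tuple[float, PlasticSynapseState]:
    """Excitatory synaptic current (nA, positive outward) at voltage ``u``.

    Advances the AMPA and NMDA conductance traces by ``dt`` (inserting a
    presynaptic event first if requested) and evaluates
    ``I = w_pre w_post g_base [S_AMPA A + S_NMDA G B(u)] (u - e_rev)``.
    """
    p = params or PlasticSynapseParams()
    _decay_dexp(state, "a_rise", "a_decay", p.tau_A, p.tau_B, dt, pre_event)
    _decay_dexp(state, "g_rise", "g_decay", p.tau_GA, p.tau_GB, dt, pre_event)
    g = state.w_pre * state.w_post * p.g_base * (
        p.S_AMPA * state.ampa_trace(p)
        + p.S_NMDA * s_nmda_scale * state.nmda_trace(p) * mg_block(u)
    )
    return g * (u - p.e_rev), state


def plasticity_step(
    state: PlasticSynapseState,
    u: float,
    pre_event: bool,
    dt: float,
    params: PlasticSynapseParams | None = None,
    force_C_zero: bool = False,
    force_Nalpha_zero: bool = False,
) -> PlasticSynapseState:
    """One forward-Euler step of the four-pathway weight dynamics.

    ``u`` is the local membrane potential at the synapse.  The ``force_*``
    flags implement receptor-blockade perturbations by clamping the
    corresponding internal variable to zero each step.
    """
    p = params or PlasticSynapseParams()
    if not math.isfinite(u):
        raise FloatingPointError("non-finite u in plasticity_step")

    _decay_dexp(state, "z_rise", "z_decay", p.tau_ZA, p.tau_ZB, dt, pre_event)
    z_s = sat(state.z_trace(p), p.M_Z)
    g_s = sat(state.nmda_trace(p), p.M_G)

    if force_C_zero:
        state.C = 0.0
    else:
        drive = p.C_gain * g_s * min(rect(u - p.theta_uC), p.C_usat)
        state.C += (drive - state.C) * (1.0 - math.exp(-dt / p.tau_C))
    c = state.C

    dw_post = (
        p.A_post_plus * rect(c - p.theta_C_plus)
        - p.A_post_minus * z_s * rect(c - p.theta_C_minus)
    )
    state.w_post = min(max(state.w_post + dt * dw_post, p.w_post_min), p.w_post_max)

    state.T += dt * (sat(rect(u - p.theta_uT), p.M_T) - state.T) / p.tau_uT
    if pre_event:
        state.w_pre -= p.A_pre_minus * state.T

    if force_Nalpha_zero:
        state.N_alpha = 0.0
    else:
        state.N_alpha += dt * (
            sat(rect(u - p.theta_uN), p.M_Nalpha) - state.N_alpha
        ) / p.tau_Nalpha
    state.N_beta += dt * (sat(state.N_alpha, p.M_Nbeta) - state.N_beta) / p.tau_Nbeta
    x = rect(state.N_alpha * state.N_beta - p.theta_NX) * z_s
    state.K_alpha += dt * (sat(x, p.M_Kalpha) - state.K_alpha) / p.tau_Kalpha
    k_beta = sat(p.S_Kbeta * state.K_alpha, p.M_Kbeta)
    state.K_gamma += dt * (k_beta - state.K_gamma) / p.tau_Kgamma
    state.w_pre += dt * p.A_pre_plus * state.K_gamma

    state.w_pre = min(max(state.w_pre, p.w_pre_min), p.w_pre_max)
    return state


def inhibitory_current(
    syn: InhibitorySynapse, u: float, dt: float, event: bool = False
) -> tuple[float, InhibitorySynapse]:
    """Inhibitory synaptic current (nA): ``weight * g(t) * (u - e_rev)``."""
    norm = dexp_norm(syn.tau_rise, syn.tau_decay)
    syn.g_rise *= math.exp(-dt / syn.tau_rise)
    syn.g_decay *= math.exp(-dt / syn.tau_decay)
    if event:
        syn.g_rise += 1.0
        syn.g_decay += 1.0
    g = syn.weight * (syn.g_decay - syn.g_rise) / norm
    return g * (u - syn.e_rev), syn
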