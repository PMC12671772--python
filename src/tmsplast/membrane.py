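"""Membrane biophysics of the reduced CA1 pyramidal cell.

This module holds (i) the region- and distance-dependent assignment of
maximal channel conductances and passive properties, (ii) Hodgkin–Huxley
style channel kinetics with a first-order internal calcium pool for the
calcium-gated potassium channels, and (iii) a vectorised evaluation of the
total transmembrane current used both directly (tests, single-compartment
studies) and as the reference for the compiled simulation kernel.

The conductance table is fixed by the cell model being reproduced: sodium,
A-type / delayed-rectifier / M-type potassium everywhere (with strongly
elevated Na and K_A in the axon initial segment and nodes of Ranvier),
HCN (Ih), T-, L- and N-type calcium and two calcium-gated potassium
conductances in the somatodendritic membrane, and an essentially passive
myelin sheath.  Three properties vary with somatic path distance d (µm):

* ``gbar_Ih(d) = 1.904e-5 * (1 + 3 d / 100)``      (linear growth)
* ``gbar_KA_dend(d) = 0.012915 / (1 + exp((300 - d)/50))``  (distal sigmoid)
* ``epas(d) = -65.73 - 5 d / 150``  mV              (distal hyperpolarising)

Channel *kinetics* are not part of the conductance table; they follow
standard CA1 sigmoidal steady-state / bell-shaped time-constant
formulations collected in one editable :class:`KineticsConfig` so that the
cell can be calibrated against behavioural anchors (somatic firing
threshold under field pulses, back-propagating action-potential
attenuation) without touching the table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .morphology import Morphology, RegionLabel

__all__ = [
    "ChannelId",
    "SpatialRule",
    "BiophysicsMap",
    "KineticsConfig",
    "GatingState",
    "assign_biophysics",
    "eval_spatial_rule",
    "channel_currents",
    "update_calcium",
    "default_table",
]


class ChannelId(str, enum.Enum):
    Na = "Na"
    KA = "KA"
    KDR = "KDR"
    KM = "KM"
    KCa = "KCa"
    CagK = "CagK"
    CaT = "CaT"
    CaL = "CaL"
    CaN = "CaN"
    Ih = "Ih"
    leak = "leak"


#: fixed channel ordering used by packed per-compartment arrays
CHANNEL_ORDER = [
    ChannelId.Na, ChannelId.KA, ChannelId.KDR, ChannelId.KM, ChannelId.KCa,
    ChannelId.CagK, ChannelId.CaT, ChannelId.CaL, ChannelId.CaN, ChannelId.Ih,
]

# reversal potentials (mV); calcium uses a fixed reversal (no GHK)
E_NA = 50.0
E_K = -90.0
E_CA = 120.0
E_H = -30.0

CA_REST = 1e-4   # mM
TAU_CA = 100.0   # ms
CA_DEPTH = 0.1   # µm submembrane shell
FARADAY = 96485.309


@dataclass(frozen=True)
class SpatialRule:
    """A conductance/potential that varies with somatic path distance d (µm).

    ``kind`` selects the functional form; ``params`` its coefficients:

    * ``linear``:  a * (1 + b * d)
    * ``sigmoid``: a / (1 + exp((c - d) / w))   params (a, c, w)
    * ``affine``:  a + b * d
    * ``range``:   linear interpolation a -> b over d in [d0, d1]
    """

    kind: str
    params: tuple[float, ...]

    def __call__(self, d: float | np.ndarray) -> float | np.ndarray:
        return eval_spatial_rule(self, d)


def eval_spatial_rule(rule: SpatialRule, d):
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("somatic path distance must be >= 0")
    p = rule.params
    if rule.kind == "linear":
        out = p[0] * (1.0 + p[1] * d)
    elif rule.kind == "sigmoid":
        out = p[0] / (1.0 + np.exp((p[1] - d) / p[2]))
    elif rule.kind == "affine":
        out = p[0] + p[1] * d
    elif rule.kind == "range":
        a, b, d0, d1 = p
        f = np.clip((d - d0) / (d1 - d0), 0.0, 1.0)
        out = a + (b - a) * f
    else:
        raise ValueError(f"unknown spatial rule kind {rule.kind!r}")
    if not np.all(np.isfinite(out)):
        raise ValueError("spatial rule evaluated to a non-finite value")
    return float(out) if out.ndim == 0 else out


IH_RULE = SpatialRule("linear", (1.904e-5, 3.0 / 100.0))
KA_DEND_RULE = SpatialRule("sigmoid", (0.012915, 300.0, 50.0))
EPAS_RULE = SpatialRule("affine", (-65.73, -5.0 / 150.0))


def _na_trunk_rule(trunk_extent: float) -> SpatialRule:
    return SpatialRule("range", (0.015, 0.02, 0.0, trunk_extent))


def _ka_trunk_rule(trunk_extent: float) -> SpatialRule:
    return SpatialRule("range", (0.1, 0.2, 0.0, trunk_extent))


Value = float | SpatialRule


@dataclass
class BiophysicsMap:
    """Per-(region, channel) maximal conductances plus passive properties.

    ``gbar[(region, channel)]`` is in S/cm² (or a :class:`SpatialRule` in
    somatic path distance); regions absent from a table row carry 0.
    ``cm`` µF/cm², ``ra`` Ω·cm, ``gpas`` S/cm², ``epas`` mV per region.
    """

    gbar: dict[tuple[RegionLabel, ChannelId], Value]
    cm: dict[RegionLabel, float]
    ra: dict[RegionLabel, float]
    gpas: dict[RegionLabel, float]
    epas: dict[RegionLabel, Value]

    def gbar_at(self, region: RegionLabel, channel: ChannelId, d: float) -> float:
        v = self.gbar.get((region, channel), 0.0)
        return eval_spatial_rule(v, d) if isinstance(v, SpatialRule) else float(v)

    def epas_at(self, region: RegionLabel, d: float) -> float:
        v = self.epas[region]
        return eval_spatial_rule(v, d) if isinstance(v, SpatialRule) else float(v)

    def to_json_dict(self) -> dict:
        def enc(v):
            if isinstance(v, SpatialRule):
                return {"rule": v.kind, "params": list(v.params)}
            return v

        return {
            "gbar": {f"{r.value}/{c.value}": enc(v) for (r, c), v in self.gbar.items()},
            "cm": {r.value: v for r, v in self.cm.items()},
            "ra": {r.value: v for r, v in self.ra.items()},
            "gpas": {r.value: v for r, v in self.gpas.items()},
            "epas": {r.value: enc(v) for r, v in self.epas.items()},
        }


# table columns -> region labels of this morphology
_SOMA = (RegionLabel.SOMA,)
_TRUNK = (RegionLabel.APICAL_TRUNK,)
_DEND = (RegionLabel.OBLIQUE, RegionLabel.TUFT, RegionLabel.BASAL)
_AISNODE = (RegionLabel.AIS, RegionLabel.NODE)
_MYELIN = (RegionLabel.MYELIN,)
_TERM = (RegionLabel.AXON_TERMINAL,)
_SOMATODENDRITIC = _SOMA + _TRUNK + _DEND


def default_table(trunk_extent: float = 400.0) -> BiophysicsMap:
    """The default conductance/passive table of the reduced CA1 cell.

    ``trunk_extent`` (µm) sets the span over which the trunk Na and K_A
    ranges (0.015–0.02 and 0.1–0.2 S/cm²) are interpolated linearly.
    """
    gbar: dict[tuple[RegionLabel, ChannelId], Value] = {}

    def put(regions, channel, value):
        for r in regions:
            gbar[(r, channel)] = value

    put(_SOMA, ChannelId.Na, 0.035)
    put(_TRUNK, ChannelId.Na, _na_trunk_rule(trunk_extent))
    put(_DEND, ChannelId.Na, 0.03828)
    put(_AISNODE, ChannelId.Na, 0.5)
    put(_TERM, ChannelId.Na, 0.035)

    put(_SOMA, ChannelId.KA, 0.0075)
    put(_TRUNK, ChannelId.KA, _ka_trunk_rule(trunk_extent))
    put(_DEND, ChannelId.KA, KA_DEND_RULE)
    put(_AISNODE, ChannelId.KA, 0.44)
    put(_TERM, ChannelId.KA, 0.0163694)

    put(_SOMA, ChannelId.KDR, 0.0015)
    put(_TRUNK, ChannelId.KDR, 0.02)
    put(_DEND, ChannelId.KDR, 0.004304)
    put(_AISNODE, ChannelId.KDR, 0.04)
    put(_TERM, ChannelId.KDR, 0.011664)

    put(_SOMA, ChannelId.KM, 0.001)
    put(_AISNODE, ChannelId.KM, 0.02)
    put(_TERM, ChannelId.KM, 0.0264739)

    put(_SOMA, ChannelId.KCa, 0.0015)
    put(_TRUNK, ChannelId.KCa, 9.031e-5)
    put(_DEND, ChannelId.KCa, 9.031e-5)

    put(_SOMATODENDRITIC, ChannelId.CagK, 4.48e-5)

    put(_SOMA, ChannelId.CaT, 0.00005)
    put(_TRUNK, ChannelId.CaT, 1.185e-6)
    put(_DEND, ChannelId.CaT, 1.185e-6)

    put(_SOMA, ChannelId.CaL, 0.0005)
    put(_TRUNK, ChannelId.CaL, 8.033e-6)
    put(_DEND, ChannelId.CaL, 8.033e-6)

    put(_SOMATODENDRITIC, ChannelId.CaN, 2.26e-6)

    put(_SOMATODENDRITIC, ChannelId.Ih, IH_RULE)

    cm = {r: 1.0 for r in RegionLabel}
    cm[RegionLabel.MYELIN] = 0.01

    ra = {r: 115.0 for r in _SOMATODENDRITIC}
    ra.update({r: 85.2 for r in _AISNODE + _TERM})
    ra[RegionLabel.MYELIN] = 60.0

    gpas = {r: 9.031e-5 for r in _SOMATODENDRITIC}
    gpas.update({r: 1.29e-4 for r in _AISNODE + _TERM})
    gpas[RegionLabel.MYELIN] = 8.89e-7

    epas: dict[RegionLabel, Value] = {r: EPAS_RULE for r in _SOMATODENDRITIC}
    epas.update({r: -79.92 for r in
                 (RegionLabel.AIS, RegionLabel.NODE, RegionLabel.MYELIN,
                  RegionLabel.AXON_TERMINAL)})

    return BiophysicsMap(gbar=gbar, cm=cm, ra=ra, gpas=gpas, epas=epas)


def assign_biophysics(
    morph: Morphology, table: BiophysicsMap | None = None
) -> BiophysicsMap:
    """Attach the conductance table to a labelled morphology.

    With no ``table`` the default is built with the trunk ranges spanning
    the morphology's actual apical-trunk extent.  Raises on labels in the
    morphology missing from the table's passive maps.
    """
    if table is None:
        trunk = morph.by_label(RegionLabel.APICAL_TRUNK)
        extent = max(
            (morph.section_start_distance(s.id) + s.length for s in trunk),
            default=400.0,
        )
        table = default_table(trunk_extent=extent)
    for sec in morph.sections.values():
        if sec.label not in table.cm or sec.label not in table.ra \
                or sec.label not in table.gpas or sec.label not in table.epas:
            raise ValueError(f"region {sec.label.value!r} missing from biophysics table")
    return table


# ---------------------------------------------------------------------------
# Channel kinetics
# ---------------------------------------------------------------------------

#: gate index layout shared with the compiled kernel
GATE_NAMES = [
    "na_m", "na_h", "ka_a", "ka_b", "kdr_n", "km_m",
    "cat_m", "cat_h", "cal_m", "can_m", "can_h", "ih_q",
    "kca_o", "cagk_o",
]
N_GATES = len(GATE_NAMES)

#: voltage gate parameter layout: (v_half, k, tau_min, tau_amp, tau_vhalf, tau_width)
_GP = 6


@dataclass
class KineticsConfig:
    """Editable kinetics for all channels.

    Voltage gates use sigmoidal steady states
    ``x_inf(v) = 1 / (1 + exp(-(v - v_half)/k))`` (negative ``k`` for
    inactivation) and bell-shaped time constants
    ``tau(v) = tau_min + tau_amp / (1 + ((v - tau_vhalf)/tau_width)^2)`` ms.
    Calcium gates relax toward a Hill function of the submembrane calcium
    concentration with a fixed time constant.  All rates are understood at
    34 °C (temperature scaling is folded into the constants).
    """

    # (v_half, k, tau_min, tau_amp, tau_vhalf, tau_width) per voltage gate
    na_m: tuple = (-23.0, 6.0, 0.06, 0.12, -30.0, 15.0)
    na_h: tuple = (-47.0, -4.0, 5.0, 22.0, -52.0, 15.0)
    ka_a: tuple = (5.0, 9.0, 2.0, 0.0, 0.0, 1.0)
    ka_b: tuple = (-56.0, -8.0, 5.0, 10.0, -60.0, 20.0)
    kdr_n: tuple = (-30.0, 6.0, 26.0, 4.0, -40.0, 25.0)
    km_m: tuple = (-35.0, 9.0, 40.0, 20.0, -40.0, 20.0)
    cat_m: tuple = (-48.0, 5.0, 2.0, 0.0, 0.0, 1.0)
    cat_h: tuple = (-72.0, -5.0, 25.0, 0.0, 0.0, 1.0)
    cal_m: tuple = (-20.0, 6.0, 1.5, 0.0, 0.0, 1.0)
    can_m: tuple = (-25.0, 6.0, 1.5, 0.0, 0.0, 1.0)
    can_h: tuple = (-60.0, -8.0, 80.0, 0.0, 0.0, 1.0)
    ih_q: tuple = (-84.0, -6.0, 40.0, 30.0, -80.0, 25.0)
    # calcium gates: (kd mM, hill coefficient, tau ms)
    kca_o: tuple = (6e-4, 2.0, 2.0)
    cagk_o: tuple = (1e-3, 2.0, 5.0)
    #: activation-midpoint shift (mV) of axonal sodium channels relative to
    #: the somatodendritic ones (AIS/node/terminal isoforms activate at more
    #: hyperpolarised potentials); applied to the Na activation gate in
    #: axonal compartments.
    axonal_na_shift: float = -16.0
    #: activation-midpoint shift (mV) of basal-dendrite sodium channels.
    #: A positive shift makes back-propagating spikes decremental in the
    #: basal tree (no local regeneration), confining strong voltage events
    #: to the perisomatic part of stratum oriens.
    basal_na_shift: float = 43.0
    #: activation-midpoint shift (mV) of tuft sodium channels.  A negative
    #: shift lets distal tuft branches fire local sodium spikes once the
    #: (disinhibited or bAP-assisted) volley summation lifts them a few mV,
    #: making distal plasticity dendritic-spike-dependent.
    tuft_na_shift: float = 0.0
    #: kinetics overrides for axonal compartments (AIS, nodes, myelin,
    #: terminal): fast delayed-rectifier and fast Na inactivation recovery
    #: keep the axon able to follow high-frequency trains while the
    #: somatodendritic membrane repolarises slowly (long plasticity-relevant
    #: depolarisation events).
    axonal_overrides: dict = field(default_factory=lambda: {
        "kdr_n": (-30.0, 6.0, 1.8, 3.0, -40.0, 25.0),
        "na_h": (-40.0, -4.0, 0.6, 7.0, -52.0, 15.0),
    })

    def axonal_variant(self) -> "KineticsConfig":
        """The kinetics used in axonal compartments."""
        return replace(self, **self.axonal_overrides)

    def pack(self) -> np.ndarray:
        """Flat (14, 6) parameter matrix consumed by the kernel."""
        rows = []
        for name in GATE_NAMES:
            p = getattr(self, name)
            rows.append(list(p) + [0.0] * (_GP - len(p)))
        return np.array(rows, dtype=float)


@dataclass
class GatingState:
    """Per-compartment gate values (n_comp, N_GATES) plus calcium (mM)."""

    gates: np.ndarray
    ca: np.ndarray

    def clip(self):
        np.clip(self.gates, 0.0, 1.0, out=self.gates)
        np.maximum(self.ca, CA_REST, out=self.ca)


def gate_steady_state(params: np.ndarray, v: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Steady-state values of all gates at voltage ``v`` and calcium ``ca``."""
    v = np.atleast_1d(np.asarray(v, float))
    ca = np.atleast_1d(np.asarray(ca, float))
    out = np.empty((v.size, N_GATES))
    for g in range(12):
        vh, k = params[g, 0], params[g, 1]
        out[:, g] = 1.0 / (1.0 + np.exp(-(v - vh) / k))
    for g, row in ((12, params[12]), (13, params[13])):
        kd, hill = row[0], row[1]
        out[:, g] = ca**hill / (ca**hill + kd**hill)
    return out


def init_gating(params: np.ndarray, v: np.ndarray) -> GatingState:
    ca = np.full(np.atleast_1d(v).size, CA_REST)
    return GatingState(gates=gate_steady_state(params, v, ca), ca=ca)


def channel_currents(
    gating: GatingState,
    v: np.ndarray,
    dt: float,
    gbar: np.ndarray,
    gpas: np.ndarray,
    epas: np.ndarray,
    kinetics: np.ndarray,
) -> tuple[np.ndarray, GatingState, np.ndarray]:
    """Advance gates by ``dt`` and return membrane current density.

    ``gbar`` is (10, n_comp) in the :data:`CHANNEL_ORDER` layout, S/cm².
    Returns ``(i_total mA/cm², updated gating, i_ca mA/cm²)``; the calcium
    pool is advanced using the calcium current.  Gate updates use the
    unconditionally stable exponential-Euler step toward the steady state.
    """
    v = np.asarray(v, float)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite membrane potential passed to channel_currents")
    g = gating.gates
    ca = gating.ca
    inf = gate_steady_state(kinetics, v, ca)
    for idx in range(N_GATES):
        if idx < 12:
            tmin, tamp, tvh, tw = kinetics[idx, 2:6]
            tau = tmin + tamp / (1.0 + ((v - tvh) / tw) ** 2)
        else:
            tau = kinetics[idx, 2]
        g[:, idx] += (inf[:, idx] - g[:, idx]) * (1.0 - np.exp(-dt / tau))
    gating.clip()

    m, h = g[:, 0], g[:, 1]
    a, b = g[:, 2], g[:, 3]
    n = g[:, 4]
    km = g[:, 5]
    ctm, cth = g[:, 6], g[:, 7]
    clm = g[:, 8]
    cnm, cnh = g[:, 9], g[:, 10]
    q = g[:, 11]
    kca, cagk = g[:, 12], g[:, 13]

    i_na = gbar[0] * m**3 * h * (v - E_NA)
    i_ka = gbar[1] * a * b * (v - E_K)
    i_kdr = gbar[2] * n * (v - E_K)
    i_km = gbar[3] * km * (v - E_K)
    i_kca = gbar[4] * kca * (v - E_K)
    i_cagk = gbar[5] * cagk * (v - E_K)
    i_cat = gbar[6] * ctm**2 * cth * (v - E_CA)
    i_cal = gbar[7] * clm**2 * (v - E_CA)
    i_can = gbar[8] * cnm * cnh * (v - E_CA)
    i_h = gbar[9] * q * (v - E_H)
    i_pas = gpas * (v - epas)

    i_ca = i_cat + i_cal + i_can
    i_total = (i_na + i_ka + i_kdr + i_km + i_kca + i_cagk + i_ca + i_h + i_pas)
    gating.ca = update_calcium(ca, i_ca, dt)
    return i_total, gating, i_ca


def update_calcium(ca: np.ndarray, i_ca: np.ndarray, dt: float) -> np.ndarray:
    """First-order submembrane calcium pool.

    ``d[ca]/dt = -k * i_ca - (ca - ca_rest)/tau`` with the influx factor
    ``k = 1e4 / (2 F depth)`` converting an inward calcium current density
    (mA/cm², negative inward) into mM/ms for a ``depth`` µm shell.  With
    zero influx the pool decays exponentially to ``ca_rest``.
    """
    k = 1e4 / (2.0 * FARADAY * CA_DEPTH)
    drive = -k * np.minimum(np.asarray(i_ca, float), 0.0)
    new = ca + dt * (drive - (ca - CA_REST) / TAU_CA)
    return np.maximum(new, CA_REST)
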