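"""Spatial discretisation and time integration of the cable equation.

The labelled morphology is split into compartments (default maximum length
20 µm); axial coupling between adjacent compartments follows the cylindrical
formula g = π r² / (Ra L) built from the two half-compartment resistances.
Voltages advance by an implicit theta scheme (Crank–Nicolson by default,
backward Euler as fallback) solved exactly on the tree by Hines elimination;
gates, calcium and synapses advance alongside inside the compiled kernel.

The extracellular quasipotential enters only through axial differences of
(v + Ve), so a spatially uniform Ve is electrically silent and adding a
constant to all quasipotentials leaves trajectories unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .membrane import (
    BiophysicsMap,
    CHANNEL_ORDER,
    ChannelId,
    KineticsConfig,
    N_GATES,
    gate_steady_state,
    CA_REST,
)
from .morphology import CellLocation, Morphology, RegionLabel, path_distance
from .stimulation import Protocol, SynapticActivation, quasipotentials, poisson_background
from .synapses import PlasticSynapseParams, SynapsePopulation

__all__ = [
    "DiscretizedCell",
    "SimConfig",
    "StateVector",
    "VoltageTrace",
    "RunResult",
    "discretize",
    "step",
    "run",
    "detect_spikes",
    "SolverError",
]

REGION_CODES = {label: i for i, label in enumerate(RegionLabel)}


class SolverError(RuntimeError):
    pass


@dataclass
class DiscretizedCell:
    """Compartmentalised cell with per-compartment parameters.

    Compartments are ordered root-first so ``parent[i] < i``; axial coupling
    ``g_pa`` (µS) connects each compartment to its parent.
    """

    morph: Morphology
    biophys: BiophysicsMap
    parent: np.ndarray          # (n,) int64
    g_pa: np.ndarray            # (n,) µS
    area: np.ndarray            # (n,) cm²
    c_nf: np.ndarray            # (n,) nF
    coords: np.ndarray          # (n, 3) µm
    region_code: np.ndarray     # (n,) int64
    sec_id: np.ndarray          # (n,) int64
    arc0: np.ndarray            # (n,)
    arc1: np.ndarray            # (n,)
    path_dist: np.ndarray       # (n,) µm at centre
    gbar_dens: np.ndarray       # (10, n) S/cm²
    gpas_dens: np.ndarray       # (n,) S/cm²
    epas: np.ndarray            # (n,) mV

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def gbar_us(self) -> np.ndarray:
        return self.gbar_dens * self.area[None, :] * 1e6

    @property
    def gpas_us(self) -> np.ndarray:
        return self.gpas_dens * self.area * 1e6

    def loc_to_comp(self, loc: CellLocation) -> int:
        """Resolve a cell location to its compartment index."""
        mask = self.sec_id == loc.section_id
        if not mask.any():
            raise KeyError(f"section {loc.section_id} not in discretised cell")
        idx = np.where(mask)[0]
        for i in idx:
            if self.arc0[i] <= loc.arc_fraction <= self.arc1[i]:
                return int(i)
        return int(idx[-1])

    def comp_of_region(self, labels) -> np.ndarray:
        codes = {REGION_CODES[l] for l in labels}
        return np.where(np.isin(self.region_code, list(codes)))[0]

    def laplacian(self) -> np.ndarray:
        """Dense axial Laplacian (µS); row sums are zero."""
        n = self.n
        L = np.zeros((n, n))
        for i in range(1, n):
            p, g = self.parent[i], self.g_pa[i]
            L[i, i] -= g
            L[p, p] -= g
            L[i, p] += g
            L[p, i] += g
        return L

    def total_area(self) -> float:
        return float(self.area.sum())


def discretize(
    morph: Morphology,
    biophys: BiophysicsMap,
    max_seg_length: float = 20.0,
) -> DiscretizedCell:
    """Split every section into compartments of at most ``max_seg_length`` µm."""
    order = morph.section_order()
    parent, g_half_prox, g_half_dist = [], [], []
    area, cnf, coords, region, secid, arc0, arc1, pdist = [], [], [], [], [], [], [], []
    gbar = []
    gpas, epas = [], []
    last_comp_of_sec: dict[int, int] = {}

    for sid in order:
        sec = morph.sections[sid]
        if sec.diam_start <= 0 or sec.diam_end <= 0:
            raise ValueError(f"section {sid} has zero diameter")
        nseg = max(1, math.ceil(sec.length / max_seg_length))
        ra = biophys.ra[sec.label]
        sec_start_d = morph.section_start_distance(sid)
        for k in range(nseg):
            f0, f1 = k / nseg, (k + 1) / nseg
            fm = 0.5 * (f0 + f1)
            idx = len(parent)
            if k == 0:
                parent.append(
                    -1 if sec.parent_id is None else last_comp_of_sec[sec.parent_id]
                )
            else:
                parent.append(idx - 1)
            # half-compartment axial resistances (Ω)
            r_um = sec.diameter_at(fm) / 2
            l_cm = (sec.length / nseg) * 1e-4
            cs_cm2 = math.pi * (r_um * 1e-4) ** 2
            r_half = ra * (l_cm / 2) / cs_cm2
            g_half_prox.append(1.0 / r_half)
            g_half_dist.append(1.0 / r_half)

            a_cm2 = sec.lateral_area(f0, f1) * 1e-8
            area.append(a_cm2)
            cnf.append(biophys.cm[sec.label] * a_cm2 * 1e3)
            coords.append(sec.point_at(fm))
            region.append(REGION_CODES[sec.label])
            secid.append(sid)
            arc0.append(f0)
            arc1.append(f1)
            d = 0.0 if sec.label is RegionLabel.SOMA else sec_start_d + fm * sec.length
            pdist.append(d)
            gbar.append([
                biophys.gbar_at(sec.label, ch, d) for ch in CHANNEL_ORDER
            ])
            gpas.append(biophys.gpas[sec.label])
            epas.append(biophys.epas_at(sec.label, d))
        last_comp_of_sec[sid] = len(parent) - 1

    n = len(parent)
    parent = np.array(parent, dtype=np.int64)
    g_pa = np.zeros(n)
    for i in range(1, n):
        p = parent[i]
        g_pa[i] = 1e6 / (1.0 / g_half_prox[i] + 1.0 / g_half_dist[p])  # µS

    return DiscretizedCell(
        morph=morph,
        biophys=biophys,
        parent=parent,
        g_pa=g_pa,
        area=np.array(area),
        c_nf=np.array(cnf),
        coords=np.array(coords),
        region_code=np.array(region, dtype=np.int64),
        sec_id=np.array(secid, dtype=np.int64),
        arc0=np.array(arc0),
        arc1=np.array(arc1),
        path_dist=np.array(pdist),
        gbar_dens=np.array(gbar).T.copy(),
        gpas_dens=np.array(gpas),
        epas=np.array(epas),
    )


@dataclass
class SimConfig:
    dt: float = 0.025               # ms
    duration: float = 0.0           # ms (0: take from protocol)
    settle_time: float = 1000.0     # ms at rest before the protocol
    seed: int = 0
    record: list[CellLocation] = field(default_factory=list)
    scheme: str = "cn"              # "cn" (theta 0.5) or "be" (theta 1)
    record_stride: int = 1          # store every k-th step
    weight_stride_ms: float = 100.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def theta(self) -> float:
        if self.scheme == "cn":
            return 0.5
        if self.scheme == "be":
            return 1.0
        raise ValueError(f"unknown integration scheme {self.scheme!r}")


@dataclass
class StateVector:
    """Voltages, gates, calcium and synapse state at one instant."""

    v: np.ndarray
    gates: np.ndarray
    ca: np.ndarray
    es_state: np.ndarray            # (ne, 13)
    is_state: np.ndarray            # (ni, 2)
    time: float = 0.0

    def copy(self) -> "StateVector":
        return StateVector(
            self.v.copy(), self.gates.copy(), self.ca.copy(),
            self.es_state.copy(), self.is_state.copy(), self.time,
        )


@dataclass
class VoltageTrace:
    location: CellLocation
    times: np.ndarray
    values: np.ndarray

    def to_csv(self, path) -> None:
        """Write the trace as a two-column (time_ms, v_mv) CSV file."""
        import pandas as pd

        pd.DataFrame({"time_ms": self.times, "v_mv": self.values}).to_csv(
            path, index=False)


@dataclass
class RunResult:
    traces: dict
    weight_times: np.ndarray        # ms
    w_pre: np.ndarray               # (nw, ne)
    w_post: np.ndarray              # (nw, ne)
    w_pre_baseline: np.ndarray
    w_post_baseline: np.ndarray
    final_state: StateVector
    event_log: dict

    def effective_weights(self) -> np.ndarray:
        return self.w_pre * self.w_post

    def baseline_effective(self) -> np.ndarray:
        return self.w_pre_baseline * self.w_post_baseline

    def final_effective(self) -> np.ndarray:
        return self.final_state.es_state[:, 11] * self.final_state.es_state[:, 12]

    def percent_change(self) -> np.ndarray:
        base = self.baseline_effective()
        return 100.0 * (self.final_effective() - base) / base


# ---------------------------------------------------------------------------
# Assembly helpers
# ---------------------------------------------------------------------------

ES_NSTATE = 14


def init_state(
    cell: DiscretizedCell,
    kinetics: KineticsConfig,
    population: SynapsePopulation | None = None,
    v0: float = -70.0,
) -> StateVector:
    v = np.full(cell.n, v0)
    kin = kinetics.pack()
    ca = np.full(cell.n, CA_REST)
    gates = gate_steady_state(kin, v, ca)
    ne = len(population.excitatory) if population else 0
    ni = len(population.inhibitory) if population else 0
    es = np.zeros((ne, ES_NSTATE))
    if population:
        for i, s in enumerate(population.excitatory):
            es[i, 11] = s.w_pre
            es[i, 12] = s.w_post
    return StateVector(v=v, gates=gates, ca=ca,
                       es_state=es, is_state=np.zeros((ni, 2)))


def _activation_selects(act: SynapticActivation, label: RegionLabel,
                        is_inhibitory: bool) -> bool:
    if act.target == "all":
        return True
    if act.target == "excitatory":
        return not is_inhibitory
    # region-restricted target
    if is_inhibitory:
        return act.include_inhibitory
    return label in act.target


def _event_arrays(protocol, population, cell, duration):
    """Per-synapse sorted event times as flat array + [start, stop] spans."""
    ne = len(population.excitatory) if population else 0
    ni = len(population.inhibitory) if population else 0
    bg = (
        poisson_background(protocol.background_rate, duration,
                           protocol.background_seed, ne + ni)
        if protocol.background_rate > 0
        else [np.empty(0)] * (ne + ni)
    )
    all_events, spans = [], []
    pos = 0

    def push(times):
        nonlocal pos
        t = np.sort(np.asarray(times))
        all_events.append(t)
        spans.append((pos, pos + len(t)))
        pos += len(t)

    if population:
        for i, s in enumerate(population.excitatory):
            label = cell.morph.sections[s.location.section_id].label
            times = [a.time for a in protocol.synaptic_activations
                     if _activation_selects(a, label, False)]
            push(np.concatenate([np.asarray(times), bg[i]]))
        for j, s in enumerate(population.inhibitory):
            label = cell.morph.sections[s.location.section_id].label
            times = [a.time for a in protocol.synaptic_activations
                     if _activation_selects(a, label, True)]
            push(np.concatenate([np.asarray(times), bg[ne + j]]))

    flat = np.concatenate(all_events) if all_events else np.empty(0)
    span_arr = np.array(spans, dtype=np.int64).reshape(-1, 2) if spans else \
        np.empty((0, 2), dtype=np.int64)
    return flat, span_arr[:ne], span_arr[ne:]


def _wave_array(protocol, dt: float, n_steps: int) -> np.ndarray:
    wave = np.zeros(n_steps + 1)
    tgrid = np.arange(n_steps + 1) * dt
    for onset, wf, _ in protocol.field_pulses:
        i0 = max(0, int(math.floor(onset / dt)))
        i1 = min(n_steps, int(math.ceil((onset + wf.pulse_width) / dt)) + 1)
        if i0 >= i1:
            continue
        wave[i0:i1 + 1] += wf.amplitude * wf.sample(tgrid[i0:i1 + 1] - onset)
    return wave


def _field_vector(protocol):
    vecs = {(f.ex, f.ey, f.ez) for _, _, f in protocol.field_pulses}
    if len(vecs) > 1:
        raise NotImplementedError("one field vector per protocol is supported")
    if not vecs:
        return None
    from .stimulation import FieldVector
    return FieldVector(*vecs.pop())


@dataclass
class KernelInputs:
    """Bundle of pre-assembled arrays for one kernel invocation."""

    cell: DiscretizedCell
    kinetics: KineticsConfig
    syn_params: PlasticSynapseParams
    population: SynapsePopulation | None = None
    g_tonic_us: np.ndarray | None = None
    snmda_scale: float = 1.0
    force_C_zero: bool = False
    force_Nalpha_zero: bool = False
    freeze_ca: bool = False

    def es_comp(self):
        if not self.population:
            return np.empty(0, dtype=np.int64)
        return np.array(
            [self.cell.loc_to_comp(s.location) for s in self.population.excitatory],
            dtype=np.int64,
        )

    def is_arrays(self):
        pop = self.population
        if not pop or not pop.inhibitory:
            z = np.empty(0)
            return (np.empty(0, dtype=np.int64), z, z.copy(), z.copy(), z.copy())
        comp = np.array(
            [self.cell.loc_to_comp(s.location) for s in pop.inhibitory],
            dtype=np.int64,
        )
        w = np.array([s.weight for s in pop.inhibitory])
        taur = np.array([s.tau_rise for s in pop.inhibitory])
        taud = np.array([s.tau_decay for s in pop.inhibitory])
        erev = np.array([s.e_rev for s in pop.inhibitory])
        return comp, w, taur, taud, erev


def _kernel_call(ki: KernelInputs, state: StateVector, protocol: Protocol | None,
                 sim: SimConfig, n_steps: int, plasticity_on: bool,
                 rec_comp: np.ndarray, rec_stride: int, w_stride: int):
    cell = ki.cell
    dt = sim.dt
    kin = ki.kinetics.pack()
    tables = _kernels.build_gate_tables(kin, dt)
    tables_ax = _kernels.build_gate_tables(ki.kinetics.axonal_variant().pack(), dt)
    cagk_par = np.array([list(ki.kinetics.kca_o), list(ki.kinetics.cagk_o)])
    na_shift = np.zeros(cell.n)
    ax_codes = [REGION_CODES[r] for r in
                (RegionLabel.AIS, RegionLabel.NODE, RegionLabel.MYELIN,
                 RegionLabel.AXON_TERMINAL)]
    is_ax = np.isin(cell.region_code, ax_codes)
    na_shift[is_ax] = ki.kinetics.axonal_na_shift
    na_shift[cell.region_code == REGION_CODES[RegionLabel.BASAL]] = \
        ki.kinetics.basal_na_shift
    na_shift[cell.region_code == REGION_CODES[RegionLabel.TUFT]] = \
        ki.kinetics.tuft_na_shift

    if protocol is not None and protocol.field_pulses:
        fld = _field_vector(protocol)
        # quasipotentials of the unit-direction field; the waveform array
        # carries amplitude (V/m) x scale(t)
        from .stimulation import FieldVector as _FV
        e = fld.as_array()
        norm = np.linalg.norm(e)
        unit = _FV(*(e / norm)) if norm > 0 else _FV(0.0, 0.0, 0.0)
        ve_unit = quasipotentials(cell, unit).ve_mv
        wave = _wave_array(protocol, dt, n_steps)
    else:
        ve_unit = np.zeros(cell.n)
        wave = np.zeros(n_steps + 1)

    if protocol is not None and protocol.current_injections:
        soma_comp = cell.comp_of_region([RegionLabel.SOMA])[0]
        inj_comp = np.array(
            [soma_comp for _ in protocol.current_injections], dtype=np.int64)
        inj_t0 = np.array([c.time for c in protocol.current_injections])
        inj_t1 = inj_t0 + np.array(
            [c.duration for c in protocol.current_injections])
        inj_amp = np.array(
            [c.amplitude_nA for c in protocol.current_injections])
    else:
        inj_comp = np.empty(0, dtype=np.int64)
        inj_t0 = inj_t1 = inj_amp = np.empty(0)

    if protocol is not None:
        events, es_ptr, is_ptr = _event_arrays(
            protocol, ki.population, cell, n_steps * dt)
    else:
        ne = len(ki.population.excitatory) if ki.population else 0
        ni = len(ki.population.inhibitory) if ki.population else 0
        events = np.empty(0)
        es_ptr = np.zeros((ne, 2), dtype=np.int64)
        is_ptr = np.zeros((ni, 2), dtype=np.int64)

    es_comp = ki.es_comp()
    is_comp, is_w, is_taur, is_taud, is_erev = ki.is_arrays()
    g_tonic = ki.g_tonic_us if ki.g_tonic_us is not None else np.zeros(cell.n)

    n_rec = n_steps // rec_stride if rec_stride > 0 else 0
    rec_out = np.zeros((len(rec_comp), n_rec))
    n_w = n_steps // w_stride if w_stride > 0 else 0
    w_out = np.zeros((n_w, len(es_comp), 2))

    status = _kernels.simulate(
        cell.parent, cell.g_pa, cell.c_nf, cell.gbar_us,
        np.ascontiguousarray(cell.gbar_dens[6:9]),
        cell.gpas_us, cell.epas, g_tonic,
        tables, tables_ax, is_ax, cagk_par, na_shift,
        state.gates, state.ca, state.v, ki.freeze_ca,
        ve_unit, wave, inj_comp, inj_t0, inj_t1, inj_amp,
        es_comp, state.es_state, ki.syn_params.pack(),
        events, es_ptr, ki.snmda_scale,
        ki.force_C_zero, ki.force_Nalpha_zero, plasticity_on,
        is_comp, is_w, state.is_state, is_taur, is_taud, is_erev,
        events, is_ptr,
        dt, n_steps, sim.theta,
        rec_comp, rec_stride, rec_out, w_stride, w_out,
    )
    if status != 0:
        raise SolverError(
            f"non-finite voltage in compartment {status - 1} "
            f"(section {cell.sec_id[status - 1]}, t <= {state.time + n_steps * dt} ms)"
        )
    return rec_out, w_out


def step(ki: KernelInputs, state: StateVector, sim: SimConfig,
         ve_protocol: Protocol | None = None, n_steps: int = 1) -> StateVector:
    """Advance the system ``n_steps`` (plasticity active), mutating ``state``."""
    rec = np.empty(0, dtype=np.int64)
    _kernel_call(ki, state, ve_protocol, sim, n_steps, True, rec, 0, 0)
    state.time += n_steps * sim.dt
    return state


def run(
    ki: KernelInputs,
    protocol: Protocol,
    sim: SimConfig,
    state: StateVector | None = None,
) -> RunResult:
    """Settle the cell, then run the protocol with plasticity enabled.

    During the settling period stimulation is off and plastic weights are
    frozen; the baseline for percentage weight changes is the state at the
    end of settling.  Deterministic: a given protocol, configuration and
    seeds reproduce results bit-for-bit.
    """
    protocol.validate()
    cell = ki.cell
    dt = sim.dt
    if state is None:
        state = init_state(cell, ki.kinetics, ki.population)

    if sim.settle_time > 0:
        n_settle = int(round(sim.settle_time / dt))
        rec = np.empty(0, dtype=np.int64)
        _kernel_call(ki, state, None, sim, n_settle, False, rec, 0, 0)
        state.time += sim.settle_time

    w_pre_base = state.es_state[:, 11].copy()
    w_post_base = state.es_state[:, 12].copy()

    duration = sim.duration if sim.duration > 0 else protocol.duration
    n_steps = int(round(duration / dt))
    soma = cell.comp_of_region([RegionLabel.SOMA])
    record = sim.record or [CellLocation(int(cell.sec_id[soma[0]]), 0.5)]
    rec_comp = np.array([cell.loc_to_comp(l) for l in record], dtype=np.int64)
    w_stride = max(1, int(round(sim.weight_stride_ms / dt)))

    rec_out, w_out = _kernel_call(
        ki, state, protocol, sim, n_steps, True,
        rec_comp, sim.record_stride, w_stride,
    )
    state.time += n_steps * dt

    t_rec = (np.arange(rec_out.shape[1]) + 1) * dt * sim.record_stride
    traces = {
        loc: VoltageTrace(loc, t_rec, rec_out[i])
        for i, loc in enumerate(record)
    }
    w_times = (np.arange(w_out.shape[0]) + 1) * w_stride * dt
    return RunResult(
        traces=traces,
        weight_times=w_times,
        w_pre=w_out[:, :, 0],
        w_post=w_out[:, :, 1],
        w_pre_baseline=w_pre_base,
        w_post_baseline=w_post_base,
        final_state=state,
        event_log={
            "protocol": protocol.descriptor(),
            "dt_ms": dt,
            "settle_ms": sim.settle_time,
            "scheme": sim.scheme,
            "seed": sim.seed,
        },
    )


def detect_spikes(trace: VoltageTrace | np.ndarray, threshold: float = 0.0,
                  times: np.ndarray | None = None,
                  refractory: float = 1.0) -> np.ndarray:
    """Upward threshold crossings with a refractory lockout (ms)."""
    if isinstance(trace, VoltageTrace):
        v, t = trace.values, trace.times
    else:
        v = np.asarray(trace)
        t = times if times is not None else np.arange(len(v), dtype=float)
    above = v >= threshold
    crossings = np.where(~above[:-1] & above[1:])[0] + 1
    out = []
    last = -np.inf
    for i in crossings:
        if t[i] - last >= refractory:
            out.append(t[i])
            last = t[i]
    return np.array(out)
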