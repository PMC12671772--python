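"""Field waveforms, uniform-field quasipotentials and stimulation protocols.

A magnetic pulse is modelled as a uniform electric field vector E with a
short temporal waveform s(t) (peak |s| = 1).  Each compartment of the
discretised cell receives the extracellular quasipotential

    Ve(x, y, z) = -(Ex x + Ey y + Ez z)

(coordinates in metres, result in volts; stored here in mV with µm
coordinates), scaled at run time by ``amplitude * s(t)``.  Only gradients of
Ve enter the cable equation, so a spatially uniform Ve is electrically
silent.

Protocols are declarative: a list of timed field pulses, a list of timed
synaptic activation events (each tagged with the synapse subset it drives),
optional somatic current injections (for pairing paradigms) and a Poisson
background specification.  Protocol builders are pure — identical inputs and
seeds give identical protocols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .morphology import RegionLabel

__all__ = [
    "FieldVector",
    "Waveform",
    "SynapticActivation",
    "CurrentInjection",
    "Protocol",
    "QuasipotentialMap",
    "quasipotentials",
    "make_waveform",
    "build_train",
    "build_tbs",
    "attach_synaptic_delay",
    "poisson_background",
    "local_electrical_stim",
    "pairing_protocol",
    "DEFAULT_FIELD_DIRECTION",
]

#: default field direction: along the somato-dendritic axis pointing from
#: the apical tuft toward the axon (-y), which depolarises the axon terminal
DEFAULT_FIELD_DIRECTION = (0.0, -1.0, 0.0)

SYNAPTIC_DELAY_MS = 1.0


@dataclass(frozen=True)
class FieldVector:
    """Uniform electric field components in V/m."""

    ex: float
    ey: float
    ez: float

    def __post_init__(self):
        if not all(np.isfinite([self.ex, self.ey, self.ez])):
            raise ValueError("field components must be finite")

    @classmethod
    def along(cls, direction, amplitude: float) -> "FieldVector":
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        return cls(*(d * amplitude))

    def as_array(self) -> np.ndarray:
        return np.array([self.ex, self.ey, self.ez])


@dataclass(frozen=True)
class Waveform:
    """Sampled unit waveform; scaled by ``amplitude`` (V/m) at run time."""

    shape: str                  # "monophasic" | "biphasic" | "custom"
    amplitude: float            # V/m
    times: np.ndarray           # ms, starting at 0
    scale: np.ndarray           # unitless, |peak| = 1, 0 outside support
    pulse_width: float          # ms

    def __post_init__(self):
        t = np.asarray(self.times, float)
        s = np.asarray(self.scale, float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and scale must be matching 1-D arrays")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "scale", s)
        if len(s) and self.amplitude > 0:
            peak = np.max(np.abs(s))
            if not np.isclose(peak, 1.0, atol=1e-9):
                raise ValueError("waveform scale must peak at |1|")

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Interpolate the unit scale onto times ``t`` (0 outside support)."""
        return np.interp(t, self.times, self.scale, left=0.0, right=0.0)


def make_waveform(shape: str, amplitude: float, dt: float = 0.005,
                  biphasic_lobes: tuple[float, float] = (0.15, 0.3)) -> Waveform:
    """Build a default pulse waveform.

    ``monophasic``: a single positive damped half-sine lobe, 0.2 ms wide.
    ``biphasic``: one damped sine cycle, 0.3 ms, with near-zero net integral
    (positive lobe first).  Any sampled waveform can be substituted by
    constructing :class:`Waveform` directly.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if shape == "monophasic":
        width = 0.2
        t = np.arange(0.0, width + dt / 2, dt)
        s = np.sin(np.pi * t / width) * np.exp(-1.5 * t / width)
    elif shape == "biphasic":
        # sharp positive lobe followed by a broad shallow negative lobe of
        # equal area (zero net integral), as in monophasic-like biphasic
        # stimulator outputs
        w1, w2 = biphasic_lobes
        width = w1 + w2
        t = np.arange(0.0, width + dt / 2, dt)
        s = np.where(
            t <= w1,
            np.sin(np.pi * t / w1),
            -(w1 / w2) * np.sin(np.pi * np.clip(t - w1, 0, w2) / w2),
        )
    else:
        raise ValueError(f"unknown waveform shape {shape!r}")
    s[-1] = 0.0
    peak = np.max(np.abs(s))
    if peak > 0 and amplitude > 0:
        s = s / peak
    elif amplitude == 0:
        s = np.zeros_like(s)
    return Waveform(shape=shape, amplitude=amplitude, times=t, scale=s,
                    pulse_width=float(t[-1]))


@dataclass(frozen=True)
class SynapticActivation:
    """A presynaptic release event at ``time`` on a subset of synapses.

    ``target``: "all" (every excitatory and inhibitory synapse), "excitatory",
    or a frozenset of :class:`RegionLabel` restricting excitatory synapses to
    sections with those labels (inhibitory synapses are included for region
    targets only when ``include_inhibitory``).
    """

    time: float
    target: object = "all"
    include_inhibitory: bool = True


@dataclass(frozen=True)
class CurrentInjection:
    time: float
    duration: float
    amplitude_nA: float
    location: str = "soma"


@dataclass
class Protocol:
    field_pulses: list[tuple[float, Waveform, FieldVector]] = field(default_factory=list)
    synaptic_activations: list[SynapticActivation] = field(default_factory=list)
    current_injections: list[CurrentInjection] = field(default_factory=list)
    background_rate: float = 0.0        # Hz per synapse
    background_seed: int = 0
    duration: float = 0.0               # ms

    def validate(self):
        for onset, wf, _ in self.field_pulses:
            if onset < 0 or onset >= self.duration:
                raise ValueError(f"pulse onset {onset} outside [0, {self.duration})")
        for act in self.synaptic_activations:
            if act.time < 0 or act.time >= self.duration:
                raise ValueError(f"activation at {act.time} outside [0, {self.duration})")

    def descriptor(self) -> dict:
        return {
            "n_field_pulses": len(self.field_pulses),
            "n_synaptic_activations": len(self.synaptic_activations),
            "n_current_injections": len(self.current_injections),
            "background_rate_hz": self.background_rate,
            "background_seed": self.background_seed,
            "duration_ms": self.duration,
            "amplitudes_vm": sorted({wf.amplitude for _, wf, _ in self.field_pulses}),
            "shapes": sorted({wf.shape for _, wf, _ in self.field_pulses}),
        }


@dataclass
class QuasipotentialMap:
    """Per-compartment Ve (mV) at unit waveform scale."""

    ve_mv: np.ndarray

    def scaled(self, scale: float) -> np.ndarray:
        return self.ve_mv * scale


def quasipotentials(cell, fld: FieldVector) -> QuasipotentialMap:
    """Uniform-field quasipotential Ve_i = -E · r_i per compartment.

    ``cell`` provides compartment centre coordinates in µm (attribute
    ``coords``, shape (n, 3)); E is in V/m, so with r in metres
    Ve[V] = -(E·r), returned in mV: ``-(E·r_µm) * 1e-6 * 1e3``.
    """
    coords_m = np.asarray(cell.coords, float) * 1e-6
    ve_v = -(coords_m @ fld.as_array())
    return QuasipotentialMap(ve_mv=ve_v * 1e3)


def build_train(
    frequency: float,
    n_pulses: int,
    waveform: Waveform,
    fld: FieldVector,
    delay: float = SYNAPTIC_DELAY_MS,
    background_rate: float = 0.0,
    background_seed: int = 0,
    duration: float | None = None,
) -> Protocol:
    """A constant-frequency pulse train with all-synapse co-activation.

    Pulse onsets at k/frequency (k = 0..n-1); every pulse is paired with a
    delayed activation of all synapses (excitatory and inhibitory).
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    period = 1000.0 / frequency
    onsets = np.arange(n_pulses) * period
    needed = float(onsets[-1] + period)
    if duration is None:
        duration = needed
    elif duration < needed:
        warnings.warn(
            f"protocol duration extended from {duration} to {needed} ms to fit train"
        )
        duration = needed
    proto = Protocol(
        field_pulses=[(float(t), waveform, fld) for t in onsets],
        background_rate=background_rate,
        background_seed=background_seed,
        duration=duration,
    )
    return attach_synaptic_delay(proto, delay)


def build_tbs(
    waveform: Waveform,
    fld: FieldVector,
    n_bursts: int = 15,
    pulses_per_burst: int = 5,
    intra_burst_hz: float = 100.0,
    burst_gap: float = 100.0,
    gap_is_onset_interval: bool = False,
    delay: float = SYNAPTIC_DELAY_MS,
    background_rate: float = 0.0,
    background_seed: int = 0,
) -> Protocol:
    """Theta-burst protocol: bursts of high-frequency pulses.

    Default 15 bursts of 5 stimuli at 100 Hz.  ``burst_gap`` is the silent
    interval between the last stimulus of one burst and the first of the
    next (100 ms default, i.e. a 140 ms burst period); set
    ``gap_is_onset_interval`` to interpret it as the onset-to-onset period
    instead.
    """
    isi = 1000.0 / intra_burst_hz
    span = (pulses_per_burst - 1) * isi
    period = burst_gap if gap_is_onset_interval else span + burst_gap
    onsets = []
    for b in range(n_bursts):
        for k in range(pulses_per_burst):
            onsets.append(b * period + k * isi)
    duration = onsets[-1] + period
    proto = Protocol(
        field_pulses=[(float(t), waveform, fld) for t in onsets],
        background_rate=background_rate,
        background_seed=background_seed,
        duration=duration,
    )
    return attach_synaptic_delay(proto, delay)


def attach_synaptic_delay(protocol: Protocol, delay: float = SYNAPTIC_DELAY_MS) -> Protocol:
    """Pair every field pulse with a delayed all-synapse activation.

    Models the presynaptic volley evoked by the pulse: excitatory and
    inhibitory synapses all release ``delay`` ms after pulse onset.
    Replaces any previously attached pulse-locked activations.
    """
    if delay < 0:
        raise ValueError("synaptic delay must be >= 0")
    acts = [
        SynapticActivation(time=onset + delay, target="all")
        for onset, _, _ in protocol.field_pulses
    ]
    out = replace(protocol, synaptic_activations=acts)
    out.duration = max(out.duration, max((a.time for a in acts), default=0.0) + 1.0)
    return out


def poisson_background(
    rate: float, duration: float, seed: int, n_synapses: int
) -> list[np.ndarray]:
    """Independent homogeneous Poisson event trains, one per synapse.

    ``rate`` in Hz, ``duration`` in ms; reproducible by ``seed``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_synapses):
        if rate == 0:
            trains.append(np.empty(0))
            continue
        mean_gap = 1000.0 / rate
        n_guess = max(16, int(2 * duration / mean_gap) + 8)
        gaps = rng.exponential(mean_gap, size=n_guess)
        t = np.cumsum(gaps)
        while t[-1] < duration:
            extra = rng.exponential(mean_gap, size=n_guess)
            t = np.concatenate([t, t[-1] + np.cumsum(extra)])
        trains.append(t[t < duration])
    return trains


def local_electrical_stim(
    target_region: set[RegionLabel] | frozenset[RegionLabel],
    pattern: str = "train",
    frequency: float = 1.0,
    n_events: int = 0,
    n_bursts: int = 15,
    pulses_per_burst: int = 5,
    intra_burst_hz: float = 100.0,
    burst_gap: float = 100.0,
    include_inhibitory: bool = True,
    background_rate: float = 0.0,
    background_seed: int = 0,
) -> Protocol:
    """Local electrical afferent stimulation: synaptic volleys, no field.

    Synchronously activates all synapses on sections in ``target_region``
    (classical electrode stimulation of afferent axons).  ``pattern`` is
    ``"train"`` (``n_events`` at ``frequency``) or ``"tbs"`` (theta-burst
    timing).  Inhibitory synapses receive the same volley only when
    ``include_inhibitory`` (disabling them models a disinhibited slice).
    """
    target = frozenset(target_region)
    if not target:
        raise ValueError("target region set must not be empty")
    if pattern == "train":
        period = 1000.0 / frequency
        times = [k * period for k in range(n_events)]
        duration = (times[-1] + period) if times else 1.0
    elif pattern == "tbs":
        isi = 1000.0 / intra_burst_hz
        period = (pulses_per_burst - 1) * isi + burst_gap
        times = [
            b * period + k * isi
            for b in range(n_bursts)
            for k in range(pulses_per_burst)
        ]
        duration = times[-1] + period
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    acts = [
        SynapticActivation(time=t, target=target, include_inhibitory=include_inhibitory)
        for t in times
    ]
    return Protocol(
        synaptic_activations=acts,
        background_rate=background_rate,
        background_seed=background_seed,
        duration=duration,
    )


def pairing_protocol(
    n_pre: int,
    n_post: int,
    pairs: int = 60,
    pair_interval: float = 1000.0,
    burst_hz: float = 100.0,
    pre_post_lag: float = 0.0,
    injection_nA: float = 2.0,
    injection_ms: float = 2.0,
    target_region: frozenset[RegionLabel] | None = None,
) -> Protocol:
    """Pre/post pairing paradigm: presynaptic events vs somatic spike bursts.

    ``n_pre`` presynaptic release events (at ``burst_hz`` when > 1) are
    paired with ``n_post`` suprathreshold somatic current injections,
    repeated ``pairs`` times every ``pair_interval`` ms.
    """
    if n_pre not in (1, 3) or n_post not in (1, 3):
        raise ValueError("n_pre and n_post must be 1 or 3")
    isi = 1000.0 / burst_hz
    target = target_region if target_region is not None else "excitatory"
    acts: list[SynapticActivation] = []
    injs: list[CurrentInjection] = []
    for p in range(pairs):
        t0 = p * pair_interval
        for k in range(n_pre):
            acts.append(SynapticActivation(
                time=t0 + k * isi, target=target, include_inhibitory=False))
        for k in range(n_post):
            injs.append(CurrentInjection(
                time=t0 + pre_post_lag + k * isi,
                duration=injection_ms, amplitude_nA=injection_nA))
    duration = pairs * pair_interval if pairs else 1.0
    return Protocol(
        synaptic_activations=acts,
        current_injections=injs,
        duration=duration,
    )
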