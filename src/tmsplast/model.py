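"""Assembly of the full simulatable model: cell + biophysics + synapses.

A :class:`Model` bundles the discretised reduced CA1 cell, its channel
kinetics, the placed synapse population and the plasticity parameters, plus
any pharmacological modifications (stored as kernel flags / conductance
edits).  Models are cheap to copy, so perturbations operate on copies.

The default construction uses the calibrated simulation profile: Table-set
synapse constants with the pathway amplitudes and base conductance set by
the behavioural calibration described in the methods notes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .cable import (
    DiscretizedCell,
    KernelInputs,
    RunResult,
    SimConfig,
    StateVector,
    discretize,
    init_state,
    run as cable_run,
)
from .membrane import BiophysicsMap, KineticsConfig, assign_biophysics
from .morphology import GeometryConfig, Morphology, build_reduced_ca1
from .stimulation import Protocol
from .synapses import PlasticSynapseParams, SynapsePopulation, place_synapses

__all__ = ["Model", "build_model", "CALIBRATED_AMPLITUDES", "calibrated_params"]


#: calibrated pathway amplitudes and base conductance (simulation profile).
#: The four amplitudes and g_base are the free parameters of the plasticity
#: rule; they are tuned so that the 10 Hz / 900-pulse uniform-field protocol
#: reproduces the reference plasticity magnitudes (see docs/methods.md).
CALIBRATED_AMPLITUDES: dict[str, float] = {
    "A_pre_plus": 5.5e-5,
    "A_pre_minus": 1.55e-7,
    "A_post_plus": 1.2e-5,
    "A_post_minus": 3.1e-7,
    "g_base": 0.01,
    "C_gain": 1.8,
    "C_usat": 1e6,
}


def calibrated_params(**overrides) -> PlasticSynapseParams:
    kw = dict(CALIBRATED_AMPLITUDES)
    kw.update(overrides)
    return PlasticSynapseParams(**kw)


@dataclass
class Model:
    morph: Morphology
    biophys: BiophysicsMap
    cell: DiscretizedCell
    kinetics: KineticsConfig
    population: SynapsePopulation
    syn_params: PlasticSynapseParams
    # pharmacology state
    snmda_scale: float = 1.0
    force_C_zero: bool = False
    force_Nalpha_zero: bool = False
    freeze_ca: bool = False
    tonic_g: float = 0.0            # S/cm² on somatodendritic membrane
    applied_perturbations: tuple = ()

    def copy(self) -> "Model":
        new = copy.copy(self)
        new.cell = replace(
            self.cell, gbar_dens=self.cell.gbar_dens.copy()
        )
        new.population = copy.deepcopy(self.population)
        new.syn_params = replace(self.syn_params)
        return new

    def g_tonic_us(self) -> np.ndarray:
        from .morphology import RegionLabel

        out = np.zeros(self.cell.n)
        if self.tonic_g > 0:
            mask = self.cell.comp_of_region([
                RegionLabel.SOMA, RegionLabel.APICAL_TRUNK, RegionLabel.OBLIQUE,
                RegionLabel.TUFT, RegionLabel.BASAL,
            ])
            out[mask] = self.tonic_g * self.cell.area[mask] * 1e6
        return out

    def kernel_inputs(self) -> KernelInputs:
        return KernelInputs(
            cell=self.cell,
            kinetics=self.kinetics,
            syn_params=self.syn_params,
            population=self.population,
            g_tonic_us=self.g_tonic_us(),
            snmda_scale=self.snmda_scale,
            force_C_zero=self.force_C_zero,
            force_Nalpha_zero=self.force_Nalpha_zero,
            freeze_ca=self.freeze_ca,
        )

    def init_state(self, v0: float = -70.0) -> StateVector:
        return init_state(self.cell, self.kinetics, self.population, v0=v0)

    def run(self, protocol: Protocol, sim: SimConfig | None = None) -> RunResult:
        sim = sim or SimConfig()
        return cable_run(self.kernel_inputs(), protocol, sim)

    def resting_potential(self, settle_ms: float = 500.0, dt: float = 0.025) -> float:
        """Somatic resting potential after a stimulation-free settling run."""
        from . import _kernels
        from .cable import _kernel_call
        from .morphology import RegionLabel

        state = self.init_state()
        sim = SimConfig(dt=dt, settle_time=0.0)
        _kernel_call(self.kernel_inputs(), state, None, sim,
                     int(round(settle_ms / dt)), False,
                     np.empty(0, dtype=np.int64), 0, 0)
        soma = self.cell.comp_of_region([RegionLabel.SOMA])[0]
        return float(state.v[soma])


def build_model(
    placement_seed: int = 0,
    weight_seed: int = 0,
    n_exc: int = 128,
    n_inh: int = 18,
    geometry: GeometryConfig | None = None,
    table: BiophysicsMap | None = None,
    kinetics: KineticsConfig | None = None,
    syn_params: PlasticSynapseParams | None = None,
    max_seg_length: float = 20.0,
) -> Model:
    """Build the default reduced CA1 model with placed synapses."""
    morph = build_reduced_ca1(geometry)
    biophys = assign_biophysics(morph, table)
    cell = discretize(morph, biophys, max_seg_length)
    params = syn_params if syn_params is not None else calibrated_params()
    population = place_synapses(
        morph, n_exc=n_exc, n_inh=n_inh,
        placement_seed=placement_seed, weight_seed=weight_seed, params=params,
    )
    return Model(
        morph=morph,
        biophys=biophys,
        cell=cell,
        kinetics=kinetics or KineticsConfig(),
        population=population,
        syn_params=params,
    )
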