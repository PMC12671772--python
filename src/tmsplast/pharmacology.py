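"""In-silico pharmacology: composable perturbations of the assembled model.

Each perturbation is a declarative parameter modification mirroring a bath /
local drug application:

* ``bicuculline`` — GABA-A antagonist: all inhibitory synaptic weights 0.
* ``ttx_dendritic`` — local TTX on the dendrites: dendritic sodium
  conductances 0, soma and axon untouched.
* ``ttx_all`` — TTX everywhere (soma, dendrites and axon).
* ``nmda_block`` — NMDA receptor antagonist: the NMDA fraction of the
  synaptic conductance is removed (``S_NMDA`` scale 0) and the internal
  variables C and Nα are clamped to zero each step.  This is the only
  perturbation that changes the baseline synaptic conductance.
* ``ltype_block`` — L-type calcium channel antagonist: gCaL 0 everywhere
  and Nα clamped to zero each step.
* ``calcium_free`` — calcium-free bath: every calcium influx mechanism off
  (CaT/CaL/CaN conductances 0, the calcium pool frozen at rest) and the
  calcium-linked synaptic variables C and Nα clamped to zero.
* ``tonic_inhibition`` — extrasynaptic GABA-A: a uniform leak conductance
  ``tonic_g`` (S/cm², reversal -75 mV) over the somatodendritic membrane.

Perturbations are idempotent and commute; ``control`` is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Model
from .morphology import RegionLabel

__all__ = ["Perturbation", "apply", "tonic_current_report", "PERTURBATION_KINDS"]

PERTURBATION_KINDS = (
    "control",
    "bicuculline",
    "ttx_dendritic",
    "ttx_all",
    "nmda_block",
    "ltype_block",
    "calcium_free",
    "tonic_inhibition",
)

_DENDRITES = (RegionLabel.APICAL_TRUNK, RegionLabel.OBLIQUE,
              RegionLabel.TUFT, RegionLabel.BASAL)


@dataclass(frozen=True)
class Perturbation:
    kind: str
    tonic_g: float = 0.0    # S/cm², only for tonic_inhibition

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


def apply(model: Model, perturbation: Perturbation | str) -> Model:
    """Return a modified copy of ``model`` with the perturbation applied."""
    if isinstance(perturbation, str):
        perturbation = Perturbation(perturbation)
    m = model.copy()
    kind = perturbation.kind
    cell = m.cell

    if kind == "control":
        pass
    elif kind == "bicuculline":
        for syn in m.population.inhibitory:
            syn.weight = 0.0
    elif kind == "ttx_dendritic":
        mask = cell.comp_of_region(_DENDRITES)
        cell.gbar_dens[0, mask] = 0.0
    elif kind == "ttx_all":
        cell.gbar_dens[0, :] = 0.0
    elif kind == "nmda_block":
        m.snmda_scale = 0.0
        m.force_C_zero = True
        m.force_Nalpha_zero = True
    elif kind == "ltype_block":
        cell.gbar_dens[7, :] = 0.0      # CaL row in CHANNEL_ORDER
        m.force_Nalpha_zero = True
    elif kind == "calcium_free":
        cell.gbar_dens[6:9, :] = 0.0    # CaT, CaL, CaN
        m.freeze_ca = True
        m.force_C_zero = True
        m.force_Nalpha_zero = True
    elif kind == "tonic_inhibition":
        if perturbation.tonic_g < 0:
            raise ValueError("tonic_g must be >= 0")
        m.tonic_g = perturbation.tonic_g

    m.applied_perturbations = model.applied_perturbations + (kind,)
    return m


def tonic_current_report(model: Model, tonic_g: float,
                         v_rest: float | None = None) -> float:
    """Total tonic GABA-A current (pA) at rest for conductance ``tonic_g``.

    ``sum(tonic_g * area * (v_rest + 75))`` over the somatodendritic
    membrane; ``v_rest`` defaults to the model's settled somatic potential.
    """
    if tonic_g == 0:
        return 0.0
    if v_rest is None:
        v_rest = model.resting_potential()
    mask = model.cell.comp_of_region(
        (RegionLabel.SOMA,) + _DENDRITES)
    area = model.cell.area[mask].sum()              # cm²
    i_amp = tonic_g * area * (v_rest + 75.0) * 1e-3  # S * V = A
    return float(i_amp * 1e12)                       # pA
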