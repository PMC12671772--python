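"""Experiment orchestration and distance-resolved plasticity analysis.

Provides the synapse masks used in the analyses (proximal stratum radiatum,
Schaffer-collateral inputs), per-run weight-change summaries and distance
profiles, the SEM-normalised error against experimental reference means,
multi-placement experiment recipes with on-disk artifacts, and small
deterministic fixtures for unit tests.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cable import RunResult, SimConfig, VoltageTrace
from .model import Model, build_model
from .morphology import (
    CellLocation,
    GeometryConfig,
    Morphology,
    RegionLabel,
    build_reduced_ca1,
    path_distance,
)
from .pharmacology import Perturbation, apply as apply_perturbation
from .stimulation import (
    DEFAULT_FIELD_DIRECTION,
    FieldVector,
    Protocol,
    build_tbs,
    build_train,
    local_electrical_stim,
    make_waveform,
    pairing_protocol,
)
from .synapses import SynapsePopulation

__all__ = [
    "RunSummary",
    "DistanceProfile",
    "FitResult",
    "ExperimentRecipe",
    "proximal_mask",
    "distal_sr_mask",
    "schaffer_mask",
    "weight_change_summary",
    "normalized_rmse",
    "run_experiment",
    "make_fixture",
    "standard_protocol",
]

SCHEMA_VERSION = 1

SCHAFFER_LAYERS = {"stratum_oriens", "stratum_radiatum"}


def proximal_mask(population: SynapsePopulation, morph: Morphology) -> np.ndarray:
    """Proximal stratum-radiatum synapses.

    True for synapses on the first half of the apical trunk (by somatic path
    distance) and on obliques attached within that first half.
    """
    trunk = morph.by_label(RegionLabel.APICAL_TRUNK)
    trunk_total = sum(s.length for s in trunk)
    half = trunk_total / 2.0
    out = np.zeros(len(population.excitatory), dtype=bool)
    for i, syn in enumerate(population.excitatory):
        sec = morph.sections[syn.location.section_id]
        if sec.label is RegionLabel.APICAL_TRUNK:
            out[i] = path_distance(morph, syn.location) <= half
        elif sec.label is RegionLabel.OBLIQUE:
            attach = morph.section_start_distance(sec.id)
            out[i] = attach <= half
    return out


def distal_sr_mask(population: SynapsePopulation, morph: Morphology) -> np.ndarray:
    """Stratum-radiatum synapses that are not proximal."""
    layers = np.array(population.layers(morph))
    return (layers == "stratum_radiatum") & ~proximal_mask(population, morph)


def schaffer_mask(population: SynapsePopulation, morph: Morphology | None = None,
                  include_oriens: bool = True) -> np.ndarray:
    """Schaffer-collateral synapses: strata oriens + radiatum inputs.

    CA3 axons target both basal (oriens) and proximal apical (radiatum)
    dendrites; tuft synapses belong to the perforant path.  Set
    ``include_oriens=False`` for the radiatum-only reading.
    """
    if morph is None:
        raise ValueError("schaffer_mask requires the morphology")
    layers = np.array(population.layers(morph))
    if include_oriens:
        return np.isin(layers, sorted(SCHAFFER_LAYERS))
    return layers == "stratum_radiatum"


@dataclass
class RunSummary:
    per_synapse: pd.DataFrame       # id, layer, distance, before, after, pct
    group_means: dict[str, float]
    protocol: dict
    seeds: dict
    perturbations: tuple = ()

    def to_json_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "group_means": self.group_means,
            "protocol": self.protocol,
            "seeds": self.seeds,
            "perturbations": list(self.perturbations),
        }


@dataclass
class DistanceProfile:
    distances_um: np.ndarray
    pct_change: np.ndarray
    layers: np.ndarray
    binned: pd.DataFrame            # per-layer mean pct


@dataclass
class FitResult:
    conditions: list
    model_means: np.ndarray
    data_means: np.ndarray
    data_sems: np.ndarray
    normalized_errors: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.conditions,
            "model_mean_pct": self.model_means,
            "data_mean_pct": self.data_means,
            "data_sem_pct": self.data_sems,
            "normalized_error": self.normalized_errors,
        })


def weight_change_summary(
    model: Model, result: RunResult, extra_masks: dict | None = None
) -> tuple[RunSummary, DistanceProfile]:
    """Per-synapse % weight changes with group means and a distance profile.

    ``Δ% = 100 (after - before) / before`` with *before* the effective
    weight at the end of settling.
    """
    if result.w_pre.size == 0 and result.final_state.es_state.size == 0:
        raise ValueError("run has no weight records")
    pop, morph = model.population, model.morph
    before = result.baseline_effective()
    after = result.final_effective()
    pct = 100.0 * (after - before) / before
    dist = pop.path_distances(morph)
    layers = np.array(pop.layers(morph))

    df = pd.DataFrame({
        "synapse_id": np.arange(len(pct)),
        "layer": layers,
        "path_distance_um": dist,
        "w_eff_before": before,
        "w_eff_after": after,
        "pct_change": pct,
    })

    masks = {
        "all": np.ones(len(pct), dtype=bool),
        "schaffer": schaffer_mask(pop, morph),
        "proximal_sr": proximal_mask(pop, morph),
        "distal_sr": distal_sr_mask(pop, morph),
        "oriens": layers == "stratum_oriens",
        "radiatum": layers == "stratum_radiatum",
        "tuft": layers == "stratum_lacunosum_moleculare",
    }
    if extra_masks:
        masks.update(extra_masks)
    group_means = {
        name: float(pct[m].mean()) if m.any() else float("nan")
        for name, m in masks.items()
    }

    binned = df.groupby("layer")["pct_change"].agg(["mean", "std", "count"])
    summary = RunSummary(
        per_synapse=df,
        group_means=group_means,
        protocol=result.event_log.get("protocol", {}),
        seeds={
            "placement": pop.placement_seed,
            "weights": pop.weight_seed,
            "sim": result.event_log.get("seed", 0),
        },
        perturbations=model.applied_perturbations,
    )
    profile = DistanceProfile(
        distances_um=dist, pct_change=pct, layers=layers, binned=binned
    )
    return summary, profile


def normalized_rmse(model_means, data_means, data_sems) -> np.ndarray:
    """Per-condition error |model - data| normalised by the data SEM."""
    m = np.asarray(model_means, float)
    d = np.asarray(data_means, float)
    s = np.asarray(data_sems, float)
    if not (m.shape == d.shape == s.shape):
        raise ValueError("model, data and SEM vectors must have equal length")
    if np.any(s <= 0):
        raise ValueError("SEMs must be > 0")
    return np.abs(m - d) / s


def fit_to_reference(model_means, reference_csv, conditions=None) -> FitResult:
    """Score model means against a user-supplied reference CSV.

    The CSV needs columns ``condition, mean_pct, sem_pct``.
    """
    ref = pd.read_csv(reference_csv)
    if conditions is not None:
        ref = ref.set_index("condition").loc[list(conditions)].reset_index()
    err = normalized_rmse(model_means, ref["mean_pct"], ref["sem_pct"])
    return FitResult(
        conditions=list(ref["condition"]),
        model_means=np.asarray(model_means, float),
        data_means=ref["mean_pct"].to_numpy(),
        data_sems=ref["sem_pct"].to_numpy(),
        normalized_errors=err,
    )


# ---------------------------------------------------------------------------
# Standard protocols and experiment recipes
# ---------------------------------------------------------------------------


def standard_protocol(
    name: str,
    frequency: float = 10.0,
    n_pulses: int = 900,
    amplitude: float = 275.0,
    shape: str = "monophasic",
    field_direction=DEFAULT_FIELD_DIRECTION,
    background_rate: float = 3.0,
    background_seed: int = 0,
    include_inhibitory: bool = True,
    target: str = "schaffer",
) -> Protocol:
    """Build one of the named study protocols.

    ``rms_train``: uniform-field pulse train with 1 ms-delayed all-synapse
    co-activation and Poisson background.  ``rms_tbs``: theta-burst version.
    ``electrical_train`` / ``electrical_tbs``: local afferent stimulation of
    the Schaffer (oriens + radiatum) or perforant-path (tuft) targets.
    """
    fld = FieldVector.along(field_direction, amplitude)
    wf = make_waveform(shape, amplitude)
    targets = {
        "schaffer": frozenset({RegionLabel.BASAL, RegionLabel.APICAL_TRUNK,
                               RegionLabel.OBLIQUE}),
        "perforant": frozenset({RegionLabel.TUFT}),
    }
    if name == "rms_train":
        return build_train(frequency, n_pulses, wf, fld,
                           background_rate=background_rate,
                           background_seed=background_seed)
    if name == "rms_tbs":
        return build_tbs(wf, fld, background_rate=background_rate,
                         background_seed=background_seed)
    if name == "electrical_train":
        return local_electrical_stim(
            targets[target], "train", frequency=frequency, n_events=n_pulses,
            include_inhibitory=include_inhibitory,
            background_rate=background_rate, background_seed=background_seed)
    if name == "electrical_tbs":
        return local_electrical_stim(
            targets[target], "tbs", include_inhibitory=include_inhibitory,
            background_rate=background_rate, background_seed=background_seed)
    raise ValueError(f"unknown protocol name {name!r}")


@dataclass
class ExperimentRecipe:
    name: str
    protocol: str = "rms_train"
    frequency: float = 10.0
    n_pulses: int = 900
    amplitude: float = 275.0
    shape: str = "monophasic"
    perturbations: tuple = ()
    tonic_g: float = 0.0
    n_placements: int = 10
    base_seed: int = 0
    target: str = "schaffer"
    include_inhibitory: bool = True
    dt: float = 0.025
    settle_ms: float = 1000.0

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _apply_recipe_perturbations(model: Model, recipe: ExperimentRecipe) -> Model:
    for kind in recipe.perturbations:
        pert = Perturbation(kind, tonic_g=recipe.tonic_g) \
            if kind == "tonic_inhibition" else Perturbation(kind)
        model = apply_perturbation(model, pert)
    return model


def run_experiment(recipe: ExperimentRecipe, out_dir) -> dict:
    """Run a recipe over seeded placements and write artifacts to disk.

    Writes one per-placement summary CSV, an aggregate JSON (means ± sd
    across placements per group) and a log with the resolved configuration
    and its content hash.  Identical recipes and seeds give identical
    aggregate artifacts.
    """
    valid_protocols = {"rms_train", "rms_tbs", "electrical_train", "electrical_tbs"}
    if recipe.protocol not in valid_protocols:
        raise ValueError(f"unknown protocol name {recipe.protocol!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = _time.time()

    group_records = []
    for k in range(recipe.n_placements):
        placement_seed = recipe.base_seed + k
        model = build_model(placement_seed=placement_seed,
                            weight_seed=recipe.base_seed)
        model = _apply_recipe_perturbations(model, recipe)
        proto = standard_protocol(
            recipe.protocol, frequency=recipe.frequency,
            n_pulses=recipe.n_pulses, amplitude=recipe.amplitude,
            shape=recipe.shape, background_seed=placement_seed,
            include_inhibitory=recipe.include_inhibitory, target=recipe.target)
        sim = SimConfig(dt=recipe.dt, settle_time=recipe.settle_ms,
                        seed=placement_seed)
        try:
            result = model.run(proto, sim)
        except Exception:
            (out / "INVALID").write_text(
                f"placement {k} (seed {placement_seed}) failed mid-run\n")
            raise
        summary, _ = weight_change_summary(model, result)
        summary.per_synapse.to_csv(out / f"placement_{k:02d}.csv", index=False)
        group_records.append(summary.group_means)

    groups = pd.DataFrame(group_records)
    aggregate = {
        "schema_version": SCHEMA_VERSION,
        "recipe": asdict(recipe),
        "config_hash": recipe.content_hash(),
        "n_placements": recipe.n_placements,
        "group_mean_pct": {c: float(groups[c].mean()) for c in groups.columns},
        "group_sd_pct": {
            c: (float(groups[c].std(ddof=1)) if len(groups) > 1 else 0.0)
            for c in groups.columns
        },
    }
    (out / "aggregate.json").write_text(json.dumps(aggregate, indent=2,
                                                   sort_keys=True))
    log = {
        "config_hash": recipe.content_hash(),
        "recipe": asdict(recipe),
        "wall_clock_s": round(_time.time() - t_start, 3),
        "schema_version": SCHEMA_VERSION,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return aggregate


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, dt: float = 0.025):
    """Deterministic small inputs for unit tests.

    * ``passive_cylinder`` — a soma + unbranched cable morphology with an
      all-passive conductance table (analytic cable solutions apply).
    * ``tiny_morphology`` — 3-section cell, < 20 compartments at 20 µm.
    * ``stdp_voltage_trace`` — 200 ms local-voltage trace with a spike
      waveform 10 ms after a presynaptic event marker.
    * ``burst_voltage_trace`` — like stdp but a 3-spike 100 Hz burst.
    """
    if kind == "passive_cylinder":
        from .membrane import BiophysicsMap, EPAS_RULE
        from .morphology import Section

        sections = {
            0: Section(0, None, RegionLabel.SOMA, 10.0, 2.0, 2.0,
                       np.array([[0.0, -5.0, 0.0], [0.0, 5.0, 0.0]])),
            1: Section(1, 0, RegionLabel.APICAL_TRUNK, 1000.0, 2.0, 2.0,
                       np.array([[0.0, 5.0, 0.0], [0.0, 1005.0, 0.0]])),
        }
        morph = Morphology(sections=sections)
        table = BiophysicsMap(
            gbar={},
            cm={r: 1.0 for r in RegionLabel},
            ra={r: 100.0 for r in RegionLabel},
            gpas={r: 1e-4 for r in RegionLabel},
            epas={r: -70.0 for r in RegionLabel},
        )
        return morph, table
    if kind == "tiny_morphology":
        from .morphology import Section

        sections = {
            0: Section(0, None, RegionLabel.SOMA, 20.0, 20.0, 20.0,
                       np.array([[0.0, -10.0, 0.0], [0.0, 10.0, 0.0]])),
            1: Section(1, 0, RegionLabel.APICAL_TRUNK, 100.0, 2.0, 2.0,
                       np.array([[0.0, 10.0, 0.0], [0.0, 110.0, 0.0]])),
            2: Section(2, 1, RegionLabel.TUFT, 100.0, 1.0, 1.0,
                       np.array([[0.0, 110.0, 0.0], [0.0, 210.0, 0.0]])),
        }
        return Morphology(sections=sections)
    if kind in ("stdp_voltage_trace", "burst_voltage_trace"):
        t = np.arange(0.0, 200.0, dt)
        v = np.full_like(t, -70.0)
        pre_time = 50.0
        n_spk = 1 if kind == "stdp_voltage_trace" else 3
        for k in range(n_spk):
            t_spk = pre_time + 10.0 + k * 10.0
            m = (t >= t_spk) & (t < t_spk + 2.0)
            v[m] = -70.0 + 110.0 * np.exp(-(t[m] - t_spk) / 0.8)
        pre_steps = np.array([int(pre_time / dt)])
        return t, v, pre_steps
    raise ValueError(f"unknown fixture kind {kind!r}")
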