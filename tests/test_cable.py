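import math

import numpy as np
import pytest

from tmsplast.cable import (
    KernelInputs,
    SimConfig,
    VoltageTrace,
    _kernel_call,
    detect_spikes,
    discretize,
    init_state,
    run,
)
from tmsplast.experiments import make_fixture, standard_protocol
from tmsplast.membrane import BiophysicsMap, KineticsConfig
from tmsplast.model import build_model
from tmsplast.morphology import CellLocation, Morphology, RegionLabel, Section
from tmsplast.stimulation import (
    DEFAULT_FIELD_DIRECTION,
    CurrentInjection,
    FieldVector,
    Protocol,
    build_train,
    make_waveform,
)


def _passive_cell(max_seg=20.0):
    morph, table = make_fixture("passive_cylinder")
    return discretize(morph, table, max_seg)


class TestDiscretize:
    def test_segment_count_ceiling(self, morph, biophys):
        cell = discretize(morph, biophys, max_seg_length=20.0)
        trunk = morph.by_label(RegionLabel.APICAL_TRUNK)
        n_trunk = sum((cell.sec_id == s.id).sum() for s in trunk)
        assert n_trunk >= 20          # 400 um at <= 20 um per compartment

    def test_axial_conductance_halves_with_length(self):
        # uniform cylinder: g = pi r^2 / (Ra L)
        morph, table = make_fixture("passive_cylinder")
        c1 = discretize(morph, table, max_seg_length=20.0)
        c2 = discretize(morph, table, max_seg_length=40.0)
        # interior couplings within the uniform cable
        g1 = np.median(c1.g_pa[2:])
        g2 = np.median(c2.g_pa[2:])
        assert g1 == pytest.approx(2 * g2, rel=1e-6)
        r_cm, L_cm, ra = 1.0e-4, 20.0e-4, 100.0
        expected_us = math.pi * r_cm**2 / (ra * L_cm) * 1e6
        assert g1 == pytest.approx(expected_us, rel=1e-6)

    def test_laplacian_row_sums_zero(self, cell):
        L = cell.laplacian()
        assert np.allclose(L.sum(axis=1), 0.0, atol=1e-9)
        assert np.allclose(L, L.T)

    def test_zero_diameter_rejected(self):
        sec = Section(0, None, RegionLabel.SOMA, 10.0, 1.0, 1.0,
                      np.array([[0.0, -5, 0], [0, 5, 0.0]]))
        sec.diam_start = 0.0       # corrupt after validation
        morph = Morphology.__new__(Morphology)
        morph.sections = {0: sec}
        morph.layer_boundaries = {}
        table = BiophysicsMap(
            gbar={}, cm={RegionLabel.SOMA: 1.0}, ra={RegionLabel.SOMA: 100.0},
            gpas={RegionLabel.SOMA: 1e-4}, epas={RegionLabel.SOMA: -70.0})
        with pytest.raises(ValueError, match="diameter"):
            discretize(morph, table)


def _passive_inputs(cell):
    from tmsplast.model import calibrated_params
    return KernelInputs(cell=cell, kinetics=KineticsConfig(),
                        syn_params=calibrated_params(), population=None)


class TestStepAndEquilibrium:
    def test_rest_is_stationary(self):
        cell = _passive_cell()
        ki = _passive_inputs(cell)
        state = init_state(cell, ki.kinetics, None, v0=-70.0)
        sim = SimConfig(settle_time=0.0)
        _kernel_call(ki, state, None, sim, 400, False,
                     np.empty(0, dtype=np.int64), 0, 0)
        assert np.allclose(state.v, -70.0, atol=1e-9)

    def test_uniform_ve_is_silent(self):
        cell = _passive_cell()
        ki = _passive_inputs(cell)
        # constant-coordinate cell => uniform Ve under any field
        cellu = discretize(*make_fixture("passive_cylinder"))
        cellu.coords[:] = [50.0, 20.0, -10.0]
        kiu = _passive_inputs(cellu)
        wf = make_waveform("monophasic", 300.0)
        fld = FieldVector.along((0, 1, 0), 300.0)
        proto = build_train(100.0, 1, wf, fld, delay=0.0)
        proto.synaptic_activations = []
        sim = SimConfig(settle_time=10.0, duration=5.0)
        res = run(kiu, proto, sim)
        tr = list(res.traces.values())[0]
        assert np.allclose(tr.values, tr.values[0], atol=1e-9)

    def test_gauge_invariance_of_coordinate_offset(self):
        """Shifting all coordinates adds a constant to Ve and must not
        change the voltage trajectory."""
        wf = make_waveform("monophasic", 250.0)
        fld = FieldVector.along(DEFAULT_FIELD_DIRECTION, 250.0)
        proto = build_train(100.0, 1, wf, fld)
        proto.synaptic_activations = []
        sim = SimConfig(settle_time=50.0, duration=8.0)

        cell_a = _passive_cell()
        res_a = run(_passive_inputs(cell_a), proto, sim)
        cell_b = _passive_cell()
        cell_b.coords = cell_b.coords + np.array([123.0, -77.0, 31.0])
        res_b = run(_passive_inputs(cell_b), proto, sim)
        va = list(res_a.traces.values())[0].values
        vb = list(res_b.traces.values())[0].values
        assert np.allclose(va, vb, atol=1e-9)


class TestPassiveCableAnalytic:
    def test_steady_state_cosh_profile(self):
        """Sealed-end cable under steady end current: the interior profile
        decays as cosh((L - x)/lambda); compare pointwise ratios within 1%."""
        morph, table = make_fixture("passive_cylinder")
        cell = discretize(morph, table, max_seg_length=5.0)
        ki = _passive_inputs(cell)
        state = init_state(cell, ki.kinetics, None, v0=-70.0)
        proto = Protocol(
            current_injections=[CurrentInjection(0.0, 1e9, 0.05)],
            duration=400.0,
        )
        sim = SimConfig(settle_time=0.0, duration=400.0, record_stride=1000)
        run(ki, proto, sim, state=state)

        lam_um = math.sqrt(1.0e-4 / (2 * 100.0 * 1e-4)) * 1e4   # 707 um
        cable = cell.sec_id == 1
        x = cell.path_dist[cable]
        dv = state.v[cable] + 70.0
        L = 1000.0
        sel = (x > 200) & (x < 900)
        expected = np.cosh((L - x[sel]) / lam_um)
        ratio = dv[sel] / expected
        assert np.std(ratio) / np.mean(ratio) < 0.01


class TestConvergenceAndDeterminism:
    def test_halving_dt_shifts_spike_time_below_100us(self, run_cache):
        wf = make_waveform("monophasic", 275.0)
        fld = FieldVector.along(DEFAULT_FIELD_DIRECTION, 275.0)
        times = {}
        for dt in (0.025, 0.0125):
            model = build_model()
            proto = build_train(50.0, 1, wf, fld)
            proto.synaptic_activations = []
            sim = SimConfig(dt=dt, settle_time=200.0,
                            record=[CellLocation(model.morph.root.id, 0.5)])
            res = model.run(proto, sim)
            spk = detect_spikes(list(res.traces.values())[0])
            assert len(spk) >= 1
            times[dt] = spk[0]
        assert abs(times[0.025] - times[0.0125]) < 0.1

    def test_bit_identical_reruns(self):
        def go():
            model = build_model()
            proto = standard_protocol("rms_train", frequency=10.0, n_pulses=5,
                                      amplitude=275.0, background_seed=4)
            sim = SimConfig(settle_time=100.0)
            res = model.run(proto, sim)
            tr = list(res.traces.values())[0].values
            return tr.copy(), res.final_state.es_state.copy()

        v1, w1 = go()
        v2, w2 = go()
        assert np.array_equal(v1, v2)
        assert np.array_equal(w1, w2)

    def test_backward_euler_scheme_runs(self):
        model = build_model()
        proto = standard_protocol("rms_train", frequency=50.0, n_pulses=1,
                                  amplitude=275.0, background_rate=0.0)
        res = model.run(proto, SimConfig(settle_time=50.0, scheme="be"))
        assert np.all(np.isfinite(list(res.traces.values())[0].values))


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        tr = VoltageTrace(CellLocation(0, 0.5), np.arange(100.0),
                          np.full(100, -70.0))
        assert detect_spikes(tr).size == 0

    def test_single_crossing(self):
        t = np.arange(0, 10, 0.1)
        v = np.full_like(t, -70.0)
        v[30:35] = 20.0
        out = detect_spikes(v, times=t)
        assert len(out) == 1
        assert out[0] == pytest.approx(3.0)

    def test_refractory_lockout(self):
        t = np.arange(0, 5, 0.05)
        v = -70 + 100 * (np.sin(2 * np.pi * t / 0.4) > 0.9)
        out = detect_spikes(v, times=t, refractory=1.0)
        assert np.all(np.diff(out) >= 1.0)


def test_kernel_plasticity_matches_scalar_reference():
    """The compiled population update reproduces the scalar dynamics when
    driven by the same local voltage trace and event times."""
    from tmsplast.synapses import PlasticSynapseState, plasticity_step, \
        synaptic_current, effective_weight

    model = build_model()
    syn_idx = 40
    loc = model.population.excitatory[syn_idx].location
    proto = standard_protocol("rms_train", frequency=10.0, n_pulses=4,
                              amplitude=275.0, background_rate=0.0)
    sim = SimConfig(settle_time=400.0, record=[loc], record_stride=1)
    res = model.run(proto, sim)
    v = list(res.traces.values())[0].values
    dt = sim.dt
    ev_times = [a.time for a in proto.synaptic_activations]
    ev_steps = {int(np.ceil(t / dt - 1e-9)) - 1 for t in ev_times}

    p = model.syn_params
    st = PlasticSynapseState(loc,
                             w_pre=res.w_pre_baseline[syn_idx],
                             w_post=res.w_post_baseline[syn_idx])
    for i in range(len(v)):
        ev = i in ev_steps
        synaptic_current(st, v[i], dt, params=p, pre_event=ev)
        plasticity_step(st, u=v[i], pre_event=ev, dt=dt, params=p)

    got = res.final_state.es_state[syn_idx, 11] * \
        res.final_state.es_state[syn_idx, 12]
    base = res.w_pre_baseline[syn_idx] * res.w_post_baseline[syn_idx]
    assert got - base == pytest.approx(effective_weight(st) - base,
                                       rel=0.05, abs=1e-5)
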