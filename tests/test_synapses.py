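import math

import numpy as np
import pytest

from tmsplast.morphology import RegionLabel
from tmsplast.synapses import (
    InhibitorySynapse,
    PlasticSynapseParams,
    PlasticSynapseState,
    dexp_peak_time,
    effective_weight,
    inhibitory_current,
    init_weights,
    mg_block,
    place_synapses,
    plasticity_step,
    synaptic_current,
)
from tmsplast.morphology import CellLocation


class TestPlacement:
    def test_default_counts(self, morph):
        pop = place_synapses(morph)
        assert len(pop.excitatory) == 128
        assert len(pop.inhibitory) == 18

    def test_layer_allocation(self, morph):
        pop = place_synapses(morph)
        layers = pop.layers(morph)
        assert layers.count("stratum_oriens") == 47
        assert layers.count("stratum_radiatum") == 73
        assert layers.count("stratum_lacunosum_moleculare") == 8

    def test_no_excitatory_on_soma_or_axon(self, morph):
        pop = place_synapses(morph, placement_seed=5)
        banned = {RegionLabel.SOMA, RegionLabel.AIS, RegionLabel.NODE,
                  RegionLabel.MYELIN, RegionLabel.AXON_TERMINAL}
        for s in pop.excitatory:
            assert morph.sections[s.location.section_id].label not in banned

    def test_placement_seed_determinism(self, morph):
        a = place_synapses(morph, placement_seed=3)
        b = place_synapses(morph, placement_seed=3)
        assert [s.location for s in a.excitatory] == \
            [s.location for s in b.excitatory]

    def test_weights_independent_of_placement(self, morph):
        a = place_synapses(morph, placement_seed=1, weight_seed=9)
        b = place_synapses(morph, placement_seed=2, weight_seed=9)
        assert [s.w_pre for s in a.excitatory] == [s.w_pre for s in b.excitatory]

    def test_too_few_synapses_rejected(self, morph):
        with pytest.raises(ValueError):
            place_synapses(morph, n_exc=2)


class TestInitWeights:
    def test_literal_multiplier_reading(self):
        p = PlasticSynapseParams(WMIN=0.22, WMAX=0.22)  # degenerate interval
        w_pre, w_post = init_weights(4, 0, p)
        assert np.allclose(w_pre, 0.11)
        assert np.allclose(w_post, 0.44)

    def test_multiplier_within_interval(self):
        p = PlasticSynapseParams()
        w_pre, w_post = init_weights(500, 2, p)
        m = w_pre / p.w_pre_init
        assert np.all(m >= p.WMIN - 1e-12)
        assert np.all(m <= p.WMAX + 1e-12)

    def test_post_pre_ratio_is_four(self):
        w_pre, w_post = init_weights(64, 1)
        assert np.allclose(w_post / w_pre, 4.0)


class TestSynapticCurrent:
    def test_zero_at_reversal(self):
        state = PlasticSynapseState(CellLocation(0, 0.5))
        i, _ = synaptic_current(state, u=0.0, dt=0.025, pre_event=True)
        assert i == pytest.approx(0.0)

    def test_ampa_peak_time(self):
        # closed-form double-exponential peak for tau 0.2 / 2 ms
        p = PlasticSynapseParams()
        tp = dexp_peak_time(p.tau_A, p.tau_B)
        assert tp == pytest.approx(
            math.log(10.0) * 0.2 * 2.0 / 1.8, rel=1e-12)
        assert tp == pytest.approx(0.5117, abs=5e-4)
        state = PlasticSynapseState(CellLocation(0, 0.5))
        dt = 0.005
        peaks = []
        state, _ = state, None
        synaptic_current(state, -70.0, dt, pre_event=True)
        t, best_t, best_a = 0.0, 0.0, 0.0
        for _ in range(400):
            t += dt
            synaptic_current(state, -70.0, dt)
            a = state.ampa_trace(p)
            if a > best_a:
                best_a, best_t = a, t
        assert best_t == pytest.approx(tp, abs=2 * dt)
        assert best_a == pytest.approx(1.0, abs=0.01)

    def test_mg_block_monotone(self):
        assert mg_block(-70.0) < mg_block(0.0)
        assert 0.0 < mg_block(-120.0) < mg_block(60.0) < 1.0


class TestPlasticityScalar:
    def test_frozen_below_all_thresholds(self):
        p = PlasticSynapseParams()
        state = PlasticSynapseState(CellLocation(0, 0.5))
        w0 = (state.w_pre, state.w_post)
        for _ in range(2000):
            plasticity_step(state, u=-80.0, pre_event=False, dt=0.025, params=p)
        assert (state.w_pre, state.w_post) == w0

    def test_depolarisation_with_pre_events_potentiates(self):
        # sustained depolarisation + recent release: C exceeds the LTP
        # threshold and w_post grows
        p = PlasticSynapseParams(C_gain=1.0, tau_C=1e-6)
        state = PlasticSynapseState(CellLocation(0, 0.5))
        w0 = state.w_post
        for k in range(4000):
            ev = (k % 400) == 0
            synaptic_current(state, -20.0, 0.025, params=p, pre_event=ev)
            plasticity_step(state, u=-20.0, pre_event=ev, dt=0.025, params=p)
        assert state.w_post > w0

    def test_force_flags_clamp_pathways(self):
        p = PlasticSynapseParams(C_gain=1.0, tau_C=1e-6)
        state = PlasticSynapseState(CellLocation(0, 0.5))
        for k in range(2000):
            ev = (k % 400) == 0
            synaptic_current(state, -20.0, 0.025, params=p, pre_event=ev)
            plasticity_step(state, u=-20.0, pre_event=ev, dt=0.025, params=p,
                            force_C_zero=True, force_Nalpha_zero=True)
        assert state.C == 0.0
        assert state.N_alpha == 0.0
        assert state.w_post == pytest.approx(2.0)

    def test_weights_respect_hard_bounds(self):
        p = PlasticSynapseParams(A_post_plus=10.0, C_gain=1.0, tau_C=1e-6)
        state = PlasticSynapseState(CellLocation(0, 0.5))
        for k in range(1000):
            ev = (k % 100) == 0
            synaptic_current(state, 0.0, 0.025, params=p, pre_event=ev)
            plasticity_step(state, u=0.0, pre_event=ev, dt=0.025, params=p)
        assert state.w_post == pytest.approx(p.w_post_max)

    def test_traces_non_negative(self):
        p = PlasticSynapseParams()
        state = PlasticSynapseState(CellLocation(0, 0.5))
        rng = np.random.default_rng(0)
        for k in range(800):
            ev = rng.random() < 0.02
            u = float(rng.uniform(-90, 20))
            synaptic_current(state, u, 0.05, params=p, pre_event=ev)
            plasticity_step(state, u=u, pre_event=ev, dt=0.05, params=p)
            assert state.ampa_trace(p) >= -1e-12
            assert state.nmda_trace(p) >= -1e-12
            assert state.z_trace(p) >= -1e-12
            assert state.C >= 0.0
            assert state.T >= 0.0

    def test_agrees_with_high_resolution_reference(self):
        """Forward-Euler step at dt matches a dt/100 reference within 1%."""
        from tmsplast.experiments import make_fixture
        from tmsplast.model import calibrated_params

        t, v, pre_steps = make_fixture("burst_voltage_trace", dt=0.025)
        t, v = t[:8000], v[:8000]          # 200 ms fixture
        p = calibrated_params()

        def run(refine):
            dt = 0.025 / refine
            state = PlasticSynapseState(CellLocation(0, 0.5))
            for i in range(len(t)):
                ev = i in pre_steps
                for j in range(refine):
                    synaptic_current(state, v[i], dt, params=p,
                                     pre_event=ev and j == 0)
                    plasticity_step(state, u=v[i], pre_event=ev and j == 0,
                                    dt=dt, params=p)
            return effective_weight(state)

    # compare relative weight change, not absolute weight
        base = PlasticSynapseState(CellLocation(0, 0.5))
        w0 = effective_weight(base)
        coarse = run(1)
        fine = run(100)
        assert coarse - w0 == pytest.approx(fine - w0, rel=0.01, abs=1e-6)


class TestEffectiveWeight:
    def test_product(self):
        s = PlasticSynapseState(CellLocation(0, 0.5), w_pre=0.5, w_post=2.0)
        assert effective_weight(s) == 1.0
        s.w_pre = 0.0
        assert effective_weight(s) == 0.0


class TestInhibitory:
    def test_zero_at_reversal(self):
        syn = InhibitorySynapse(CellLocation(0, 0.5))
        i, _ = inhibitory_current(syn, u=-75.0, dt=0.025, event=True)
        assert i == pytest.approx(0.0)

    def test_zero_weight_always_zero(self):
        syn = InhibitorySynapse(CellLocation(0, 0.5), weight=0.0)
        total = 0.0
        for k in range(100):
            i, _ = inhibitory_current(syn, -60.0, 0.025, event=(k == 0))
            total += abs(i)
        assert total == 0.0

    def test_outward_above_reversal(self):
        syn = InhibitorySynapse(CellLocation(0, 0.5))
        inhibitory_current(syn, -60.0, 0.025, event=True)
        i, _ = inhibitory_current(syn, -60.0, 0.5)
        assert i > 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            InhibitorySynapse(CellLocation(0, 0.5), weight=-1.0)
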