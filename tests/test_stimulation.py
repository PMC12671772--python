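import numpy as np
import pytest

from tmsplast.morphology import RegionLabel
from tmsplast.stimulation import (
    DEFAULT_FIELD_DIRECTION,
    FieldVector,
    attach_synaptic_delay,
    build_tbs,
    build_train,
    local_electrical_stim,
    make_waveform,
    pairing_protocol,
    poisson_background,
    quasipotentials,
)


class _FakeCell:
    def __init__(self, coords):
        self.coords = np.asarray(coords, float)


class TestQuasipotentials:
    def test_zero_field(self):
        cell = _FakeCell(np.random.default_rng(0).normal(size=(5, 3)) * 100)
        ve = quasipotentials(cell, FieldVector(0, 0, 0)).ve_mv
        assert np.allclose(ve, 0.0)

    def test_hand_value(self):
        # 100 V/m along x at (100 um, 0, 0): Ve = -E.r = -0.01 V = -10 mV
        cell = _FakeCell([[100.0, 0.0, 0.0]])
        ve = quasipotentials(cell, FieldVector(100.0, 0, 0)).ve_mv
        assert ve[0] == pytest.approx(-10.0)

    def test_additive_in_field(self):
        cell = _FakeCell(np.random.default_rng(1).normal(size=(7, 3)) * 200)
        e1, e2 = FieldVector(50, -20, 10), FieldVector(-5, 80, 3)
        esum = FieldVector(45, 60, 13)
        v1 = quasipotentials(cell, e1).ve_mv
        v2 = quasipotentials(cell, e2).ve_mv
        vs = quasipotentials(cell, esum).ve_mv
        assert np.allclose(v1 + v2, vs)

    def test_constant_offset_shifts_uniformly(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(6, 3)) * 100
        fld = FieldVector(120.0, 30.0, -40.0)
        v0 = quasipotentials(_FakeCell(coords), fld).ve_mv
        v1 = quasipotentials(_FakeCell(coords + [10.0, -5.0, 2.0]), fld).ve_mv
        assert np.allclose(v1 - v0, (v1 - v0)[0])


class TestWaveforms:
    def test_zero_amplitude_is_all_zero(self):
        wf = make_waveform("monophasic", 0.0)
        assert np.allclose(wf.scale, 0.0)

    def test_monophasic_peak_normalised(self):
        wf = make_waveform("monophasic", 275.0)
        assert np.max(np.abs(wf.scale)) == pytest.approx(1.0)
        assert np.all(wf.scale >= -1e-12)

    def test_biphasic_near_zero_net_integral(self):
        wf = make_waveform("biphasic", 250.0)
        net = abs(np.trapezoid(wf.scale, wf.times))
        gross = np.trapezoid(np.abs(wf.scale), wf.times)
        assert net < 0.05 * gross

    def test_unknown_shape(self):
        with pytest.raises(ValueError):
            make_waveform("triphasic", 100.0)

    def test_scale_zero_outside_support(self):
        wf = make_waveform("monophasic", 100.0)
        assert wf.sample(np.array([-1.0, wf.pulse_width + 1.0])).tolist() == [0, 0]


class TestTrains:
    def _wf_field(self, amp=275.0):
        return (make_waveform("monophasic", amp),
                FieldVector.along(DEFAULT_FIELD_DIRECTION, amp))

    def test_900_pulse_10hz_last_onset(self):
        wf, fld = self._wf_field()
        proto = build_train(10.0, 900, wf, fld)
        onsets = [t for t, _, _ in proto.field_pulses]
        assert len(onsets) == 900
        assert onsets[-1] == pytest.approx(89_900.0)   # (900-1)/10 s

    def test_single_pulse_at_zero(self):
        wf, fld = self._wf_field()
        proto = build_train(7.0, 1, wf, fld)
        assert [t for t, _, _ in proto.field_pulses] == [0.0]

    def test_constant_inter_pulse_interval(self):
        wf, fld = self._wf_field()
        proto = build_train(8.0, 40, wf, fld)
        onsets = np.array([t for t, _, _ in proto.field_pulses])
        assert np.allclose(np.diff(onsets), 125.0)

    def test_every_pulse_paired_with_one_activation(self):
        wf, fld = self._wf_field()
        proto = build_train(10.0, 25, wf, fld)
        assert len(proto.synaptic_activations) == 25
        for (onset, _, _), act in zip(proto.field_pulses,
                                      proto.synaptic_activations):
            assert act.time == pytest.approx(onset + 1.0)
            assert act.target == "all"


class TestTBS:
    def test_burst_structure(self):
        wf = make_waveform("biphasic", 275.0)
        fld = FieldVector.along(DEFAULT_FIELD_DIRECTION, 275.0)
        proto = build_tbs(wf, fld)
        onsets = np.array([t for t, _, _ in proto.field_pulses])
        assert len(onsets) == 75                       # 15 bursts x 5
        bursts = onsets.reshape(15, 5)
        assert np.allclose(np.diff(bursts, axis=1), 10.0)   # 100 Hz
        # 100 ms gap between last stimulus and next burst onset
        assert np.allclose(bursts[1:, 0] - bursts[:-1, -1], 100.0)


class TestDelays:
    def test_delay_attaches_at_onset_plus_delay(self):
        wf = make_waveform("monophasic", 100.0)
        fld = FieldVector(0, -100.0, 0)
        proto = build_train(10.0, 3, wf, fld, delay=0.0)
        proto2 = attach_synaptic_delay(proto, 1.0)
        assert [a.time for a in proto2.synaptic_activations] == \
            pytest.approx([1.0, 101.0, 201.0])
        proto3 = attach_synaptic_delay(proto, 0.0)
        assert [a.time for a in proto3.synaptic_activations] == \
            pytest.approx([0.0, 100.0, 200.0])

    def test_negative_delay_rejected(self):
        wf = make_waveform("monophasic", 100.0)
        proto = build_train(10.0, 2, wf, FieldVector(0, -100.0, 0))
        with pytest.raises(ValueError):
            attach_synaptic_delay(proto, -0.5)


class TestPoissonBackground:
    def test_zero_rate_empty(self):
        trains = poisson_background(0.0, 1000.0, 1, 10)
        assert all(len(t) == 0 for t in trains)

    def test_total_count_within_3_sigma(self):
        rate, dur, n = 3.0, 100_000.0, 128
        trains = poisson_background(rate, dur, 7, n)
        total = sum(len(t) for t in trains)
        mean = rate * (dur / 1000.0) * n          # 38,400
        sigma = np.sqrt(mean)
        assert abs(total - mean) < 3 * sigma

    def test_seed_reproducibility(self):
        a = poisson_background(3.0, 5000.0, 11, 16)
        b = poisson_background(3.0, 5000.0, 11, 16)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestLocalElectrical:
    SCHAFFER = frozenset({RegionLabel.BASAL, RegionLabel.APICAL_TRUNK,
                          RegionLabel.OBLIQUE})

    def test_train_targets_and_counts(self):
        proto = local_electrical_stim(self.SCHAFFER, "train",
                                      frequency=1.0, n_events=900)
        assert len(proto.synaptic_activations) == 900
        assert not proto.field_pulses
        for act in proto.synaptic_activations:
            assert RegionLabel.TUFT not in act.target

    def test_tbs_pattern_on_tuft(self):
        proto = local_electrical_stim(frozenset({RegionLabel.TUFT}), "tbs")
        assert len(proto.synaptic_activations) == 75
        assert all(act.target == frozenset({RegionLabel.TUFT})
                   for act in proto.synaptic_activations)

    def test_zero_events_empty(self):
        proto = local_electrical_stim(self.SCHAFFER, "train", n_events=0)
        assert proto.synaptic_activations == []

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            local_electrical_stim(frozenset(), "train", n_events=1)


class TestPairing:
    def test_single_pairing_counts(self):
        proto = pairing_protocol(1, 1, pairs=5)
        assert len(proto.synaptic_activations) == 5
        assert len(proto.current_injections) == 5

    def test_triplets_at_100hz(self):
        proto = pairing_protocol(3, 3, pairs=2)
        pre = [a.time for a in proto.synaptic_activations[:3]]
        post = [c.time for c in proto.current_injections[:3]]
        assert np.allclose(np.diff(pre), 10.0)
        assert np.allclose(np.diff(post), 10.0)

    def test_zero_pairs_empty(self):
        proto = pairing_protocol(1, 3, pairs=0)
        assert not proto.synaptic_activations
        assert not proto.current_injections

    def test_counts_must_be_1_or_3(self):
        with pytest.raises(ValueError):
            pairing_protocol(2, 1)


def test_protocol_builders_are_pure():
    wf = make_waveform("monophasic", 275.0)
    fld = FieldVector.along(DEFAULT_FIELD_DIRECTION, 275.0)
    a = build_train(10.0, 10, wf, fld, background_seed=3)
    b = build_train(10.0, 10, wf, fld, background_seed=3)
    assert [t for t, _, _ in a.field_pulses] == [t for t, _, _ in b.field_pulses]
    assert [x.time for x in a.synaptic_activations] == \
        [x.time for x in b.synaptic_activations]
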