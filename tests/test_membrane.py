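import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmsplast.membrane import (
    CA_REST,
    TAU_CA,
    ChannelId,
    KineticsConfig,
    SpatialRule,
    assign_biophysics,
    channel_currents,
    default_table,
    eval_spatial_rule,
    init_gating,
    update_calcium,
    IH_RULE,
    KA_DEND_RULE,
    EPAS_RULE,
)
from tmsplast.morphology import RegionLabel

FARADAY = 96485.309
CA_DEPTH = 0.1


class TestConductanceTable:
    """Golden values of the region x channel conductance grid."""

    @pytest.mark.parametrize("region,channel,value", [
        (RegionLabel.SOMA, ChannelId.Na, 0.035),
        (RegionLabel.AIS, ChannelId.Na, 0.5),
        (RegionLabel.NODE, ChannelId.Na, 0.5),
        (RegionLabel.AXON_TERMINAL, ChannelId.Na, 0.035),
        (RegionLabel.OBLIQUE, ChannelId.Na, 0.03828),
        (RegionLabel.SOMA, ChannelId.KA, 0.0075),
        (RegionLabel.AIS, ChannelId.KA, 0.44),
        (RegionLabel.AXON_TERMINAL, ChannelId.KA, 0.0163694),
        (RegionLabel.SOMA, ChannelId.KDR, 0.0015),
        (RegionLabel.APICAL_TRUNK, ChannelId.KDR, 0.02),
        (RegionLabel.TUFT, ChannelId.KDR, 0.004304),
        (RegionLabel.NODE, ChannelId.KDR, 0.04),
        (RegionLabel.AXON_TERMINAL, ChannelId.KDR, 0.011664),
        (RegionLabel.SOMA, ChannelId.KM, 0.001),
        (RegionLabel.AIS, ChannelId.KM, 0.02),
        (RegionLabel.AXON_TERMINAL, ChannelId.KM, 0.0264739),
        (RegionLabel.SOMA, ChannelId.KCa, 0.0015),
        (RegionLabel.APICAL_TRUNK, ChannelId.KCa, 9.031e-5),
        (RegionLabel.SOMA, ChannelId.CagK, 4.48e-5),
        (RegionLabel.SOMA, ChannelId.CaT, 5e-5),
        (RegionLabel.BASAL, ChannelId.CaT, 1.185e-6),
        (RegionLabel.SOMA, ChannelId.CaL, 5e-4),
        (RegionLabel.OBLIQUE, ChannelId.CaL, 8.033e-6),
        (RegionLabel.SOMA, ChannelId.CaN, 2.26e-6),
        # regions absent from a row carry zero conductance
        (RegionLabel.MYELIN, ChannelId.Na, 0.0),
        (RegionLabel.AIS, ChannelId.CaL, 0.0),
        (RegionLabel.APICAL_TRUNK, ChannelId.KM, 0.0),
    ])
    def test_gbar_cells(self, region, channel, value):
        table = default_table()
        assert table.gbar_at(region, channel, d=10.0) == pytest.approx(value)

    def test_passive_golden(self):
        t = default_table()
        assert t.cm[RegionLabel.MYELIN] == 0.01
        assert t.cm[RegionLabel.SOMA] == 1.0
        assert t.ra[RegionLabel.SOMA] == 115.0
        assert t.ra[RegionLabel.MYELIN] == 60.0
        assert t.ra[RegionLabel.AIS] == 85.2
        assert t.gpas[RegionLabel.MYELIN] == 8.89e-7
        assert t.gpas[RegionLabel.NODE] == 1.29e-4
        assert t.gpas[RegionLabel.SOMA] == 9.031e-5
        assert t.epas_at(RegionLabel.AIS, 0.0) == -79.92
        assert t.epas_at(RegionLabel.MYELIN, 0.0) == -79.92

    def test_trunk_ranges_interpolated(self):
        t = default_table(trunk_extent=400.0)
        assert t.gbar_at(RegionLabel.APICAL_TRUNK, ChannelId.Na, 0.0) == \
            pytest.approx(0.015)
        assert t.gbar_at(RegionLabel.APICAL_TRUNK, ChannelId.Na, 400.0) == \
            pytest.approx(0.02)
        assert t.gbar_at(RegionLabel.APICAL_TRUNK, ChannelId.KA, 200.0) == \
            pytest.approx(0.15)

    def test_assign_rejects_unknown_region(self, morph):
        table = default_table()
        del table.cm[RegionLabel.TUFT]
        with pytest.raises(ValueError, match="tuft"):
            assign_biophysics(morph, table)


class TestSpatialRules:
    def test_ih_values(self):
        assert eval_spatial_rule(IH_RULE, 0.0) == pytest.approx(1.904e-5)
        # hand evaluation: 1.904e-5 * (1 + 3*100/100)
        assert eval_spatial_rule(IH_RULE, 100.0) == pytest.approx(7.616e-5)

    def test_epas_values(self):
        assert eval_spatial_rule(EPAS_RULE, 0.0) == pytest.approx(-65.73)
        assert eval_spatial_rule(EPAS_RULE, 150.0) == pytest.approx(-70.73)

    def test_ka_dend_sigmoid(self):
        # midpoint of the sigmoid at d = 300
        assert eval_spatial_rule(KA_DEND_RULE, 300.0) == \
            pytest.approx(0.012915 / 2)
        assert eval_spatial_rule(KA_DEND_RULE, 0.0) < 1e-4

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            eval_spatial_rule(IH_RULE, -1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            eval_spatial_rule(SpatialRule("cubic", (1.0,)), 1.0)


class TestChannelCurrents:
    def _passive_setup(self, n=4, v=-70.0):
        kin = KineticsConfig().pack()
        gbar = np.zeros((10, n))
        gpas = np.full(n, 1e-4)
        epas = np.full(n, -65.0)
        gating = init_gating(kin, np.full(n, v))
        return kin, gbar, gpas, epas, gating

    def test_passive_limit(self):
        kin, gbar, gpas, epas, gating = self._passive_setup()
        v = np.full(4, -70.0)
        i, _, _ = channel_currents(gating, v, 0.025, gbar, gpas, epas, kin)
        assert np.allclose(i, 1e-4 * (-70.0 + 65.0))

    def test_kdr_vanishes_at_reversal(self):
        kin, gbar, gpas, epas, gating = self._passive_setup(v=-90.0)
        gbar[2, :] = 0.02          # KDR only
        gpas[:] = 0.0
        v = np.full(4, -90.0)      # E_K
        i, _, _ = channel_currents(gating, v, 0.025, gbar, gpas, epas, kin)
        assert np.allclose(i, 0.0, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.floats(min_value=-100, max_value=40),
                    min_size=5, max_size=25))
    def test_gates_stay_in_unit_interval(self, vtrace):
        kin = KineticsConfig().pack()
        gbar = np.full((10, 1), 1e-3)
        gating = init_gating(kin, np.array([-70.0]))
        for v in vtrace:
            _, gating, _ = channel_currents(
                gating, np.array([v]), 0.1, gbar,
                np.array([1e-4]), np.array([-65.0]), kin)
            assert np.all(gating.gates >= 0.0)
            assert np.all(gating.gates <= 1.0)


class TestCalciumPool:
    def test_rest_is_fixed_point(self):
        ca = np.array([CA_REST])
        out = update_calcium(ca, np.array([0.0]), 0.025)
        assert out[0] == pytest.approx(CA_REST)

    def test_monotone_decay_without_influx(self):
        ca = np.array([10 * CA_REST])
        prev = ca[0]
        for _ in range(100):
            ca = update_calcium(ca, np.array([0.0]), 0.1)
            assert ca[0] <= prev
            prev = ca[0]
        assert ca[0] > CA_REST - 1e-12

    def test_steady_state_matches_closed_form(self):
        # dca/dt = -k i - (ca - rest)/tau  =>  ca_ss = rest + tau k |i|
        i_ca = -1e-3  # inward
        k = 1e4 / (2 * FARADAY * CA_DEPTH)
        expected = CA_REST + TAU_CA * k * abs(i_ca)
        ca = np.array([CA_REST])
        for _ in range(20000):
            ca = update_calcium(ca, np.array([i_ca]), 0.1)
        assert ca[0] == pytest.approx(expected, rel=1e-3)
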