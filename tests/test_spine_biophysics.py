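import math

import numpy as np
import pytest

from spinekit import (
    CableParams,
    SimulationConfig,
    SpineGeometryModel,
    SpineMorphometry,
    SynapseParams,
    alpha_conductance,
    batch_membrane_potential_peaks,
    build_spine_circuit,
    cylinder_passive,
    exp_euler_step,
    membrane_potential_peak,
    peak_depolarization,
    reference_peak_depolarization,
    simulate,
)
from spinekit.spine_biophysics import SpineCircuit, morphometry_to_geometry
from spinekit.synthetic_data import sample_geometries

CABLE = CableParams()
SYN = SynapseParams()


def _single_compartment(d=1.0, L=1.0, gbar=0.0):
    """An isolated cylinder with no couplings, for pure-decay checks."""
    area, C, gl, Ra = cylinder_passive(d, L, CABLE)
    return SpineCircuit(
        names=["solo"],
        diameters_um=np.array([d]),
        lengths_um=np.array([L]),
        areas_m2=np.array([area]),
        C_F=np.array([C]),
        g_leak_S=np.array([gl]),
        Ra_Ohm=np.array([Ra]),
        couplings=[],
        syn_index=0,
        gbar_S=gbar,
        cable=CABLE,
    )


class TestCylinderPassive:
    def test_unit_cylinder_si_values(self):
        area, C, gl, Ra = cylinder_passive(1.0, 1.0, CABLE)
        assert area == pytest.approx(math.pi * 1e-12, rel=1e-12)
        assert C == pytest.approx(math.pi * 1e-14, rel=1e-12)
        # g_leak = area / Rm with Rm = 2 ohm m^2
        assert gl == pytest.approx(math.pi * 1e-12 / 2.0, rel=1e-12)

    def test_length_scaling_is_linear(self):
        a1, C1, g1, R1 = cylinder_passive(1.0, 1.0, CABLE)
        a2, C2, g2, R2 = cylinder_passive(1.0, 2.0, CABLE)
        assert (a2, C2, g2, R2) == pytest.approx((2 * a1, 2 * C1, 2 * g1, 2 * R1))

    def test_diameter_scaling(self):
        a1, _, _, R1 = cylinder_passive(1.0, 1.0, CABLE)
        a2, _, _, R2 = cylinder_passive(2.0, 1.0, CABLE)
        assert a2 == pytest.approx(2 * a1)
        assert R2 == pytest.approx(R1 / 4)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            cylinder_passive(0.0, 1.0, CABLE)


class TestCircuitConstruction:
    def test_mushroom_three_compartments_and_gbar(self):
        geom = SpineGeometryModel(
            kind="mushroom",
            head_diameter=0.43,
            head_length=0.43,
            neck_diameter=0.175,
            neck_length=0.38,
        )
        circ = build_spine_circuit(geom, CABLE, SYN)
        assert circ.names == ["dendrite", "neck", "head"]
        assert circ.gbar_S == pytest.approx(
            132.0 * math.pi * 0.43e-6 * 0.43e-6, rel=1e-12
        )
        assert circ.syn_index == 2

    def test_stubby_two_compartments(self):
        circ = build_spine_circuit(
            SpineGeometryModel(kind="stubby", head_diameter=0.44, head_length=0.32),
            CABLE,
            SYN,
        )
        assert circ.names == ["dendrite", "head"]
        assert len(circ.couplings) == 1

    def test_symmetric_vs_child_coupling(self):
        geom = SpineGeometryModel(kind="stubby", head_diameter=0.5, head_length=1.0)
        sym = build_spine_circuit(geom, CABLE, SYN, coupling="symmetric")
        child = build_spine_circuit(geom, CABLE, SYN, coupling="child_ra")
        assert sym.couplings[0][2] == pytest.approx(
            0.5 * (sym.Ra_Ohm[0] + sym.Ra_Ohm[1])
        )
        assert child.couplings[0][2] == pytest.approx(child.Ra_Ohm[1])

    def test_mushroom_requires_neck(self):
        with pytest.raises(ValueError):
            SpineGeometryModel(kind="mushroom", head_diameter=0.5, head_length=0.5)


class TestAlphaConductance:
    def test_closed_form_values(self):
        gbar, tau = 3.0e-10, 2.0
        assert alpha_conductance(tau, gbar, tau) == pytest.approx(gbar, rel=1e-15)
        assert alpha_conductance(0.0, gbar, tau) == 0.0
        assert alpha_conductance(-1.0, gbar, tau) == 0.0
        assert alpha_conductance(2 * tau, gbar, tau) == pytest.approx(
            gbar * 2 * math.exp(-1), rel=1e-15
        )

    def test_peak_is_global_maximum(self):
        t = np.arange(0.0, 20.0, 1e-4)
        g = alpha_conductance(t, 1.0, 2.0)
        assert t[g.argmax()] == pytest.approx(2.0, abs=1e-4)
        assert g.max() <= 1.0 + 1e-15


class TestExpEulerStep:
    def test_isolated_compartment_decays_with_membrane_tau(self):
        # tau_m = Rm * Cm = 20 ms regardless of geometry
        circ = _single_compartment()
        circ.Vm_mV = np.array([CABLE.Em + 10.0])
        dt = 1e-6
        exp_euler_step(circ, 0.0, dt)
        expected = CABLE.Em + 10.0 * math.exp(-dt / 20e-3)
        assert circ.Vm_mV[0] == pytest.approx(expected, rel=1e-12)

    def test_steady_state_is_fixed_point(self):
        circ = _single_compartment()
        circ.Vm_mV = np.array([CABLE.Em])
        exp_euler_step(circ, 0.0, 1e-6)
        assert circ.Vm_mV[0] == pytest.approx(CABLE.Em, abs=1e-12)

    def test_small_dt_limit_matches_ode_rhs(self):
        geom = SpineGeometryModel(kind="stubby", head_diameter=0.6, head_length=1.0)
        circ = build_spine_circuit(geom, CABLE, SYN)
        circ.Vm_mV = np.array([CABLE.Em + 1.0, CABLE.Em + 3.0])
        V0 = circ.Vm_mV.copy()
        g = 1e-10
        dt = 1e-13  # small enough that the O(G·dt/C) term is below tolerance
        V1 = exp_euler_step(circ, g, dt, Esyn_mV=SYN.Esyn)
        rate = (V1 - V0) / dt
        # ODE right-hand side at V0
        gc = 1.0 / circ.couplings[0][2]
        rhs0 = (
            circ.g_leak_S[0] * (CABLE.Em - V0[0]) + gc * (V0[1] - V0[0])
        ) / circ.C_F[0]
        rhs1 = (
            circ.g_leak_S[1] * (CABLE.Em - V0[1])
            + gc * (V0[0] - V0[1])
            + g * (SYN.Esyn - V0[1])
        ) / circ.C_F[1]
        assert rate[0] == pytest.approx(rhs0, rel=1e-5)
        assert rate[1] == pytest.approx(rhs1, rel=1e-5)


class TestSimulate:
    def test_zero_density_stays_at_rest(self):
        geom = SpineGeometryModel(kind="stubby", head_diameter=0.8, head_length=1.0)
        syn0 = SynapseParams(gbar_density=0.0)
        circ = build_spine_circuit(geom, CABLE, syn0)
        res = simulate(circ, syn0, SimulationConfig(dt_us=1.0, duration_ms=50.0))
        assert np.abs(res.Vm_traces_mV - CABLE.Em).max() < 1e-12
        assert res.peak_depolarization_mV == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("geom", sample_geometries(6, seed=5))
    def test_passive_voltage_bound(self, geom):
        circ = build_spine_circuit(geom, CABLE, SYN)
        res = simulate(circ, SYN, SimulationConfig(dt_us=1.0, duration_ms=20.0))
        assert res.Vm_traces_mV.min() >= CABLE.Em - 1e-9
        assert res.Vm_traces_mV.max() <= SYN.Esyn + 1e-9

    def test_reversal_saturation(self):
        geom = SpineGeometryModel(
            kind="mushroom",
            head_diameter=0.43,
            head_length=0.43,
            neck_diameter=0.175,
            neck_length=0.38,
        )
        hot = SynapseParams(gbar_density=132.0 * 1e4)
        circ = build_spine_circuit(geom, CABLE, hot)
        res = simulate(circ, hot, SimulationConfig(dt_us=1.0, duration_ms=50.0))
        assert res.peak_depolarization_mV == pytest.approx(
            SYN.Esyn - CABLE.Em, abs=1.0
        )

    def test_peak_monotone_in_density(self):
        geom = SpineGeometryModel(kind="stubby", head_diameter=0.6, head_length=1.0)
        peaks = []
        for scale in (1.0, 2.0, 4.0):
            syn = SynapseParams(gbar_density=132.0 * scale)
            circ = build_spine_circuit(geom, CABLE, syn)
            res = simulate(circ, syn, SimulationConfig(dt_us=1.0, duration_ms=20.0))
            peaks.append(res.peak_depolarization_mV)
        assert peaks[0] < peaks[1] < peaks[2]

    def test_isyn_sign_and_peak_accessor(self):
        geom = SpineGeometryModel(kind="stubby", head_diameter=0.6, head_length=1.0)
        circ = build_spine_circuit(geom, CABLE, SYN)
        res = simulate(circ, SYN, SimulationConfig(dt_us=1.0, duration_ms=20.0))
        # I_syn = g (Vm - Esyn) is negative (inward) for Vm < Esyn
        assert res.Isyn_trace_nA.min() < 0
        assert res.Isyn_trace_nA[0] == 0.0
        assert peak_depolarization(res) == res.peak_depolarization_mV


class TestOracleAgreement:
    @pytest.mark.parametrize("geom", sample_geometries(2, seed=9))
    def test_converged_step_matches_adaptive_reference(self, geom):
        circ = build_spine_circuit(geom, CABLE, SYN)
        ref = reference_peak_depolarization(circ, SYN, t_end_ms=25.0)
        (peak,) = batch_membrane_potential_peaks(
            [geom], CABLE, SYN, SimulationConfig(dt_us=1.0 / 64, duration_ms=25.0)
        )
        assert peak == pytest.approx(ref, rel=0.01)

    def test_error_vs_reference_halves_with_dt(self):
        # first-order scheme: fixed-step error shrinks ~linearly in dt
        geom = sample_geometries(1, seed=9)[0]
        circ = build_spine_circuit(geom, CABLE, SYN)
        ref = reference_peak_depolarization(circ, SYN, t_end_ms=20.0)
        errs = []
        for dt in (1.0, 0.5, 0.25):
            (peak,) = batch_membrane_potential_peaks(
                [geom], CABLE, SYN, SimulationConfig(dt_us=dt, duration_ms=20.0)
            )
            errs.append(abs(peak - ref))
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.3)


class TestFeatureMapping:
    def _morph(self, **kw):
        base = dict(
            volume=0.5,
            area=4.0,
            length=2.3,
            max_diameter=0.8,
            neck_mean_diameter=0.3,
            spine_class="mushroom",
        )
        base.update(kw)
        return SpineMorphometry(**base)

    def test_thin_spines_not_modelled(self):
        m = self._morph(spine_class="thin", max_diameter=0.3, neck_mean_diameter=0.12)
        assert membrane_potential_peak(m) is None

    def test_mushroom_mapping(self):
        geom = morphometry_to_geometry(self._morph())
        assert geom.kind == "mushroom"
        assert geom.head_diameter == 0.8
        assert geom.head_length == 0.8
        assert geom.neck_length == pytest.approx(2.3 - 0.8)
        assert geom.neck_diameter == 0.3

    def test_stubby_composition_identity(self):
        geom = SpineGeometryModel(kind="stubby", head_diameter=0.44, head_length=0.32)
        cfg = SimulationConfig(dt_us=1.0, duration_ms=20.0)
        direct = membrane_potential_peak(geom, CABLE, SYN, cfg)
        circ = build_spine_circuit(geom, CABLE, SYN)
        assert direct == pytest.approx(
            simulate(circ, SYN, cfg).peak_depolarization_mV, rel=1e-12
        )

    def test_degenerate_neck_flagged_missing_with_warning(self):
        m = self._morph(length=0.5, max_diameter=0.8)  # head longer than spine
        with pytest.warns(UserWarning, match="neck length"):
            assert membrane_potential_peak(m) is None

    def test_neck_length_increases_head_peak(self):
        cfg = SimulationConfig(dt_us=1.0, duration_ms=30.0)
        peaks = []
        for nl in (0.38, 1.5, 3.0, 4.37):
            geom = SpineGeometryModel(
                kind="mushroom",
                head_diameter=0.8,
                head_length=0.8,
                neck_diameter=0.3,
                neck_length=nl,
            )
            peaks.append(membrane_potential_peak(geom, CABLE, SYN, cfg))
        assert all(b >= a - 1e-9 for a, b in zip(peaks, peaks[1:]))

    def test_batch_matches_single(self):
        geoms = sample_geometries(4, seed=2) + [None]
        cfg = SimulationConfig(dt_us=1.0, duration_ms=20.0)
        batch = batch_membrane_potential_peaks(geoms, CABLE, SYN, cfg)
        for geom, pk in zip(geoms, batch):
            if geom is None:
                assert pk is None
            else:
                assert pk == pytest.approx(
                    membrane_potential_peak(geom, CABLE, SYN, cfg), rel=1e-9
                )
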