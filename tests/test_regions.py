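import numpy as np
import pytest
from dataclasses import replace

from bgthsim.connectome import synth_connectome
from bgthsim.engine import euler_step
from bgthsim.errors import ParameterError, ValidationError
from bgthsim.regions import (
    BGTHParams,
    CONNECTIONS,
    REGIONS,
    SMCParams,
    _REGION_SYNAPSES,
    apply_disease_state,
    gate_derivatives,
    init_ensemble,
    ionic_currents,
    regional_rhs,
    smc_input,
    synapse_derivatives,
    synaptic_current,
    synaptic_currents,
)


@pytest.fixture
def params():
    return BGTHParams()


class TestGateKinetics:
    @pytest.mark.parametrize("region", ["STN", "GPi", "GPe", "TH"])
    def test_steady_state_is_fixed_point(self, params, region):
        rp = params.regions[region]
        v = -55.0
        gates = {name: kin.x_inf(v) for name, kin in rp.gates.items()}
        derivs = gate_derivatives(gates, v, rp, region)
        for name in rp.gates:
            assert derivs[name] == pytest.approx(0.0, abs=1e-12)

    def test_zero_rate_scale_freezes_gates(self, params):
        rp = params.regions["STN"]
        frozen = replace(
            rp, gates={k: replace(kin, rate_scale=0.0)
                       for k, kin in rp.gates.items()}
        )
        gates = {name: 0.31 for name in frozen.gates}
        derivs = gate_derivatives(gates, -40.0, frozen, "STN")
        for name in frozen.gates:
            assert derivs[name] == 0.0

    def test_calcium_pool_decays_exponentially_without_influx(self, params):
        """With g_Ca = g_T = 0 the pool obeys dw/dt = -e_w * l_w * w."""
        rp = replace(params.regions["STN"], g_Ca=0.0, g_T=0.0)
        w0 = 0.8
        gates = {"h": 0.5, "n": 0.5, "r": 0.5, "c": 0.5, "w": w0}
        dt = 0.01
        w = w0
        for _ in range(1000):
            d = gate_derivatives(
                {**gates, "w": w}, -60.0, rp, "STN")["w"]
            w += d * dt
        t = 1000 * dt
        assert w == pytest.approx(w0 * np.exp(-rp.e_w * rp.l_w * t), rel=1e-4)

    def test_gate_values_bounded_in_unit_interval_at_extremes(self, params):
        for region in REGIONS:
            rp = params.regions[region]
            for kin in rp.gates.values():
                for v in (-120.0, 60.0):
                    assert 0.0 <= kin.x_inf(v) <= 1.0
                    assert kin.tau(v) > 0.0


class TestIonicCurrents:
    def test_zero_gating_or_reversal_gives_zero_current(self, params):
        rp = params.regions["GPe"]
        gates = {"h": 0.0, "n": 0.0, "r": 0.0, "c": 0.0, "w": 0.0}
        cur = ionic_currents(rp.E_L, gates, rp, "GPe")
        # every non-leak current is gated to zero; leak vanishes at E_L
        for name, value in cur.items():
            assert value == pytest.approx(0.0, abs=1e-12), name

    def test_stn_t_current_vanishes_at_zero_inactivation(self, params):
        rp = params.regions["STN"]
        gates = {"h": 0.5, "n": 0.5, "r": 0.0, "c": 0.0, "w": 0.0}
        cur = ionic_currents(-30.0, gates, rp, "STN")
        assert cur["I_T"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_leak_substitution(self, params):
        rp = replace(params.regions["GPe"], g_L=0.3)
        gates = {"h": 0.0, "n": 0.0, "r": 0.0, "c": 0.0, "w": 0.0}
        cur = ionic_currents(rp.E_L + 10.0, gates, rp, "GPe")
        assert cur["I_L"] == pytest.approx(3.0)

    def test_current_linear_in_conductance(self, params):
        rp = params.regions["STN"]
        doubled = replace(rp, g_Na=2 * rp.g_Na)
        gates = {"h": 0.6, "n": 0.4, "r": 0.2, "c": 0.3, "w": 1.0}
        v = -40.0
        assert ionic_currents(v, gates, doubled, "STN")["I_Na"] == pytest.approx(
            2 * ionic_currents(v, gates, rp, "STN")["I_Na"]
        )

    def test_th_carries_only_four_currents(self, params):
        rp = params.regions["TH"]
        cur = ionic_currents(-60.0, {"h": 0.5, "r": 0.5}, rp, "TH")
        assert set(cur) == {"I_Na", "I_K", "I_L", "I_T"}

    def test_unknown_region_rejected(self, params):
        with pytest.raises(ParameterError):
            ionic_currents(-60.0, {}, params.regions["STN"], "SNr")


class TestSynapticCurrents:
    def test_zero_activation_gives_zero_everywhere(self, params):
        v = {r: -60.0 for r in REGIONS}
        syn = {name: 0.0 for name in CONNECTIONS}
        cur = synaptic_currents(v, syn, params.synapses)
        assert all(value == 0.0 for value in cur.values())

    def test_reversal_potential_nulls_current(self, params):
        sp = params.synapses["GPi->TH"]
        v = {r: -60.0 for r in REGIONS}
        v["TH"] = sp.E_syn
        syn = {name: 0.7 for name in CONNECTIONS}
        cur = synaptic_currents(v, syn, params.synapses)
        assert cur["GPi->TH"] == pytest.approx(0.0)

    def test_topology_matches_circuit_diagram(self):
        """Exactly six connections; STN-source excitatory, pallidal-source
        inhibitory; TH receives only the GPi projection."""
        assert set(CONNECTIONS) == {
            "GPe->STN", "STN->GPi", "STN->GPe", "GPe->GPi", "GPe->GPe",
            "GPi->TH",
        }
        assert _REGION_SYNAPSES["TH"] == ("GPi->TH",)
        assert _REGION_SYNAPSES["STN"] == ("GPe->STN",)
        p = BGTHParams()
        for name, sp in p.synapses.items():
            source = name.split("->")[0]
            if source == "STN":
                assert sp.E_syn == 0.0  # excitatory
            else:
                assert sp.E_syn < -60.0  # inhibitory

    def test_non_modelled_connection_rejected(self, params):
        with pytest.raises(ParameterError):
            synaptic_current("TH->STN", -60.0, 0.5, params.synapses)

    def test_activation_kinetics_bounded(self, params):
        v = {r: 0.0 for r in REGIONS}  # strong presynaptic depolarization
        syn = {name: 1.0 for name in CONNECTIONS}
        derivs = synapse_derivatives(v, syn, params.synapses)
        assert all(d <= 0.0 for d in derivs.values())  # cannot exceed 1


class TestSMC:
    def test_pulse_window_and_gap(self):
        smc = SMCParams(amplitude=3.5, pulse_width=5.0, period=25.0)
        assert smc_input(2.0, smc) == 3.5
        assert smc_input(27.0, smc) == 3.5  # second period
        assert smc_input(10.0, smc) == 0.0
        assert smc_input(24.9, smc) == 0.0

    def test_integral_over_one_period(self):
        smc = SMCParams()
        dt = 0.01
        t = np.arange(0.0, smc.period, dt)
        integral = sum(smc_input(float(x), smc) for x in t) * dt
        assert integral == pytest.approx(smc.amplitude * smc.pulse_width,
                                         abs=smc.amplitude * dt)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ParameterError):
            SMCParams(pulse_width=30.0, period=25.0).validate()


class TestDiseaseState:
    def test_healthy_is_identity(self, params):
        assert apply_disease_state(params, 0) is params

    def test_pd_reduces_bias_currents_except_th(self, params):
        diseased = apply_disease_state(params, 1)
        for region in ("STN", "GPi", "GPe"):
            assert diseased.regions[region].I_app == pytest.approx(
                params.regions[region].I_app
                - params.regions[region].pd_reduction
            )
        assert diseased.regions["TH"].I_app == params.regions["TH"].I_app

    def test_idempotent_on_pristine_base(self, params):
        a = apply_disease_state(params, 1)
        b = apply_disease_state(params, 1)
        for region in REGIONS:
            assert a.regions[region].I_app == b.regions[region].I_app
        # base parameters untouched
        assert params.regions["GPe"].I_app == BGTHParams().regions["GPe"].I_app

    def test_invalid_flag_rejected(self, params):
        with pytest.raises(ParameterError):
            apply_disease_state(params, 2)


def _quiet_params():
    """Parameters with every current and input silenced."""
    p = BGTHParams()
    for region in REGIONS:
        rp = p.regions[region]
        p.regions[region] = replace(
            rp, g_Na=0.0, g_K=0.0, g_L=0.0, g_T=0.0, g_Ca=0.0, g_ahp=0.0,
            I_app=0.0, e_w=0.0,
        )
    for name, sp in p.synapses.items():
        p.synapses[name] = replace(sp, g_syn=0.0)
    p.smc = SMCParams(amplitude=0.0)
    return p


class TestRegionalRHS:
    def test_constant_input_limit(self):
        p = _quiet_params()
        for region in REGIONS:
            p.regions[region] = replace(p.regions[region], I_app=2.5)
        ens = init_ensemble(p)
        zero = {r: (0.0, 0.0) for r in REGIONS}
        dv, _, _ = regional_rhs(ens, np.zeros((4, 4)), zero, {}, 0.0, p)
        assert np.allclose(dv, 2.5)  # cm = 1

    def test_equal_voltages_null_diffusion(self):
        p = _quiet_params()
        c = synth_connectome(4, 1.0, seed=3)
        ens = init_ensemble(p, v0=-64.0)
        zero = {r: (0.0, 0.0) for r in REGIONS}
        dv, _, _ = regional_rhs(ens, c.laplacian, zero, {}, 0.0, p)
        assert np.allclose(dv, 0.0, atol=1e-12)

    def test_pure_diffusion_conserves_total_voltage(self):
        """Symmetric Laplacian with equal per-region diffusion scales
        conserves sum(v) under Euler stepping."""
        p = _quiet_params()
        c = synth_connectome(4, 1.0, seed=5)
        ens = init_ensemble(p)
        ens.v = np.array([-70.0, -60.0, -50.0, -66.0])
        zero = {r: (0.0, 0.0) for r in REGIONS}
        total0 = ens.v.sum()
        for k in range(10_000):
            dv, _, _ = regional_rhs(ens, c.laplacian, zero, {}, k * 0.01, p)
            ens.v = euler_step(ens.v, dv, 0.01)
        assert abs(ens.v.sum() - total0) / abs(total0) < 1e-6

    def test_micro_currents_enter_additively(self):
        p = _quiet_params()
        ens = init_ensemble(p)
        avg = {r: (3.0, -1.0) for r in REGIONS}
        zero = {r: (0.0, 0.0) for r in REGIONS}
        dv_with, _, _ = regional_rhs(ens, np.zeros((4, 4)), avg, {}, 0.0, p)
        dv_zero, _, _ = regional_rhs(ens, np.zeros((4, 4)), zero, {}, 0.0, p)
        assert np.allclose(dv_with - dv_zero, 2.0)

    def test_dimension_mismatch_rejected(self):
        p = _quiet_params()
        ens = init_ensemble(p)
        zero = {r: (0.0, 0.0) for r in REGIONS}
        with pytest.raises(ValidationError):
            regional_rhs(ens, np.zeros((5, 5)), zero, {}, 0.0, p)

    def test_extra_nodes_feel_only_diffusion(self):
        p = _quiet_params()
        c = synth_connectome(6, 1.0, seed=9)
        ens = init_ensemble(p, n_nodes=6)
        ens.v = np.array([-65.0, -65.0, -65.0, -65.0, -40.0, -80.0])
        zero = {r: (0.0, 0.0) for r in REGIONS}
        dv, _, _ = regional_rhs(ens, c.laplacian, zero, {}, 0.0, p)
        Lv = c.laplacian @ ens.v
        assert dv[4] == pytest.approx(-0.1 * Lv[4])
        assert dv[5] == pytest.approx(-0.1 * Lv[5])
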