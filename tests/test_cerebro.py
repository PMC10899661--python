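import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from tiltsim.cerebro import (AutoregulationState, CerebralBoundary,
                             CSFICPState, autoreg_scales,
                             autoregulation_update, co2_activation,
                             csf_flows, effective_compliance,
                             icp_closed_form, icp_from_volume, icp_rhs,
                             icp_volume_rhs, intracranial_compliance,
                             simulate_fixed_boundaries, spinal_column)
from tiltsim.params import CerebralParams

P = CerebralParams()


class TestAutoregulation:
    def test_set_point_equilibrium(self):
        st = AutoregulationState()
        for _ in range(200):
            st = autoregulation_update(P.cbf_n, st, 0.5, P)
        assert st.x_aut == pytest.approx(0.0, abs=1e-12)
        assert st.c_scale == pytest.approx(1.0, abs=1e-9)
        assert st.r_scale == pytest.approx(1.0, abs=1e-9)

    def test_sustained_high_flow_constricts(self):
        st = AutoregulationState()
        for _ in range(2000):
            st = autoregulation_update(1.2 * P.cbf_n, st, 0.5, P)
        assert st.c_scale < 1.0       # compliance falls
        assert st.r_scale > 1.0       # resistance rises

    def test_scales_bounded_by_sigmoid(self):
        cc_lo, _ = autoreg_scales(1e6, 0.0, P)
        cc_hi, _ = autoreg_scales(-1e6, 0.0, P)
        assert cc_lo == pytest.approx(1.0 - P.g_c, abs=1e-9)
        assert cc_hi == pytest.approx(1.0 + P.g_c, abs=1e-9)

    def test_disabled_returns_unity(self):
        assert autoreg_scales(5.0, 0.0, P, enabled=False) == (1.0, 1.0)


class TestCO2Reactivity:
    def test_nominal_paco2_is_neutral(self):
        st = AutoregulationState()
        for _ in range(500):
            st = co2_activation(P.paco2_n, st, 1.0, P)
        assert st.x_co2 == pytest.approx(0.0, abs=1e-12)

    def test_hypercapnia_dilates(self):
        st = AutoregulationState()
        for _ in range(4000):
            st = co2_activation(55.0, st, 1.0, P)
        assert st.x_co2 > 0
        assert st.c_scale > 1.0
        assert st.r_scale < 1.0

    def test_step_time_constant_recovered(self):
        """Fit an exponential to the simulated CO2 step response: the fitted
        time constant matches the configured tau within 2%."""
        dt = 0.25
        st = AutoregulationState()
        ts, xs = [], []
        for i in range(int(6 * P.tau_co2 / dt)):
            st = co2_activation(50.0, st, dt, P)
            ts.append((i + 1) * dt)
            xs.append(st.x_co2)
        target = P.g_co2 * np.log(50.0 / P.paco2_n)
        popt, _ = curve_fit(lambda t, tau: target * (1 - np.exp(-t / tau)),
                            np.array(ts), np.array(xs), p0=[30.0])
        assert popt[0] == pytest.approx(P.tau_co2, rel=0.02)


class TestCSF:
    def test_zero_outflow_gradient(self):
        qf, qo = csf_flows(14.0, -0.1, -0.1, P.r_f, P.r_o)
        assert qo == 0.0

    def test_no_backward_formation(self):
        qf, qo = csf_flows(5.0, 10.0, -10.0, P.r_f, P.r_o)
        assert qf == 0.0
        assert qo > 0.0

    def test_steady_state_balances(self):
        # at the calibrated pre-tilt point formation equals outflow
        qf, qo = csf_flows(14.42, -0.1, -10.35, P.r_f, P.r_o)
        assert qf == pytest.approx(qo, rel=0.02)

    def test_invalid_resistances(self):
        with pytest.raises(ValueError):
            csf_flows(10.0, 0.0, -10.0, -1.0, P.r_o)


class TestIntracranialCompliance:
    def test_strictly_decreasing_in_icp(self):
        icps = np.linspace(-4.0, 40.0, 100)
        cs = [intracranial_compliance(x, P) for x in icps]
        assert np.all(np.diff(cs) < 0)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            intracranial_compliance(P.icp_min - 1.0, P)

    def test_constant_inflow_matches_closed_form(self):
        """Constant net inflow into the pure cranial elastance element:
        the integrated ICP matches the analytic exponential within 1e-6."""
        q = 0.002
        icp0 = 2.0
        sol = solve_ivp(lambda t, y: icp_volume_rhs(y[0], q, P), (0, 400),
                        [icp0], rtol=1e-11, atol=1e-12, dense_output=True)
        t = np.linspace(0, 400, 60)
        assert np.max(np.abs(sol.sol(t)[0] - icp_closed_form(icp0, q, t, P))) < 1e-6

    def test_zero_inflow_fixed_posture_is_stationary(self):
        st = CSFICPState(icp=5.0, qf=0.0, qo=0.0)
        assert icp_rhs(st, 0.0, P, angle=30.0, angle_rate=0.0) == 0.0


class TestPostureRedistribution:
    def test_tilt_moves_icp_by_the_csf_column_share(self):
        """At constant stored volume, tilting from 80 deg head-up to 6 deg
        head-down raises ICP by about 10-11 mmHg through spinal-sac
        redistribution."""
        icp_hut = icp_from_volume(0.0, np.sin(np.deg2rad(80.0)), P)
        icp_hdt = icp_from_volume(0.0, np.sin(np.deg2rad(-6.0)), P)
        assert icp_hut == pytest.approx(P.icp_ref, abs=1e-6)
        assert icp_hdt - icp_hut == pytest.approx(10.9, abs=1.5)

    def test_redistribution_is_reversible(self):
        back = icp_from_volume(0.0, np.sin(np.deg2rad(80.0)), P)
        there = icp_from_volume(0.0, np.sin(np.deg2rad(-30.0)), P)
        again = icp_from_volume(0.0, np.sin(np.deg2rad(80.0)), P)
        assert back == pytest.approx(again, abs=1e-9)
        assert there > back

    def test_effective_compliance_stiffens_head_down(self):
        assert effective_compliance(10.9, P) < effective_compliance(-0.1, P)
        assert spinal_column(P) > 0


@pytest.fixture(scope="module")
def baseline():
    return simulate_fixed_boundaries(CerebralBoundary(), t_end=400.0)


class TestCerebralNetwork:

    def test_calibrated_operating_point(self, baseline):
        # pre-tilt boundaries reproduce the calibrated ladder
        assert baseline.cbf == pytest.approx(11.63, rel=0.01)
        assert baseline.icp == pytest.approx(-0.1, abs=0.3)
        assert baseline.pressures["mca_l"] == pytest.approx(63.4, abs=1.0)
        assert baseline.pressures["dm_l"] == pytest.approx(36.5, abs=1.5)
        assert baseline.pressures["ccap"] == pytest.approx(14.4, abs=1.0)
        assert baseline.pressures["cv"] == pytest.approx(4.16, abs=0.6)
        assert baseline.pressures["dvs"] == pytest.approx(-10.8, abs=1.0)

    def test_head_down_boundaries_give_reported_state(self, baseline):
        """Head-down boundary pressures drive the network to the reported
        post-tilt state: CBF ~ +7%, distal resistance up ~13%, distal
        compliance down ~17%."""
        b = CerebralBoundary(p_ica_l=87.7, p_ica_r=87.7, p_vert=87.7,
                             p_svc=7.9, angle=-6.0)
        st = simulate_fixed_boundaries(b, t_end=600.0)
        assert st.cbf == pytest.approx(12.4, rel=0.05)
        assert st.icp == pytest.approx(10.9, abs=1.5)
        assert st.autoreg.r_scale == pytest.approx(1.13, abs=0.04)
        assert st.autoreg.c_scale == pytest.approx(0.83, abs=0.05)

    def test_autoregulation_plateau(self, baseline):
        """Steady CBF changes by less than 10% for +/-15% perfusion steps;
        with autoregulation disabled the passive change is proportional."""
        regulated = {}
        for f in (1.15, 0.85):
            b = CerebralBoundary(p_ica_l=65.8 * f, p_ica_r=65.8 * f,
                                 p_vert=65.8 * f)
            st = simulate_fixed_boundaries(b, t_end=600.0)
            regulated[f] = st.cbf / baseline.cbf - 1.0
            assert abs(regulated[f]) < 0.10
        passive0 = simulate_fixed_boundaries(CerebralBoundary(),
                                             autoregulation=False, t_end=600.0)
        b = CerebralBoundary(p_ica_l=65.8 * 1.15, p_ica_r=65.8 * 1.15,
                             p_vert=65.8 * 1.15)
        passive1 = simulate_fixed_boundaries(b, autoregulation=False,
                                             t_end=600.0)
        rel = passive1.cbf / passive0.cbf - 1.0
        assert rel > 0.10        # roughly proportional to the +15% step
        assert regulated[1.15] < 0.5 * rel

    def test_left_right_symmetry(self):
        """Symmetric boundary pressures give identical left/right pressures
        (and hence flows) throughout the network."""
        st = simulate_fixed_boundaries(CerebralBoundary(), t_end=200.0)
        assert st.pressures["cw_l"] == pytest.approx(st.pressures["cw_r"], abs=1e-8)
        assert st.pressures["mca_l"] == pytest.approx(st.pressures["mca_r"], abs=1e-8)
        assert st.pressures["dm_l"] == pytest.approx(st.pressures["dm_r"], abs=1e-8)

    def test_hypercapnia_raises_cbf(self):
        st40 = simulate_fixed_boundaries(CerebralBoundary(), t_end=500.0)
        st55 = simulate_fixed_boundaries(CerebralBoundary(), t_end=500.0,
                                         paco2=55.0)
        assert st55.cbf > 1.05 * st40.cbf
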