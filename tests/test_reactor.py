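"""Plug-flow reactor model, RK4 integrator, and trajectory invariants."""

import numpy as np
import pytest

from pherokin._fastsim import integrate_reactor
from pherokin.errors import DomainError, IntegrationFailureError, StateConsistencyError
from pherokin.kinetics import KineticParameters
from pherokin.reactor import (
    ImmobilizationParameters,
    ReactorGeometry,
    ReactorState,
    enzyme_activity,
    ode_rhs,
    residence_time,
    rk4_integrate,
    rk4_step,
    simulate_conversion_curve,
)
from pherokin.synthetic import REFERENCE_IMMOBILIZATION, REFERENCE_KINETICS, S0_UM


class TestResidenceTime:
    def test_unit_case(self):
        geom = ReactorGeometry(1.0, 1000.0, 1000.0)  # 1 mm x 1 mm x 1 mm = 1 uL
        assert geom.volume_ul == pytest.approx(1.0)
        assert residence_time(geom, 1.0) == pytest.approx(1.0)

    def test_meandering_channel_geometry(self):
        # 9.8 mm x 250 um x 50 um channel holds 0.1225 uL
        geom = ReactorGeometry(9.8, 250.0, 50.0, void_fraction=1.0)
        assert geom.volume_ul == pytest.approx(0.1225, rel=1e-12)
        assert residence_time(geom, 0.1225) == pytest.approx(1.0, rel=1e-12)

    def test_doubling_flow_halves_tau(self):
        geom = ReactorGeometry(9.8, 300.0, 50.0)
        assert residence_time(geom, 2.0) == pytest.approx(residence_time(geom, 1.0) / 2)

    @pytest.mark.parametrize("flow", [0.0, -1.0])
    def test_non_positive_flow_rejected(self, flow):
        geom = ReactorGeometry(9.8, 250.0, 50.0)
        with pytest.raises(DomainError):
            residence_time(geom, flow)

    def test_void_fraction_bounds(self):
        with pytest.raises(DomainError):
            ReactorGeometry(9.8, 250.0, 50.0, void_fraction=1.5)


class TestEnzymeActivity:
    def test_initial_condition(self):
        immo = ImmobilizationParameters(f_ad=0.34, k_d=1.4, e0=10.0)
        assert enzyme_activity(0.0, immo) == pytest.approx(10.0)

    def test_no_deactivation_limit(self):
        immo = ImmobilizationParameters(f_ad=0.0, k_d=0.0, e0=10.0)
        for t in (0.0, 5.0, 100.0):
            assert enzyme_activity(t, immo) == pytest.approx(10.0)

    def test_half_life_identity(self):
        # K_D = 1.4 1/h gives a ~0.495 h half-life
        immo = ImmobilizationParameters(f_ad=0.34, k_d=1.4, e0=10.0)
        assert enzyme_activity(np.log(2) / 1.4, immo) == pytest.approx(5.0, rel=1e-12)

    def test_negative_age_rejected(self):
        immo = ImmobilizationParameters(f_ad=0.34, k_d=1.4, e0=10.0)
        with pytest.raises(DomainError):
            enzyme_activity(-0.1, immo)


class TestOdeRhs:
    immo = ImmobilizationParameters(f_ad=0.34, k_d=0.0, e0=10.0)

    def test_empty_reactor_fixed_point(self):
        state = ReactorState(s=0.0, es=0.0, p=3.0)
        assert ode_rhs(state, REFERENCE_KINETICS, self.immo) == (0.0, 0.0, 0.0)

    def test_pure_binding_limit(self):
        # k_b = k_r = 0 reduces dS/dtau to -k_f * E_free * S
        params = KineticParameters(k_f=2.0, k_b=1e-300, k_r=1e-300)
        state = ReactorState(s=5.0, es=1.0, p=0.0)
        ds, des, dp = ode_rhs(state, params, self.immo)
        assert ds == pytest.approx(-2.0 * (10.0 - 1.0) * 5.0)
        assert des == pytest.approx(-ds)
        assert dp == pytest.approx(0.0)

    def test_es_exceeding_enzyme_rejected(self):
        state = ReactorState(s=5.0, es=11.0, p=0.0)
        with pytest.raises(StateConsistencyError):
            ode_rhs(state, REFERENCE_KINETICS, self.immo)

    def test_quasi_steady_state_matches_mm_closed_form(self):
        # with E0 << S0 + Km the relaxed complex obeys k_r*ES = Vmax*S/(Km+S)
        rng = np.random.default_rng(42)
        s0 = 119.0
        for _ in range(20):
            k_f = rng.uniform(0.5, 5.0)
            km = rng.uniform(10.0, 100.0)
            split = rng.uniform(0.2, 0.8)
            k_b, k_r = km * k_f * split, km * k_f * (1 - split)
            e0 = 0.01 * (s0 + km)
            lam = k_f * (s0 + e0) + k_b + k_r
            immo = ImmobilizationParameters(f_ad=0.0, k_d=0.0, e0=e0)
            params = KineticParameters(k_f=k_f, k_b=k_b, k_r=k_r)
            traj = simulate_conversion_curve(
                params, immo, s0, tau_max=20.0 / lam, n_points=51
            )
            s, es = traj.s_um[-1], traj.es_um[-1]
            qss_rate = k_r * es
            mm_rate = k_r * e0 * s / (km + s)
            assert qss_rate == pytest.approx(mm_rate, rel=0.01)


class TestRK4:
    @staticmethod
    def decay(_tau, y):
        return -y

    def test_exponential_decay_accuracy(self):
        grid = np.linspace(0.0, 1.0, 101)  # dtau = 0.01
        ys = rk4_integrate(self.decay, [1.0], grid)
        assert ys[-1, 0] == pytest.approx(np.exp(-1.0), abs=1e-8)

    def test_fourth_order_convergence(self):
        # halving the step cuts the global error ~16x: log-log slope in [3.7, 4.3]
        hs = np.array([0.2, 0.1, 0.05, 0.025])
        errors = []
        for h in hs:
            grid = np.arange(0.0, 1.0 + h / 2, h)
            ys = rk4_integrate(self.decay, [1.0], grid)
            errors.append(abs(ys[-1, 0] - np.exp(-1.0)))
        slope = np.polyfit(np.log(hs), np.log(errors), 1)[0]
        assert 3.7 <= slope <= 4.3

    def test_zero_rhs_constant_trajectory(self):
        ys = rk4_integrate(lambda t, y: np.zeros_like(y), [2.0, 3.0], np.linspace(0, 5, 11))
        assert np.all(ys == [2.0, 3.0])

    def test_negative_state_beyond_tolerance_raises(self):
        with pytest.raises(IntegrationFailureError):
            rk4_integrate(lambda t, y: np.array([-1.0]), [0.05], np.linspace(0, 1, 11))

    def test_tiny_negative_clamped_to_zero(self):
        # overshoot into [-1e-9, 0) is clamped to zero, not an error
        ys = rk4_integrate(lambda t, y: np.array([-1e-10]), [5e-11], np.linspace(0, 1, 2))
        assert ys[-1, 0] == 0.0

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(DomainError):
            rk4_integrate(self.decay, [1.0], [0.0, 0.5, 0.5])

    def test_step_requires_positive_dtau(self):
        with pytest.raises(DomainError):
            rk4_step(self.decay, 0.0, np.array([1.0]), 0.0)


class TestSimulateConversionCurve:
    def test_initial_state_is_s0_p0(self):
        traj = simulate_conversion_curve(
            REFERENCE_KINETICS, REFERENCE_IMMOBILIZATION, S0_UM, tau_max=1.0
        )
        assert traj.s_um[0] == S0_UM
        assert traj.p_um[0] == 0.0
        assert traj.conversion[0] == 0.0

    def test_long_time_plateau_from_conservation(self):
        # with K_D = 0, S -> 0 and P -> (1 - F_AD) * S0 = 78.54 uM
        immo = ImmobilizationParameters(f_ad=0.34, k_d=0.0, e0=REFERENCE_IMMOBILIZATION.e0)
        traj = simulate_conversion_curve(REFERENCE_KINETICS, immo, S0_UM, tau_max=30.0)
        assert traj.s_um[-1] == pytest.approx(0.0, abs=1e-6)
        assert traj.p_um[-1] == pytest.approx(0.66 * 119.0, rel=1e-6)

    def test_conservation_invariant_along_trajectory(self):
        traj = simulate_conversion_curve(
            REFERENCE_KINETICS, REFERENCE_IMMOBILIZATION, S0_UM, tau_max=1.5
        )
        total = traj.s_um + traj.es_um + traj.p_um / (1 - 0.34)
        drift = np.max(np.abs(total - S0_UM)) / S0_UM
        assert drift < 1e-6

    def test_monotone_substrate_and_product(self):
        traj = simulate_conversion_curve(
            REFERENCE_KINETICS, REFERENCE_IMMOBILIZATION, S0_UM, tau_max=1.5
        )
        assert np.all(np.diff(traj.s_um) <= 1e-12)
        assert np.all(np.diff(traj.p_um) >= -1e-12)

    def test_no_adsorption_yield_identity(self):
        # F_AD = 0 makes Y(tau) = X(tau) - ES(tau)/S0 a conservation identity
        immo = ImmobilizationParameters(f_ad=0.0, k_d=0.0, e0=REFERENCE_IMMOBILIZATION.e0)
        traj = simulate_conversion_curve(REFERENCE_KINETICS, immo, S0_UM, tau_max=1.5)
        np.testing.assert_allclose(
            traj.yield_, traj.conversion - traj.es_um / S0_UM, atol=1e-9
        )

    def test_deactivation_acts_through_active_enzyme_only(self):
        # aging t hours is exactly a rescaling E0 -> E0 * exp(-K_D * t)
        t_age = 19.0
        scale = np.exp(-1.4 * t_age)
        aged = simulate_conversion_curve(
            REFERENCE_KINETICS, REFERENCE_IMMOBILIZATION, S0_UM,
            tau_max=1.0, enzyme_age_h=t_age,
        )
        immo_scaled = ImmobilizationParameters(
            f_ad=0.34, k_d=1.4, e0=REFERENCE_IMMOBILIZATION.e0 * scale
        )
        fresh = simulate_conversion_curve(
            REFERENCE_KINETICS, immo_scaled, S0_UM, tau_max=1.0
        )
        np.testing.assert_allclose(aged.s_um, fresh.s_um, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(aged.p_um, fresh.p_um, rtol=1e-12, atol=1e-12)


class TestFastIntegratorAgreement:
    def test_fast_path_matches_generic_rk4(self):
        # same algorithm, same steps: the njit fitting path must agree with
        # the public integrator to near round-off
        k = REFERENCE_KINETICS
        immo = REFERENCE_IMMOBILIZATION
        taus = np.array([0.3, 0.6, 1.2])
        h = 1e-3  # below the stability limit so both paths use this step
        s_fast, p_fast, status = integrate_reactor(
            k.k_f, k.k_b, k.k_r, immo.f_ad, immo.e0, S0_UM, 0.0, taus, h, 10**7
        )
        assert status == 0

        def f(_tau, y):
            s, es, _p = y
            e_free = max(immo.e0 - es, 0.0)
            b = k.k_f * e_free * s
            return (-b + k.k_b * es, b - (k.k_b + k.k_r) * es, (1 - immo.f_ad) * k.k_r * es)

        ys = rk4_integrate(f, (S0_UM, 0.0, 0.0), np.concatenate([[0.0], taus]), max_dtau=h)
        np.testing.assert_allclose(s_fast, ys[1:, 0], rtol=1e-10)
        np.testing.assert_allclose(p_fast, ys[1:, 2], rtol=1e-10)

    def test_step_budget_reports_failure(self):
        taus = np.array([1.0])
        _, _, status = integrate_reactor(
            1e5, 1.0, 1.0, 0.34, 63.0, 119.0, 0.0, taus, 1e-3, 1000
        )
        assert status == 1
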