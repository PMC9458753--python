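import math

import numpy as np
import pytest

from resistfam.exceptions import DomainError
from resistfam.resistance_models import (
    MODEL_IDS,
    DoseSchedule,
    ResistanceSpec,
    Transition,
    default_gamma,
    drug_concentration,
    initial_resistance_fraction,
    is_viable,
    simulate_treatment,
    treatment_rhs,
)

FULL_PARAMS = dict(
    r_S=0.1, r_R=0.05, lam_S=0.05, lam_R=0.004, g=0.01, S0=150.0, R0=50.0
)


def params_for(spec, **overrides):
    p = {n: FULL_PARAMS[n] for n in spec.free_params}
    p.update(overrides)
    return p


class TestSpec:
    @pytest.mark.parametrize(
        "model_id,k", [("1.1", 3), ("1.2", 6), ("2.1", 6), ("2.2", 7), ("3.1", 6), ("3.2", 7)]
    )
    def test_parameter_counts(self, model_id, k):
        assert ResistanceSpec(model_id).k == k

    @pytest.mark.parametrize(
        "model_id,transition",
        [("1.1", Transition.none), ("2.2", Transition.random), ("3.1", Transition.drug_induced)],
    )
    def test_transition_map(self, model_id, transition):
        assert ResistanceSpec(model_id).transition is transition

    def test_pre_existing_flag(self):
        assert not ResistanceSpec("2.1").pre_existing
        assert ResistanceSpec("2.2").pre_existing

    def test_unknown_id_rejected(self):
        with pytest.raises(DomainError):
            ResistanceSpec("4.1")


class TestGamma:
    def test_value_to_4dp(self):
        assert round(default_gamma(), 4) == 0.1459

    def test_half_life_identity(self):
        assert math.exp(-default_gamma() * 4.75) == pytest.approx(0.5)

    def test_decay_of_single_dose(self):
        sched = DoseSchedule(dose=5.0, interval=7.0, n_doses=1)
        D = drug_concentration(sched, np.array([4.75]))
        assert D[0] == pytest.approx(2.5)


class TestRhs:
    def test_model_11_drug_free(self):
        spec = ResistanceSpec("1.1")
        dS, dR, dD = treatment_rhs(spec, (200.0, 0.0, 0.0), params_for(spec))
        assert dS == pytest.approx(0.1 * 200)
        assert dR == 0.0

    def test_drug_induced_flux(self):
        spec = ResistanceSpec("3.1")
        p = params_for(spec, g=0.01)
        S, D = 100.0, 5.0
        dS, dR, _ = treatment_rhs(spec, (S, 0.0, D), p)
        flux = 0.01 * S * D
        assert flux == pytest.approx(5.0)
        assert dR == pytest.approx(0.05 * 0.0 + flux - 0.004 * D * 0.0)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_transition_conserves_total(self, model_id):
        spec = ResistanceSpec(model_id)
        p = params_for(spec, r_S=0, lam_S=0)
        for name in ("r_R", "lam_R"):
            if name in p:
                p[name] = 0
        dS, dR, _ = treatment_rhs(spec, (100.0, 20.0, 5.0), p)
        assert dS + dR == pytest.approx(0.0, abs=1e-12)

    def test_negative_state_rejected(self):
        spec = ResistanceSpec("1.1")
        with pytest.raises(DomainError):
            treatment_rhs(spec, (-1.0, 0.0, 0.0), params_for(spec))

    def test_drug_decay_term(self):
        spec = ResistanceSpec("1.1")
        _, _, dD = treatment_rhs(spec, (1.0, 0.0, 10.0), params_for(spec), gamma=0.2)
        assert dD == pytest.approx(-2.0)


class TestViability:
    def test_growth_disadvantage_required(self):
        spec = ResistanceSpec("2.2")
        assert not is_viable(spec, params_for(spec, r_S=0.1, r_R=0.12))

    def test_model_11_no_r_constraints(self):
        spec = ResistanceSpec("1.1")
        assert is_viable(spec, {"r_S": 0.1, "lam_S": 0.05, "S0": 200.0})

    def test_equal_kill_rates_rejected(self):
        spec = ResistanceSpec("1.2")
        assert not is_viable(spec, params_for(spec, lam_S=0.05, lam_R=0.05))

    def test_negative_parameter_rejected(self):
        spec = ResistanceSpec("1.2")
        assert not is_viable(spec, params_for(spec, r_R=-0.01))

    def test_r0_forced_zero_for_x1(self):
        spec = ResistanceSpec("2.1")
        assert not is_viable(spec, {**params_for(spec), "R0": 10.0})


class TestInitialResistanceFraction:
    def test_zero(self):
        assert initial_resistance_fraction({"S0": 100, "R0": 0}) == 0

    def test_half(self):
        assert initial_resistance_fraction({"S0": 50, "R0": 50}) == 0.5

    def test_tenth(self):
        assert initial_resistance_fraction({"S0": 90, "R0": 10}) == pytest.approx(0.1)

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            initial_resistance_fraction({"S0": 0, "R0": 0})


class TestSimulate:
    def test_drug_jump_after_week(self):
        sched = DoseSchedule(dose=5.0, interval=7.0, n_doses=2)
        spec = ResistanceSpec("1.1")
        traj = simulate_treatment(
            spec, params_for(spec), sched, np.array([0.0, 6.999, 7.0])
        )
        g = default_gamma()
        assert traj.D[0] == pytest.approx(5.0)
        assert traj.D[1] == pytest.approx(5 * math.exp(-g * 6.999), rel=1e-6)
        assert traj.D[2] == pytest.approx(5 * math.exp(-g * 7) + 5, rel=1e-9)
        assert traj.D[2] == pytest.approx(6.80, abs=0.005)

    def test_pre_dose_flag(self):
        sched = DoseSchedule(dose=5.0, interval=7.0, n_doses=2)
        spec = ResistanceSpec("1.1")
        traj = simulate_treatment(
            spec, params_for(spec), sched, np.array([0.0, 7.0]), pre_dose=True
        )
        g = default_gamma()
        assert traj.D[0] == pytest.approx(0.0)
        assert traj.D[1] == pytest.approx(5 * math.exp(-g * 7))

    def test_model_11_closed_form(self):
        spec = ResistanceSpec("1.1")
        p = {"r_S": 0.12, "lam_S": 0.04, "S0": 180.0}
        sched = DoseSchedule(dose=5.0, interval=7.0, n_doses=6)
        times = np.linspace(0.0, 40.0, 81)
        traj = simulate_treatment(spec, p, sched, times)
        g = default_gamma()

        def int_D(t):
            return sum(
                5.0 * (1 - math.exp(-g * (t - td))) / g
                for td in sched.dose_times()
                if t >= td
            )

        expect = np.array(
            [p["S0"] * math.exp(p["r_S"] * t - p["lam_S"] * int_D(t)) for t in times]
        )
        np.testing.assert_allclose(traj.V, expect, rtol=1e-6)

    def test_drug_free_exponential_mixture(self):
        spec = ResistanceSpec("2.2")
        p = params_for(spec, lam_S=1e-12, lam_R=0.0, g=0.0)
        sched = DoseSchedule(dose=0.0, interval=7.0, n_doses=5)
        times = np.linspace(0.0, 28.0, 29)
        traj = simulate_treatment(spec, p, sched, times)
        expect = p["S0"] * np.exp(p["r_S"] * times) + p["R0"] * np.exp(p["r_R"] * times)
        np.testing.assert_allclose(traj.V, expect, rtol=1e-8)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_analytic_matches_rk_oracle(self, model_id, weekly_schedule):
        spec = ResistanceSpec(model_id)
        p = params_for(spec)
        times = np.array([0.0, 2.0, 5.0, 7.0, 11.0, 14.0, 20.0, 28.0, 40.0, 56.0])
        a = simulate_treatment(spec, p, weekly_schedule, times, method="analytic")
        b = simulate_treatment(spec, p, weekly_schedule, times, method="rk")
        np.testing.assert_allclose(a.V, b.V, rtol=1e-6)
        np.testing.assert_allclose(a.S, b.S, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(a.R, b.R, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_states_stay_nonnegative(self, model_id, weekly_schedule):
        spec = ResistanceSpec(model_id)
        times = np.linspace(0.0, 56.0, 113)
        traj = simulate_treatment(spec, params_for(spec), weekly_schedule, times)
        for series in (traj.S, traj.R, traj.D):
            assert np.all(series >= -1e-9)

    def test_more_kill_means_less_sensitive(self, weekly_schedule):
        spec = ResistanceSpec("1.1")
        times = np.linspace(1.0, 42.0, 42)
        low = simulate_treatment(
            spec, {"r_S": 0.1, "lam_S": 0.02, "S0": 200.0}, weekly_schedule, times
        )
        high = simulate_treatment(
            spec, {"r_S": 0.1, "lam_S": 0.05, "S0": 200.0}, weekly_schedule, times
        )
        assert np.all(high.S < low.S)

    def test_piecewise_equals_manual_restart(self):
        # integrating across a dose impulse == restarting with D reset by hand
        spec = ResistanceSpec("2.1")
        p = params_for(spec)
        sched = DoseSchedule(dose=5.0, interval=7.0, n_doses=2)
        full = simulate_treatment(spec, p, sched, np.array([0.0, 7.0, 10.0]))
        # manual: run [0,7], then restart at 7 with D + 5 as a fresh single-dose
        first = simulate_treatment(
            spec, p, DoseSchedule(dose=5.0, n_doses=1), np.array([0.0, 7.0])
        )
        g = default_gamma()
        d7 = 5.0 * math.exp(-g * 7.0) + 5.0
        restart_params = dict(p, S0=float(first.S[1]), R0=float(first.R[1]))
        spec22 = ResistanceSpec("2.2")
        second = simulate_treatment(
            spec22, restart_params, DoseSchedule(dose=d7, n_doses=1), np.array([0.0, 3.0])
        )
        assert full.V[2] == pytest.approx(float(second.V[1]), rel=1e-9)
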