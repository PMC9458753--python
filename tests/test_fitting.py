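import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from resistfam.cohort import Group, TumorTimecourse
from resistfam.exceptions import DomainError, FitError
from resistfam.fitting import (
    FitConfig,
    FitProblem,
    default_bounds,
    gradient_descent,
    make_resistance_problem,
    multistart,
    multistart_fit,
    perturbation_range,
    qmc_search,
    scale_sobol_point,
    sse,
)
from resistfam.resistance_models import DoseSchedule, ResistanceSpec


def exp_problem(r_true=0.08, v0=200.0, times=None):
    """1-parameter exponential toy: fit r with V0 known."""
    times = np.linspace(0, 30, 11) if times is None else times
    observed = v0 * np.exp(r_true * times)
    return FitProblem(
        param_names=("r",),
        lo=np.array([0.0]),
        hi=np.array([0.2]),
        predict=lambda P: v0 * np.exp(np.atleast_2d(P)[:, [0]] * times[None, :]),
        viable=lambda P: np.ones(np.atleast_2d(P).shape[0], dtype=bool),
        observed=observed,
    )


class TestSse:
    def test_identity(self, treated_tc):
        assert sse(treated_tc.volumes, treated_tc) == 0

    def test_hand_sum(self):
        assert sse([0.0, 0.0], [1.0, 2.0]) == 5.0

    def test_censored_point_excluded(self):
        tc = TumorTimecourse(
            "m", Group.treatment, np.array([0.0, 3.0, 6.0]),
            np.array([1.0, 9.0, 2.0]), [False, True, False],
        )
        assert sse(np.array([1.0, 0.0, 2.0]), tc) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            sse([1.0], [1.0, 2.0])


class TestBounds:
    def test_defaults_resolve_v0(self):
        b = default_bounds(ResistanceSpec("2.2"), v0=150.0)
        assert b["r_S"] == (0.0, 0.2)
        assert b["r_R"] == (0.0, 0.1)
        assert b["g"] == (0.0, 0.1)
        assert b["S0"] == (0.0, 300.0)
        assert b["R0"] == (0.0, 300.0)

    def test_scale_endpoints(self):
        bounds = [(0.0, 0.2), (1.0, 3.0)]
        np.testing.assert_allclose(scale_sobol_point([0, 0], bounds), [0.0, 1.0])
        np.testing.assert_allclose(scale_sobol_point([1, 1], bounds), [0.2, 3.0])

    def test_scale_midpoint_r_s(self):
        assert scale_sobol_point([0.5], [(0.0, 0.2)])[0] == pytest.approx(0.1)

    def test_out_of_unit_cube_rejected(self):
        with pytest.raises(DomainError):
            scale_sobol_point([1.5], [(0, 1)])


class TestQmc:
    def test_single_point(self):
        prob = exp_problem()
        res = qmc_search(prob, n_points=1)
        # first unscrambled Sobol point is the origin -> r = 0
        assert res.params[0] == pytest.approx(0.0)
        assert res.n_viable == 1

    def test_beats_random_search(self):
        prob = exp_problem()
        res = qmc_search(prob, n_points=1024)
        rng = np.random.default_rng(0)
        draws = rng.uniform(0, 0.2, size=(1000, 1))
        assert res.sse <= prob.sse_batch(draws).min()

    def test_viability_filter(self):
        prob = exp_problem()
        filtered = FitProblem(
            param_names=prob.param_names, lo=prob.lo, hi=prob.hi,
            predict=prob.predict,
            viable=lambda P: np.atleast_2d(P)[:, 0] > 0.1,
            observed=prob.observed,
        )
        res = qmc_search(filtered, n_points=256)
        assert res.params[0] > 0.1

    def test_no_viable_point_raises(self):
        prob = exp_problem()
        dead = FitProblem(
            param_names=prob.param_names, lo=prob.lo, hi=prob.hi,
            predict=prob.predict,
            viable=lambda P: np.zeros(np.atleast_2d(P).shape[0], dtype=bool),
            observed=prob.observed,
        )
        with pytest.raises(FitError, match="n_points"):
            qmc_search(dead, n_points=64)

    def test_deterministic_given_seed(self):
        prob = exp_problem()
        a = qmc_search(prob, n_points=512, seed=3, scramble=True)
        b = qmc_search(prob, n_points=512, seed=3, scramble=True)
        np.testing.assert_array_equal(a.params, b.params)
        assert a.sse == b.sse


class TestPerturbationRange:
    def test_paper_example(self):
        assert perturbation_range(0.2) == (-1e-2, 1e-2)

    def test_order_two(self):
        assert perturbation_range(200.0) == (-10.0, 10.0)

    def test_zero_convention(self):
        assert perturbation_range(0.0) == (-1e-4, 1e-4)

    def test_symmetric(self):
        lo, hi = perturbation_range(0.037)
        assert lo == -hi
        assert hi == pytest.approx(1e-3)


class TestGradientDescent:
    def test_no_iterations_is_noop(self):
        prob = exp_problem()
        res = gradient_descent(prob, np.array([0.05]), n_iter=0, rng=0)
        assert res.params[0] == 0.05

    def test_trace_monotone_nonincreasing(self):
        prob = exp_problem()
        res = gradient_descent(prob, np.array([0.02]), n_iter=2000, rng=1)
        assert np.all(np.diff(res.trace) <= 0)

    def test_converges_on_1d_toy(self):
        r_true = 0.08
        prob = exp_problem(r_true=r_true)
        res = gradient_descent(prob, np.array([r_true + 0.01]), n_iter=10_000, rng=2)
        # golden-section oracle on the same objective
        oracle = minimize_scalar(
            lambda r: prob.sse_batch(np.array([[r]]))[0],
            bracket=(0.0, 0.2),
            method="golden",
        )
        assert abs(res.params[0] - r_true) < 1e-3
        assert abs(res.params[0] - oracle.x) < 1e-3

    def test_nonviable_start_rejected(self):
        prob = exp_problem()
        bad = FitProblem(
            param_names=prob.param_names, lo=prob.lo, hi=prob.hi,
            predict=prob.predict,
            viable=lambda P: np.atleast_2d(P)[:, 0] < 0.01,
            observed=prob.observed,
        )
        with pytest.raises(DomainError):
            gradient_descent(bad, np.array([0.05]), n_iter=10, rng=0)


class TestMultistart:
    def test_final_is_per_start_minimum(self, treated_tc):
        spec = ResistanceSpec("1.1")
        cfg = FitConfig(n_qmc=512, n_iter=200, n_starts=4, seed=5)
        fit = multistart_fit(spec, treated_tc, cfg)
        finals = [s.final_sse for s in fit.per_start]
        assert fit.sse == pytest.approx(min(finals))
        assert fit.sse <= min(s.qmc_sse for s in fit.per_start)

    def test_deterministic(self, treated_tc):
        spec = ResistanceSpec("1.1")
        cfg = FitConfig(n_qmc=256, n_iter=100, n_starts=3, seed=11)
        a = multistart_fit(spec, treated_tc, cfg)
        b = multistart_fit(spec, treated_tc, cfg)
        assert a == b

    def test_linear_toy_matches_normal_equations(self):
        # fit y = a + b t with the same machinery; closed-form OLS oracle
        times = np.linspace(0, 10, 12)
        rng = np.random.default_rng(7)
        y = 3.0 + 0.7 * times + rng.normal(0, 0.1, len(times))
        prob = FitProblem(
            param_names=("a", "b"),
            lo=np.array([0.0, 0.0]),
            hi=np.array([10.0, 2.0]),
            predict=lambda P: (
                np.atleast_2d(P)[:, [0]] + np.atleast_2d(P)[:, [1]] * times[None, :]
            ),
            viable=lambda P: np.ones(np.atleast_2d(P).shape[0], dtype=bool),
            observed=y,
        )
        params, best_sse, _ = multistart(prob, FitConfig(4096, 4000, 3, seed=1))
        X = np.column_stack([np.ones_like(times), times])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        ols_sse = float(((X @ beta - y) ** 2).sum())
        assert best_sse <= ols_sse * 1.01

    def test_scaling_invariance_exponential_family(self):
        # doubling V0 and all volumes doubles S0 and leaves rates unchanged
        times = np.array([0.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0])
        spec = ResistanceSpec("1.1")
        sched = DoseSchedule(dose=5.0, interval=7.0, n_doses=5)
        from resistfam.resistance_models import simulate_treatment

        base_params = {"r_S": 0.1, "lam_S": 0.05, "S0": 200.0}
        v = simulate_treatment(spec, base_params, sched, times).V
        cfg = FitConfig(n_qmc=2048, n_iter=2000, n_starts=3, seed=3)
        fit1 = multistart_fit(
            spec, TumorTimecourse("a", Group.treatment, times, v), cfg, schedule=sched
        )
        fit2 = multistart_fit(
            spec, TumorTimecourse("a", Group.treatment, times, 2 * v), cfg,
            schedule=sched,
        )
        assert fit2.best_params["S0"] == pytest.approx(
            2 * fit1.best_params["S0"], rel=0.05
        )
        assert fit2.best_params["r_S"] == pytest.approx(
            fit1.best_params["r_S"], abs=0.01
        )

    def test_viability_preserved_at_optimum(self, treated_tc):
        from resistfam.resistance_models import is_viable

        spec = ResistanceSpec("2.2")
        cfg = FitConfig(n_qmc=512, n_iter=300, n_starts=2, seed=9)
        fit = multistart_fit(spec, treated_tc, cfg)
        assert is_viable(spec, fit.best_params)
        total = fit.best_params["S0"] + fit.best_params["R0"]
        assert 0 < total <= 2 * treated_tc.v0
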