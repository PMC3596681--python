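"""Optimizers: perturbation search (3^m enumeration) and Gauss-Newton."""

import itertools

import numpy as np
import pytest

from gttfit import (
    Diverged,
    IntegratorConfig,
    ObjectiveConfig,
    PerturbConfig,
    SingularNormalEquations,
    SynthConfig,
    ValidationError,
    finite_difference_gradient,
    gauss_newton,
    gauss_newton_core,
    perturbation_search,
    perturbation_step,
    simulate_gtt,
    table1_fixture,
)
from gttfit.errors import NumericalError


class CountingObjective:
    def __init__(self, fn):
        self.fn = fn
        self.calls = 0

    def __call__(self, p):
        self.calls += 1
        return self.fn(p)


class TestPerturbationStep:
    def test_enumeration_count_is_3_to_the_m(self):
        """Five parameters, three levels each: exactly 243 objective calls."""
        obj = CountingObjective(lambda p: float(np.sum((p - 1.0) ** 2)))
        p = np.full(5, 2.0)
        perturbation_step(p, np.full(5, 0.1), obj, obj.fn(p))
        assert obj.calls == 243

    def test_one_dimensional_quadratic_moves_toward_minimum(self):
        # (p-1)^2 at p=0 with delta 0.5: candidates {-0.5, 0, 0.5} score
        # {2.25, 1, 0.25}; positivity off so the negative candidate is scored
        obj = lambda p: float((p[0] - 1.0) ** 2)
        new_p, new_ssr = perturbation_step(np.array([0.0]), np.array([0.5]), obj,
                                           obj(np.array([0.0])), enforce_positive=False)
        assert new_p[0] == pytest.approx(0.5)
        assert new_ssr == pytest.approx(0.25)

    def test_no_improvement_returns_input_unchanged(self):
        obj = lambda p: float(np.sum(p**2))
        p = np.array([1e-9, 1e-9])  # already at the grid minimum
        new_p, new_ssr = perturbation_step(p, np.array([1.0, 1.0]), obj, obj(p),
                                           enforce_positive=False)
        assert np.array_equal(new_p, p)
        assert new_ssr == obj(p)

    @pytest.mark.parametrize("centre", [(0.3, 0.9), (1.5, 0.2)])
    def test_matches_exhaustive_enumeration_oracle(self, centre):
        """The chosen candidate equals the argmin of an independent exhaustive
        enumeration of the 3^2 grid on a fixed quadratic."""
        obj = lambda p: float((p[0] - 1.0) ** 2 + 2.0 * (p[1] - 0.5) ** 2)
        p = np.array(centre)
        d = np.array([0.25, 0.25])
        grid = [p + np.array(s) * d for s in itertools.product((-1, 0, 1), repeat=2)]
        oracle_best = min(grid, key=lambda c: obj(c))
        new_p, _ = perturbation_step(p, d, obj, obj(p), enforce_positive=False)
        if obj(oracle_best) < obj(p):
            assert np.allclose(new_p, oracle_best)
        else:
            assert np.array_equal(new_p, p)

    def test_failing_candidates_are_skipped_not_fatal(self):
        def obj(p):
            if p[0] < 1.0:
                raise NumericalError("boom")
            return float(p[0])

        new_p, new_ssr = perturbation_step(np.array([1.5]), np.array([1.0]), obj,
                                           obj(np.array([1.5])), enforce_positive=False)
        assert np.array_equal(new_p, np.array([1.5]))  # only failing moves improve


class TestPerturbationSearch:
    def test_fixed_point_at_truth(self, case1_params, noise_free_case1,
                                  fast_objective_config):
        res = perturbation_search(case1_params.as_array(), noise_free_case1,
                                  fast_objective_config)
        assert res.ssr < 1e-9
        assert np.allclose(res.params, case1_params.as_array(), rtol=1e-4)

    def test_recovery_from_inflated_start(self, case1_params, noise_free_case1,
                                          fast_objective_config):
        """Starting 20% high in every rate, the search returns to the truth."""
        truth = case1_params.as_array()
        res = perturbation_search(truth * 1.2, noise_free_case1, fast_objective_config,
                                  PerturbConfig(min_delta_fraction=1e-5))
        assert res.ssr < 1e-4
        assert np.max(np.abs(res.params - truth) / truth) < 0.05

    def test_improves_on_published_parameters(self, case1_params, table1,
                                              fast_objective_config):
        """Restarted from the published fit, the search must end at or below
        the published parameters' own SSR (<0.1 on the measured series)."""
        case1, _ = table1
        res = perturbation_search(case1_params.as_array(), case1, fast_objective_config,
                                  PerturbConfig(max_iterations=60,
                                                min_delta_fraction=1e-4))
        assert res.ssr <= 0.1

    def test_trace_non_increasing_and_consistent(self, case1_params, table1,
                                                 fast_objective_config):
        case1, _ = table1
        res = perturbation_search(case1_params.as_array() * 1.1, case1,
                                  fast_objective_config,
                                  PerturbConfig(max_iterations=30,
                                                min_delta_fraction=1e-4))
        trace = res.ssr_trace
        assert all(b <= a for a, b in zip(trace, trace[1:]))
        assert res.ssr == trace[-1]

    def test_rejects_non_positive_start(self, table1, fast_objective_config):
        case1, _ = table1
        with pytest.raises(ValidationError):
            perturbation_search(np.array([0.01, -0.01, 0.01, 0.01]), case1,
                                fast_objective_config)


class TestFiniteDifferenceGradient:
    def test_central_is_exact_for_quadratics(self):
        obj = lambda p: float(p[0] ** 2)
        g = finite_difference_gradient(obj, np.array([2.0]), np.array([0.1]), "central")
        assert g[0] == pytest.approx(4.0, abs=1e-12)

    def test_forward_carries_first_order_bias(self):
        obj = lambda p: float(p[0] ** 2)
        g = finite_difference_gradient(obj, np.array([2.0]), np.array([0.1]), "forward")
        assert g[0] == pytest.approx(4.1, abs=1e-12)

    def test_backward_bias_mirrors_forward(self):
        obj = lambda p: float(p[0] ** 2)
        g = finite_difference_gradient(obj, np.array([2.0]), np.array([0.1]), "backward")
        assert g[0] == pytest.approx(3.9, abs=1e-12)

    @pytest.mark.parametrize("scheme", ["forward", "backward", "central"])
    def test_constant_objective_has_zero_gradient(self, scheme):
        g = finite_difference_gradient(lambda p: 7.0, np.ones(3), np.full(3, 0.1), scheme)
        assert np.array_equal(g, np.zeros(3))


class TestGaussNewton:
    def test_linear_model_converges_in_one_iteration(self):
        """g(t) = -p*t on exact data: the linearisation is exact, so the first
        normal-equations solve lands on the least-squares solution."""
        t = np.array([1.0, 2.0, 3.0])
        obs = -2.5 * t

        def residual_fn(p):
            return obs - (-p[0] * t)

        res = gauss_newton_core(residual_fn, np.array([1.0]))
        assert res.params[0] == pytest.approx(2.5, rel=1e-8)
        assert res.ssr_trace[1] == pytest.approx(0.0, abs=1e-16)

    def test_recovers_rates_from_nearby_start(self, case1_params, noise_free_case1,
                                              fast_objective_config):
        truth = case1_params.as_array()
        res = gauss_newton(truth * 1.05, noise_free_case1, fast_objective_config)
        assert res.termination == "converged"
        assert np.max(np.abs(res.params - truth) / truth) < 0.01

    def test_far_start_fails_loudly_not_silently(self, table1, fast_objective_config):
        """Poor starts must raise a distinct numerical error (the fragility
        that motivates the derivative-free search), never return garbage."""
        case1, _ = table1
        with pytest.raises((SingularNormalEquations, Diverged, NumericalError)):
            gauss_newton(np.array([0.02185, 0.2008, 0.14945, 0.0225]), case1,
                         fast_objective_config)

    def test_divergence_raises_after_five_growing_steps(self):
        # Newton on cbrt doubles the iterate and grows the SSR every step
        res_fn = lambda p: np.array([np.cbrt(p[0])])
        with pytest.raises(Diverged):
            gauss_newton_core(res_fn, np.array([1.0]), max_iter=50)

    def test_underdetermined_problem_rejected(self):
        with pytest.raises(ValidationError):
            gauss_newton_core(lambda p: np.array([p[0]]), np.array([1.0, 2.0]))
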