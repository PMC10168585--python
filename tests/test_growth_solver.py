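import dataclasses

import pytest

from rbakit import (
    AnalysisSettings,
    LinearProblem,
    Medium,
    Row,
    UnboundedGrowthError,
    Variable,
    build_lp,
    is_feasible,
    maximize_growth,
    optimize_at_growth,
    solve_lp,
)
from rbakit import toys
from rbakit.parameters import linear_bounded
from conftest import dense_mu_max


class TestSolveLP:
    def test_trivial_maximization(self):
        problem = LinearProblem(
            mu=0.0,
            variables=(Variable("x", "flux", 0.0, float("inf")),),
            rows=(Row("cap", "target", {"x": 1.0}, "<=", 3.0),),
            objective={"x": 1.0},
            sense="max",
        )
        state = solve_lp(problem)
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(3.0)

    def test_contradictory_rows_are_infeasible(self):
        problem = LinearProblem(
            mu=0.0,
            variables=(Variable("x", "flux", 0.0, float("inf")),),
            rows=(Row("impossible", "target", {"x": 1.0}, "<=", -1.0),),
        )
        assert solve_lp(problem).status == "infeasible"

    def test_unbounded_objective_reported(self):
        problem = LinearProblem(
            mu=0.0,
            variables=(Variable("x", "flux", 0.0, float("inf")),),
            rows=(),
            objective={"x": 1.0},
            sense="max",
        )
        assert solve_lp(problem).status == "unbounded"

    def test_parsimonious_solve_is_rechecked_feasible(self, self_replicator):
        problem = build_lp(self_replicator, mu=0.5)
        objective = {v.name: 1.0 for v in problem.variables if v.kind != "flux"}
        state = solve_lp(problem.with_objective(objective, "min"))
        assert state.status == "optimal"
        assert state.max_violation <= 1e-8


class TestIsFeasible:
    def test_target_free_model_feasible_at_zero_growth(self, self_replicator):
        assert is_feasible(self_replicator, 0.0)

    def test_feasibility_boundary_matches_closed_form(self, self_replicator):
        assert is_feasible(self_replicator, 0.99)
        assert not is_feasible(self_replicator, 1.01)

    def test_pinned_toy_boundary(self, pinned):
        assert is_feasible(pinned, 0.79)
        assert not is_feasible(pinned, 0.81)


class TestMaximizeGrowth:
    def test_self_replicator_closed_form(self, self_replicator):
        assert maximize_growth(self_replicator).mu == pytest.approx(1.0, rel=2e-6)

    def test_asymmetric_efficiencies_closed_form(self):
        model = toys.make_self_replicator(kE=2, kR=6, n_E=1, n_R=1, D=1)
        assert maximize_growth(model).mu == pytest.approx(1.5, rel=2e-6)

    def test_pinned_optimum_is_the_hand_solution(self, pinned):
        state = maximize_growth(pinned)
        assert state.mu == pytest.approx(0.8, rel=2e-6)
        assert state.enzyme_concentrations["uptake_enzyme"] == pytest.approx(0.4, abs=1e-5)
        assert state.machine_concentrations["translation"] == pytest.approx(0.4, abs=1e-5)

    def test_reported_state_satisfies_constraints(self, pinned):
        state = maximize_growth(pinned)
        assert state.status == "optimal"
        assert state.max_violation <= 1e-8

    def test_unbounded_growth_is_a_diagnostic(self):
        # efficiencies growing linearly with mu outpace dilution forever
        model = toys.make_self_replicator()
        runaway = linear_bounded(1.0, 4.0, 1.0, 1e9)
        enzymes = {
            "uptake_enzyme": dataclasses.replace(
                model.enzymes["uptake_enzyme"], forward_efficiency=runaway
            )
        }
        processes = {
            "translation": dataclasses.replace(
                model.processes["translation"], efficiency=runaway
            )
        }
        pathological = dataclasses.replace(model, enzymes=enzymes, processes=processes)
        with pytest.raises(UnboundedGrowthError):
            maximize_growth(pathological)

    def test_infeasible_at_zero_growth_reported(self, pinned):
        from rbakit import Target, impose_target
        from rbakit.parameters import constant

        blocked = impose_target(
            pinned, Target("impossible", "concentration_ge", "housekeeping_protein", constant(5.0))
        )
        state = maximize_growth(blocked)
        assert state.status == "infeasible" and state.mu == 0.0

    @pytest.mark.parametrize("lam", [0.25, 1.0, 3.0])
    def test_homogeneity_in_all_efficiencies(self, pinned, lam, settings):
        from rbakit import scale_efficiency

        scaled = pinned
        for catalyst in ("uptake_enzyme", "translation"):
            scaled = scale_efficiency(scaled, catalyst, lam)
        assert maximize_growth(scaled).mu == pytest.approx(
            lam * maximize_growth(pinned).mu, rel=10 * settings.bisection_tol
        )

    def test_bisection_agrees_with_dense_grid_oracle(self, pinned):
        mu_bisect = maximize_growth(pinned).mu
        mu_scan, resolution = dense_mu_max(pinned, n_points=2000)
        assert abs(mu_bisect - mu_scan) <= 2 * resolution


class TestOptimizeAtGrowth:
    def test_machine_maximization_hand_lp(self, pinned):
        state = optimize_at_growth(pinned, 0.4, objective={"translation": 1.0}, sense="max")
        assert state.objective_value == pytest.approx(0.6, abs=1e-8)

    def test_machine_minimization_hand_lp(self, pinned):
        state = optimize_at_growth(pinned, 0.4, objective={"translation": 1.0}, sense="min")
        assert state.objective_value == pytest.approx(1.0 / 15.0, abs=1e-8)

    def test_zero_objective_returns_a_feasible_point(self, pinned):
        state = optimize_at_growth(pinned, 0.4, objective={})
        assert state.status == "optimal"
        assert state.max_violation <= 1e-8

    def test_above_maximal_growth_is_infeasible(self, pinned):
        state = optimize_at_growth(pinned, 0.9, objective={"translation": 1.0}, sense="max")
        assert state.status == "infeasible"
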