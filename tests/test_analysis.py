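import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from rbakit import (
    AnalysisSettings,
    Medium,
    Metabolite,
    Reaction,
    default_factor_grid,
    find_min_substrate,
    find_switch_concentration,
    is_feasible,
    local_sensitivities,
    maximize_growth,
    medium_screen,
    optimize_at_growth,
    parameter_screen,
    pareto_front,
    production_tradeoff,
    rva_over_growth,
    sample_ensemble,
    variability_analysis,
)
from rbakit import toys


class TestMediumScreen:
    def test_monod_curve_values_and_monotonicity(self, importer):
        grid = [0.0, 0.05, 0.1, 1.0, 100.0]
        result = medium_screen(importer, "nutrient_ext", grid, flux_ids=["uptake"])
        mus = result.table["mu_max"].to_numpy()
        assert list(result.table["nutrient_ext"]) == grid
        assert mus[0] == pytest.approx(0.0, abs=1e-5)  # no import, no growth
        assert mus[2] == pytest.approx(8.0 / 15.0, rel=1e-4)  # half-saturation
        assert mus[-1] == pytest.approx(0.8, rel=1e-3)  # saturated plateau
        assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))

    def test_per_point_failures_do_not_abort_the_screen(self, importer):
        with pytest.raises(ValueError):
            medium_screen(importer, "nutrient_ext", [-1.0])
        result = medium_screen(importer, "nutrient_ext", [0.1])
        assert list(result.table["status"]) == ["optimal"]

    def test_non_external_axis_rejected(self, importer):
        with pytest.raises(KeyError):
            medium_screen(importer, "precursor", [1.0])


class TestFindMinSubstrate:
    def test_inverse_of_the_monod_curve(self, importer, settings):
        conc = find_min_substrate(importer, "nutrient_ext", 8.0 / 15.0)
        assert conc == pytest.approx(0.1, rel=1e-3)
        mu = maximize_growth(importer, Medium({"nutrient_ext": conc}), settings).mu
        assert mu >= 8.0 / 15.0 - 1e-9

    def test_zero_target_needs_no_substrate(self, importer):
        assert find_min_substrate(importer, "nutrient_ext", 0.0) == 0.0

    def test_asymptotic_plateau_is_reported_unreachable(self, importer):
        with pytest.raises(ValueError, match="unreachable"):
            find_min_substrate(importer, "nutrient_ext", 0.8, conc_scan_max=1e6)


class TestParameterScreen:
    def test_default_grid_spans_published_range(self):
        grid = default_factor_grid()
        assert grid[0] == pytest.approx(0.01)
        assert grid[-1] == pytest.approx(100.0)

    def test_ribosome_scaling_closed_form(self, self_replicator):
        result = parameter_screen(self_replicator, "translation", [0.5, 1.0, 2.0])
        assert list(result.table["mu_max"]) == pytest.approx(
            [2.0 / 3.0, 1.0, 4.0 / 3.0], rel=1e-5
        )

    def test_growth_is_monotone_in_the_scaling_factor(self, pinned):
        result = parameter_screen(pinned, "uptake_enzyme", default_factor_grid(9))
        mus = result.table["mu_max"].to_numpy()
        assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))


class TestLocalSensitivities:
    def test_symmetric_catalysts_split_control_evenly(self, pinned):
        report = local_sensitivities(pinned)
        values = dict(zip(report.table["parameter"], report.table["sensitivity"]))
        assert values["uptake_enzyme"] == pytest.approx(0.5, abs=1e-4)
        assert values["translation"] == pytest.approx(0.5, abs=1e-4)

    def test_sensitivities_sum_to_one_on_constant_efficiency_toys(self, secretion):
        report = local_sensitivities(secretion)
        assert report.table["sensitivity"].sum() == pytest.approx(1.0, abs=1e-3)

    def test_unused_pathway_has_exactly_zero_control(self, overflow, overflow_medium):
        # far below the switch, the overflow branch carries no flux
        medium = overflow_medium.updated(substrate_ext=0.01)
        report = local_sensitivities(overflow, medium, parameter_ids=["overflow_enzyme"])
        assert report.table["sensitivity"].iloc[0] == 0.0

    def test_infeasible_reference_rejected(self, importer):
        with pytest.raises(ValueError):
            local_sensitivities(importer, Medium({"nutrient_ext": 0.0}))


class TestSampleEnsemble:
    def test_same_seed_reproduces_bitwise(self, pinned):
        settings = AnalysisSettings(ensemble_n=5, seed=11)
        a = sample_ensemble(pinned, settings=settings, flux_ids=["uptake"])
        b = sample_ensemble(pinned, settings=settings, flux_ids=["uptake"])
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_different_seeds_draw_different_factors(self, pinned):
        a = sample_ensemble(pinned, settings=AnalysisSettings(ensemble_n=3, seed=1))
        b = sample_ensemble(pinned, settings=AnalysisSettings(ensemble_n=3, seed=2))
        assert not a.table["factor:uptake_enzyme"].equals(b.table["factor:uptake_enzyme"])

    def test_vanishing_sigma_recovers_the_reference(self, pinned, settings):
        narrow = AnalysisSettings(ensemble_n=4, ensemble_sigma=1e-12, seed=3)
        result = sample_ensemble(pinned, settings=narrow)
        reference = maximize_growth(pinned).mu
        assert np.allclose(result.table["mu_max"], reference, rtol=10 * settings.bisection_tol)


class TestVariabilityAnalysis:
    def test_machine_range_at_half_maximal_growth(self, pinned):
        result = variability_analysis(pinned, 0.4, variable_ids=["translation"])
        row = result.table.iloc[0]
        assert row["min"] == pytest.approx(1.0 / 15.0, abs=1e-6)
        assert row["max"] == pytest.approx(0.6, abs=1e-6)

    def test_feasible_region_collapses_at_maximal_growth(self, pinned):
        result = variability_analysis(pinned, 0.8, variable_ids=["translation"])
        row = result.table.iloc[0]
        assert row["min"] == pytest.approx(0.4, abs=1e-6)
        assert row["max"] == pytest.approx(0.4, abs=1e-6)

    def test_above_maximal_growth_everything_is_infeasible(self, pinned):
        result = variability_analysis(pinned, 0.9, variable_ids=["translation", "uptake"])
        assert (result.table["status_min"] == "infeasible").all()
        assert (result.table["status_max"] == "infeasible").all()

    def test_free_spontaneous_cycle_is_reported_unbounded(self, pinned):
        # two spontaneous reversible conversions of the same pool form a
        # cycle whose circulating flux nothing bounds
        loop_a = Reaction("loop_a", {"precursor": -1.0, "pool2": 1.0}, reversible=True)
        loop_b = Reaction("loop_b", {"precursor": -1.0, "pool2": 1.0}, reversible=True)
        model = dataclasses.replace(
            pinned,
            metabolites={**pinned.metabolites, "pool2": Metabolite("pool2")},
            reactions={**pinned.reactions, "loop_a": loop_a, "loop_b": loop_b},
        )
        result = variability_analysis(model, 0.4, variable_ids=["loop_a"])
        row = result.table.iloc[0]
        assert row["status_max"] == "unbounded" and math.isinf(row["max"])


class TestRvaOverGrowth:
    def test_ranges_match_the_hand_lp_at_both_fractions(self, pinned):
        results = rva_over_growth(pinned, variable_ids=["translation"], fractions=(0.5, 1.0))
        half, full = (r.table.iloc[0] for r in results)
        assert half["min"] == pytest.approx(1.0 / 15.0, abs=1e-5)
        assert half["max"] == pytest.approx(0.6, abs=1e-5)
        assert full["min"] == pytest.approx(0.4, abs=1e-5)
        assert full["max"] == pytest.approx(0.4, abs=1e-5)

    def test_range_width_shrinks_with_growth(self, pinned):
        fractions = (0.25, 0.5, 0.75, 1.0)
        results = rva_over_growth(pinned, variable_ids=["translation"], fractions=fractions)
        widths = [r.table.iloc[0]["max"] - r.table.iloc[0]["min"] for r in results]
        assert all(b <= a + 1e-9 for a, b in zip(widths, widths[1:]))

    def test_full_fitness_range_contains_the_optimum(self, pinned):
        optimum = maximize_growth(pinned)
        (result,) = rva_over_growth(pinned, variable_ids=["translation"], fractions=(1.0,))
        row = result.table.iloc[0]
        value = optimum.machine_concentrations["translation"]
        assert row["min"] - 1e-8 <= value <= row["max"] + 1e-8

    def test_fraction_outside_unit_interval_rejected(self, pinned):
        with pytest.raises(ValueError):
            rva_over_growth(pinned, fractions=(0.0, 1.0))


class TestParetoFront:
    def test_endpoints_match_single_objective_optima(self, secretion):
        mu = 0.9 * maximize_growth(secretion).mu
        front = pareto_front(secretion, mu, None, "product_synthesis", "maintenance")
        unconstrained = optimize_at_growth(
            secretion, mu, objective={"product_synthesis": 1.0}
        ).objective_value
        assert front.table["a_opt"].iloc[0] == pytest.approx(unconstrained, abs=1e-8)
        b_max = optimize_at_growth(
            secretion, mu, objective={"maintenance": 1.0}
        ).objective_value
        assert front.table["b_level"].iloc[-1] == pytest.approx(b_max, abs=1e-8)

    def test_front_is_non_increasing(self, secretion):
        mu = 0.9 * maximize_growth(secretion).mu
        front = pareto_front(secretion, mu, None, "product_synthesis", "maintenance")
        a = front.table["a_opt"].to_numpy()
        assert all(later <= earlier + 1e-8 for earlier, later in zip(a, a[1:]))

    def test_two_sink_front_is_a_straight_line(self, secretion):
        mu = 0.9 * maximize_growth(secretion).mu
        front = pareto_front(secretion, mu, None, "product_synthesis", "maintenance")
        b = front.table["b_level"].to_numpy()
        a = front.table["a_opt"].to_numpy()
        fitted = np.polyval(np.polyfit(b, a, 1), b)
        assert np.max(np.abs(a - fitted)) < 1e-6

    def test_front_points_dominate_a_feasibility_grid(self, secretion):
        """Brute-force oracle: no feasible (A, B) demand pair beats the front."""
        mu = 0.9 * maximize_growth(secretion).mu
        front = pareto_front(secretion, mu, None, "product_synthesis", "maintenance")
        b_levels = front.table["b_level"].to_numpy()
        a_front = front.table["a_opt"].to_numpy()
        a_grid = np.linspace(0.0, a_front[0] * 1.1, 12)
        b_grid = np.linspace(0.0, b_levels[-1], 12)
        from rbakit import Target, impose_target
        from rbakit.parameters import constant

        def demanding(a_demand, b_demand):
            return impose_target(
                impose_target(
                    secretion,
                    Target("a_demand", "flux_ge", "product_synthesis", constant(float(a_demand))),
                ),
                Target("b_demand", "flux_ge", "maintenance", constant(float(b_demand))),
            )

        for a_demand in a_grid:
            for b_demand in b_grid:
                feasible = is_feasible(demanding(a_demand, b_demand), mu)
                front_a = float(np.interp(b_demand, b_levels, a_front))
                assert feasible == (a_demand <= front_a + 1e-6) or (
                    abs(a_demand - front_a) < 1e-6
                )
        # beyond the measured b_max nothing is feasible
        assert not is_feasible(demanding(0.0, 1.05 * b_levels[-1]), mu)


class TestProductionTradeoff:
    def test_no_production_at_full_fitness(self, secretion):
        result = production_tradeoff(secretion, None, "product_synthesis", (0.5, 1.0))
        assert result.table["production"].iloc[-1] == pytest.approx(0.0, abs=1e-5)

    def test_production_is_non_increasing_in_fitness(self, secretion):
        result = production_tradeoff(
            secretion, None, "product_synthesis", (0.25, 0.5, 0.75, 1.0)
        )
        prod = result.table["production"].to_numpy()
        assert all(later <= earlier + 1e-8 for earlier, later in zip(prod, prod[1:]))

    def test_matches_direct_fixed_growth_optimization(self, secretion):
        mu_max = maximize_growth(secretion).mu
        result = production_tradeoff(secretion, None, "product_synthesis", (0.5,))
        direct = optimize_at_growth(
            secretion, 0.5 * mu_max, objective={"product_synthesis": 1.0}
        )
        assert result.table["production"].iloc[0] == pytest.approx(
            direct.objective_value, abs=1e-9
        )


class TestSwitchConcentration:
    def test_located_switch_matches_the_closed_form(self, overflow, overflow_medium):
        expected = toys.overflow_switch_concentration(10, 1, 1.0, 0.5, 1.0, 10.0)
        located = find_switch_concentration(
            overflow, "overflow", "substrate_ext", (1e-2, 1e1), overflow_medium
        )
        assert located == pytest.approx(expected, rel=1e-3)
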