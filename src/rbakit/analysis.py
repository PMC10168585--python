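"""High-level resource-allocation analyses.

Everything here composes the growth solver: medium screens (Monod curves),
minimum-substrate inference, single-parameter screens, local scaled
sensitivities, global lognormal ensembles, Resource Variability Analysis
(RVA) and epsilon-constraint Pareto fronts. Results are small tidy
:class:`pandas.DataFrame` tables wrapped in dataclasses that carry the run
metadata needed to reproduce them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lp import Row, build_lp
from .model import (
    AnalysisSettings,
    Medium,
    RBAModel,
    scale_efficiency,
)
from .solve import (
    OPTIMAL,
    UNBOUNDED,
    SolutionState,
    maximize_growth,
    optimize_at_growth,
    solve_lp,
)

__all__ = [
    "ScreenResult",
    "EnsembleResult",
    "SensitivityReport",
    "VariabilityResult",
    "ParetoFront",
    "medium_screen",
    "find_min_substrate",
    "parameter_screen",
    "default_factor_grid",
    "local_sensitivities",
    "sample_ensemble",
    "variability_analysis",
    "rva_over_growth",
    "pareto_front",
    "production_tradeoff",
    "find_switch_concentration",
]

SENSITIVITY_ZERO_THRESHOLD = 1e-6


@dataclass(frozen=True)
class ScreenResult:
    """One row per screened axis value: maximal growth rate, status, fluxes."""

    axis: str
    table: pd.DataFrame


@dataclass(frozen=True)
class EnsembleResult:
    """Per-sample scaling factors, maximal growth rate and selected fluxes."""

    seed: int
    sigma: float
    table: pd.DataFrame


@dataclass(frozen=True)
class SensitivityReport:
    """Scaled sensitivities d ln(mu_max) / d ln(k) per catalyst efficiency."""

    mu_reference: float
    table: pd.DataFrame


@dataclass(frozen=True)
class VariabilityResult:
    """Feasible [min, max] range per variable at a fixed growth rate."""

    mu: float
    table: pd.DataFrame


@dataclass(frozen=True)
class ParetoFront:
    """Epsilon-constraint front: optimal A at increasing demands on B."""

    mu: float
    objective_a: str
    objective_b: str
    table: pd.DataFrame


def _catalyst_ids(model: RBAModel) -> list[str]:
    return list(model.enzymes) + list(model.processes)


def _flux_record(state: SolutionState, flux_ids: Sequence[str]) -> dict[str, float]:
    return {
        f"flux:{rid}": (state.fluxes.get(rid, math.nan) if state.status == OPTIMAL else math.nan)
        for rid in flux_ids
    }


def medium_screen(
    model: RBAModel,
    metabolite: str,
    concentrations: Sequence[float],
    medium: Medium | None = None,
    settings: AnalysisSettings | None = None,
    flux_ids: Sequence[str] | None = None,
) -> ScreenResult:
    """Monod-style screen: maximal growth rate vs. one external concentration.

    Each grid point overrides the metabolite's medium entry, maximizes
    growth and records the parsimonious optimum's exchange fluxes.
    Per-point failures are recorded in the status column; the screen
    continues.
    """
    settings = settings or AnalysisSettings()
    medium = medium if medium is not None else Medium({})
    met = model.metabolites.get(metabolite)
    if met is None or not met.external:
        raise KeyError(f"{metabolite!r} is not an external metabolite of the model")
    if flux_ids is None:
        flux_ids = list(model.reactions)
    records = []
    for conc in concentrations:
        if conc < 0:
            raise ValueError(f"concentrations must be >= 0, got {conc}")
        point_medium = medium.updated(**{metabolite: float(conc)})
        try:
            state = maximize_growth(model, point_medium, settings)
        except Exception as exc:  # keep screening; record the failure
            records.append(
                {metabolite: conc, "mu_max": math.nan, "status": f"error: {exc}"}
            )
            continue
        rec = {metabolite: conc, "mu_max": state.mu, "status": state.status}
        rec.update(_flux_record(state, flux_ids))
        records.append(rec)
    return ScreenResult(axis=metabolite, table=pd.DataFrame.from_records(records))


def find_min_substrate(
    model: RBAModel,
    metabolite: str,
    mu_target: float,
    medium: Medium | None = None,
    settings: AnalysisSettings | None = None,
    conc_scan_max: float = 1e6,
) -> float:
    """Minimum concentration of ``metabolite`` at which ``mu_target`` is reachable.

    Bisects the concentration axis; the returned concentration satisfies
    ``mu_max(c) >= mu_target`` to within the bisection tolerance. If even
    the saturating concentration ``conc_scan_max`` cannot reach the target
    (the Monod curve approaches its plateau only asymptotically), raises a
    ``ValueError`` stating the saturated maximal growth rate.
    """
    settings = settings or AnalysisSettings()
    medium = medium if medium is not None else Medium({})
    if mu_target < 0:
        raise ValueError("mu_target must be >= 0")
    if mu_target == 0:
        return 0.0

    def mu_at(conc: float) -> float:
        return maximize_growth(model, medium.updated(**{metabolite: conc}), settings).mu

    mu_sat = mu_at(conc_scan_max)
    if mu_target > mu_sat:
        raise ValueError(
            f"growth rate {mu_target} is unreachable: saturated mu_max at "
            f"concentration {conc_scan_max:g} is {mu_sat:.6g}"
        )
    lo, hi = 0.0, 1.0
    while mu_at(hi) < mu_target:
        hi *= 4.0
        if hi > conc_scan_max:
            hi = conc_scan_max
            break
    tol = settings.bisection_tol
    while hi - lo > tol * max(hi, tol):
        mid = 0.5 * (lo + hi)
        if mu_at(mid) >= mu_target:
            hi = mid
        else:
            lo = mid
    return hi


def default_factor_grid(n: int = 25) -> np.ndarray:
    """Logarithmic scaling-factor grid spanning [0.01, 100]."""
    return np.logspace(-2.0, 2.0, n)


def parameter_screen(
    model: RBAModel,
    catalyst_id: str,
    factors: Sequence[float] | None = None,
    medium: Medium | None = None,
    settings: AnalysisSettings | None = None,
    flux_ids: Sequence[str] | None = None,
) -> ScreenResult:
    """Maximal growth rate vs. a scaling factor on one catalyst efficiency."""
    settings = settings or AnalysisSettings()
    if factors is None:
        factors = default_factor_grid()
    if flux_ids is None:
        flux_ids = []
    records = []
    for factor in factors:
        scaled = scale_efficiency(model, catalyst_id, float(factor))
        try:
            state = maximize_growth(scaled, medium, settings)
        except Exception as exc:
            records.append({"factor": factor, "mu_max": math.nan, "status": f"error: {exc}"})
            continue
        rec = {"factor": factor, "mu_max": state.mu, "status": state.status}
        rec.update(_flux_record(state, flux_ids))
        records.append(rec)
    return ScreenResult(axis="factor", table=pd.DataFrame.from_records(records))


def local_sensitivities(
    model: RBAModel,
    medium: Medium | None = None,
    parameter_ids: Iterable[str] | None = None,
    settings: AnalysisSettings | None = None,
) -> SensitivityReport:
    """Scaled sensitivities s = d ln(mu_max) / d ln(k) per catalyst efficiency.

    Estimated by a symmetric finite difference in log space with half-step
    ``settings.fd_step``: each efficiency is scaled by ``exp(+/-delta)`` and
    growth is re-maximized. Because the difference divides by ``2*delta``,
    the inner bisection runs at a tolerance tightened to at most 1e-8 so
    growth-rate noise stays well below the estimator's truncation error.
    Sensitivities below 1e-6 in magnitude are reported as exactly 0.
    """
    settings = settings or AnalysisSettings()
    inner = dc_replace(settings, bisection_tol=min(settings.bisection_tol, 1e-8))
    reference = maximize_growth(model, medium, inner, parsimonious=False)
    if reference.status != OPTIMAL or reference.mu <= 10 * inner.bisection_tol:
        raise ValueError("reference model has no positive maximal growth rate")
    ids = list(parameter_ids) if parameter_ids is not None else _catalyst_ids(model)
    delta = settings.fd_step
    records = []
    for cid in ids:
        up = maximize_growth(
            scale_efficiency(model, cid, math.exp(delta)), medium, inner, parsimonious=False
        )
        down = maximize_growth(
            scale_efficiency(model, cid, math.exp(-delta)), medium, inner, parsimonious=False
        )
        if up.mu <= 0 or down.mu <= 0:
            raise ValueError(f"growth collapses when perturbing {cid!r}; sensitivity undefined")
        s = (math.log(up.mu) - math.log(down.mu)) / (2.0 * delta)
        if abs(s) < SENSITIVITY_ZERO_THRESHOLD:
            s = 0.0
        records.append({"parameter": cid, "sensitivity": s})
    return SensitivityReport(
        mu_reference=reference.mu, table=pd.DataFrame.from_records(records)
    )


def sample_ensemble(
    model: RBAModel,
    medium: Medium | None = None,
    settings: AnalysisSettings | None = None,
    flux_ids: Sequence[str] | None = None,
) -> EnsembleResult:
    """Global sensitivity ensemble with lognormally scaled enzyme efficiencies.

    Each of ``settings.ensemble_n`` samples multiplies every *enzyme*
    efficiency by its own factor ``x`` with ``ln(x) ~ N(0, sigma^2)``
    (process efficiencies are left untouched), then re-maximizes growth.
    Bitwise reproducible for a fixed ``settings.seed``; infeasible samples
    are recorded in the status column, not fatal.
    """
    settings = settings or AnalysisSettings()
    if flux_ids is None:
        flux_ids = []
    rng = np.random.default_rng(settings.seed)
    enzyme_ids = list(model.enzymes)
    records = []
    for i in range(settings.ensemble_n):
        factors = np.exp(rng.normal(0.0, settings.ensemble_sigma, size=len(enzyme_ids)))
        perturbed = model
        for eid, factor in zip(enzyme_ids, factors):
            perturbed = scale_efficiency(perturbed, eid, float(factor))
        rec: dict[str, float | str] = {"sample": i}
        for eid, factor in zip(enzyme_ids, factors):
            rec[f"factor:{eid}"] = float(factor)
        try:
            state = maximize_growth(perturbed, medium, settings)
            rec["mu_max"] = state.mu
            rec["status"] = state.status
            rec.update(_flux_record(state, flux_ids))
        except Exception as exc:
            rec["mu_max"] = math.nan
            rec["status"] = f"error: {exc}"
        records.append(rec)
    return EnsembleResult(
        seed=settings.seed, sigma=settings.ensemble_sigma,
        table=pd.DataFrame.from_records(records),
    )


def variability_analysis(
    model: RBAModel,
    mu: float,
    medium: Medium | None = None,
    variable_ids: Sequence[str] | None = None,
    settings: AnalysisSettings | None = None,
) -> VariabilityResult:
    """Resource Variability Analysis: feasible range of each variable at fixed ``mu``.

    Two LP solves (minimize, maximize) per variable. At an infeasible growth
    rate every range is reported infeasible; an unbounded maximum is
    reported with status ``unbounded`` and max = +inf, not an exception.
    """
    settings = settings or AnalysisSettings()
    problem = build_lp(model, mu, medium)
    names = set(problem.variable_names())
    if variable_ids is None:
        variable_ids = sorted(names)
    records = []
    for vid in variable_ids:
        if vid not in names:
            raise KeyError(f"{vid!r} is not a variable (reaction, enzyme or process id)")
        lo_state = solve_lp(problem.with_objective({vid: 1.0}, "min"),
                            feasibility_tol=settings.feasibility_tol, want_duals=False)
        hi_state = solve_lp(problem.with_objective({vid: 1.0}, "max"),
                            feasibility_tol=settings.feasibility_tol, want_duals=False)
        records.append(
            {
                "id": vid,
                "min": lo_state.objective_value if lo_state.status == OPTIMAL else (
                    -math.inf if lo_state.status == UNBOUNDED else math.nan
                ),
                "max": hi_state.objective_value if hi_state.status == OPTIMAL else (
                    math.inf if hi_state.status == UNBOUNDED else math.nan
                ),
                "status_min": lo_state.status,
                "status_max": hi_state.status,
            }
        )
    return VariabilityResult(mu=mu, table=pd.DataFrame.from_records(records))


def rva_over_growth(
    model: RBAModel,
    medium: Medium | None = None,
    variable_ids: Sequence[str] | None = None,
    fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    settings: AnalysisSettings | None = None,
) -> list[VariabilityResult]:
    """RVA along a grid of growth rates given as fractions of mu_max.

    mu_max is computed once; the returned per-fraction tables are the
    growth/flexibility trade-off curves (converging upper and lower fronts
    that meet at the optimum).
    """
    settings = settings or AnalysisSettings()
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
    mu_max = maximize_growth(model, medium, settings).mu
    return [
        variability_analysis(model, f * mu_max, medium, variable_ids, settings)
        for f in fractions
    ]


def _objective_map(objective: str | Mapping[str, float]) -> dict[str, float]:
    if isinstance(objective, str):
        return {objective: 1.0}
    return dict(objective)


def pareto_front(
    model: RBAModel,
    mu: float,
    medium: Medium | None = None,
    objective_a: str | Mapping[str, float] = "",
    objective_b: str | Mapping[str, float] = "",
    settings: AnalysisSettings | None = None,
    log_levels: bool = False,
) -> ParetoFront:
    """Epsilon-constraint Pareto front between two maximization objectives.

    At fixed sub-maximal ``mu``: find ``b_max`` (the unconstrained maximum
    of B), then for ``settings.pareto_points`` demand levels
    ``b in [0, b_max]`` maximize A subject to ``B >= b``. The resulting
    front is non-increasing in ``b``.
    """
    settings = settings or AnalysisSettings()
    obj_a, obj_b = _objective_map(objective_a), _objective_map(objective_b)
    name_a = objective_a if isinstance(objective_a, str) else "+".join(sorted(obj_a))
    name_b = objective_b if isinstance(objective_b, str) else "+".join(sorted(obj_b))
    problem = build_lp(model, mu, medium)
    b_state = solve_lp(problem.with_objective(obj_b, "max"),
                       feasibility_tol=settings.feasibility_tol, want_duals=False)
    if b_state.status == UNBOUNDED:
        raise ValueError(f"objective {name_b!r} is unbounded at mu={mu}")
    if b_state.status != OPTIMAL:
        raise ValueError(f"no feasible state at mu={mu} (status {b_state.status})")
    b_max = b_state.objective_value
    if log_levels:
        levels = np.geomspace(max(b_max * 1e-6, 1e-12), b_max, settings.pareto_points)
        levels[0] = 0.0
    else:
        levels = np.linspace(0.0, b_max, settings.pareto_points)
    records = []
    for b in levels:
        constrained = problem.with_rows(
            [Row("epsilon::b_demand", "target", obj_b, ">=", float(b))]
        )
        a_state = solve_lp(constrained.with_objective(obj_a, "max"),
                           feasibility_tol=settings.feasibility_tol, want_duals=False)
        if a_state.status == UNBOUNDED:
            raise ValueError(f"objective {name_a!r} is unbounded at mu={mu}")
        records.append(
            {
                "b_level": float(b),
                "a_opt": a_state.objective_value if a_state.status == OPTIMAL else math.nan,
                "status": a_state.status,
            }
        )
    return ParetoFront(
        mu=mu, objective_a=name_a, objective_b=name_b,
        table=pd.DataFrame.from_records(records),
    )


def production_tradeoff(
    model: RBAModel,
    medium: Medium | None = None,
    product_reaction: str = "",
    fitness_fractions: Sequence[float] = (0.25, 0.5, 0.75, 0.9, 1.0),
    settings: AnalysisSettings | None = None,
) -> ScreenResult:
    """Maximal product flux vs. relative fitness (mu as a fraction of mu_max)."""
    settings = settings or AnalysisSettings()
    if product_reaction not in model.reactions:
        raise KeyError(f"unknown product reaction {product_reaction!r}")
    for f in fitness_fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fitness fractions must lie in (0, 1], got {f}")
    mu_max = maximize_growth(model, medium, settings).mu
    records = []
    for f in fitness_fractions:
        state = optimize_at_growth(
            model, f * mu_max, medium, {product_reaction: 1.0}, "max", settings
        )
        records.append(
            {
                "fitness_fraction": f,
                "mu": f * mu_max,
                "production": state.objective_value if state.status == OPTIMAL else math.nan,
                "status": state.status,
            }
        )
    return ScreenResult(axis="fitness_fraction", table=pd.DataFrame.from_records(records))


def find_switch_concentration(
    model: RBAModel,
    byproduct_reaction: str,
    metabolite: str,
    conc_range: tuple[float, float] = (1e-3, 1e2),
    medium: Medium | None = None,
    settings: AnalysisSettings | None = None,
    grid_points: int = 25,
    flux_threshold: float = 1e-6,
) -> float:
    """Locate the substrate concentration where byproduct secretion switches on.

    Dense logarithmic screen of the parsimonious optimum's secretion flux to
    bracket the switch, then bisection on the on/off indicator. This is the
    operational definition of the overflow switch point.
    """
    settings = settings or AnalysisSettings()
    medium = medium if medium is not None else Medium({})

    def secretes(conc: float) -> bool:
        state = maximize_growth(model, medium.updated(**{metabolite: conc}), settings)
        return state.status == OPTIMAL and state.fluxes.get(byproduct_reaction, 0.0) > flux_threshold

    grid = np.geomspace(conc_range[0], conc_range[1], grid_points)
    flags = [secretes(c) for c in grid]
    if all(flags) or not any(flags):
        raise ValueError(
            f"no secretion switch of {byproduct_reaction!r} inside "
            f"concentration range {conc_range}"
        )
    first_on = next(i for i, flag in enumerate(flags) if flag)
    lo = grid[first_on - 1] if first_on > 0 else conc_range[0]
    hi = grid[first_on]
    tol = settings.bisection_tol
    while hi - lo > tol * max(hi, tol):
        mid = 0.5 * (lo + hi)
        if secretes(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
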