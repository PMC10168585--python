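"""LP solving, feasibility testing and growth-rate maximization.

The growth rate enters the constraint coefficients, so the RBA problem is
not a single LP: feasibility is monotone in ``mu`` (the dilution demand
grows while the capacities do not keep pace), and the maximal growth rate is
the feasibility boundary. :func:`maximize_growth` brackets that boundary by
doubling and closes it by bisection, then solves once more at the last
*feasible* growth rate so the returned state is always constructible.

Among the (often degenerate) optima at the maximal growth rate, a
parsimonious secondary objective — minimize the summed enzyme and machine
concentrations — selects a reproducible representative by default; pass
``parsimonious=False`` for the raw feasibility point.

The LP backend is :func:`scipy.optimize.linprog` (HiGHS); its output is
re-checked for primal feasibility independently of the backend, and a
violation beyond ``feasibility_tol`` is reported as ``tolerance_failure``
rather than silently accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .lp import LinearProblem, build_lp, lp_to_dense
from .model import AnalysisSettings, Medium, RBAModel

__all__ = [
    "SolutionState",
    "UnboundedGrowthError",
    "solve_lp",
    "is_feasible",
    "maximize_growth",
    "optimize_at_growth",
    "parsimonious_objective",
]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
TOLERANCE_FAILURE = "tolerance_failure"

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}


class UnboundedGrowthError(RuntimeError):
    """The model is feasible at the bisection cap — a model pathology."""


@dataclass
class SolutionState:
    """Solver output: growth rate, primal vectors, duals and status."""

    mu: float
    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)
    enzyme_concentrations: dict[str, float] = field(default_factory=dict)
    machine_concentrations: dict[str, float] = field(default_factory=dict)
    duals: dict[str, float] = field(default_factory=dict)
    medium: Medium | None = None
    max_violation: float = 0.0
    message: str = ""

    def variable_value(self, name: str) -> float:
        for table in (self.fluxes, self.enzyme_concentrations, self.machine_concentrations):
            if name in table:
                return table[name]
        raise KeyError(name)


def _primal_violation(dense, x: np.ndarray) -> float:
    """Largest absolute constraint/bound violation of ``x``."""
    worst = 0.0
    if dense.A.size:
        ax = dense.A @ x
        for i, rel in enumerate(dense.relations):
            if rel == "=":
                worst = max(worst, abs(ax[i] - dense.b[i]))
            elif rel == "<=":
                worst = max(worst, ax[i] - dense.b[i])
            else:
                worst = max(worst, dense.b[i] - ax[i])
    worst = max(worst, float(np.max(dense.lower - x, initial=0.0)))
    worst = max(worst, float(np.max(x - dense.upper, initial=0.0)))
    return worst


def solve_lp(
    problem: LinearProblem,
    feasibility_tol: float = 1e-8,
    want_duals: bool = True,
) -> SolutionState:
    """Solve ``problem`` with HiGHS and independently re-check the primal.

    The result is deterministic for a fixed problem and tolerances. Solver
    failures surface as status ``tolerance_failure`` with the backend
    message, never as an exception.
    """
    dense = lp_to_dense(problem)
    sign = -1.0 if problem.sense == "max" else 1.0

    eq_idx = [i for i, rel in enumerate(dense.relations) if rel == "="]
    ub_idx = [i for i, rel in enumerate(dense.relations) if rel != "="]
    A_eq = dense.A[eq_idx] if eq_idx else None
    b_eq = dense.b[eq_idx] if eq_idx else None
    if ub_idx:
        flip = np.array([-1.0 if dense.relations[i] == ">=" else 1.0 for i in ub_idx])
        A_ub = dense.A[ub_idx] * flip[:, None]
        b_ub = dense.b[ub_idx] * flip
    else:
        A_ub = b_ub = None

    res = linprog(
        sign * dense.c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(dense.lower, dense.upper)),
        method="highs",
        options=_HIGHS_OPTIONS,
    )

    state = SolutionState(mu=problem.mu, status=TOLERANCE_FAILURE, message=res.message or "")
    if res.status == 2:
        state.status = INFEASIBLE
        return state
    if res.status == 3:
        state.status = UNBOUNDED
        return state
    if res.status != 0 or res.x is None:
        return state

    x = np.asarray(res.x, dtype=float)
    violation = _primal_violation(dense, x)
    state.max_violation = violation
    if violation > feasibility_tol:
        state.message = f"primal violation {violation:.3e} exceeds tolerance {feasibility_tol:.1e}"
        return state

    state.status = OPTIMAL
    state.objective_value = float(sign * res.fun)
    for variable, value in zip(problem.variables, x):
        if variable.kind == "flux":
            state.fluxes[variable.name] = float(value)
        elif variable.kind == "enzyme":
            state.enzyme_concentrations[variable.name] = float(value)
        else:
            state.machine_concentrations[variable.name] = float(value)
    if want_duals:
        duals: dict[str, float] = {}
        if eq_idx and res.eqlin is not None:
            for pos, i in enumerate(eq_idx):
                duals[dense.row_names[i]] = float(res.eqlin.marginals[pos])
        if ub_idx and res.ineqlin is not None:
            for pos, i in enumerate(ub_idx):
                marg = float(res.ineqlin.marginals[pos])
                if dense.relations[i] == ">=":
                    marg = -marg
                duals[dense.row_names[i]] = marg
        state.duals = duals
    return state


def parsimonious_objective(problem: LinearProblem) -> dict[str, float]:
    """Minimize-total-catalyst objective over the problem's concentration variables."""
    return {v.name: 1.0 for v in problem.variables if v.kind in ("enzyme", "machine")}


#: Smallest total catalyst concentration counted as a nontrivial cell state.
#: Well below any density capacity of interest, far above solver tolerances.
GROWTH_SUPPORT_THRESHOLD = 1e-9


def _zero_point_feasible(problem: LinearProblem, tol: float = 1e-12) -> bool:
    """Whether the all-zero vector satisfies the problem (the homogeneous case)."""
    for row in problem.rows:
        if row.relation == "=" and abs(row.rhs) > tol:
            return False
        if row.relation == "<=" and row.rhs < -tol:
            return False
        if row.relation == ">=" and row.rhs > tol:
            return False
    return all(v.lower <= 0.0 <= v.upper for v in problem.variables)


def is_feasible(
    model: RBAModel,
    mu: float,
    medium: Medium | None = None,
    settings: AnalysisSettings | None = None,
) -> bool:
    """Whether ``(mu, medium)`` admits a balanced-growth state.

    For models whose targets (or flux bounds) rule out the zero vector this
    is plain LP feasibility. For purely homogeneous models the zero state is
    feasible at every growth rate, so feasibility instead asks for a
    *nontrivial* state: the maximal total catalyst concentration must be
    positive (at ``mu = 0`` the zero cell counts as feasible by convention).
    """
    settings = settings or AnalysisSettings()
    problem = build_lp(model, mu, medium)
    if not _zero_point_feasible(problem):
        state = solve_lp(problem, feasibility_tol=settings.feasibility_tol, want_duals=False)
        return state.status == OPTIMAL
    if mu == 0.0:
        return True
    support = parsimonious_objective(problem)
    state = solve_lp(
        problem.with_objective(support, "max"),
        feasibility_tol=settings.feasibility_tol,
        want_duals=False,
    )
    if state.status == UNBOUNDED:
        return True
    return state.status == OPTIMAL and (state.objective_value or 0.0) > GROWTH_SUPPORT_THRESHOLD


def maximize_growth(
    model: RBAModel,
    medium: Medium | None = None,
    settings: AnalysisSettings | None = None,
    parsimonious: bool = True,
) -> SolutionState:
    """Bisect the feasibility boundary in ``mu`` and solve at the optimum.

    Returns a state solved at the last feasible growth rate (conservative:
    never a rate that is actually infeasible). If the model is infeasible
    even at ``mu = 0`` the status is ``infeasible`` with ``mu = 0``.

    Raises
    ------
    UnboundedGrowthError
        If the model is still feasible at ``settings.mu_scan_max`` —
        growth unbounded within the scan window, a model pathology.
    """
    settings = settings or AnalysisSettings()
    medium = medium if medium is not None else Medium({})
    tol = settings.bisection_tol

    if not is_feasible(model, 0.0, medium, settings):
        return SolutionState(mu=0.0, status=INFEASIBLE, medium=medium,
                             message="infeasible at zero growth")

    lo = 0.0
    mu = tol
    while mu < settings.mu_scan_max and is_feasible(model, mu, medium, settings):
        lo = mu
        mu *= 2.0
    if mu >= settings.mu_scan_max:
        if is_feasible(model, settings.mu_scan_max, medium, settings):
            raise UnboundedGrowthError(
                f"model is feasible at mu_scan_max={settings.mu_scan_max}; "
                "growth rate appears unbounded"
            )
        hi = settings.mu_scan_max
    else:
        hi = mu

    while hi - lo > tol * max(hi, tol):
        mid = 0.5 * (lo + hi)
        if is_feasible(model, mid, medium, settings):
            lo = mid
        else:
            hi = mid

    problem = build_lp(model, lo, medium)
    if parsimonious:
        objective = parsimonious_objective(problem)
        # Homogeneous models admit the zero cell at any feasible growth rate;
        # there the representative state *fills* the cell (maximal total
        # catalyst concentration, density-limited) instead of emptying it.
        sense = "max" if _zero_point_feasible(problem) else "min"
    else:
        objective, sense = {}, "min"
    state = solve_lp(
        problem.with_objective(objective, sense), feasibility_tol=settings.feasibility_tol
    )
    state.mu = lo
    state.medium = medium
    return state


def optimize_at_growth(
    model: RBAModel,
    mu: float,
    medium: Medium | None = None,
    objective: Mapping[str, float] | None = None,
    sense: str = "max",
    settings: AnalysisSettings | None = None,
) -> SolutionState:
    """Optimize a linear side objective over named variables at fixed ``mu``.

    With an empty objective this is a pure feasibility solve; at a growth
    rate above the maximum the status is ``infeasible``.
    """
    settings = settings or AnalysisSettings()
    medium = medium if medium is not None else Medium({})
    problem = build_lp(model, mu, medium, objective=objective or {}, sense=sense)
    state = solve_lp(problem, feasibility_tol=settings.feasibility_tol)
    state.medium = medium
    return state
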