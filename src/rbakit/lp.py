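"""Assembly of the growth-rate-parametric linear program.

At a fixed growth rate ``mu`` and medium, an RBA model becomes an ordinary
LP over the variables

* ``nu_j`` — one flux per reaction (free if reversible, else >= 0),
* ``E_e`` — one concentration per enzyme (>= 0),
* ``M_p`` — one concentration per process machine (>= 0),

subject to four constraint blocks:

1. **mass balance** (one equality per internal metabolite): reaction fluxes
   must cover the dilution-by-growth demand ``mu * a_mi * c_i`` for the
   synthesis of every catalyst and every pinned macromolecule pool.
2. **capacity** (per catalysed reaction): ``nu_j <= k+_app * E_e`` and, if
   reversible, ``-nu_j <= k-_app * E_e``.
3. **process capacity** (per process): the total synthesis load
   ``mu * sum_i d_i * c_i`` over the process's products must not exceed
   ``k_p * M_p``.
4. **density** (per compartment): total weighted macromolecule concentration
   must fit in the compartment's capacity ``D_c``.

plus explicit rows for flux targets and for concentration targets on
macromolecules that are expressible through catalyst variables. Pinned
concentrations of standalone macromolecule pools (appearing in no catalyst)
are substituted as constants into blocks 1, 3 and 4 — fewer variables, same
polytope. Internal metabolites are treated as steady-state pools without a
dilution term of their own; a concentration target on an internal metabolite
adds the corresponding ``mu * c`` replenishment demand to its mass balance.

Because ``mu`` multiplies all dilution terms, the constraints are linear at
fixed ``mu`` but the feasible set shrinks as ``mu`` grows, which is what the
growth-rate bisection in :mod:`rbakit.solve` exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .model import (
    CONCENTRATION_KINDS,
    Medium,
    RBAModel,
)
from .parameters import ParameterFunction

__all__ = ["Variable", "Row", "LinearProblem", "DenseLP", "LPBuildError", "build_lp", "lp_to_dense"]

BLOCKS = ("mass_balance", "capacity", "process_capacity", "density", "target")

_RELATIONS = ("=", "<=", ">=")


class LPBuildError(ValueError):
    """A constraint coefficient could not be evaluated to a finite number."""


@dataclass(frozen=True)
class Variable:
    name: str
    kind: str  # flux | enzyme | machine
    lower: float
    upper: float


@dataclass(frozen=True)
class Row:
    name: str
    block: str
    coeffs: Mapping[str, float]
    relation: str
    rhs: float

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")
        if self.relation not in _RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class LinearProblem:
    """An LP instantiated at a fixed growth rate and medium."""

    mu: float
    variables: tuple[Variable, ...]
    rows: tuple[Row, ...]
    objective: Mapping[str, float] = field(default_factory=dict)
    sense: str = "min"

    def __post_init__(self) -> None:
        names = {v.name for v in self.variables}
        for row in self.rows:
            unknown = set(row.coeffs) - names
            if unknown:
                raise ValueError(f"row {row.name!r} references undeclared variables {sorted(unknown)}")
        unknown = set(self.objective) - names
        if unknown:
            raise ValueError(f"objective references undeclared variables {sorted(unknown)}")
        if self.sense not in ("min", "max"):
            raise ValueError(f"sense must be 'min' or 'max', got {self.sense!r}")

    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def with_objective(self, objective: Mapping[str, float], sense: str) -> "LinearProblem":
        return replace(self, objective=dict(objective), sense=sense)

    def with_rows(self, extra: Sequence[Row]) -> "LinearProblem":
        return replace(self, rows=self.rows + tuple(extra))


@dataclass(frozen=True)
class DenseLP:
    """Matrix form of a :class:`LinearProblem` with deterministic ordering."""

    A: np.ndarray
    relations: tuple[str, ...]
    b: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    c: np.ndarray
    row_names: tuple[str, ...]
    col_names: tuple[str, ...]
    sense: str


def _eval(fn: ParameterFunction, mu: float, medium: Medium | None, context: str) -> float:
    try:
        value = fn(mu, medium)
    except Exception as exc:
        raise LPBuildError(f"evaluating parameter for {context}: {exc}") from exc
    if not math.isfinite(value):
        raise LPBuildError(f"parameter for {context} evaluated to {value} at mu={mu}")
    return value


def build_lp(
    model: RBAModel,
    mu: float,
    medium: Medium | None = None,
    objective: Mapping[str, float] | None = None,
    sense: str = "min",
) -> LinearProblem:
    """Instantiate the four constraint blocks of ``model`` at ``(mu, medium)``.

    Row counts: one mass-balance row per internal metabolite; one capacity
    row per catalysed reaction plus one more per reversible catalysed
    reaction; one row per process; one per compartment; one per flux target
    and per free (catalyst-expressible) concentration target.
    """
    if mu < 0:
        raise ValueError(f"growth rate must be >= 0, got {mu}")
    medium = medium if medium is not None else Medium({})

    variables: list[Variable] = []
    for rxn in model.reactions.values():
        lower = -math.inf if rxn.reversible else 0.0
        variables.append(Variable(rxn.id, "flux", lower, math.inf))
    for enz in model.enzymes.values():
        variables.append(Variable(enz.id, "enzyme", 0.0, math.inf))
    for proc in model.processes.values():
        variables.append(Variable(proc.id, "machine", 0.0, math.inf))

    catalyst_macs = model.catalyst_macromolecules()

    # Partition concentration targets: pinned standalone pools become
    # constants; catalyst-expressible ones become explicit target rows;
    # internal-metabolite pools add a dilution demand to their mass balance.
    pinned_pools: dict[str, float] = {}
    metabolite_pools: dict[str, float] = {}
    row_targets = []
    for tgt in model.targets.values():
        value = _eval(tgt.value, mu, medium, f"target {tgt.id}")
        if tgt.kind in CONCENTRATION_KINDS:
            if tgt.subject in model.metabolites:
                metabolite_pools[tgt.subject] = metabolite_pools.get(tgt.subject, 0.0) + value
            elif tgt.subject in catalyst_macs:
                row_targets.append((tgt, value))
            else:
                pinned_pools[tgt.subject] = pinned_pools.get(tgt.subject, 0.0) + value
        else:
            row_targets.append((tgt, value))

    # Linear expression (variable coeffs, constant) for each macromolecule's
    # total concentration.
    conc_terms: dict[str, dict[str, float]] = {mid: {} for mid in model.macromolecules}
    conc_const: dict[str, float] = {mid: 0.0 for mid in model.macromolecules}
    for enz in model.enzymes.values():
        for mac, count in enz.composition.items():
            conc_terms[mac][enz.id] = conc_terms[mac].get(enz.id, 0.0) + count
    for proc in model.processes.values():
        for mac, count in proc.machine_composition.items():
            conc_terms[mac][proc.id] = conc_terms[mac].get(proc.id, 0.0) + count
    for mac, value in pinned_pools.items():
        conc_const[mac] += value

    rows: list[Row] = []

    # (1) mass balance -----------------------------------------------------
    for met in model.internal_metabolites():
        coeffs: dict[str, float] = {}
        for rxn in model.reactions.values():
            s = rxn.stoichiometry.get(met.id)
            if s:
                coeffs[rxn.id] = coeffs.get(rxn.id, 0.0) + s
        rhs = 0.0
        for mac in model.macromolecules.values():
            cost = mac.precursor_cost.get(met.id)
            if not cost:
                continue
            for var, count in conc_terms[mac.id].items():
                coeffs[var] = coeffs.get(var, 0.0) - mu * cost * count
            rhs += mu * cost * conc_const[mac.id]
        rhs += mu * metabolite_pools.get(met.id, 0.0)
        rows.append(Row(f"mass_balance::{met.id}", "mass_balance", coeffs, "=", rhs))

    # (2) catalytic capacity ----------------------------------------------
    for rxn in model.reactions.values():
        if rxn.enzyme is None:
            continue  # spontaneous: bounds only
        enz = model.enzymes[rxn.enzyme]
        k_fwd = _eval(enz.forward_efficiency, mu, medium, f"enzyme {enz.id} (forward)")
        rows.append(
            Row(f"capacity_fwd::{rxn.id}", "capacity", {rxn.id: 1.0, enz.id: -k_fwd}, "<=", 0.0)
        )
        if rxn.reversible:
            k_bwd = _eval(
                enz.backward_efficiency, mu, medium, f"enzyme {enz.id} (backward)"
            )
            rows.append(
                Row(
                    f"capacity_bwd::{rxn.id}",
                    "capacity",
                    {rxn.id: -1.0, enz.id: -k_bwd},
                    "<=",
                    0.0,
                )
            )

    # (3) process capacity -------------------------------------------------
    for proc in model.processes.values():
        k_p = _eval(proc.efficiency, mu, medium, f"process {proc.id}")
        coeffs = {proc.id: -k_p}
        const_load = 0.0
        for mac_id in sorted(proc.products):
            mac = model.macromolecules[mac_id]
            demand = proc.demand_for(mac)
            for var, count in conc_terms[mac_id].items():
                coeffs[var] = coeffs.get(var, 0.0) + mu * demand * count
            const_load += mu * demand * conc_const[mac_id]
        rows.append(
            Row(f"process_capacity::{proc.id}", "process_capacity", coeffs, "<=", -const_load)
        )

    # (4) density ----------------------------------------------------------
    for comp in model.compartments.values():
        cap = _eval(comp.density_capacity, mu, medium, f"compartment {comp.id}")
        coeffs = {}
        const_mass = 0.0
        for mac in model.macromolecules.values():
            if mac.compartment != comp.id:
                continue
            for var, count in conc_terms[mac.id].items():
                coeffs[var] = coeffs.get(var, 0.0) + mac.weight * count
            const_mass += mac.weight * conc_const[mac.id]
        rows.append(Row(f"density::{comp.id}", "density", coeffs, "<=", cap - const_mass))

    # (5) target rows ------------------------------------------------------
    relation_of = {
        "flux_eq": "=",
        "flux_ge": ">=",
        "flux_le": "<=",
        "concentration_eq": "=",
        "concentration_ge": ">=",
    }
    for tgt, value in row_targets:
        if tgt.kind in CONCENTRATION_KINDS:
            coeffs = dict(conc_terms[tgt.subject])
        else:
            coeffs = {tgt.subject: 1.0}
        rows.append(Row(f"target::{tgt.id}", "target", coeffs, relation_of[tgt.kind], value))

    return LinearProblem(
        mu=mu,
        variables=tuple(variables),
        rows=tuple(rows),
        objective=dict(objective) if objective else {},
        sense=sense,
    )


def lp_to_dense(problem: LinearProblem) -> DenseLP:
    """Matrix form with variables in declaration order and rows in block order.

    The round trip preserves every coefficient exactly (pure reindexing).
    """
    col_names = tuple(v.name for v in problem.variables)
    index = {name: i for i, name in enumerate(col_names)}
    n = len(col_names)
    m = len(problem.rows)
    A = np.zeros((m, n))
    b = np.zeros(m)
    relations = []
    row_names = []
    for i, row in enumerate(problem.rows):
        for name, coeff in row.coeffs.items():
            A[i, index[name]] += coeff
        b[i] = row.rhs
        relations.append(row.relation)
        row_names.append(row.name)
    lower = np.array([v.lower for v in problem.variables])
    upper = np.array([v.upper for v in problem.variables])
    c = np.zeros(n)
    for name, coeff in problem.objective.items():
        c[index[name]] += coeff
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b)) and np.all(np.isfinite(c))):
        raise LPBuildError("non-finite coefficient in assembled LP")
    return DenseLP(
        A=A,
        relations=tuple(relations),
        b=b,
        lower=lower,
        upper=upper,
        c=c,
        row_names=tuple(row_names),
        col_names=col_names,
        sense=problem.sense,
    )
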