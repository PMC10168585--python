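"""Core domain types for resource-allocation (RBA) cell models.

An :class:`RBAModel` describes a growing cell as a set of production and
consumption processes: metabolic reactions catalysed by enzymes, and
macromolecular processes (translation, folding, transport) catalysed by
machines. At balanced growth every macromolecule must be resynthesized at
rate ``mu * concentration`` to compensate dilution, which couples metabolic
fluxes to catalyst concentrations and makes the feasible set shrink with the
growth rate.

Unit conventions (documented, not enforced): concentrations in mmol per gram
dry weight, time in hours, macromolecule weights in amino-acid equivalents.

Model edits (:func:`knock_out`, :func:`scale_efficiency`,
:func:`impose_target`) are copy-on-write: they return a new model and never
mutate their input, so analysis code can branch models cheaply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .parameters import (
    MissingMediumEntry,
    ParameterFunction,
    constant,
    product_of,
)

__all__ = [
    "Compartment",
    "Metabolite",
    "Macromolecule",
    "Reaction",
    "Enzyme",
    "Process",
    "Target",
    "Medium",
    "RBAModel",
    "AnalysisSettings",
    "Diagnostic",
    "TARGET_KINDS",
    "validate_model",
    "knock_out",
    "scale_efficiency",
    "impose_target",
]

TARGET_KINDS = ("concentration_eq", "concentration_ge", "flux_eq", "flux_ge", "flux_le")

CONCENTRATION_KINDS = ("concentration_eq", "concentration_ge")
FLUX_KINDS = ("flux_eq", "flux_ge", "flux_le")


@dataclass(frozen=True)
class Compartment:
    """A cellular compartment with a density capacity D_c (weight per volume)."""

    id: str
    density_capacity: ParameterFunction


@dataclass(frozen=True)
class Metabolite:
    """A small molecule; external metabolites are boundary species set by the medium."""

    id: str
    external: bool = False


@dataclass(frozen=True)
class Macromolecule:
    """A macromolecule species (protein, rRNA, ...).

    ``weight`` is the density weight w_i (e.g. amino-acid length);
    ``precursor_cost`` maps internal metabolite ids to the amount a_mi
    consumed per unit synthesized; ``producing_process`` names the machine
    process that polymerizes it, if any.
    """

    id: str
    weight: float
    compartment: str
    precursor_cost: Mapping[str, float] = field(default_factory=dict)
    producing_process: str | None = None


@dataclass(frozen=True)
class Reaction:
    """A metabolic reaction with stoichiometry S_mj (negative = consumed)."""

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    enzyme: str | None = None


@dataclass(frozen=True)
class Enzyme:
    """An enzyme built from macromolecules, with apparent catalytic efficiencies.

    ``forward_efficiency`` (k+_app) relates forward flux to enzyme
    concentration; ``backward_efficiency`` (k-_app) is present exactly when
    the catalysed reaction is reversible.
    """

    id: str
    composition: Mapping[str, float]
    forward_efficiency: ParameterFunction
    backward_efficiency: ParameterFunction | None = None


@dataclass(frozen=True)
class Process:
    """A macromolecular process (e.g. translation) run by a dedicated machine.

    The machine processes its ``products`` at rate ``efficiency`` per unit
    machine; synthesizing one unit of product i costs ``demand_per_unit[i]``
    processing capacity (default: the product's weight, as for a ribosome
    polymerizing amino acids).
    """

    id: str
    machine_composition: Mapping[str, float]
    efficiency: ParameterFunction
    products: frozenset[str] = frozenset()
    demand_per_unit: Mapping[str, float] = field(default_factory=dict)

    def demand_for(self, macromolecule: "Macromolecule") -> float:
        if macromolecule.id in self.demand_per_unit:
            return self.demand_per_unit[macromolecule.id]
        return macromolecule.weight


@dataclass(frozen=True)
class Target:
    """An empirical target constraint: a pinned concentration or flux value/bound."""

    id: str
    kind: str
    subject: str
    value: ParameterFunction

    def __post_init__(self) -> None:
        if self.kind not in TARGET_KINDS:
            raise ValueError(f"unknown target kind {self.kind!r}")


@dataclass(frozen=True)
class Medium:
    """External metabolite concentrations (mM), keyed by metabolite id."""

    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", dict(self.concentrations))

    def __getitem__(self, key: str) -> float:
        return self.concentrations[key]

    def __contains__(self, key: str) -> bool:
        return key in self.concentrations

    def get(self, key: str, default: float | None = None) -> float | None:
        return self.concentrations.get(key, default)

    def updated(self, **changes: float) -> "Medium":
        """A copy with the given concentrations replaced/added."""
        merged = dict(self.concentrations)
        merged.update(changes)
        return Medium(merged)


@dataclass(frozen=True)
class AnalysisSettings:
    """Numerical settings shared by the solver and the analysis suite.

    bisection_tol:
        relative tolerance on the growth rate in bisections.
    fd_step:
        log-scale half-step delta of the symmetric finite difference used for
        scaled sensitivities d ln(mu_max) / d ln(k_app).
    ensemble_sigma / ensemble_n:
        std of ln(scaling factor) and sample count for global sensitivity
        ensembles.
    mu_scan_max:
        upper bracket cap for growth-rate bisection (per hour).
    pareto_points:
        number of epsilon-constraint levels per Pareto front.
    feasibility_tol:
        absolute constraint-violation tolerance for independent primal
        re-checks of solver output.
    """

    bisection_tol: float = 1e-6
    fd_step: float = math.log(1.01)
    ensemble_sigma: float = math.log(1.1)
    ensemble_n: int = 1000
    seed: int = 0
    mu_scan_max: float = 10.0
    pareto_points: int = 20
    feasibility_tol: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("bisection_tol", "fd_step", "ensemble_sigma", "mu_scan_max", "feasibility_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ensemble_n < 1:
            raise ValueError("ensemble_n must be >= 1")
        if self.pareto_points < 2:
            raise ValueError("pareto_points must be >= 2")


def _as_dict(items: Iterable, kind: str) -> dict:
    out: dict = {}
    for item in items:
        if item.id in out:
            raise ValueError(f"duplicate {kind} id {item.id!r}")
        out[item.id] = item
    return out


@dataclass(frozen=True)
class RBAModel:
    """A whole-cell resource-allocation model.

    Component collections are stored as insertion-ordered ``{id: component}``
    dicts; the constructor accepts any iterables of components.
    """

    name: str
    compartments: Mapping[str, Compartment] = field(default_factory=dict)
    metabolites: Mapping[str, Metabolite] = field(default_factory=dict)
    macromolecules: Mapping[str, Macromolecule] = field(default_factory=dict)
    reactions: Mapping[str, Reaction] = field(default_factory=dict)
    enzymes: Mapping[str, Enzyme] = field(default_factory=dict)
    processes: Mapping[str, Process] = field(default_factory=dict)
    targets: Mapping[str, Target] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr, kind in (
            ("compartments", "compartment"),
            ("metabolites", "metabolite"),
            ("macromolecules", "macromolecule"),
            ("reactions", "reaction"),
            ("enzymes", "enzyme"),
            ("processes", "process"),
            ("targets", "target"),
        ):
            value = getattr(self, attr)
            if not isinstance(value, dict):
                object.__setattr__(self, attr, _as_dict(value, kind))

    # Convenience lookups -------------------------------------------------
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites.values() if not m.external]

    def external_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites.values() if m.external]

    def reaction_of_enzyme(self, enzyme_id: str) -> Reaction | None:
        for rxn in self.reactions.values():
            if rxn.enzyme == enzyme_id:
                return rxn
        return None

    def catalyst_macromolecules(self) -> set[str]:
        """Macromolecules appearing in any enzyme or machine composition."""
        used: set[str] = set()
        for enz in self.enzymes.values():
            used.update(enz.composition)
        for proc in self.processes.values():
            used.update(proc.machine_composition)
        return used

    def all_ids(self) -> list[str]:
        ids: list[str] = []
        for coll in (
            self.compartments,
            self.metabolites,
            self.macromolecules,
            self.reactions,
            self.enzymes,
            self.processes,
            self.targets,
        ):
            ids.extend(coll)
        return ids


@dataclass(frozen=True)
class Diagnostic:
    """A validation finding: the offending component and the violated rule."""

    component: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.component}: {self.rule}"


def _check_parameter(
    fn: ParameterFunction,
    owner: str,
    model: RBAModel,
    out: list[Diagnostic],
    mu_grid: Sequence[float],
    allow_zero: bool = True,
) -> None:
    refs = fn.external_metabolites()
    for ref in refs:
        met = model.metabolites.get(ref)
        if met is None or not met.external:
            out.append(
                Diagnostic(owner, f"parameter references non-external metabolite {ref!r}")
            )
            return
    probe = Medium({ref: 1.0 for ref in refs})
    for mu in mu_grid:
        try:
            value = fn(mu, probe)
        except MissingMediumEntry:  # pragma: no cover - probe covers refs
            out.append(Diagnostic(owner, "parameter evaluation failed"))
            return
        if not math.isfinite(value):
            out.append(Diagnostic(owner, f"parameter evaluates non-finite at mu={mu}"))
            return
        if value < 0:
            out.append(Diagnostic(owner, f"parameter evaluates negative ({value}) at mu={mu}"))
            return
        if value == 0 and not allow_zero:
            out.append(Diagnostic(owner, f"parameter evaluates to zero at mu={mu}"))
            return


def validate_model(
    model: RBAModel, settings: AnalysisSettings | None = None
) -> list[Diagnostic]:
    """Check every structural invariant; return diagnostics (empty iff valid).

    Diagnostics, not exceptions: a broken model is reported in full so that
    file importers can surface all problems with context at once.
    """
    settings = settings or AnalysisSettings()
    out: list[Diagnostic] = []
    mu_grid = (0.0, 0.5 * settings.mu_scan_max, settings.mu_scan_max)

    if not model.compartments:
        out.append(Diagnostic(model.name or "model", "model has no compartments"))

    seen: set[str] = set()
    for cid in model.all_ids():
        if cid in seen:
            out.append(Diagnostic(cid, "duplicate id across component collections"))
        seen.add(cid)

    for comp in model.compartments.values():
        _check_parameter(comp.density_capacity, f"compartment {comp.id}", model, out, mu_grid)

    internal = {m.id for m in model.internal_metabolites()}

    for mac in model.macromolecules.values():
        owner = f"macromolecule {mac.id}"
        if not mac.weight > 0:
            out.append(Diagnostic(owner, f"weight must be > 0, got {mac.weight}"))
        if mac.compartment not in model.compartments:
            out.append(Diagnostic(owner, f"unknown compartment {mac.compartment!r}"))
        for met, cost in mac.precursor_cost.items():
            if met not in internal:
                out.append(Diagnostic(owner, f"precursor {met!r} is not an internal metabolite"))
            if not cost > 0:
                out.append(Diagnostic(owner, f"precursor cost for {met!r} must be > 0"))
        if mac.producing_process is not None:
            proc = model.processes.get(mac.producing_process)
            if proc is None:
                out.append(Diagnostic(owner, f"unknown producing process {mac.producing_process!r}"))
            elif mac.id not in proc.products:
                out.append(
                    Diagnostic(owner, f"process {proc.id!r} does not list it among its products")
                )

    enzyme_uses: dict[str, list[str]] = {}
    for rxn in model.reactions.values():
        owner = f"reaction {rxn.id}"
        if not rxn.stoichiometry:
            out.append(Diagnostic(owner, "empty stoichiometry"))
        for met in rxn.stoichiometry:
            if met not in model.metabolites:
                out.append(Diagnostic(owner, f"unknown metabolite {met!r} in stoichiometry"))
        if rxn.enzyme is not None:
            if rxn.enzyme not in model.enzymes:
                out.append(Diagnostic(owner, f"unknown enzyme {rxn.enzyme!r}"))
            enzyme_uses.setdefault(rxn.enzyme, []).append(rxn.id)

    for enz in model.enzymes.values():
        owner = f"enzyme {enz.id}"
        uses = enzyme_uses.get(enz.id, [])
        if len(uses) != 1:
            out.append(
                Diagnostic(owner, f"must be referenced by exactly one reaction, found {len(uses)}")
            )
        for mac, count in enz.composition.items():
            if mac not in model.macromolecules:
                out.append(Diagnostic(owner, f"unknown macromolecule {mac!r} in composition"))
            if not count > 0:
                out.append(Diagnostic(owner, f"composition count for {mac!r} must be > 0"))
        rxn = model.reactions.get(uses[0]) if len(uses) == 1 else None
        if rxn is not None:
            if rxn.reversible and enz.backward_efficiency is None:
                out.append(Diagnostic(owner, "reversible reaction requires a backward efficiency"))
            if not rxn.reversible and enz.backward_efficiency is not None:
                out.append(Diagnostic(owner, "irreversible reaction must not have a backward efficiency"))
        _check_parameter(enz.forward_efficiency, owner, model, out, mu_grid)
        if enz.backward_efficiency is not None:
            _check_parameter(enz.backward_efficiency, owner, model, out, mu_grid)

    for proc in model.processes.values():
        owner = f"process {proc.id}"
        for mac, count in proc.machine_composition.items():
            if mac not in model.macromolecules:
                out.append(Diagnostic(owner, f"unknown macromolecule {mac!r} in machine composition"))
            if not count > 0:
                out.append(Diagnostic(owner, f"machine composition count for {mac!r} must be > 0"))
        for mac in proc.products:
            if mac not in model.macromolecules:
                out.append(Diagnostic(owner, f"unknown product macromolecule {mac!r}"))
        for mac, demand in proc.demand_per_unit.items():
            if mac not in proc.products:
                out.append(Diagnostic(owner, f"demand_per_unit key {mac!r} is not a product"))
            if not demand > 0:
                out.append(Diagnostic(owner, f"demand_per_unit for {mac!r} must be > 0"))
        _check_parameter(proc.efficiency, owner, model, out, mu_grid)

    for tgt in model.targets.values():
        out.extend(_target_diagnostics(model, tgt))
        _check_parameter(tgt.value, f"target {tgt.id}", model, out, mu_grid)

    return out


def _target_diagnostics(model: RBAModel, target: Target) -> list[Diagnostic]:
    owner = f"target {target.id}"
    out: list[Diagnostic] = []
    if target.kind in FLUX_KINDS:
        if target.subject not in model.reactions:
            out.append(Diagnostic(owner, f"flux target subject {target.subject!r} is not a reaction"))
    else:
        met = model.metabolites.get(target.subject)
        if met is not None:
            if met.external:
                out.append(
                    Diagnostic(owner, "concentration target on an external metabolite is invalid")
                )
        elif target.subject not in model.macromolecules:
            out.append(
                Diagnostic(
                    owner,
                    f"concentration target subject {target.subject!r} is neither a metabolite nor a macromolecule",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Copy-on-write model edits
# ---------------------------------------------------------------------------


def knock_out(model: RBAModel, catalyst_ids: Iterable[str]) -> RBAModel:
    """Return a copy with the named catalysts' efficiencies set to constant 0.

    Knockouts zero the efficiency rather than removing components, so the LP
    keeps its shape across edits (the capacity rows then force zero flux /
    zero processing).
    """
    ids = set(catalyst_ids)
    if not ids:
        return model
    enzymes = dict(model.enzymes)
    processes = dict(model.processes)
    zero = constant(0.0)
    for cid in sorted(ids):
        if cid in enzymes:
            enz = enzymes[cid]
            enzymes[cid] = replace(
                enz,
                forward_efficiency=zero,
                backward_efficiency=None if enz.backward_efficiency is None else zero,
            )
        elif cid in processes:
            processes[cid] = replace(processes[cid], efficiency=zero)
        else:
            raise KeyError(f"unknown catalyst id {cid!r} (not an enzyme or process)")
    return replace(model, enzymes=enzymes, processes=processes)


def scale_efficiency(model: RBAModel, catalyst_id: str, factor: float) -> RBAModel:
    """Return a copy with the catalyst's efficiency function(s) multiplied by ``factor``.

    The original function is wrapped as ``product(constant(factor), original)``
    so scalings compose and invert exactly.
    """
    if not factor > 0:
        raise ValueError(f"scaling factor must be > 0, got {factor}")
    wrap = lambda fn: product_of(constant(factor), fn)  # noqa: E731
    if catalyst_id in model.enzymes:
        enz = model.enzymes[catalyst_id]
        enzymes = dict(model.enzymes)
        enzymes[catalyst_id] = replace(
            enz,
            forward_efficiency=wrap(enz.forward_efficiency),
            backward_efficiency=(
                None if enz.backward_efficiency is None else wrap(enz.backward_efficiency)
            ),
        )
        return replace(model, enzymes=enzymes)
    if catalyst_id in model.processes:
        processes = dict(model.processes)
        processes[catalyst_id] = replace(
            processes[catalyst_id], efficiency=wrap(model.processes[catalyst_id].efficiency)
        )
        return replace(model, processes=processes)
    raise KeyError(f"unknown catalyst id {catalyst_id!r} (not an enzyme or process)")


def impose_target(model: RBAModel, target: Target) -> RBAModel:
    """Return a copy with ``target`` appended to the target collection."""
    if target.id in model.targets or target.id in set(model.all_ids()):
        raise ValueError(f"duplicate target id {target.id!r}")
    problems = _target_diagnostics(model, target)
    if problems:
        raise ValueError("; ".join(str(p) for p in problems))
    targets = dict(model.targets)
    targets[target.id] = target
    return replace(model, targets=targets)
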