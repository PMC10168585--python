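"""Desk-scale cell models with known closed-form or brute-force behaviour.

These generators replace a genome-scale model as the test and demo
substrate: each one is small enough to solve by hand, yet exercises every
constraint block. Closed forms for the maximal growth rate are documented in
the generator docstrings and re-derived in the test suite by an independent
dense feasibility scan, so the formulas cannot silently drift from the
builders.

The cast:

* **self-replicator** — one nutrient-to-precursor reaction plus a
  translation machine; the minimal cell that must rebuild its own catalysts.
* **pinned replicator** — adds a housekeeping protein pool pinned by a
  concentration target; the non-growth proteome burden.
* **Michaelis-Menten importer** — the pinned replicator with a
  substrate-saturating transporter; produces Monod growth curves.
* **overflow branch** — two alternative energy pathways (high-yield/slow
  vs. low-yield/fast with a secreted byproduct); reproduces the
  respiration-to-overflow switch as substrate becomes abundant.
* **secretion** — the pinned replicator plus a product pathway and an
  energy-dissipating maintenance sink; the substrate for growth/production
  trade-offs and two-objective Pareto fronts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import (
    Compartment,
    Macromolecule,
    Medium,
    Metabolite,
    Process,
    RBAModel,
    Reaction,
    Enzyme,
    Target,
)
from .parameters import constant, michaelis_menten

__all__ = [
    "ToySpec",
    "make_self_replicator",
    "make_pinned_replicator",
    "make_mm_importer",
    "make_overflow_branch",
    "make_secretion",
    "self_replicator_mu_max",
    "pinned_mu_max",
    "mm_importer_mu_max",
    "overflow_switch_concentration",
    "random_self_replicator",
    "random_pinned_replicator",
    "saturating_medium",
]

TOY_KINDS = ("self_replicator", "pinned_replicator", "mm_importer", "overflow_branch", "secretion")


@dataclass(frozen=True)
class ToySpec:
    """A named toy-model recipe: kind plus numeric parameters."""

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TOY_KINDS:
            raise ValueError(f"unknown toy kind {self.kind!r}")
        for name, value in self.params.items():
            if name == "c0":
                if value < 0:
                    raise ValueError("c0 must be >= 0")
            elif not value > 0:
                raise ValueError(f"toy parameter {name} must be > 0, got {value}")

    def build(self) -> RBAModel:
        builder = {
            "self_replicator": make_self_replicator,
            "pinned_replicator": make_pinned_replicator,
            "mm_importer": make_mm_importer,
            "overflow_branch": make_overflow_branch,
            "secretion": make_secretion,
        }[self.kind]
        return builder(**dict(self.params))


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------


def self_replicator_mu_max(kE: float, kR: float, n_E: float, n_R: float) -> float:
    """mu_max = 1 / (n_E/kE + n_R/kR); the density capacity D cancels out."""
    return 1.0 / (n_E / kE + n_R / kR)


def pinned_mu_max(
    kE: float, kR: float, n_E: float, n_R: float, n_H: float, c0: float, D: float
) -> float:
    """mu_max = (1 - n_H*c0/D) / (n_E/kE + n_R/kR)."""
    return (1.0 - n_H * c0 / D) / (n_E / kE + n_R / kR)


def mm_importer_mu_max(
    conc: float, vmax: float, km: float, kR: float, c0: float, D: float
) -> float:
    """Monod curve mu_max(c) = (1 - c0/D) / (1/(vmax*c/(c+km)) + 1/kR)."""
    if conc <= 0:
        return 0.0
    k_imp = vmax * conc / (conc + km)
    return (1.0 - c0 / D) / (1.0 / k_imp + 1.0 / kR)


def overflow_switch_concentration(
    vmax: float, km: float, y_resp: float, y_ovfl: float, k_resp: float, k_ovfl: float
) -> float:
    """Substrate concentration where the two pathways' proteome costs tie.

    Per unit precursor flux, pathway P with yield y and efficiency k costs
    (1/y)(1/k + 1/k_import(c)) proteome; the tie point solves for the import
    efficiency k* and inverts the Michaelis-Menten curve. Raises if the
    pathways never switch within the importer's saturation range.
    """
    num = 1.0 / y_ovfl - 1.0 / y_resp
    den = 1.0 / (y_resp * k_resp) - 1.0 / (y_ovfl * k_ovfl)
    if den <= 0 or num <= 0:
        raise ValueError("parameter sets never switch: overflow or respiration always dominates")
    k_star = num / den
    if not 0 < k_star < vmax:
        raise ValueError(
            f"pathway costs tie at import efficiency {k_star:.4g}, outside (0, vmax={vmax}); "
            "no switch within the importer's range"
        )
    return km * k_star / (vmax - k_star)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _cell(name: str, D: float) -> tuple[Compartment, Metabolite, Metabolite]:
    cytosol = Compartment("cytosol", constant(D))
    nutrient = Metabolite("nutrient_ext", external=True)
    precursor = Metabolite("precursor", external=False)
    return cytosol, nutrient, precursor


def _protein(pid: str, weight: float) -> Macromolecule:
    return Macromolecule(
        pid,
        weight=weight,
        compartment="cytosol",
        precursor_cost={"precursor": weight},
        producing_process="translation",
    )


def make_self_replicator(
    kE: float = 2.0, kR: float = 2.0, n_E: float = 1.0, n_R: float = 1.0, D: float = 1.0
) -> RBAModel:
    """The minimal self-replicating cell.

    One reaction imports the external nutrient and converts it to a
    precursor; a translation machine (the "ribosome") polymerizes the
    precursor into the uptake enzyme's protein (weight ``n_E``) and its own
    protein (weight ``n_R``). Closed form::

        mu_max = 1 / (n_E/kE + n_R/kR)

    independent of the density capacity ``D`` (density never binds alone:
    shrinking all concentrations preserves feasibility).
    """
    cytosol, nutrient, precursor = _cell("self_replicator", D)
    uptake_protein = _protein("uptake_protein", n_E)
    ribosome_protein = _protein("ribosome_protein", n_R)
    uptake = Reaction("uptake", {"nutrient_ext": -1.0, "precursor": 1.0}, enzyme="uptake_enzyme")
    uptake_enzyme = Enzyme("uptake_enzyme", {"uptake_protein": 1.0}, constant(kE))
    translation = Process(
        "translation",
        machine_composition={"ribosome_protein": 1.0},
        efficiency=constant(kR),
        products=frozenset({"uptake_protein", "ribosome_protein"}),
    )
    return RBAModel(
        name="self_replicator",
        compartments=[cytosol],
        metabolites=[nutrient, precursor],
        macromolecules=[uptake_protein, ribosome_protein],
        reactions=[uptake],
        enzymes=[uptake_enzyme],
        processes=[translation],
    )


def make_pinned_replicator(
    kE: float = 2.0,
    kR: float = 2.0,
    n_E: float = 1.0,
    n_R: float = 1.0,
    n_H: float = 1.0,
    c0: float = 0.2,
    D: float = 1.0,
) -> RBAModel:
    """Self-replicator plus a pinned housekeeping protein pool.

    A housekeeping protein (weight ``n_H``) with a ``concentration_eq``
    target ``c0`` claims density space and translation capacity without
    contributing to growth. Closed form::

        mu_max = (1 - n_H*c0/D) / (n_E/kE + n_R/kR)

    The optimum at mu_max is unique (the feasible region collapses to a
    point), which makes this the reference model for variability analysis.
    """
    if n_H * c0 >= D:
        raise ValueError(
            f"housekeeping demand n_H*c0 = {n_H * c0} must stay below density capacity D = {D}"
        )
    base = make_self_replicator(kE=kE, kR=kR, n_E=n_E, n_R=n_R, D=D)
    housekeeping = _protein("housekeeping_protein", n_H)
    translation = base.processes["translation"]
    processes = [
        Process(
            translation.id,
            machine_composition=translation.machine_composition,
            efficiency=translation.efficiency,
            products=translation.products | {"housekeeping_protein"},
        )
    ]
    target = Target("housekeeping_level", "concentration_eq", "housekeeping_protein", constant(c0))
    return RBAModel(
        name="pinned_replicator",
        compartments=list(base.compartments.values()),
        metabolites=list(base.metabolites.values()),
        macromolecules=list(base.macromolecules.values()) + [housekeeping],
        reactions=list(base.reactions.values()),
        enzymes=list(base.enzymes.values()),
        processes=processes,
        targets=[target],
    )


def make_mm_importer(
    vmax: float = 2.0, km: float = 0.1, kR: float = 2.0, c0: float = 0.2, D: float = 1.0
) -> RBAModel:
    """Pinned replicator with a substrate-saturating importer.

    The uptake enzyme's efficiency is ``vmax * c / (c + km)`` in the
    external nutrient concentration ``c``, so the maximal growth rate traces
    a Monod curve::

        mu_max(c) = (1 - c0/D) / (1/(vmax*c/(c+km)) + 1/kR)

    (unit protein weights), strictly increasing and saturating at the pinned
    replicator's value.
    """
    base = make_pinned_replicator(kE=vmax, kR=kR, n_E=1.0, n_R=1.0, n_H=1.0, c0=c0, D=D)
    importer = base.enzymes["uptake_enzyme"]
    enzymes = [
        Enzyme(importer.id, importer.composition, michaelis_menten(vmax, km, "nutrient_ext"))
    ]
    return RBAModel(
        name="mm_importer",
        compartments=list(base.compartments.values()),
        metabolites=list(base.metabolites.values()),
        macromolecules=list(base.macromolecules.values()),
        reactions=list(base.reactions.values()),
        enzymes=enzymes,
        processes=list(base.processes.values()),
        targets=list(base.targets.values()),
    )


def make_overflow_branch(
    vmax: float = 10.0,
    km: float = 1.0,
    y_resp: float = 1.0,
    y_ovfl: float = 0.5,
    k_resp: float = 1.0,
    k_ovfl: float = 10.0,
    kR: float = 2.0,
    c0: float = 0.1,
    D: float = 1.0,
) -> RBAModel:
    """Two alternative energy pathways and a substrate-dependent switch.

    A Michaelis-Menten importer feeds an intermediate that either of two
    pathways converts to precursor: "respiration" (high yield ``y_resp``,
    low efficiency ``k_resp``) or "overflow" (low yield ``y_ovfl``, high
    efficiency ``k_ovfl``) which additionally secretes a byproduct. At low
    substrate the importer is the expensive step and the high-yield pathway
    wins; at high substrate the cheap-import regime favours the
    proteome-cheap overflow pathway. A pinned housekeeping pool ``c0`` keeps
    the cell nontrivial at every growth rate; it does not move the switch,
    which is a tie of *marginal* proteome costs available in closed form via
    :func:`overflow_switch_concentration` and located numerically by a dense
    screen in the analysis suite.

    Raises if the parameters admit no switch inside the importer's range.
    """
    switch = overflow_switch_concentration(vmax, km, y_resp, y_ovfl, k_resp, k_ovfl)
    assert switch > 0
    if c0 >= D:
        raise ValueError("housekeeping demand c0 must stay below density capacity D")
    cytosol = Compartment("cytosol", constant(D))
    metabolites = [
        Metabolite("substrate_ext", external=True),
        Metabolite("intermediate"),
        Metabolite("precursor"),
        Metabolite("byproduct_ext", external=True),
    ]
    proteins = [
        _protein("importer_protein", 1.0),
        _protein("respiration_protein", 1.0),
        _protein("overflow_protein", 1.0),
        _protein("ribosome_protein", 1.0),
        _protein("housekeeping_protein", 1.0),
    ]
    reactions = [
        Reaction("import", {"substrate_ext": -1.0, "intermediate": 1.0}, enzyme="importer"),
        Reaction(
            "respiration", {"intermediate": -1.0, "precursor": y_resp}, enzyme="respiration_enzyme"
        ),
        Reaction(
            "overflow",
            {"intermediate": -1.0, "precursor": y_ovfl, "byproduct_ext": 1.0},
            enzyme="overflow_enzyme",
        ),
    ]
    enzymes = [
        Enzyme("importer", {"importer_protein": 1.0}, michaelis_menten(vmax, km, "substrate_ext")),
        Enzyme("respiration_enzyme", {"respiration_protein": 1.0}, constant(k_resp)),
        Enzyme("overflow_enzyme", {"overflow_protein": 1.0}, constant(k_ovfl)),
    ]
    translation = Process(
        "translation",
        machine_composition={"ribosome_protein": 1.0},
        efficiency=constant(kR),
        products=frozenset(p.id for p in proteins),
    )
    housekeeping = Target(
        "housekeeping_level", "concentration_eq", "housekeeping_protein", constant(c0)
    )
    return RBAModel(
        name="overflow_branch",
        compartments=[cytosol],
        metabolites=metabolites,
        macromolecules=proteins,
        reactions=reactions,
        enzymes=enzymes,
        processes=[translation],
        targets=[housekeeping],
    )


def make_secretion(
    kE: float = 2.0,
    kR: float = 2.0,
    kP: float = 2.0,
    c0: float = 0.2,
    D: float = 1.0,
) -> RBAModel:
    """Pinned replicator plus a product pathway and a maintenance sink.

    A product-synthesis reaction (enzyme efficiency ``kP``) exports the
    precursor as an external product, and a spontaneous maintenance reaction
    dissipates precursor without catalyst cost (an ATP-turnover stand-in).
    At the maximal growth rate all resources go to growth, so production is
    zero; below it, precursor and proteome slack can be traded between the
    two sinks, yielding straight-line Pareto fronts.
    """
    base = make_pinned_replicator(kE=kE, kR=kR, n_E=1.0, n_R=1.0, n_H=1.0, c0=c0, D=D)
    product_ext = Metabolite("product_ext", external=True)
    product_protein = _protein("product_enzyme_protein", 1.0)
    product_rxn = Reaction(
        "product_synthesis", {"precursor": -1.0, "product_ext": 1.0}, enzyme="product_enzyme"
    )
    maintenance = Reaction("maintenance", {"precursor": -1.0})
    product_enzyme = Enzyme("product_enzyme", {"product_enzyme_protein": 1.0}, constant(kP))
    translation = base.processes["translation"]
    processes = [
        Process(
            translation.id,
            machine_composition=translation.machine_composition,
            efficiency=translation.efficiency,
            products=translation.products | {"product_enzyme_protein"},
        )
    ]
    return RBAModel(
        name="secretion",
        compartments=list(base.compartments.values()),
        metabolites=list(base.metabolites.values()) + [product_ext],
        macromolecules=list(base.macromolecules.values()) + [product_protein],
        reactions=list(base.reactions.values()) + [product_rxn, maintenance],
        enzymes=list(base.enzymes.values()) + [product_enzyme],
        processes=processes,
        targets=list(base.targets.values()),
    )


# ---------------------------------------------------------------------------
# Randomized variants (log-uniform parameters, for conditioning sweeps)
# ---------------------------------------------------------------------------


def _log_uniform(rng: np.random.Generator, low: float = 0.1, high: float = 10.0) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def random_self_replicator(rng: np.random.Generator) -> tuple[RBAModel, float]:
    """A random-parameter self-replicator and its closed-form mu_max."""
    kE, kR, n_E, n_R, D = (_log_uniform(rng) for _ in range(5))
    model = make_self_replicator(kE=kE, kR=kR, n_E=n_E, n_R=n_R, D=D)
    return model, self_replicator_mu_max(kE, kR, n_E, n_R)


def random_pinned_replicator(rng: np.random.Generator) -> tuple[RBAModel, float]:
    """A random-parameter pinned replicator and its closed-form mu_max."""
    kE, kR, n_E, n_R, n_H, D = (_log_uniform(rng) for _ in range(6))
    c0 = float(rng.uniform(0.0, 0.9 * D / n_H))
    model = make_pinned_replicator(kE=kE, kR=kR, n_E=n_E, n_R=n_R, n_H=n_H, c0=c0, D=D)
    return model, pinned_mu_max(kE, kR, n_E, n_R, n_H, c0, D)


def saturating_medium(model: RBAModel, concentration: float = 1e6) -> Medium:
    """A medium saturating every external metabolite of ``model``."""
    return Medium({m.id: concentration for m in model.external_metabolites()})
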