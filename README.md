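# rbakit

Resource Balance Analysis (RBA) for growing cells: growth-rate-parametric
linear programs, growth maximization by feasibility bisection, and the
standard resource-allocation analysis repertoire — at desk scale.

## The problem

Constraint-based metabolic models (FBA) predict fluxes from stoichiometry
and a fixed biomass recipe. RBA goes further: it also accounts for the
*catalysts* that carry those fluxes. Every enzyme and every macromolecular
machine (ribosomes, transporters, chaperones) must itself be synthesized at
rate μ·concentration to balance dilution by growth, must be processed by
machines of finite efficiency, and must fit into crowded compartments. At a
fixed growth rate μ and medium, these requirements form a linear program
over the fluxes ν_j, enzyme concentrations E_j and machine concentrations
M_p, with four constraint blocks:

1. **mass balance** — Σ_j S_mj ν_j = μ Σ_i a_mi c_i for every internal
   metabolite m (fluxes cover the precursor demand of catalyst synthesis);
2. **catalytic capacity** — ν_j ≤ k⁺_app,j E_j (and −ν_j ≤ k⁻_app,j E_j if
   reversible);
3. **process capacity** — μ Σ_i d_ip c_i ≤ k_p M_p for every machine
   process p (e.g. translation load vs. ribosome capacity);
4. **density** — Σ_{i∈c} w_i c_i ≤ D_c for every compartment c,

plus empirical *target* constraints (pinned concentrations or fluxes).
Because μ multiplies the dilution demand, the feasible set shrinks as μ
grows; the largest feasible μ is the predicted maximal growth rate μmax,
found by bisection on feasibility. On top of this solver the package builds
Monod curves and medium screens, minimum-substrate inference, parameter
screens, local scaled sensitivities d ln μmax / d ln k_app, global
lognormal efficiency ensembles, Resource Variability Analysis (RVA — the
RBA analogue of flux variability analysis) and ε-constraint Pareto fronts
between metabolic objectives at sub-maximal growth.

Who it is for: modellers who want RBA's resource-allocation logic in an
inspectable, scriptable form — for teaching, method development, and
analysis prototyping — with built-in toy cell models whose behaviour is
known in closed form.

## A worked example

The *pinned replicator* is the smallest interesting cell: one uptake
reaction (enzyme efficiency kE = 2/h), a translation machine (kR = 2/h), a
housekeeping protein pool pinned at c0 = 0.2 inside a density capacity
D = 1. Its maximal growth rate has the closed form
μmax = (1 − c0/D)/(1/kE + 1/kR) = 0.8/h.

```python
from rbakit import maximize_growth, variability_analysis, local_sensitivities
from rbakit import toys

cell = toys.make_pinned_replicator(kE=2, kR=2, n_E=1, n_R=1, n_H=1, c0=0.2, D=1)

state = maximize_growth(cell)
print(state.mu)                        # 0.8
print(state.enzyme_concentrations)     # {'uptake_enzyme': 0.4}
print(state.machine_concentrations)    # {'translation': 0.4}

rva = variability_analysis(cell, 0.4, variable_ids=["translation"])
print(rva.table[["min", "max"]])       # min 0.0667, max 0.6

sens = local_sensitivities(cell)
print(sens.table)                      # uptake_enzyme 0.5, translation 0.5
```

At μmax the optimum is unique: enzyme and ribosome each occupy 0.4 of the
cell, the housekeeping pool the remaining 0.2 (the density constraint is
tight: 0.4 + 0.4 + 0.2 = 1). At half-maximal growth the ribosome
concentration may range anywhere in [1/15, 0.6] — slower growth buys
flexibility — and at μmax the range collapses to the single point 0.4.
Control over growth is split evenly between the two catalysts
(sensitivities 0.5/0.5, summing to 1 as homogeneity requires).

The same machinery runs from the shell:

```bash
rbakit solve --model my_model/ --medium glc_ext=1.0 --output out/
rbakit rva   --model my_model/ --mu-fraction 0.5 --variables translation
rbakit pareto --model my_model/ --objective-a product_synthesis --objective-b maintenance
```

Models are directories of SBtab-flavoured TSV tables (`rbakit model
validate`, `rbakit model convert`); solutions export to CSV/SBtab, Escher
reaction-flux JSON and Proteomaps mass-share TSV.

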