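# Methods

## The model

An `RBAModel` describes a cell in balanced growth. Small metabolites are
steady-state pools; macromolecules (proteins, machines' parts) carry a
density weight w_i (amino-acid equivalents), a compartment, and a precursor
cost a_mi per unit synthesized. Enzymes and process machines are built from
macromolecules with fixed stoichiometric compositions. All concentration
variables are in mmol per gram dry weight, time in hours; units are a
documented convention, not enforced numerically.

At growth rate μ and a given medium, the model instantiates a linear
program over fluxes ν_j (free if reversible, else ≥ 0), enzyme
concentrations E_e ≥ 0 and machine concentrations M_p ≥ 0:

* mass balance (equality, one per internal metabolite):
  Σ_j S_mj ν_j − μ Σ_i a_mi c_i = μ·(pinned-pool demand). Dilution of the
  small-metabolite pools themselves is **not** modelled; a concentration
  target on an internal metabolite adds its μ·c replenishment demand to the
  right-hand side.
* catalytic capacity: ν_j − k⁺ E ≤ 0, and −ν_j − k⁻ E ≤ 0 for reversible
  reactions. Reversible fluxes are single free variables with two capacity
  rows rather than split non-negative pairs: half the variables, the same
  polytope. Spontaneous reactions get bounds only.
* process capacity: μ Σ_{i∈products(p)} d_ip c_i − k_p M_p ≤ 0, where
  d_ip defaults to the product's weight (a ribosome's load is proportional
  to chain length).
* density: Σ_{i∈c} w_i c_i ≤ D_c(μ).

Concentration targets on macromolecules that appear in no catalyst
composition (standalone pools, e.g. a housekeeping protein) are substituted
as constants into the mass-balance, process and density rows — fewer
variables, identical polytope. A `concentration_ge` target on such a pool is
substituted at its bound value, i.e. as the minimal mandatory allocation;
this is exact whenever carrying more of the pool than required cannot help,
which holds for all models shipped here. Concentration targets on
macromolecules expressible through catalyst variables become explicit rows,
as do flux targets.

Parameter functions — enzyme/machine efficiencies, density capacities,
target values — are scalar functions of μ and of at most one external
concentration, drawn from a fixed vocabulary: `constant`,
`linear_bounded` (clipped affine in μ), `michaelis_menten` (saturating in
one external metabolite), and `product` (composition, used by the editing
operations so scalings invert exactly). The vocabulary covers constant
kcats, growth-rate-dependent machine efficiencies and medium-dependent
transporter efficiencies; it is deliberately small so archives stay
readable.

## Growth maximization

Feasibility is monotone in μ: the dilution terms scale with μ while the
capacities do not, so the feasible set shrinks and vanishes at μmax.
`maximize_growth` brackets the boundary by doubling from μ = bisection_tol
and bisects until the bracket's relative width is below `bisection_tol`
(default 1e-6). It returns the last *feasible* μ, never the midpoint, so
the reported state is always constructible. A model still feasible at
`mu_scan_max` (default 10/h; raise it for models with faster kinetics)
raises an unbounded-growth diagnostic.

Purely homogeneous models (no targets) admit the zero vector at every μ,
which would make plain LP feasibility useless. Feasibility there means a
*nontrivial* state: the maximal total catalyst concentration must exceed
1e-9. This threshold separates sharply — any nontrivial ray scales up until
density binds, giving total concentrations of order D/w — and the zero cell
is accepted at μ = 0 by convention.

Optima at μmax are often degenerate. By default the returned state is the
parsimonious one (minimal total enzyme + machine concentration); for
homogeneous models, whose parsimonious state would be the empty cell, the
representative state instead fills the cell (maximal total catalyst
concentration). Pass `parsimonious=False` for the raw feasibility point.

The LP backend is scipy's HiGHS, run at 1e-9 primal/dual tolerances. Every
optimal solution is re-checked for primal feasibility independently of the
backend at an absolute tolerance of 1e-8; violations surface as status
`tolerance_failure`, never silently.

## Analyses

* **Medium screens / Monod curves** re-maximize growth per concentration of
  one external metabolite and record the optimum's fluxes. Per-point
  failures land in the status column; the screen continues.
* **Minimum substrate** inverts the Monod curve by bisection on the
  concentration axis; the returned concentration satisfies
  μmax(c) ≥ μ_target. A target above the saturated plateau raises an error
  stating that plateau.
* **Parameter screens** wrap one catalyst's efficiency in a scaling factor
  (default grid: 25 points, logarithmic over [0.01, 100]).
* **Local sensitivities** are unitless scaled derivatives
  d ln μmax / d ln k, estimated by a symmetric finite difference in log
  space with half-step δ = ln(1.01). Finite differences over bisection were
  chosen over dual-based formulas because they remain robust at degenerate
  optima. Since the estimator divides by 2δ ≈ 0.02, the inner bisection
  tolerance is tightened to min(bisection_tol, 1e-8) so growth-rate noise
  (~1e-8 relative) stays two orders below the estimator's truncation error
  (~1e-5 for curvatures of order one). Magnitudes below 1e-6 are reported
  as exactly zero — the operational definition of "non-zero sensitivity".
* **Global ensembles** multiply every *enzyme* efficiency by its own
  lognormal factor (ln x ~ N(0, σ²), default σ = ln 1.1, n = 1000 samples)
  and re-maximize growth per sample. Process efficiencies are left
  untouched by default. Sampling uses `numpy.random.default_rng(seed)`;
  the result table is bitwise reproducible from the seed.
* **RVA** minimizes and maximizes each requested variable at fixed μ (two
  LP solves per variable). Unbounded directions are reported as ±inf with
  status `unbounded`, infeasible growth rates as all-infeasible rows.
  `rva_over_growth` computes μmax once and evaluates the ranges at the
  requested fractions of it.
* **Pareto fronts** use the ε-constraint method at fixed sub-maximal μ:
  find b_max = max B, then maximize A subject to B ≥ b on a linear grid of
  20 levels in [0, b_max] (a logarithmic grid is available by flag). At
  μmax the front degenerates to a point, so fronts are meaningful only for
  μ < μmax.
* **Production trade-offs** maximize a product flux at μ = f·μmax over a
  grid of fitness fractions f.
* The **overflow switch** concentration is defined operationally: the
  substrate concentration at which the parsimonious optimum's byproduct
  secretion turns on, bracketed by a 25-point logarithmic screen and
  refined by bisection on the on/off indicator.

## Toy models

The generators in `rbakit.toys` are the package's test and demonstration
substrate. They emulate the *structure* of whole-cell RBA models — nutrient
import, precursor economy, a self-replicating translation machine, pinned
non-growth proteome, alternative pathways with a yield/efficiency
trade-off, product secretion — with one-reaction pathways and unit protein
weights. They do not emulate genome-scale features: no isoenzymes, no
multi-compartment transport chains, no μ-dependent machine efficiencies,
no thousands-fold parameter heterogeneity. Passing tests therefore
demonstrate the correctness of the algorithms (LP assembly, bisection,
screens, RVA, fronts) on models whose answers are known exactly; they say
nothing about the biological accuracy of any particular genome-scale
parameterization.

Closed forms (unit weights unless shown): self-replicator
μmax = 1/(n_E/kE + n_R/kR); pinned replicator
μmax = (1 − n_H c0/D)/(n_E/kE + n_R/kR); Michaelis–Menten importer
μmax(c) = (1 − c0/D)/(1/(vmax·c/(c+km)) + 1/kR). The overflow toy's
switch concentration solves the proteome-cost tie
(1/y_resp)(1/k_resp + 1/k_imp) = (1/y_ovfl)(1/k_ovfl + 1/k_imp); with the
defaults (vmax = 10, km = 1, y = 1 vs 0.5, k = 1 vs 10, kR = 2, c0 = 0.1,
D = 1) the tie sits at k_imp = 1.25, i.e. c* = 1/7 mM. The default
parameters were chosen once so that every regime (import-limited,
translation-limited, both pathway modes) is exercised within a
two-decade concentration range. Generator docstrings document the closed
forms, and the tests re-derive them with an independent dense feasibility
scan so formulas and builders cannot drift apart silently. Randomized
variants draw parameters log-uniformly from [0.1, 10] to exercise
conditioning; their μmax can reach ~50/h, so scans over them must raise
`mu_scan_max` accordingly.

## Numerical choices and degenerate inputs

* Bisection tolerance 1e-6 relative on μ; feasibility re-check 1e-8
  absolute; sensitivity zero-threshold 1e-6; parsimonious tie-break as
  above.
* Knockouts set efficiencies to constant 0 rather than deleting
  components, keeping the LP's shape stable across edits; a knocked-out
  capacity row reads ν ≤ 0.
* Edits are copy-on-write; scaling wraps functions in
  `product(constant(f), ·)` so a scale by f followed by 1/f restores every
  evaluated parameter to relative 1e-12.
* Michaelis–Menten evaluation returns 0 when concentration + km = 0; a
  missing medium entry raises a dedicated error naming the metabolite.
* Floats serialize with `repr` (shortest round-trip form) everywhere, so
  one read/write cycle of a model archive is byte-identical and CSV
  exports keep full precision.

## Problem sizes

The shipped tests and the acceptance script run entirely on the toy
models: 100 random draws per replicator family for closed-form recovery,
10^4-point (tests) / 2·10^3-point (script) dense feasibility scans as the
bisection oracle, 1000-sample ensembles at the overflow switch, and
20-point fronts checked against a 191-level sweep. These sizes were chosen
to give sub-grid-resolution agreement checks while keeping a full run in
the minutes range on a single core.

## Known limitations

* The RBA-XML dialect of other RBA software is not parsed; the native
  format is the documented SBtab-flavoured TSV archive.
* Metabolite pools have no dilution term (see above); models relying on
  that term need an explicit concentration target to approximate it.
* The ε-constraint front assumes both objectives are bounded at the chosen
  μ; free cycles must be capped by targets first.
* `concentration_ge` on a standalone pool is treated as pinned at the
  bound (see above) — exact for mandatory-burden semantics, not for pools
  that could beneficially overshoot.
* No warm starts across screens; every point solves from scratch. At toy
  scale this is irrelevant; genome-scale users would want a persistent
  HiGHS instance.
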