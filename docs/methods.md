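# Methods

## Model and scope

The package operates on mass-action reaction networks: species `x_1…x_n`,
reactions `j` with reactant stoichiometries `α_ji`, product stoichiometries
`β_ji` and rate constants `k_j > 0`, inducing the polynomial system
`dx_i/dt = Σ_j k_j S_ij x^{α_j}` with `S = β − α`. Orders of magnitude are
encoded relative to a small parameter `ε ∈ (0,1)` (default 0.1): a positive
quantity `q` has integer order `round(log q / log ε)`, so smaller quantities
have larger orders. Exact half-integer ratios round away from zero; the rule
is centralized in `parameter_order` and can be swapped. Rational orders with
common denominator `q` are supported by pre-multiplying all `γ` by `q`
upstream of the solver (integer arithmetic throughout otherwise).

A species order vector `a` equilibrates species `i` when the minimal degree
`μ_j = γ_j + ⟨a, α_j⟩` over the positive monomials of its equation equals the
minimal degree over the negative ones. This is a necessary condition for the
species to be fast (to relax onto an invariant manifold); it is weaker than a
steady state and deliberately so. Permanency (boundedness of the rescaled
concentrations away from 0 and ∞) is *not* checked: equilibrations whose
truncation cannot support a valid reduced model are still reported, together
with the timescale data a modeller needs to discard them.

## Monomial bookkeeping

Each reaction contributes the monomial `k_j S_ij x^{α_j}` to every equation
it touches. Terms with identical sign, exponent vector *and* order are merged
by summing magnitudes; terms sharing sign and exponents but of different
order stay separate. This matters: the complex equation of the reduced
enzymatic example carries both `−k_-1 x2` and `−k2 x2`, and collapsing them
into one coefficient `k_-1 + k2` would (a) hide which process is dominant on
each branch, (b) break exact cancellation in pool detection (the
quasi-equilibrium truncation conserves `x1 + x2` only because the retained
`k_-1` terms cancel exactly), and (c) change the truncated models. The cost
is that an equation may contain a positive and a negative monomial with equal
exponents that can equilibrate each other; that is the intended reading of
the balance condition on per-reaction monomials. Species with an empty
equation are flagged inert; species with a single-signed equation are
excluded from equilibration constraints and reported in
`excluded_variables` (a production-only product would otherwise make every
model infeasible).

## Conservation laws

Semi-positive integer left-kernel vectors (`bᵀS = 0`, `b ≥ 0`, gcd 1) are
enumerated with the classical Farkas/Fourier–Motzkin construction, column by
column, with support-minimality pruning at every step; the result is the set
of minimal-support P-invariants. For systems written down directly (no
reaction structure, e.g. after eliminating a species by hand) the same
computation runs on the exact species-by-monomial signed coefficient matrix,
with float magnitudes converted losslessly to rationals. Each law is
evaluated at the initial state; its constant's order `κ` enters the solver as
`min(order(b_i) + a_i over members) = κ`. Laws with zero initial total have
no finite order and are dropped with a warning. Laws can also be supplied in
a JSON side-car file (`--laws`), overriding computation.

## Constraint encoding and search

The solver targets a deliberately narrow constraint language — integer
interval variables, affine forms, `form ≤ form`, reified equality
`b ⇔ (form = form)`, cardinality sums — implemented in `fd.py`, so any
finite-domain or SMT backend supporting reification could be substituted.
Per constrained species one shared minimum variable `M_i` is posted with
`min_with_count(positive degrees, M_i, c⁺)` and `min_with_count(negative
degrees, M_i, c⁻)`, `c⁺, c⁻ ≥ 1`: the two sides must reach a common minimum,
i.e. the overall minimum is attained at least twice with opposite signs.
`min_with_count(L, M, C)` posts `M ≤ f` for every form and `C = Σ_f [f = M]`
through reified indicators, so fixing `M` prunes forms and disequalities on
forms force other indicators — propagation flows in all directions without
branching. A `min_count` knob (default 2, i.e. implied by the per-side
condition) strengthens the total multiplicity for non-steady-state use.

Propagation is bounds-consistent and run to a fixpoint; enumeration is
dichotomic search on the order variables (domains split at the midpoint, no
variable-selection heuristic), with an exact arithmetic feasibility check at
every leaf, so completeness within the box never depends on propagation
strength. Decision variables are created only for species that occur in some
constraint form; a species appearing nowhere (e.g. a terminal product) would
otherwise multiply every solution count by the box width. Boxes are
symmetric `[−D, D]`; `solve_with_expansion` starts at D = 2 and doubles to at
most 128 while the solution set is empty. Solutions outside the final box are
knowingly missed; `boundary_hit` (some solution touches the walls) and
`truncated` (the enumeration cap, default 10⁶, was reached) flag the two ways
the box may be too small — together they are the practical detector of
under-constrained problems with infinitely many solutions. Within one box,
the solution set at `D` is a subset of the set at `2D`.

An independent oracle (`oracle.py`) re-evaluates the equilibration and
conservation conditions on every grid point of the box with vectorised
numpy, sharing no code with the propagation/search path; solver output is
compared against it exhaustively in the tests and the acceptance script.

## Partial equilibration and branches

Complete equilibration of all two-signed species can be infeasible even when
individual equations have rich solution sets (two min-plus equations may be
incompatible as identities). `solve_partial_union` enumerates the union over
single-species requirements — every order vector at which *at least one*
species equilibrates — and the classifier records the exact equilibrated set
per solution. Maximisation of the number of equilibrated species (a Max-CSP)
is out of scope.

Solutions are grouped into branches by signature: equilibrated-variable set,
active (minimum-attaining) monomials per equation, and active members per
conservation law. The law component is required: two families of fully
equilibrated solutions can differ only in which species carries the conserved
total. Junction points where adjacent branches meet have strictly larger
signatures (more monomials simultaneously active); each such class is
attached to the dominated branch with the most solutions, so the branch
count reflects the generic half-line structure rather than measure-zero
intersections.

## Truncation, timescales, pools

At an equilibration, `truncate` keeps per equation exactly the monomials of
minimal degree and records `μ_i,min − a_i`: the rescaled derivative of
species `i` scales as `ε^{μ_i,min − a_i}`, so ascending exponent orders
variables fastest first. Truncation is idempotent. Pools are semi-positive
left-kernel vectors of the *truncated* species-by-monomial coefficient
matrix (columns keyed by exponent vector and order, entries exact rationals)
that do not annihilate the full matrix; each pool is reported with its
residual — the signed, pool-weighted sum of the dropped monomials, which is
the pool variable's slow derivative. Pool detection works on monomials, not
reactions, because truncation acts on monomials and the relevant
cancellations (e.g. `x1 + x2` under quasi-equilibrium) are monomial-level.
The closed-form reduced ODE after eliminating fast variables is not derived
symbolically; the residual monomials plus the order bookkeeping carry the
information needed to verify fast/slow assignments.

## SBML input

The reader accepts SBML Level 2/3 with purely polynomial kinetics. Kinetic
laws are translated from MathML (plus/times/minus/divide/power, numeric
constants, function-definition expansion) to sympy, all parameters,
compartment sizes and boundary/constant species are substituted numerically,
and the law is expanded; each polynomial term becomes one effective
mass-action reaction (coefficient magnitude as rate constant, term exponents
as reactant stoichiometry, original net stoichiometry applied with the
term's sign). Reversible mass-action laws thus split into forward and
reverse reactions. Boundary/constant species are folded into rate constants
— they have no ODE to equilibrate. Events are ignored; models with SBML
rules are rejected wholesale as non-polynomial, the conservative reading of
"purely polynomial kinetics" given that rules rewrite quantities the laws
depend on. Rejections carry the offending reaction id.

## Synthetic data

`fixtures` provides the enzymatic mechanism in three forms (4-species
network, 3-species network with the product dropped, and the 2-variable
eliminated system) and seeded random networks. Fixture rate constants and
initial concentrations are exact powers `ε^γ` with unit prefactors, so order
computation is rounding-free and solver tests are insulated from the
rounding rule. The two canonical regimes instantiate
`(γ_1, γ_-1, γ_2, γ_e) = (0, 0, 1, 1)` (dissociation dominates catalysis)
and `(0, 2, 0, 1)` (catalysis dominates); the substrate's initial order is 0.
Random networks draw at-most-bimolecular reactant sides with stoichiometries
in {1, 2}, 1–2 products, and orders uniform on [0, 3] — enough spread to
exercise every constraint type while keeping the `[−6, 6]^n` oracle grid
exhaustive in milliseconds. These generators emulate the *structure* of
curated repository models at desk scale; they do not reproduce hub species
with dozens of reactions, rational orders, or the unit pathologies of real
SBML (e.g. concentrations of order 10⁻²¹ shifting every solution far from
the origin), so passing tests demonstrate correctness of the algebra and the
search, not coverage of repository-scale parsing corner cases.

## Problem sizes and numerical choices

Test and acceptance runs use 2–5 species, up to 8 reactions, boxes up to
`[−8, 8]`, and ensembles of 50 random networks — sizes at which the
brute-force oracle is exact and fast, which is what makes the dual-route
check meaningful. Defaults: ε = 0.1, initial box 2, maximal box 128,
enumeration cap 10⁶, `min_count` 2. Exact integer/rational arithmetic is
used everywhere past the initial order rounding (kernel computations convert
float magnitudes to exact binary rationals), so there are no tolerance
parameters in the solver itself. Ties between equally dominant monomials are
not broken: all minimum-attaining monomials are retained by truncation and
reported as active.

## Known limitations

* Complete-equilibration enumeration only, plus the single-species partial
  union; no Max-CSP maximisation of the equilibrated set.
* Integer orders only (rational orders require caller-side rescaling).
* Permanency is not checked; some reported branches do not correspond to
  valid reduced models.
* The Farkas construction is exponential in the worst case (guarded by a row
  budget); it is intended for the small-to-medium networks this tool
  targets.
* The SBML subset excludes rules, algebraic constraints and delayed events;
  models relying on them are rejected rather than approximated.
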