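# tropicalize

Tropical equilibration and model reduction of mass-action reaction networks
by finite-domain constraint solving.

## The problem

A biochemical network with mass-action kinetics induces the polynomial ODE
system

    dx_i/dt = Σ_j k_j S_ij x^α_j ,

where `S` is the stoichiometric matrix and each right-hand side is a signed
sum of monomials. When rate constants are only known by order of magnitude,
write `k_j = k̄_j ε^γ_j` and `x_i = x̄_i ε^{a_i}` for a small `ε` (default
0.1; *small* quantities have *large* orders, `γ = round(log k / log ε)`).
Every monomial then has an integer degree `μ_j = γ_j + ⟨a, α_j⟩`, and an
order vector `a` **tropically equilibrates** species `i` when its dominant
production and consumption terms balance:

    min(μ_j : S_ij > 0) = min(μ_j : S_ij < 0).

This min-plus condition is the lowest-order shadow of a steady state: it is
what must hold for a fast variable to relax onto a slow invariant manifold.
Solving it for all (or a chosen subset of) species, together with the
rescaled conservation-law constraints `min over members(order(b_i) + a_i) =
κ` (with `κ` the order of the conserved total), yields the admissible
scalings of the network. Each solution drives a **tropical truncation**: the
model keeping only the dominant monomials, with the exponents `μ_i,min − a_i`
ranking variables from fast to slow, and with newly conserved **pools**
(linear forms conserved by the truncated but not the full dynamics)
identifying the slow aggregate variables — the algebraic skeleton of
quasi-steady-state and quasi-equilibrium reductions.

Finding integer equilibrations is NP-hard in general. The package encodes
the problem over finite domains `a_i ∈ [−D, D]` using a *reified
min-with-count* constraint — one shared minimum variable per equation, 0/1
indicators linked bidirectionally to `degree = minimum`, and cardinality
sums — so that domain pruning propagates in all directions before any
branching. Enumeration is complete within the box via dichotomic search
(domain bisection), and the box grows by doubling (D = 2, 4, …, 128) until
solutions appear.

## What is in the package

| module | contents |
| --- | --- |
| `network_io` | plain-text reaction format and an SBML L2/L3 reader restricted to polynomial kinetics (anything else raises `NonPolynomialKineticsError`) |
| `polynomial_system` | signed-monomial ODE assembly, ε-orders, tropical degrees |
| `conservation` | minimal semi-positive conservation laws (P-invariants) and their constant orders |
| `tropical_solver` | CSP construction, `min_with_count`, complete enumeration, domain expansion, partial-equilibration union, branch grouping |
| `reduction` | tropical truncation, timescale ordering, pool detection |
| `fixtures` | the Michaelis–Menten instantiations and seeded random networks |
| `oracle` | independent brute-force grid enumeration used for cross-checks |
| `fd` | the small finite-domain engine (interval domains, reified equality, bisection search) |
| `cli` | `tropicalize solve MODEL` / `tropicalize batch DIR` |

## Worked example

The enzymatic mechanism `S + E ⇌ ES → P + E` with `k1 = k−1 = 1`,
`k2 = 0.1`, `e0 = 0.1` (orders 0, 0, 1, 1 at ε = 0.1):

```python
import tropicalize as tz
from tropicalize.polynomial_system import build_odes
from tropicalize.conservation import attach_constants, find_invariants

text = """
init: S = 1.0
init: E = 0.1
S + E -> ES ; k=1.0
ES -> S + E ; k=1.0
ES -> P + E ; k=0.1
"""
network = tz.parse_reaction_text(text)
system = build_odes(network, epsilon=0.1)
laws = attach_constants(find_invariants(system),
                        network.initial_concentrations, epsilon=0.1)
result = tz.solve_with_expansion(tz.build_problem(system, laws, domain=2))
for branch in tz.group_branches(result, system):
    rep = branch.representative
    print("branch:", rep.orders, "equilibrated:", sorted(rep.equilibrated))
    print(tz.truncate(system, rep).render())
```

prints (abridged):

```
conserved: {'E': 1, 'ES': 1} constant: 0.1 kappa: 1
conserved: {'S': 1, 'ES': 1, 'P': 1} constant: 1.0 kappa: 0
solutions: 4 domain: 2 excluded: ['P']
branch: {'S': 0, 'E': 1, 'ES': 1, 'P': 0} equilibrated: ['E', 'ES', 'S']
dS/dt = -1*E*S +1*ES
dE/dt = -1*E*S +1*ES
dES/dt = +1*E*S -1*ES
dP/dt = +0.1*ES
pool: d(ES + S)/dt = -0.1*ES
timescales (fastest first): [('E', 0), ('ES', 0), ('S', 1), ('P', 2)]
```

Reading: both conservation laws are recovered with their constant orders
(`e0 = 0.1` has order 1). The product `P`, produced but never consumed, is
excluded from equilibration. On the reported branch the substrate sits at
order 0 and the complex at order 1, binding and unbinding dominate the
truncated dynamics (quasi-equilibrium of the first reaction), and the
truncation conserves the pool `z = S + ES`, whose slow decay `z' = −k2·ES`
is driven by the dominated catalytic term — the tropical counterpart of the
classical Michaelis–Menten reduction.

The same analysis from the shell:

```sh
tropicalize solve mm.txt --reduce        # JSON report to stdout
tropicalize batch models/ --format tsv   # one row per SBML file
```

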