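"""Tropical equilibration as a finite-domain constraint problem.

An order vector ``a`` tropically equilibrates species ``i`` when the minimal
epsilon-degree among the positive monomials of its ODE equals the minimal
degree among the negative ones:

    min(mu_j : S_ij > 0) = min(mu_j : S_ij < 0),   mu_j = gamma_j + <a, alpha_j>

The encoding introduces one shared minimum variable ``M_i`` per constrained
species, linked to both monomial lists through a reified min-with-count
constraint, so that propagation flows in all directions before any branching.
Conservation laws contribute ``min(member degrees) = kappa``.  Enumeration
uses dichotomic search over symmetric boxes ``[-D, D]^n`` with iterative
domain doubling from D=2 up to D=128.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from . import fd
from .conservation import ConservationLaw
from .polynomial_system import Monomial, PolynomialSystem, monomial_degree, parameter_order

__all__ = [
    "NothingToEquilibrate",
    "TropicalProblem",
    "Equilibration",
    "SolutionSet",
    "Branch",
    "build_problem",
    "min_with_count",
    "solve_all",
    "solve_with_expansion",
    "solve_partial_union",
    "classify_solution",
    "group_branches",
]

MAX_DOMAIN = 128
DEFAULT_SOLUTION_CAP = 10 ** 6


class NothingToEquilibrate(ValueError):
    """No species has monomials of both signs: the problem is empty."""


@dataclass
class TropicalProblem:
    system: PolynomialSystem
    constrained_species: List[str]
    order_species: List[str]  # species carrying a decision variable
    excluded_variables: List[str]  # species without an equilibration constraint
    laws: List[ConservationLaw]
    min_count: int = 2
    domain: int = 2

    def law_form(self, law: ConservationLaw, s: str) -> Tuple[int, str]:
        """Degree form of one member of a conservation law: order(b_s) + a_s."""
        return (parameter_order(law.coefficients[s], self.system.epsilon), s)


@dataclass
class Equilibration:
    orders: Dict[str, int]
    achieved_minimum: Dict[str, int]
    active_monomials: Dict[str, List[Monomial]]
    equilibrated: Set[str]

    def order_tuple(self, species: Sequence[str]) -> Tuple[int, ...]:
        return tuple(self.orders[s] for s in species if s in self.orders)


@dataclass
class SolutionSet:
    solutions: List[Equilibration]
    domain_used: int
    boundary_hit: bool
    truncated: bool
    excluded_variables: List[str]
    problem: Optional[TropicalProblem] = None

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.solutions)


def build_problem(system: PolynomialSystem,
                  laws: Sequence[ConservationLaw] = (),
                  min_count: int = 2,
                  domain: int = 2,
                  require: Optional[Iterable[str]] = None) -> TropicalProblem:
    """Assemble the constraint problem for a polynomial system.

    ``require`` restricts the equilibration constraints to a subset of
    species (partial equilibration); by default every species whose equation
    carries monomials of both signs is constrained.  Species with
    single-signed or empty equations never are; they land in
    ``excluded_variables``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if domain < 1:
        raise ValueError("domain must be >= 1")
    candidates = [s for s in system.species
                  if system.positive(s) and system.negative(s)]
    if require is not None:
        require = set(require)
        bad = require - set(candidates)
        if bad:
            raise NothingToEquilibrate(
                f"species {sorted(bad)} cannot be equilibrated "
                f"(single-signed or empty equation)")
        constrained = [s for s in candidates if s in require]
    else:
        constrained = candidates
    if not constrained:
        raise NothingToEquilibrate("no species with both production and "
                                   "consumption monomials")
    excluded = [s for s in system.species if s not in constrained]
    referenced: Set[str] = set()
    for s in constrained:
        for m in system.equations[s]:
            referenced.update(sp for sp, _ in m.exponents)
    for law in laws:
        referenced.update(law.members())
    order_species = [s for s in system.species if s in referenced]
    return TropicalProblem(system=system,
                           constrained_species=constrained,
                           order_species=order_species,
                           excluded_variables=excluded,
                           laws=list(laws),
                           min_count=min_count,
                           domain=domain)


def min_with_count(forms: Sequence[fd.Affine], m: fd.Var, c: fd.Var,
                   doms: Dict[fd.Var, Tuple[int, int]],
                   tag: str) -> List[fd.Constraint]:
    """The reified min/3 constraint: ``m <= every form`` and ``c`` counts the
    forms equal to ``m``.

    On the empty list the count is fixed to zero.  Fresh 0/1 indicator
    variables are registered in ``doms``; reified equality links each
    indicator to ``form == m`` so information propagates in all directions.
    """
    constraints: List[fd.Constraint] = []
    bools: List[fd.Var] = []
    m_form = fd.Affine.from_terms(0, {m: 1})
    for i, form in enumerate(forms):
        constraints.append(fd.LessEq(m_form, form))
        b = fd.Var(f"{tag}.eq{i}")
        doms[b] = (0, 1)
        bools.append(b)
        constraints.append(fd.ReifiedEq(b, form, m_form))
    constraints.append(fd.SumEq(tuple(bools), c))
    return constraints


def _degree_affine(gamma: int, exponents: Tuple[Tuple[str, int], ...],
                   avars: Mapping[str, fd.Var]) -> fd.Affine:
    return fd.Affine.from_terms(gamma, {avars[s]: e for s, e in exponents})


def _check_point(problem: TropicalProblem, orders: Dict[str, int]) -> bool:
    """Exact feasibility test of one order vector (used at search leaves)."""
    system = problem.system
    for s in problem.constrained_species:
        pos = [monomial_degree(m, orders) for m in system.positive(s)]
        neg = [monomial_degree(m, orders) for m in system.negative(s)]
        if min(pos) != min(neg):
            return False
        mn = min(pos)
        if pos.count(mn) + neg.count(mn) < problem.min_count:
            return False
    for law in problem.laws:
        degs = [g + orders[s] for g, s in
                (problem.law_form(law, s) for s in law.members())]
        if min(degs) != law.kappa:
            return False
    return True


def solve_all(problem: TropicalProblem,
              solution_cap: int = DEFAULT_SOLUTION_CAP) -> SolutionSet:
    """Enumerate every equilibration in the box ``[-D, D]^n``.

    Complete within the box: dichotomic search over the order variables with
    bounds propagation through the reified min constraints, and an exact
    check at every leaf.
    """
    system = problem.system
    D = problem.domain
    doms: Dict[fd.Var, Tuple[int, int]] = {}
    avars = {s: fd.Var(f"a[{s}]") for s in problem.order_species}
    for v in avars.values():
        doms[v] = (-D, D)
    constraints: List[fd.Constraint] = []
    for s in problem.constrained_species:
        pos = [_degree_affine(m.gamma, m.exponents, avars)
               for m in system.positive(s)]
        neg = [_degree_affine(m.gamma, m.exponents, avars)
               for m in system.negative(s)]
        mvar = fd.Var(f"M[{s}]")
        lo = min(f.bounds(fd.Store(doms))[0] for f in pos + neg)
        hi = max(f.bounds(fd.Store(doms))[1] for f in pos + neg)
        doms[mvar] = (lo, hi)
        cpos = fd.Var(f"C+[{s}]")
        cneg = fd.Var(f"C-[{s}]")
        doms[cpos] = (1, len(pos))
        doms[cneg] = (1, len(neg))
        constraints += min_with_count(pos, mvar, cpos, doms, f"P[{s}]")
        constraints += min_with_count(neg, mvar, cneg, doms, f"N[{s}]")
        if problem.min_count > 2:
            total = fd.Var(f"C[{s}]")
            doms[total] = (problem.min_count, len(pos) + len(neg))
            constraints.append(fd.SumEq((cpos, cneg), total))
    for li, law in enumerate(problem.laws):
        forms = [fd.Affine.from_terms(g, {avars[s]: 1})
                 for g, s in (problem.law_form(law, s) for s in law.members())]
        kvar = fd.Var(f"K[{li}]")
        doms[kvar] = (law.kappa, law.kappa)
        cvar = fd.Var(f"KC[{li}]")
        doms[cvar] = (1, len(forms))
        constraints += min_with_count(forms, kvar, cvar, doms, f"L[{li}]")

    engine = fd.Engine(constraints)
    decision = [avars[s] for s in problem.order_species]
    solutions: List[Equilibration] = []
    truncated = False
    boundary_hit = False

    def on_solution(assignment: Dict[fd.Var, int]) -> bool:
        nonlocal truncated, boundary_hit
        orders = {s: assignment[avars[s]] for s in problem.order_species}
        if not _check_point(problem, orders):
            return True
        if len(solutions) >= solution_cap:
            truncated = True
            return False
        if any(abs(v) == D for v in orders.values()):
            boundary_hit = True
        solutions.append(classify_solution(problem.system, orders))
        return True

    engine.solve(fd.Store(dict(doms)), decision, on_solution)
    return SolutionSet(solutions=solutions, domain_used=D,
                       boundary_hit=boundary_hit, truncated=truncated,
                       excluded_variables=list(problem.excluded_variables),
                       problem=problem)


def solve_with_expansion(problem: TropicalProblem,
                         solution_cap: int = DEFAULT_SOLUTION_CAP,
                         max_domain: int = MAX_DOMAIN) -> SolutionSet:
    """Solve with iterative domain doubling: D = 2, 4, 8, ... up to 128.

    Returns the solution set of the first domain with at least one solution,
    or the (empty) result at the maximal domain.
    """
    D = problem.domain
    result: Optional[SolutionSet] = None
    while True:
        problem.domain = D
        result = solve_all(problem, solution_cap=solution_cap)
        if result.solutions or D >= max_domain:
            return result
        D = min(2 * D, max_domain)


def solve_partial_union(system: PolynomialSystem,
                        laws: Sequence[ConservationLaw] = (),
                        domain: int = 6,
                        min_count: int = 2,
                        solution_cap: int = DEFAULT_SOLUTION_CAP) -> SolutionSet:
    """All order vectors equilibrating *at least one* species.

    Complete equilibration may be infeasible (two tropical equations can be
    incompatible as min-plus identities), yet individual equations still
    carry branches of partially equilibrated solutions.  This enumerates the
    union of the solution sets obtained by requiring each equilibratable
    species in turn, deduplicated by order vector; the classifier records the
    per-solution equilibrated set exactly, so branch grouping of the union
    reflects the full (partial + complete) branch structure.
    """
    candidates = [s for s in system.species
                  if system.positive(s) and system.negative(s)]
    if not candidates:
        raise NothingToEquilibrate("no species with both production and "
                                   "consumption monomials")
    seen: Dict[Tuple[Tuple[str, int], ...], Equilibration] = {}
    boundary = truncated = False
    problem = None
    for s in candidates:
        problem = build_problem(system, laws, min_count=min_count,
                                domain=domain, require=[s])
        res = solve_all(problem, solution_cap=solution_cap)
        boundary |= res.boundary_hit
        truncated |= res.truncated
        for sol in res.solutions:
            seen.setdefault(tuple(sorted(sol.orders.items())), sol)
    excluded = [s for s in system.species if s not in candidates]
    return SolutionSet(solutions=list(seen.values()), domain_used=domain,
                       boundary_hit=boundary, truncated=truncated,
                       excluded_variables=excluded, problem=problem)


def classify_solution(system: PolynomialSystem,
                      orders: Mapping[str, int]) -> Equilibration:
    """Per-equation minima, active monomials and the equilibrated set.

    A species is equilibrated when both signs are present in its equation and
    their minimal degrees coincide.  Equations referencing species without an
    assigned order are skipped.
    """
    achieved: Dict[str, int] = {}
    active: Dict[str, List[Monomial]] = {}
    equilibrated: Set[str] = set()
    for s in system.species:
        eq = system.equations[s]
        if not eq:
            continue
        needed = {sp for m in eq for sp, _ in m.exponents}
        if not needed <= set(orders):
            continue
        degs = [monomial_degree(m, orders) for m in eq]
        mn = min(degs)
        achieved[s] = mn
        active[s] = [m for m, d in zip(eq, degs) if d == mn]
        pos = [d for m, d in zip(eq, degs) if m.sign > 0]
        neg = [d for m, d in zip(eq, degs) if m.sign < 0]
        if pos and neg and min(pos) == min(neg):
            equilibrated.add(s)
    return Equilibration(orders=dict(orders), achieved_minimum=achieved,
                         active_monomials=active, equilibrated=equilibrated)


Signature = Tuple[FrozenSet[str], Tuple[FrozenSet, ...], Tuple[FrozenSet[str], ...]]


@dataclass
class Branch:
    signature: Signature
    solutions: List[Equilibration]
    representative: Equilibration

    @property
    def count(self) -> int:
        return len(self.solutions)

    @property
    def equilibrated(self) -> FrozenSet[str]:
        return self.signature[0]


def _signature(sol: Equilibration, system: PolynomialSystem,
               laws: Sequence[ConservationLaw], epsilon: float) -> Signature:
    active_sig = tuple(
        frozenset(m.key() for m in sol.active_monomials.get(s, []))
        for s in system.species
    )
    law_sig = []
    for law in laws:
        degs = {s: parameter_order(law.coefficients[s], epsilon) + sol.orders[s]
                for s in law.members() if s in sol.orders}
        mn = min(degs.values()) if degs else None
        law_sig.append(frozenset(s for s, d in degs.items() if d == mn))
    return (frozenset(sol.equilibrated), active_sig, tuple(law_sig))


def _sig_leq(a: Signature, b: Signature) -> bool:
    """Componentwise containment: a's signature is dominated by b's."""
    return (a[0] <= b[0]
            and all(x <= y for x, y in zip(a[1], b[1]))
            and all(x <= y for x, y in zip(a[2], b[2])))


def group_branches(solutions: SolutionSet,
                   system: PolynomialSystem) -> List[Branch]:
    """Partition a solution set into branches.

    Two solutions share a branch when they have the same equilibrated set,
    the same active monomials in every equation and the same active members
    of every conservation law.  Junction points, where the dominant monomials
    of two adjacent branches are simultaneously active, have a strictly
    larger signature; each such class is attached to the dominated branch
    with the most solutions, so the branch count reflects the generic
    (maximal-family) structure.
    """
    if not solutions.solutions:
        return []
    laws = solutions.problem.laws if solutions.problem else []
    groups: Dict[Signature, List[Equilibration]] = {}
    for sol in solutions.solutions:
        groups.setdefault(
            _signature(sol, system, laws, system.epsilon), []).append(sol)
    sigs = list(groups)
    minimal = [s for s in sigs
               if not any(t != s and _sig_leq(t, s) for t in sigs)]
    branches = {s: list(groups[s]) for s in minimal}
    for s in sigs:
        if s in branches:
            continue
        below = [t for t in minimal if _sig_leq(t, s)]
        target = sorted(below, key=lambda t: (-len(groups[t]), repr(t)))[0]
        branches[target].extend(groups[s])
    out = []
    for s in minimal:
        sols = branches[s]
        rep = min(sols, key=lambda e: sorted(e.orders.items()))
        out.append(Branch(signature=s, solutions=sols, representative=rep))
    out.sort(key=lambda b: sorted(b.representative.orders.items()))
    return out
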