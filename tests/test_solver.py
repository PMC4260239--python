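"""Constraint encoding, enumeration, classification and branch grouping."""

import pytest

import tropicalize as tz
from tropicalize import fd
from tropicalize.conservation import ConservationLaw, attach_constants, find_invariants
from tropicalize.fixtures import (FixtureSpec, michaelis_menten_reduced,
                                  michaelis_menten_unreduced, random_network)
from tropicalize.polynomial_system import Monomial, PolynomialSystem, build_odes
from tropicalize.tropical_solver import min_with_count


def orders_set(solution_set):
    return sorted(tuple(sorted(s.orders.items())) for s in solution_set.solutions)


def oracle_set(system, laws=(), domain=6, **kw):
    return sorted(tuple(sorted(o.items()))
                  for o in tz.brute_force_orders(system, laws, domain, **kw))


def solve_box(system, laws=(), domain=6, **kw):
    return tz.solve_all(tz.build_problem(system, laws, domain=domain, **kw))


class TestMinWithCount:
    def _solve(self, doms, constraints, decision):
        engine = fd.Engine(constraints)
        found = []
        engine.solve(fd.Store(dict(doms)), decision,
                     lambda a: (found.append(dict(a)), True)[1])
        return engine, found

    def test_counts_minimum_multiplicity(self):
        doms = {}
        m, c = fd.Var("m"), fd.Var("c")
        doms[m] = (-10, 10)
        doms[c] = (1, 3)
        forms = [fd.Affine.of(3), fd.Affine.of(5), fd.Affine.of(3)]
        cons = min_with_count(forms, m, c, doms, "t")
        engine, found = self._solve(doms, cons, [m, c])
        assert found == [{m: 3, c: 2}]

    def test_empty_list_fixes_count_to_zero(self):
        doms = {}
        m, c = fd.Var("m"), fd.Var("c")
        doms[m] = (0, 0)
        doms[c] = (0, 5)
        cons = min_with_count([], m, c, doms, "t")
        store = fd.Store(doms)
        assert fd.Engine(cons).propagate(store)
        assert store.dom[c] == (0, 0)

    def test_reified_propagation_forces_remaining_form(self):
        """With m=2 fixed and count >= 1, the free form must equal 2."""
        doms = {}
        m, c, x = fd.Var("m"), fd.Var("c"), fd.Var("x")
        doms[m] = (2, 2)
        doms[c] = (1, 2)
        doms[x] = (-10, 10)
        forms = [fd.Affine.from_terms(0, {x: 1}), fd.Affine.of(5)]
        cons = min_with_count(forms, m, c, doms, "t")
        store = fd.Store(doms)
        assert fd.Engine(cons).propagate(store)
        assert store.dom[x] == (2, 2)

    def test_singleton_with_count_one_pins_minimum(self):
        doms = {}
        m, c, x = fd.Var("m"), fd.Var("c"), fd.Var("x")
        doms[m] = (-10, 10)
        doms[c] = (1, 1)
        doms[x] = (4, 4)
        cons = min_with_count([fd.Affine.from_terms(0, {x: 1})], m, c, doms, "t")
        store = fd.Store(doms)
        assert fd.Engine(cons).propagate(store)
        assert store.dom[m] == (4, 4)


class TestSolveAll:
    def test_reduced_mm_matches_grid_oracle(self, reduced_a):
        """Complete enumeration over [-4,4]^2 equals the brute-force grid and
        lies on the two known half-lines a2=ge and a2=a1+g1+ge-g_1."""
        res = solve_box(reduced_a, domain=4)
        assert orders_set(res) == oracle_set(reduced_a, domain=4)
        for sol in res.solutions:
            a1, a2 = sol.orders["x1"], sol.orders["x2"]
            assert (a2 == 1 and a1 <= 0) or (a2 == a1 + 1 and a1 >= 0)

    def test_unsatisfiable_conservation_is_empty(self, reduced_a):
        law = ConservationLaw({"x1": 1}, constant=None, kappa=-30)
        res = solve_box(reduced_a, laws=[law], domain=4)
        assert res.solutions == []

    def test_single_equation_unique_solution(self):
        net = tz.parse_reaction_text(" -> x ; k=1.0\nx -> ; k=1.0")
        system = build_odes(net, 0.1)
        res = solve_box(system, domain=2)
        assert orders_set(res) == [(("x", 0),)]

    def test_solution_cap_sets_truncated_flag(self, reduced_a):
        res = tz.solve_all(tz.build_problem(reduced_a, domain=6),
                           solution_cap=3)
        assert res.truncated and len(res.solutions) == 3

    def test_boundary_hit_flag(self, reduced_a):
        res = solve_box(reduced_a, domain=4)
        assert res.boundary_hit  # the half-lines run into the box walls

    def test_nothing_to_equilibrate(self):
        net = tz.parse_reaction_text(" -> x ; k=1.0")
        system = build_odes(net, 0.1)
        with pytest.raises(tz.NothingToEquilibrate):
            tz.build_problem(system)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_networks(self, seed):
        """Solver enumeration equals exhaustive grid scan on random networks."""
        net = random_network(n_species=4, n_reactions=6, order_range=(0, 3),
                             seed=seed)
        system = build_odes(net, 0.1)
        laws = attach_constants(find_invariants(system),
                                net.initial_concentrations, 0.1)
        try:
            res = solve_box(system, laws, domain=6)
        except tz.NothingToEquilibrate:
            assert oracle_set(system, laws, domain=6) == []
            return
        assert orders_set(res) == oracle_set(system, laws, domain=6)

    @pytest.mark.parametrize("seed", [1, 3, 5])
    def test_monotone_in_domain(self, seed):
        net = random_network(n_species=3, n_reactions=5, seed=seed)
        system = build_odes(net, 0.1)
        try:
            small = set(orders_set(solve_box(system, domain=3)))
        except tz.NothingToEquilibrate:
            return
        big = set(orders_set(solve_box(system, domain=6)))
        assert small <= big

    def test_gamma_shift_invariance(self, reduced_a):
        """Shifting every gamma of one equation by delta leaves the solution
        set unchanged and shifts that equation's achieved minimum by delta."""
        delta = 3
        shifted = PolynomialSystem(
            species=list(reduced_a.species),
            equations={
                "x1": [Monomial(m.sign, m.magnitude, m.gamma + delta,
                                m.exponents) for m in reduced_a.equations["x1"]],
                "x2": list(reduced_a.equations["x2"]),
            },
            epsilon=reduced_a.epsilon,
        )
        base = solve_box(reduced_a, domain=4)
        moved = solve_box(shifted, domain=4)
        assert orders_set(base) == orders_set(moved)
        for b, m in zip(base.solutions, moved.solutions):
            assert m.achieved_minimum["x1"] == b.achieved_minimum["x1"] + delta
            assert m.achieved_minimum["x2"] == b.achieved_minimum["x2"]

    def test_soundness_of_returned_equilibrations(self, reduced_b):
        res = solve_box(reduced_b, domain=5)
        prob = res.problem
        for sol in res.solutions:
            again = tz.classify_solution(reduced_b, sol.orders)
            assert set(prob.constrained_species) <= again.equilibrated


class TestExpansion:
    def test_expansion_reaches_order_minus_five(self):
        net = tz.parse_reaction_text(" -> x ; k=1.0\nx -> ; k=1e-5")
        system = build_odes(net, 0.1)
        res = tz.solve_with_expansion(tz.build_problem(system, domain=2))
        assert res.domain_used == 8
        assert orders_set(res) == [(("x", -5),)]

    def test_no_expansion_when_solvable_at_two(self, reduced_a):
        res = tz.solve_with_expansion(tz.build_problem(reduced_a, domain=2))
        assert res.domain_used == 2
        assert orders_set(res) == orders_set(solve_box(reduced_a, domain=2))

    def test_infeasible_everywhere_stops_at_128(self):
        net = tz.parse_reaction_text(" -> x ; k=1.0\nx -> ; k=1.0")
        system = build_odes(net, 0.1)
        law = ConservationLaw({"x": 1}, constant=None, kappa=300)
        res = tz.solve_with_expansion(tz.build_problem(system, [law], domain=2))
        assert res.solutions == [] and res.domain_used == 128


class TestClassifyAndBranches:
    def test_oblique_branch_equilibrates_both(self, reduced_a):
        sol = tz.classify_solution(reduced_a, {"x1": 2, "x2": 3})
        assert sol.equilibrated == {"x1", "x2"}

    def test_quasi_stationarity_equilibrates_only_complex(self, reduced_b):
        # on a2 = a1 + g1 + ge - g2 with a1 > g2 - g1
        sol = tz.classify_solution(reduced_b, {"x1": 2, "x2": 3})
        assert sol.equilibrated == {"x2"}

    def test_dominated_side_is_not_equilibrated(self, reduced_b):
        sol = tz.classify_solution(reduced_b, {"x1": 1, "x2": 1})
        assert "x2" not in sol.equilibrated
        assert "x1" in sol.equilibrated

    def test_branch_counts_by_regime(self, reduced_a, reduced_b):
        union_a = tz.solve_partial_union(reduced_a, domain=6)
        union_b = tz.solve_partial_union(reduced_b, domain=6)
        assert len(tz.group_branches(union_a, reduced_a)) == 2
        assert len(tz.group_branches(union_b, reduced_b)) == 4

    def test_singleton_solution_is_one_branch(self):
        net = tz.parse_reaction_text(" -> x ; k=1.0\nx -> ; k=1.0")
        system = build_odes(net, 0.1)
        res = solve_box(system, domain=2)
        assert len(tz.group_branches(res, system)) == 1

    def test_unreduced_mm_conservation_constraint(self, spec_regime_a):
        """The 3-variable mechanism with min(a2,a3)=ge recovers the two
        complete-equilibration branches split by the active law member."""
        net = michaelis_menten_unreduced(spec_regime_a)
        system = build_odes(net, spec_regime_a.epsilon)
        laws = attach_constants(find_invariants(system),
                                net.initial_concentrations,
                                spec_regime_a.epsilon)
        assert [l.coefficients for l in laws] == [{"x2": 1, "x3": 1}]
        assert laws[0].kappa == 1
        res = solve_box(system, laws, domain=6)
        assert orders_set(res) == oracle_set(system, laws, domain=6)
        branches = tz.group_branches(res, system)
        assert len(branches) == 2
        law_actives = {b.signature[2] for b in branches}
        assert law_actives == {(frozenset({"x2"}),), (frozenset({"x3"}),)}
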