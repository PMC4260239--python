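"""Worked example systems and random mass-action networks.

The Michaelis-Menten mechanism  S + E <=> ES -> P + E  is the canonical
small example: the 4-species network, its 3-species form with the product
dropped (the system analysed together with the enzyme conservation law
x2 + x3 = e0), and the 2-variable system obtained by eliminating both
conservation laws,

    x1' = -k1 x1 (e0 - x2) + k_-1 x2
    x2' =  k1 x1 (e0 - x2) - (k_-1 + k2) x2

with x1 = [S] and x2 = [ES].  Rate constants are taken as exact powers
``epsilon**gamma`` (unit prefactors) so that integer orders are free of
rounding ambiguity and solver behaviour can be checked against the known
branch structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .network_io import Reaction, ReactionNetwork
from .polynomial_system import Monomial, PolynomialSystem

__all__ = [
    "FixtureSpec",
    "michaelis_menten_full",
    "michaelis_menten_unreduced",
    "michaelis_menten_reduced",
    "random_network",
]


@dataclass
class FixtureSpec:
    """Parameter orders for a worked example.

    ``parameter_orders`` uses the keys ``k1``, ``k_1`` (the reverse
    constant), ``k2`` for rate constants, ``e`` for the total enzyme e0 and
    optionally ``s`` for the initial substrate (default order 0).
    """

    name: str = "mm"
    parameter_orders: Dict[str, int] = field(default_factory=dict)
    epsilon: float = 0.1
    seed: int = 0

    def value(self, key: str, default_order: int = 0) -> float:
        return self.epsilon ** self.parameter_orders.get(key, default_order)


def michaelis_menten_full(spec: FixtureSpec) -> ReactionNetwork:
    """The 4-species, 3-reaction mechanism; x1=[S], x2=[ES], x3=[E], x4=[P]."""
    k1, k_1, k2 = (spec.value(k) for k in ("k1", "k_1", "k2"))
    return ReactionNetwork(
        species=["x1", "x2", "x3", "x4"],
        initial_concentrations={"x1": spec.value("s"), "x2": 0.0,
                                "x3": spec.value("e"), "x4": 0.0},
        reactions=[
            Reaction({"x1": 1, "x3": 1}, {"x2": 1}, k1, id="bind"),
            Reaction({"x2": 1}, {"x1": 1, "x3": 1}, k_1, id="unbind"),
            Reaction({"x2": 1}, {"x3": 1, "x4": 1}, k2, id="cat"),
        ],
    )


def michaelis_menten_unreduced(spec: FixtureSpec) -> ReactionNetwork:
    """The 3-variable form with the product eliminated (x4' = k2 x2 dropped).

    Its only semi-positive invariant is the enzyme law x2 + x3 = e0, so the
    tropical problem is the pair of equilibration equations for x1 and x2/x3
    plus the constraint min(a2, a3) = gamma_e.
    """
    k1, k_1, k2 = (spec.value(k) for k in ("k1", "k_1", "k2"))
    return ReactionNetwork(
        species=["x1", "x2", "x3"],
        initial_concentrations={"x1": spec.value("s"), "x2": 0.0,
                                "x3": spec.value("e")},
        reactions=[
            Reaction({"x1": 1, "x3": 1}, {"x2": 1}, k1, id="bind"),
            Reaction({"x2": 1}, {"x1": 1, "x3": 1}, k_1, id="unbind"),
            Reaction({"x2": 1}, {"x3": 1}, k2, id="cat"),
        ],
    )


def michaelis_menten_reduced(spec: FixtureSpec) -> PolynomialSystem:
    """The 2-variable system after eliminating x3 and x4 by the invariants.

    Monomials are kept per rate constant (the k_-1 and k2 consumption terms
    of x2 stay separate), matching the tropical equations

        g1 + ge + a1 = min(g1 + a1, g_-1) + a2
        g1 + ge + a1 = min(g1 + a1, min(g_-1, g2)) + a2
    """
    g = spec.parameter_orders
    g1, g_1, g2 = g.get("k1", 0), g.get("k_1", 0), g.get("k2", 0)
    ge = g.get("e", 0)
    eps = spec.epsilon
    k1, k_1, k2 = eps ** g1, eps ** g_1, eps ** g2
    e0 = eps ** ge
    eq1 = [
        Monomial.make(-1, k1 * e0, g1 + ge, {"x1": 1}),
        Monomial.make(+1, k1, g1, {"x1": 1, "x2": 1}),
        Monomial.make(+1, k_1, g_1, {"x2": 1}),
    ]
    eq2 = [
        Monomial.make(+1, k1 * e0, g1 + ge, {"x1": 1}),
        Monomial.make(-1, k1, g1, {"x1": 1, "x2": 1}),
        Monomial.make(-1, k_1, g_1, {"x2": 1}),
        Monomial.make(-1, k2, g2, {"x2": 1}),
    ]
    return PolynomialSystem(
        species=["x1", "x2"],
        equations={"x1": eq1, "x2": eq2},
        epsilon=eps,
        initial_orders={"x1": g.get("s", 0)},
        initial_concentrations={"x1": spec.value("s"), "x2": 0.0},
    )


_REACTANT_PATTERNS: Tuple[Tuple[int, ...], ...] = ((1,), (2,), (1, 1))


def random_network(n_species: int, n_reactions: int,
                   order_range: Tuple[int, int] = (0, 3),
                   seed: int = 0,
                   epsilon: float = 0.1) -> ReactionNetwork:
    """A reproducible random mass-action network.

    Reactant sides are at most bimolecular with stoichiometries in {1, 2};
    every rate constant and initial concentration is an exact power
    ``epsilon**gamma`` with gamma drawn uniformly from ``order_range``
    (inclusive).  The same seed yields byte-identical output.
    """
    if n_species < 1 or n_reactions < 1:
        raise ValueError("need at least one species and one reaction")
    rng = np.random.default_rng(seed)
    species = [f"s{i + 1}" for i in range(n_species)]
    lo, hi = order_range
    reactions = []
    for j in range(n_reactions):
        pattern = _REACTANT_PATTERNS[rng.integers(len(_REACTANT_PATTERNS))]
        chosen = rng.choice(n_species, size=len(pattern),
                            replace=False if len(pattern) <= n_species else True)
        reactants: Dict[str, int] = {}
        for sp, coef in zip(chosen, pattern):
            reactants[species[sp]] = reactants.get(species[sp], 0) + int(coef)
        n_prod = int(rng.integers(1, 3))
        products: Dict[str, int] = {}
        for sp in rng.choice(n_species, size=n_prod, replace=True):
            products[species[sp]] = products.get(species[sp], 0) + 1
        gamma = int(rng.integers(lo, hi + 1))
        reactions.append(Reaction(reactants=reactants, products=products,
                                  rate_constant=epsilon ** gamma,
                                  id=f"r{j + 1}"))
    inits = {s: epsilon ** int(rng.integers(lo, hi + 1)) for s in species}
    return ReactionNetwork(species=species, initial_concentrations=inits,
                           reactions=reactions)
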