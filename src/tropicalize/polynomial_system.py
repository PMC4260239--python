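"""Signed-monomial ODE representation of a mass-action network.

A mass-action network with rate constants ``k_j`` and stoichiometric matrix
``S`` induces the polynomial system

    dx_i/dt = sum_j k_j S_ij x^alpha_j

Every term on a right-hand side is kept as a :class:`Monomial` carrying its
sign, its merged positive magnitude ``|k_j S_ij|``, the integer epsilon-order
``gamma`` of that magnitude, and the exponent vector ``alpha_j``.  Orders
follow the convention that *small* quantities have *large* orders: a quantity
``q`` has order ``round(log q / log epsilon)`` for an ``epsilon`` in (0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .network_io import ReactionNetwork

__all__ = [
    "Monomial",
    "PolynomialSystem",
    "build_odes",
    "parameter_order",
    "monomial_degree",
]


def parameter_order(k: float, epsilon: float) -> int:
    """Integer epsilon-order of a positive quantity.

    Returns ``round(log(k) / log(epsilon))``, rounding exact half-integers
    away from zero.  With ``epsilon=0.1``, ``k=0.001`` has order 3 and
    ``k=2e4`` has order -4.
    """
    if k <= 0:
        raise ValueError(f"parameter_order requires k > 0, got {k!r}")
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie strictly in (0, 1), got {epsilon!r}")
    x = math.log(k) / math.log(epsilon)
    # round half away from zero; documented, centralized tie rule
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class Monomial:
    """One signed term ``sign * magnitude * x^exponents`` of an ODE."""

    sign: int  # +1 or -1
    magnitude: float  # positive merged coefficient |k_j S_ij|
    gamma: int  # epsilon-order of the magnitude
    exponents: Tuple[Tuple[str, int], ...]  # sorted, zero entries removed

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")
        if any(e < 0 for _, e in self.exponents):
            raise ValueError("exponents must be nonnegative")

    @staticmethod
    def make(sign: int, magnitude: float, gamma: int,
             exponents: Mapping[str, int]) -> "Monomial":
        exps = tuple(sorted((s, int(e)) for s, e in exponents.items() if e != 0))
        return Monomial(sign=sign, magnitude=float(magnitude), gamma=int(gamma),
                        exponents=exps)

    @property
    def exponent_map(self) -> Dict[str, int]:
        return dict(self.exponents)

    def key(self) -> Tuple[int, int, Tuple[Tuple[str, int], ...]]:
        """Identity used for merging, grouping and comparison."""
        return (self.sign, self.gamma, self.exponents)

    def render(self) -> str:
        parts = [f"{'+' if self.sign > 0 else '-'}{self.magnitude:g}"]
        for s, e in self.exponents:
            parts.append(s if e == 1 else f"{s}^{e}")
        return "*".join(parts)


def monomial_degree(m: Monomial, a: Mapping[str, int]) -> int:
    """Tropical degree ``mu = gamma + <a, alpha>`` of a monomial at orders ``a``."""
    try:
        return m.gamma + sum(a[s] * e for s, e in m.exponents)
    except KeyError as exc:  # pragma: no cover - message only
        raise KeyError(f"no order assigned to species {exc.args[0]!r}") from exc


@dataclass
class PolynomialSystem:
    """Per-species signed monomial sums plus stoichiometric bookkeeping.

    ``stoichiometric_matrix`` (species x reactions) is present when the system
    was built from a reaction network; systems written down directly (e.g.
    after eliminating species through a conservation law) may leave it None,
    in which case conservation analysis falls back to the species-by-monomial
    coefficient matrix.
    """

    species: List[str]
    equations: Dict[str, List[Monomial]]
    epsilon: float
    stoichiometric_matrix: Optional[np.ndarray] = None
    initial_orders: Optional[Dict[str, int]] = None
    initial_concentrations: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie strictly in (0, 1)")
        missing = [s for s in self.species if s not in self.equations]
        if missing:
            raise ValueError(f"equations missing for species {missing}")

    def inert_species(self) -> List[str]:
        """Species with an empty right-hand side (no monomial at all)."""
        return [s for s in self.species if not self.equations[s]]

    def positive(self, s: str) -> List[Monomial]:
        return [m for m in self.equations[s] if m.sign > 0]

    def negative(self, s: str) -> List[Monomial]:
        return [m for m in self.equations[s] if m.sign < 0]

    def coefficient_matrix(self) -> Tuple[List[Tuple[Tuple[str, int], ...]], np.ndarray]:
        """Species-by-monomial signed coefficient matrix.

        Columns are distinct exponent vectors; the entry for species ``i`` is
        the signed sum of magnitudes of all its monomials with that exponent
        vector.  This matrix determines d/dt of any linear form exactly.
        """
        cols: List[Tuple[Tuple[str, int], ...]] = sorted(
            {m.exponents for eq in self.equations.values() for m in eq}
        )
        idx = {c: j for j, c in enumerate(cols)}
        mat = np.zeros((len(self.species), len(cols)))
        for i, s in enumerate(self.species):
            for m in self.equations[s]:
                mat[i, idx[m.exponents]] += m.sign * m.magnitude
        return cols, mat

    def render(self) -> str:
        lines = []
        for s in self.species:
            rhs = " ".join(m.render() for m in self.equations[s]) or "0"
            lines.append(f"d{s}/dt = {rhs}")
        return "\n".join(lines)


def _merge(terms: Sequence[Monomial]) -> List[Monomial]:
    """Merge monomials with identical (sign, order, exponent vector).

    Terms sharing sign and exponents but of *different* order stay separate:
    each reaction contributes its own monomial to the tropical problem, and
    truncation/pool analysis relies on the individual coefficients.
    """
    merged: Dict[Tuple[int, int, Tuple[Tuple[str, int], ...]], float] = {}
    for m in terms:
        merged[m.key()] = merged.get(m.key(), 0.0) + m.magnitude
    out = [Monomial(sign=k[0], magnitude=v, gamma=k[1], exponents=k[2])
           for k, v in merged.items()]
    out.sort(key=lambda m: (m.exponents, -m.sign, m.gamma))
    return out


def build_odes(network: ReactionNetwork, epsilon: float) -> PolynomialSystem:
    """Assemble the signed-monomial ODE system of a mass-action network.

    Each reaction ``j`` contributes the monomial ``k_j S_ij x^alpha_j`` to
    every species ``i`` with ``S_ij != 0``; gamma is the epsilon-order of the
    term's magnitude ``k_j |S_ij|``.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie strictly in (0, 1)")
    species = list(network.species)
    sp_index = {s: i for i, s in enumerate(species)}
    stoich = np.zeros((len(species), len(network.reactions)), dtype=int)
    raw: Dict[str, List[Monomial]] = {s: [] for s in species}
    for j, rxn in enumerate(network.reactions):
        for s in set(rxn.reactants) | set(rxn.products):
            sij = rxn.products.get(s, 0) - rxn.reactants.get(s, 0)
            stoich[sp_index[s], j] = sij
            if sij == 0:
                continue
            mag = rxn.rate_constant * abs(sij)
            raw[s].append(Monomial.make(
                sign=1 if sij > 0 else -1,
                magnitude=mag,
                gamma=parameter_order(mag, epsilon),
                exponents=rxn.reactants,
            ))
    equations = {s: _merge(raw[s]) for s in species}
    initial_orders = {
        s: parameter_order(c, epsilon)
        for s, c in network.initial_concentrations.items() if c > 0
    }
    return PolynomialSystem(
        species=species,
        equations=equations,
        epsilon=epsilon,
        stoichiometric_matrix=stoich,
        initial_orders=initial_orders or None,
        initial_concentrations=dict(network.initial_concentrations),
    )
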