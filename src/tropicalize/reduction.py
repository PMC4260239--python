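"""Tropically truncated systems, timescales and conserved pools.

At a given equilibration the tropically truncated model keeps, in each
equation, exactly the monomials of minimal epsilon-degree; every dominated
monomial is dropped.  The exponent ``mu_i,min - a_i`` of the rescaled
derivative orders the variables by timescale (smaller exponent = faster).

The truncated dynamics may conserve linear forms that the full dynamics does
not ("pools"): these are slow variables driven by the previously dominated
monomials, and are detected as semi-positive left-kernel vectors of the
truncated species-by-monomial coefficient matrix that fail to annihilate the
full one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Tuple

from .conservation import minimal_semipositive_left_kernel
from .polynomial_system import Monomial, PolynomialSystem, monomial_degree
from .tropical_solver import Equilibration

__all__ = ["TruncatedSystem", "Pool", "truncate", "order_timescales",
           "find_new_pools"]


@dataclass
class Pool:
    """A linear form conserved by the truncated but not the full dynamics.

    ``residual`` holds the signed sum of the dominated monomials weighted by
    the pool coefficients: the slow derivative of the pool variable.
    """

    coefficients: Dict[str, int]
    residual: List[Monomial]

    def render(self) -> str:
        form = " + ".join(f"{c}*{s}" if c != 1 else s
                          for s, c in sorted(self.coefficients.items()))
        rhs = " ".join(m.render() for m in self.residual) or "0"
        return f"d({form})/dt = {rhs}"


@dataclass
class TruncatedSystem:
    base: PolynomialSystem
    orders: Equilibration
    retained: Dict[str, List[Monomial]]
    dropped: Dict[str, List[Monomial]]
    timescale_exponents: Dict[str, int]
    pools: List[Pool] = field(default_factory=list)

    def as_system(self) -> PolynomialSystem:
        """The truncated model as a polynomial system of its own."""
        return PolynomialSystem(
            species=list(self.base.species),
            equations={s: list(ms) for s, ms in self.retained.items()},
            epsilon=self.base.epsilon,
            initial_concentrations=dict(self.base.initial_concentrations),
        )

    def render(self) -> str:
        lines = []
        for s in self.base.species:
            rhs = " ".join(m.render() for m in self.retained.get(s, [])) or "0"
            lines.append(f"d{s}/dt = {rhs}")
        for p in self.pools:
            lines.append(f"pool: {p.render()}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "orders": self.orders.orders,
            "retained": {s: [m.render() for m in ms]
                         for s, ms in self.retained.items()},
            "timescale_exponents": self.timescale_exponents,
            "pools": [{"coefficients": p.coefficients,
                       "residual": [m.render() for m in p.residual]}
                      for p in self.pools],
        }


def truncate(system: PolynomialSystem, eq: Equilibration) -> TruncatedSystem:
    """Keep only the dominant (minimal-degree) monomials of each equation."""
    retained: Dict[str, List[Monomial]] = {}
    dropped: Dict[str, List[Monomial]] = {}
    exponents: Dict[str, int] = {}
    for s in system.species:
        monomials = system.equations[s]
        if not monomials:
            retained[s] = []
            dropped[s] = []
            continue
        needed = {sp for m in monomials for sp, _ in m.exponents}
        if not needed <= set(eq.orders):
            raise KeyError(f"orders do not cover species needed by d{s}/dt")
        degs = [monomial_degree(m, eq.orders) for m in monomials]
        mn = min(degs)
        retained[s] = [m for m, d in zip(monomials, degs) if d == mn]
        dropped[s] = [m for m, d in zip(monomials, degs) if d > mn]
        if s in eq.orders:
            exponents[s] = mn - eq.orders[s]
    trunc = TruncatedSystem(base=system, orders=eq, retained=retained,
                            dropped=dropped, timescale_exponents=exponents)
    trunc.pools = find_new_pools(trunc)
    return trunc


def order_timescales(trunc: TruncatedSystem) -> List[Tuple[str, int]]:
    """Species ordered fastest first by the exponent ``mu_min - a``.

    The rescaled derivative of species ``i`` scales as ``epsilon^(mu_i,min -
    a_i)``; a smaller exponent therefore means a faster variable.  Ties keep
    the system's species order.
    """
    items = [(s, trunc.timescale_exponents[s])
             for s in trunc.base.species if s in trunc.timescale_exponents]
    return sorted(items, key=lambda it: (it[1],
                                         trunc.base.species.index(it[0])))


def _coefficient_matrix(equations: Dict[str, List[Monomial]],
                        species: List[str]):
    """Exact signed species-by-monomial matrix; columns keyed by
    (exponents, gamma) so distinct-order terms stay distinct."""
    cols = sorted({(m.exponents, m.gamma)
                   for eq in equations.values() for m in eq})
    idx = {c: j for j, c in enumerate(cols)}
    mat = [[Fraction(0)] * len(cols) for _ in species]
    for i, s in enumerate(species):
        for m in equations.get(s, []):
            mat[i][idx[(m.exponents, m.gamma)]] += \
                m.sign * Fraction(m.magnitude)
    return cols, mat


def _annihilates(vec: Tuple[int, ...], mat: List[List[Fraction]]) -> bool:
    ncols = len(mat[0]) if mat else 0
    return all(sum(b * row[j] for b, row in zip(vec, mat)) == 0
               for j in range(ncols))


def find_new_pools(trunc: TruncatedSystem) -> List[Pool]:
    """Conserved pools of the truncated dynamics absent from the full one."""
    species = trunc.base.species
    _, tmat = _coefficient_matrix(trunc.retained, species)
    _, fmat = _coefficient_matrix(trunc.base.equations, species)
    if not tmat or not tmat[0]:
        return []
    pools: List[Pool] = []
    for vec in minimal_semipositive_left_kernel(tmat):
        if _annihilates(vec, fmat):
            continue  # already a conservation law of the full system
        coeffs = {s: int(b) for s, b in zip(species, vec) if b}
        residual: Dict[Tuple, Fraction] = {}
        for s, b in coeffs.items():
            for m in trunc.dropped.get(s, []):
                key = (m.exponents, m.gamma)
                residual[key] = residual.get(key, Fraction(0)) \
                    + b * m.sign * Fraction(m.magnitude)
        monos = []
        for (exps, gamma), c in sorted(residual.items()):
            if c == 0:
                continue
            monos.append(Monomial(sign=1 if c > 0 else -1,
                                  magnitude=float(abs(c)), gamma=gamma,
                                  exponents=exps))
        pools.append(Pool(coefficients=coeffs, residual=monos))
    return pools
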