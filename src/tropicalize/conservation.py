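"""Semi-positive conservation laws (P-invariants) and their constant orders.

A conservation law of a reaction network is a semi-positive integer vector
``b`` with ``b^T S = 0``: the linear form ``sum_i b_i x_i`` is constant along
every trajectory.  For systems without reaction structure (e.g. written down
after eliminating species) the same computation runs on the exact
species-by-monomial signed coefficient matrix, whose left kernel likewise
characterises conserved linear forms of the dynamics.

Enumeration uses the classical Farkas / Fourier-Motzkin construction on the
columns of the matrix, which yields every *minimal-support* semi-positive
kernel vector with coprime entries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .polynomial_system import PolynomialSystem, parameter_order

__all__ = ["ConservationLaw", "find_invariants", "attach_constants",
           "minimal_semipositive_left_kernel"]


@dataclass
class ConservationLaw:
    """Coefficients b (nonnegative, gcd 1), conserved constant and its order."""

    coefficients: Dict[str, int]
    constant: Optional[float] = None
    kappa: Optional[int] = None

    def members(self) -> List[str]:
        return [s for s, c in self.coefficients.items() if c > 0]

    def value_at(self, concentrations: Mapping[str, float]) -> float:
        return sum(c * concentrations.get(s, 0.0)
                   for s, c in self.coefficients.items())


def _normalize(vec: Tuple[Fraction, ...]) -> Tuple[int, ...]:
    """Scale a rational vector to coprime integers."""
    denom = math.lcm(*(f.denominator for f in vec)) if vec else 1
    ints = [int(f * denom) for f in vec]
    g = math.gcd(*ints) if any(ints) else 1
    return tuple(v // g for v in ints)


def minimal_semipositive_left_kernel(matrix: Sequence[Sequence[Fraction]],
                                     max_rows: int = 100_000
                                     ) -> List[Tuple[int, ...]]:
    """All minimal-support semi-positive integer vectors b with b^T M = 0.

    ``matrix`` is species-by-columns with exact (Fraction) entries.  The
    Farkas construction starts from the identity paired with the matrix rows
    and eliminates one column at a time, combining rows of opposite residual
    sign with positive coefficients only; ``max_rows`` guards against the
    (exponential) worst case.
    """
    n = len(matrix)
    if n == 0:
        return []
    ncols = len(matrix[0])
    rows: List[Tuple[Tuple[Fraction, ...], Tuple[Fraction, ...]]] = [
        (tuple(Fraction(1) if j == i else Fraction(0) for j in range(n)),
         tuple(Fraction(x) for x in matrix[i]))
        for i in range(n)
    ]
    for c in range(ncols):
        keep = [r for r in rows if r[1][c] == 0]
        pos = [r for r in rows if r[1][c] > 0]
        neg = [r for r in rows if r[1][c] < 0]
        for bp, rp in pos:
            for bn, rn in neg:
                lam, mu = -rn[c], rp[c]  # both positive
                b = tuple(lam * x + mu * y for x, y in zip(bp, bn))
                r = tuple(lam * x + mu * y for x, y in zip(rp, rn))
                keep.append((b, r))
        # prune non-minimal supports early to control growth
        uniq: Dict[Tuple[int, ...], Tuple[Tuple[Fraction, ...], Tuple[Fraction, ...]]] = {}
        for b, r in keep:
            uniq[_normalize(b)] = (b, r)
        items = list(uniq.items())
        supports = [frozenset(i for i, v in enumerate(k) if v) for k, _ in items]
        rows = []
        for i, (k, br) in enumerate(items):
            if any(j != i and supports[j] < supports[i] for j in range(len(items))):
                continue
            rows.append(br)
        if len(rows) > max_rows:
            raise RuntimeError("P-invariant enumeration exceeded row budget")
    result = {_normalize(b) for b, _ in rows}
    result = {v for v in result if any(v)}
    # final minimal-support filter
    out: List[Tuple[int, ...]] = []
    sups = {v: frozenset(i for i, x in enumerate(v) if x) for v in result}
    for v in sorted(result):
        if any(w != v and sups[w] < sups[v] for w in result):
            continue
        out.append(v)
    return out


def find_invariants(system: PolynomialSystem) -> List[Dict[str, int]]:
    """Generating set of minimal-support semi-positive conservation laws.

    Uses the stoichiometric matrix when available, otherwise the exact
    monomial coefficient matrix of the equations.  Returns coefficient
    vectors as species -> positive-integer maps; empty list if the left
    kernel contains no semi-positive vector.
    """
    if system.stoichiometric_matrix is not None:
        mat = [[Fraction(int(x)) for x in row]
               for row in np.asarray(system.stoichiometric_matrix, dtype=int)]
    else:
        _, cmat = system.coefficient_matrix()
        mat = [[Fraction(float(x)) for x in row] for row in cmat]
    if not mat or not mat[0]:
        mat = [[Fraction(0)] for _ in system.species] if system.species else []
    vecs = minimal_semipositive_left_kernel(mat)
    return [
        {s: int(v) for s, v in zip(system.species, vec) if v}
        for vec in vecs
    ]


def attach_constants(laws: Iterable[Mapping[str, int]],
                     initial_concentrations: Mapping[str, float],
                     epsilon: float) -> List[ConservationLaw]:
    """Evaluate each law at the initial condition and attach its order kappa.

    Laws whose initial total is zero have no finite order and are dropped
    with a warning.
    """
    out: List[ConservationLaw] = []
    for law in laws:
        coeffs = {s: int(c) for s, c in law.items() if c}
        total = sum(c * initial_concentrations.get(s, 0.0)
                    for s, c in coeffs.items())
        if total <= 0:
            warnings.warn(
                f"conservation law {coeffs} has zero initial total; dropped")
            continue
        out.append(ConservationLaw(coefficients=coeffs, constant=total,
                                   kappa=parameter_order(total, epsilon)))
    return out
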