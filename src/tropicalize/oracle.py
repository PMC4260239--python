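"""Brute-force grid enumeration of tropical equilibrations.

Independent reference route used to cross-check the constraint solver: every
integer point of the box ``[-D, D]^n`` is tested directly against the
equilibration condition (minimal positive degree equals minimal negative
degree per constrained equation) and the conservation-law condition
(minimal member degree equals kappa), vectorised with numpy.  It shares no
code with the propagation/search path.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Set

import numpy as np

from .conservation import ConservationLaw
from .polynomial_system import PolynomialSystem, parameter_order

__all__ = ["brute_force_orders"]


def brute_force_orders(system: PolynomialSystem,
                       laws: Sequence[ConservationLaw] = (),
                       domain: int = 6,
                       min_count: int = 2,
                       require: Optional[Sequence[str]] = None,
                       ) -> List[Dict[str, int]]:
    """All order vectors in ``[-domain, domain]^n`` satisfying the tropical
    equilibration and conservation constraints, by exhaustive scan."""
    candidates = [s for s in system.species
                  if any(m.sign > 0 for m in system.equations[s])
                  and any(m.sign < 0 for m in system.equations[s])]
    constrained = [s for s in candidates
                   if require is None or s in set(require)]
    referenced: Set[str] = set()
    for s in constrained:
        for m in system.equations[s]:
            referenced.update(sp for sp, _ in m.exponents)
    for law in laws:
        referenced.update(law.members())
    variables = [s for s in system.species if s in referenced]
    if not constrained:
        return []
    vidx = {s: i for i, s in enumerate(variables)}

    grid = np.array(list(itertools.product(
        range(-domain, domain + 1), repeat=len(variables))), dtype=int)
    if grid.size == 0:
        grid = np.zeros((1, 0), dtype=int)

    feasible = np.ones(len(grid), dtype=bool)
    for s in constrained:
        eq = system.equations[s]
        exps = np.array([[dict(m.exponents).get(v, 0) for v in variables]
                         for m in eq], dtype=int)
        gammas = np.array([m.gamma for m in eq], dtype=int)
        degs = grid @ exps.T + gammas  # points x monomials
        signs = np.array([m.sign for m in eq])
        pos_min = degs[:, signs > 0].min(axis=1)
        neg_min = degs[:, signs < 0].min(axis=1)
        feasible &= pos_min == neg_min
        overall = np.minimum(pos_min, neg_min)
        count = (degs == overall[:, None]).sum(axis=1)
        feasible &= count >= min_count
    for law in laws:
        members = law.members()
        cols = np.array([[1 if v == s else 0 for v in variables]
                         for s in members], dtype=int)
        gammas = np.array([parameter_order(law.coefficients[s], system.epsilon)
                           for s in members], dtype=int)
        degs = grid @ cols.T + gammas
        feasible &= degs.min(axis=1) == law.kappa
    return [dict(zip(variables, map(int, point))) for point in grid[feasible]]
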