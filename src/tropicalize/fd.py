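"""A small finite-domain constraint engine with reified constraints.

The tropical equilibration problem needs only a narrow constraint language:
integer variables with interval domains, affine forms over them, ``form <=
form`` inequalities, reified equality indicators ``b <=> (form == form)``,
and cardinality sums over indicators.  This module implements exactly that,
with bounds-consistent propagation to a fixpoint and complete enumeration by
dichotomic search (domain bisection) over a designated list of decision
variables.  Propagation is sound (never discards a solution); completeness
comes from the search, with an exact feasibility check at every leaf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

__all__ = ["Var", "Affine", "Store", "Constraint", "LessEq", "ReifiedEq",
           "SumGE", "SumEq", "Engine", "Infeasible"]


class Infeasible(Exception):
    """Raised internally when a domain becomes empty."""


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Affine:
    """``const + sum(coeff_i * var_i)`` with integer coefficients."""

    const: int = 0
    terms: Tuple[Tuple[Var, int], ...] = ()

    @staticmethod
    def of(const: int = 0, **_ignored) -> "Affine":
        return Affine(const=const)

    @staticmethod
    def from_terms(const: int, terms: Dict[Var, int]) -> "Affine":
        return Affine(const=int(const),
                      terms=tuple(sorted(((v, int(c)) for v, c in terms.items()
                                          if c != 0), key=lambda t: t[0].name)))

    def __sub__(self, other: "Affine") -> "Affine":
        terms: Dict[Var, int] = {}
        for v, c in self.terms:
            terms[v] = terms.get(v, 0) + c
        for v, c in other.terms:
            terms[v] = terms.get(v, 0) - c
        return Affine.from_terms(self.const - other.const, terms)

    def bounds(self, store: "Store") -> Tuple[int, int]:
        lo = hi = self.const
        for v, c in self.terms:
            vlo, vhi = store.dom[v]
            if c > 0:
                lo += c * vlo
                hi += c * vhi
            else:
                lo += c * vhi
                hi += c * vlo
        return lo, hi

    def value(self, store: "Store") -> Optional[int]:
        lo, hi = self.bounds(store)
        return lo if lo == hi else None

    def eval(self, assignment: Dict[Var, int]) -> int:
        return self.const + sum(c * assignment[v] for v, c in self.terms)


class Store:
    """Interval domains for all variables; cheap to copy for search."""

    def __init__(self, dom: Dict[Var, Tuple[int, int]]):
        self.dom = dom

    def copy(self) -> "Store":
        return Store(dict(self.dom))

    def set_min(self, v: Var, lo: int) -> bool:
        clo, chi = self.dom[v]
        if lo <= clo:
            return False
        if lo > chi:
            raise Infeasible
        self.dom[v] = (lo, chi)
        return True

    def set_max(self, v: Var, hi: int) -> bool:
        clo, chi = self.dom[v]
        if hi >= chi:
            return False
        if hi < clo:
            raise Infeasible
        self.dom[v] = (clo, hi)
        return True

    def fix(self, v: Var, value: int) -> bool:
        a = self.set_min(v, value)
        b = self.set_max(v, value)
        return a or b

    def is_fixed(self, v: Var) -> bool:
        lo, hi = self.dom[v]
        return lo == hi


class Constraint:
    def propagate(self, store: Store) -> bool:
        """Tighten domains; return True if anything changed."""
        raise NotImplementedError


@dataclass
class LessEq(Constraint):
    """``lhs <= rhs`` for affine forms, with bounds propagation both ways."""

    lhs: Affine
    rhs: Affine

    def __post_init__(self) -> None:
        self.diff = self.rhs - self.lhs  # require diff >= 0

    def propagate(self, store: Store) -> bool:
        changed = False
        lo, hi = self.diff.bounds(store)
        if hi < 0:
            raise Infeasible
        if lo >= 0:
            return False
        # for each term, bound the variable so diff can still reach >= 0
        for v, c in self.diff.terms:
            vlo, vhi = store.dom[v]
            rest_hi = hi - (c * vhi if c > 0 else c * vlo)
            if c > 0:
                # c*v >= -rest_hi  =>  v >= ceil(-rest_hi / c)
                changed |= store.set_min(v, math.ceil(-rest_hi / c))
            else:
                # c*v >= -rest_hi with c < 0  =>  v <= rest_hi / (-c)
                changed |= store.set_max(v, math.floor(rest_hi / (-c)))
        return changed


@dataclass
class ReifiedEq(Constraint):
    """``b = 1  <=>  lhs == rhs`` with a 0/1 indicator variable ``b``."""

    b: Var
    lhs: Affine
    rhs: Affine

    def __post_init__(self) -> None:
        self.diff = self.lhs - self.rhs
        self._eq = [LessEq(self.lhs, self.rhs), LessEq(self.rhs, self.lhs)]

    def propagate(self, store: Store) -> bool:
        blo, bhi = store.dom[self.b]
        dlo, dhi = self.diff.bounds(store)
        changed = False
        if dlo > 0 or dhi < 0:  # disequality certain
            changed |= store.set_max(self.b, 0)
            return changed
        if dlo == 0 and dhi == 0:  # equality certain
            changed |= store.set_min(self.b, 1)
            return changed
        if blo == 1:
            for c in self._eq:
                changed |= c.propagate(store)
        elif bhi == 0 and (dlo == 0 or dhi == 0):
            # forbid the single boundary value making diff == 0
            for v, c in self.diff.terms:
                if all(store.is_fixed(w) for w, _ in self.diff.terms if w != v):
                    rest = self.diff.const + sum(
                        cc * store.dom[w][0] for w, cc in self.diff.terms
                        if w != v)
                    # need c*v + rest != 0
                    if rest % c == 0:
                        bad = -rest // c
                        vlo, vhi = store.dom[v]
                        if vlo == bad:
                            changed |= store.set_min(v, bad + 1)
                        elif vhi == bad:
                            changed |= store.set_max(v, bad - 1)
        return changed


@dataclass
class SumGE(Constraint):
    """``sum(bools) >= k``."""

    bools: Tuple[Var, ...]
    k: int

    def propagate(self, store: Store) -> bool:
        hi_sum = sum(store.dom[b][1] for b in self.bools)
        if hi_sum < self.k:
            raise Infeasible
        changed = False
        if hi_sum == self.k:
            for b in self.bools:
                if store.dom[b][1] == 1:
                    changed |= store.set_min(b, 1)
        return changed


@dataclass
class SumEq(Constraint):
    """``sum(bools) == total`` for an integer variable ``total``."""

    bools: Tuple[Var, ...]
    total: Var

    def propagate(self, store: Store) -> bool:
        lo = sum(store.dom[b][0] for b in self.bools)
        hi = sum(store.dom[b][1] for b in self.bools)
        changed = store.set_min(self.total, lo)
        changed |= store.set_max(self.total, hi)
        tlo, thi = store.dom[self.total]
        if hi == tlo:
            for b in self.bools:
                if store.dom[b][1] == 1:
                    changed |= store.set_min(b, 1)
        if lo == thi:
            for b in self.bools:
                if store.dom[b][0] == 0:
                    changed |= store.set_max(b, 0)
        return changed


@dataclass
class Engine:
    """Propagation to fixpoint plus dichotomic (bisection) search."""

    constraints: List[Constraint] = field(default_factory=list)

    def propagate(self, store: Store) -> bool:
        """Run all propagators to a fixpoint; False if infeasible."""
        try:
            changed = True
            while changed:
                changed = False
                for c in self.constraints:
                    changed |= c.propagate(store)
        except Infeasible:
            return False
        return True

    def solve(self, store: Store, decision_vars: Sequence[Var],
              on_solution: Callable[[Dict[Var, int]], bool]) -> None:
        """Enumerate all assignments of ``decision_vars``.

        ``on_solution`` receives each leaf assignment that survives
        propagation and must return True to continue the search.  Domains are
        bisected at their midpoint (dichotomic search), without a
        variable-selection heuristic.
        """
        self._search(store, list(decision_vars), on_solution)

    def _search(self, store: Store, dvars: List[Var],
                on_solution: Callable[[Dict[Var, int]], bool]) -> bool:
        if not self.propagate(store):
            return True
        branch_var = next((v for v in dvars if not store.is_fixed(v)), None)
        if branch_var is None:
            assignment = {v: store.dom[v][0] for v in dvars}
            return on_solution(assignment)
        lo, hi = store.dom[branch_var]
        mid = (lo + hi) // 2
        left = store.copy()
        left.dom[branch_var] = (lo, mid)
        if not self._search(left, dvars, on_solution):
            return False
        right = store.copy()
        right.dom[branch_var] = (mid + 1, hi)
        return self._search(right, dvars, on_solution)
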