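"""Reading reaction networks from SBML and a plain-text reaction format.

Only purely polynomial (mass-action-like) kinetics are accepted: a kinetic
law must expand, after numeric substitution of parameters, compartments and
boundary species, into a polynomial in the dynamic species with real
coefficients.  Anything else (rational Michaelis-Menten rates, exponentials,
piecewise laws, SBML rules) raises :class:`NonPolynomialKineticsError`.

The plain-text format, one reaction per line::

    # comment
    init: S = 1.0
    S + E -> ES ; k=1.0
    ES -> S + E ; k=0.1
    2 A -> B    ; k=0.5
"""

from __future__ import annotations

import math
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import sympy

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ReactionSyntaxError",
    "SBMLParseError",
    "NonPolynomialKineticsError",
    "parse_reaction_text",
    "render_reaction_text",
    "parse_sbml",
]


class ReactionSyntaxError(ValueError):
    """Malformed plain-text reaction input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class SBMLParseError(ValueError):
    """The file is not a well-formed SBML level 2/3 document."""


class NonPolynomialKineticsError(ValueError):
    """A kinetic law is not expandable to a polynomial in the species."""

    def __init__(self, reaction_id: str, message: str = ""):
        detail = f": {message}" if message else ""
        super().__init__(
            f"reaction {reaction_id!r} has non-polynomial kinetics{detail}")
        self.reaction_id = reaction_id


@dataclass
class Reaction:
    reactants: Dict[str, int]
    products: Dict[str, int]
    rate_constant: float
    id: Optional[str] = None

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for s, c in side.items():
                if c < 0 or int(c) != c:
                    raise ValueError(
                        f"stoichiometric coefficient of {s} must be a "
                        f"nonnegative integer, got {c!r}")
        if self.rate_constant <= 0:
            raise ValueError("rate constant must be positive")


@dataclass
class ReactionNetwork:
    species: List[str]
    initial_concentrations: Dict[str, float] = field(default_factory=dict)
    reactions: List[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.species)
        for rxn in self.reactions:
            referenced = set(rxn.reactants) | set(rxn.products)
            missing = referenced - known
            if missing:
                raise ValueError(
                    f"reaction references unknown species {sorted(missing)}")
        for s, c in self.initial_concentrations.items():
            if c < 0:
                raise ValueError(f"negative initial concentration for {s}")


_SIDE_TERM = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_]*)\s*$")


def _parse_side(text: str, lineno: int) -> Dict[str, int]:
    side: Dict[str, int] = {}
    text = text.strip()
    if not text:  # empty side: pure production or degradation
        return side
    for term in text.split("+"):
        m = _SIDE_TERM.match(term)
        if not m:
            raise ReactionSyntaxError(f"cannot parse species term {term.strip()!r}",
                                      lineno)
        coef = int(m.group(1)) if m.group(1) else 1
        side[m.group(2)] = side.get(m.group(2), 0) + coef
    return side


def parse_reaction_text(text: str) -> ReactionNetwork:
    """Parse the plain-text reaction format into a :class:`ReactionNetwork`.

    Duplicate species on one side accumulate; ``init:`` lines set initial
    concentrations; ``#`` starts a comment.  Zero-rate reactions are dropped
    with a warning, negative rate constants are an error.
    """
    species: List[str] = []
    seen = set()
    inits: Dict[str, float] = {}
    reactions: List[Reaction] = []

    def note(name: str) -> None:
        if name not in seen:
            seen.add(name)
            species.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("init:"):
            body = line[len("init:"):].strip()
            m = re.match(r"^([A-Za-z_][A-Za-z0-9_]*)\s*=\s*([-+0-9.eE]+)$", body)
            if not m:
                raise ReactionSyntaxError(f"cannot parse init line {body!r}", lineno)
            note(m.group(1))
            inits[m.group(1)] = float(m.group(2))
            continue
        if ";" not in line or "->" not in line:
            raise ReactionSyntaxError("expected 'LHS -> RHS ; k=VALUE'", lineno)
        eqn, rate = line.rsplit(";", 1)
        m = re.match(r"^\s*k\s*=\s*([-+0-9.eE]+)\s*$", rate)
        if not m:
            raise ReactionSyntaxError(f"cannot parse rate {rate.strip()!r}", lineno)
        k = float(m.group(1))
        lhs, rhs = eqn.split("->", 1)
        reactants = _parse_side(lhs, lineno)
        products = _parse_side(rhs, lineno)
        for s in list(reactants) + list(products):
            note(s)
        if k < 0:
            raise ReactionSyntaxError(f"nonpositive rate constant {k}", lineno)
        if k == 0:
            warnings.warn(f"line {lineno}: zero-rate reaction dropped")
            continue
        reactions.append(Reaction(reactants=reactants, products=products,
                                  rate_constant=k, id=f"r{len(reactions) + 1}"))
    return ReactionNetwork(species=species, initial_concentrations=inits,
                           reactions=reactions)


def render_reaction_text(network: ReactionNetwork) -> str:
    """Render a network back to the plain-text format (round-trip safe)."""

    def side(st: Dict[str, int]) -> str:
        return " + ".join(
            (f"{c} {s}" if c != 1 else s) for s, c in sorted(st.items()))

    lines = [f"init: {s} = {network.initial_concentrations[s]!r}"
             for s in network.species if s in network.initial_concentrations]
    for rxn in network.reactions:
        lines.append(f"{side(rxn.reactants)} -> {side(rxn.products)} ; "
                     f"k={rxn.rate_constant!r}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# SBML reading (level 2 / level 3, mass-action / polynomial kinetics only)
# --------------------------------------------------------------------------

_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _children(el: ET.Element) -> List[ET.Element]:
    return list(el)


class _MathError(ValueError):
    pass


def _mathml_to_sympy(el: ET.Element, symbols: Dict[str, sympy.Symbol],
                     functions: Dict[str, "tuple"]) -> sympy.Expr:
    """Translate the polynomial-friendly MathML subset to a sympy expression."""
    tag = _local(el.tag)
    if tag == "math":
        kids = _children(el)
        if len(kids) != 1:
            raise _MathError("expected a single expression under <math>")
        return _mathml_to_sympy(kids[0], symbols, functions)
    if tag == "cn":
        txt = (el.text or "").strip()
        ctype = el.get("type", "real")
        kids = _children(el)
        if ctype in ("e-notation", "rational") and kids:
            sep_tail = (kids[0].tail or "").strip()
            if ctype == "e-notation":
                return sympy.Float(float(txt) * 10.0 ** float(sep_tail))
            return sympy.Rational(int(txt), int(sep_tail))
        if ctype == "integer":
            return sympy.Integer(int(txt))
        return sympy.Float(float(txt))
    if tag == "ci":
        name = (el.text or "").strip()
        return symbols.setdefault(name, sympy.Symbol(name))
    if tag == "csymbol":
        raise _MathError(f"unsupported csymbol {el.text!r}")
    if tag == "apply":
        kids = _children(el)
        op, args = kids[0], kids[1:]
        op_tag = _local(op.tag)
        if op_tag == "ci":  # call of a functionDefinition
            fname = (op.text or "").strip()
            if fname not in functions:
                raise _MathError(f"call of unknown function {fname!r}")
            bvars, body = functions[fname]
            if len(bvars) != len(args):
                raise _MathError(f"arity mismatch calling {fname!r}")
            vals = [_mathml_to_sympy(a, symbols, functions) for a in args]
            return body.xreplace(dict(zip(bvars, vals)))
        vals = [_mathml_to_sympy(a, symbols, functions) for a in args]
        if op_tag == "plus":
            return sympy.Add(*vals) if vals else sympy.Integer(0)
        if op_tag == "times":
            return sympy.Mul(*vals) if vals else sympy.Integer(1)
        if op_tag == "minus":
            if len(vals) == 1:
                return -vals[0]
            if len(vals) == 2:
                return vals[0] - vals[1]
            raise _MathError("minus takes 1 or 2 arguments")
        if op_tag == "divide":
            if len(vals) != 2:
                raise _MathError("divide takes 2 arguments")
            return vals[0] / vals[1]
        if op_tag == "power":
            if len(vals) != 2:
                raise _MathError("power takes 2 arguments")
            return vals[0] ** vals[1]
        if op_tag == "root":
            raise _MathError("root is not polynomial")
        raise _MathError(f"unsupported operator <{op_tag}>")
    if tag == "lambda":
        raise _MathError("unexpected bare lambda")
    raise _MathError(f"unsupported MathML element <{tag}>")


def _find(el: ET.Element, name: str) -> Optional[ET.Element]:
    for child in el.iter():
        if _local(child.tag) == name:
            return child
    return None


def _findall(parent: Optional[ET.Element], name: str) -> List[ET.Element]:
    if parent is None:
        return []
    return [c for c in parent.iter() if _local(c.tag) == name]


def parse_sbml(path: str) -> ReactionNetwork:
    """Read an SBML level 2/3 model with purely polynomial kinetics.

    Every kinetic law is expanded, with all parameters, compartment sizes and
    boundary/constant species substituted by their numeric values, into a
    polynomial in the dynamic species; each polynomial term then becomes one
    effective mass-action reaction.  Models with rules, or with any law that
    does not expand to such a polynomial, are rejected with
    :class:`NonPolynomialKineticsError`.  Events are ignored.
    """
    try:
        tree = ET.parse(path)
    except FileNotFoundError:
        raise
    except ET.ParseError as exc:
        raise SBMLParseError(f"malformed SBML in {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLParseError(f"{path} is not an SBML document")
    model = next((c for c in root if _local(c.tag) == "model"), None)
    if model is None:
        raise SBMLParseError(f"{path} contains no <model>")

    def section(name: str) -> Optional[ET.Element]:
        return next((c for c in model if _local(c.tag) == name), None)

    rules = _findall(section("listOfRules"), "assignmentRule") \
        + _findall(section("listOfRules"), "rateRule") \
        + _findall(section("listOfRules"), "algebraicRule")
    if rules:
        raise NonPolynomialKineticsError(
            "<listOfRules>", "SBML rules make kinetics non-polynomial")

    compartments: Dict[str, float] = {}
    for c in _findall(section("listOfCompartments"), "compartment"):
        size = c.get("size", c.get("volume"))
        compartments[c.get("id")] = float(size) if size is not None else 1.0

    globals_: Dict[str, float] = {}
    for p in _findall(section("listOfParameters"), "parameter"):
        if p.get("value") is not None:
            globals_[p.get("id")] = float(p.get("value"))

    functions: Dict[str, tuple] = {}
    for f in _findall(section("listOfFunctionDefinitions"), "functionDefinition"):
        lam = _find(f, "lambda")
        if lam is None:
            continue
        kids = _children(lam)
        bvars = []
        for bv in kids[:-1]:
            if _local(bv.tag) != "bvar":
                raise SBMLParseError("malformed functionDefinition lambda")
            bvars.append(sympy.Symbol((_children(bv)[0].text or "").strip()))
        syms = {str(b): b for b in bvars}
        body = _mathml_to_sympy(kids[-1], syms, functions)
        functions[f.get("id")] = (bvars, body)

    species_order: List[str] = []
    dynamic: List[str] = []
    fixed_values: Dict[str, float] = {}
    inits: Dict[str, float] = {}
    for sp in _findall(section("listOfSpecies"), "species"):
        sid = sp.get("id")
        species_order.append(sid)
        comp = sp.get("compartment")
        size = compartments.get(comp, 1.0)
        if sp.get("initialConcentration") is not None:
            value = float(sp.get("initialConcentration"))
        elif sp.get("initialAmount") is not None:
            value = float(sp.get("initialAmount")) / (size if size else 1.0)
        else:
            value = 0.0
        boundary = sp.get("boundaryCondition") in ("true", "1")
        constant = sp.get("constant") in ("true", "1")
        if boundary or constant:
            # no ODE to equilibrate: folded into rate constants
            fixed_values[sid] = value
        else:
            dynamic.append(sid)
            inits[sid] = value

    # initialAssignments may override parameter or species values
    for ia in _findall(section("listOfInitialAssignments"), "initialAssignment"):
        target = ia.get("symbol")
        math_el = _find(ia, "math")
        if math_el is None:
            continue
        syms: Dict[str, sympy.Symbol] = {}
        try:
            expr = _mathml_to_sympy(math_el, syms, functions)
        except _MathError as exc:
            raise SBMLParseError(f"cannot evaluate initialAssignment for "
                                 f"{target}: {exc}") from exc
        subs = {sympy.Symbol(k): v for k, v in
                {**globals_, **compartments, **fixed_values, **inits}.items()}
        value = expr.xreplace(subs)
        if not value.is_number:
            raise SBMLParseError(
                f"initialAssignment for {target} is not numeric")
        value = float(value)
        if target in globals_ or target not in set(species_order):
            globals_[target] = value
        elif target in fixed_values:
            fixed_values[target] = value
        else:
            inits[target] = value

    dyn_syms = {s: sympy.Symbol(s) for s in dynamic}
    reactions: List[Reaction] = []
    for j, rxn in enumerate(_findall(section("listOfReactions"), "reaction")):
        rid = rxn.get("id") or f"reaction{j + 1}"

        def stoich_side(tag: str) -> Dict[str, int]:
            out: Dict[str, int] = {}
            sec = next((c for c in rxn if _local(c.tag) == tag), None)
            for ref in _findall(sec, "speciesReference"):
                sto = float(ref.get("stoichiometry", "1"))
                if sto != int(sto):
                    raise NonPolynomialKineticsError(
                        rid, f"non-integer stoichiometry {sto}")
                sid = ref.get("species")
                out[sid] = out.get(sid, 0) + int(sto)
            return out

        alpha = stoich_side("listOfReactants")
        beta = stoich_side("listOfProducts")
        klaw = next((c for c in rxn if _local(c.tag) == "kineticLaw"), None)
        if klaw is None:
            raise NonPolynomialKineticsError(rid, "missing kinetic law")
        locals_: Dict[str, float] = {}
        for p in _findall(klaw, "parameter") + _findall(klaw, "localParameter"):
            if p.get("value") is not None:
                locals_[p.get("id")] = float(p.get("value"))
        math_el = next((c for c in klaw if _local(c.tag) == "math"), None)
        if math_el is None:
            raise NonPolynomialKineticsError(rid, "missing <math>")
        syms: Dict[str, sympy.Symbol] = dict(dyn_syms)
        try:
            expr = _mathml_to_sympy(math_el, syms, functions)
        except _MathError as exc:
            raise NonPolynomialKineticsError(rid, str(exc)) from exc
        numeric = {**globals_, **compartments, **fixed_values, **locals_}
        expr = expr.xreplace({sympy.Symbol(k): sympy.Float(v)
                              for k, v in numeric.items()})
        expr = sympy.expand(sympy.together(expr))
        free = expr.free_symbols - set(dyn_syms.values())
        if free:
            raise NonPolynomialKineticsError(
                rid, f"unresolved symbols {sorted(map(str, free))}")
        try:
            poly = sympy.Poly(expr, *dyn_syms.values()) if dyn_syms else None
        except sympy.PolynomialError as exc:
            raise NonPolynomialKineticsError(rid, str(exc)) from exc
        net = {s: beta.get(s, 0) - alpha.get(s, 0)
               for s in set(alpha) | set(beta) if s in dyn_syms}
        terms = (poly.terms() if poly is not None
                 else ([(tuple(), expr)] if expr.is_number else None))
        if terms is None:
            raise NonPolynomialKineticsError(rid, "law is not polynomial")
        dyn_list = list(dyn_syms)
        for t, (monom, coeff) in enumerate(terms):
            c = complex(coeff)
            if abs(c.imag) > 0:
                raise NonPolynomialKineticsError(rid, "complex coefficient")
            c = c.real
            if c == 0:
                continue
            exps = {dyn_list[i]: int(e) for i, e in enumerate(monom) if e}
            sgn = 1 if c > 0 else -1
            term_alpha = dict(exps)
            term_beta = {}
            for s, d in net.items():
                b = term_alpha.get(s, 0) + sgn * d
                if b < 0:
                    raise NonPolynomialKineticsError(
                        rid, f"term {t} consumes {s} without it appearing "
                             f"in the rate")
                if b:
                    term_beta[s] = b
            k = abs(c)
            if math.isclose(k, 0.0):
                continue
            reactions.append(Reaction(reactants=term_alpha, products=term_beta,
                                      rate_constant=k,
                                      id=rid if len(terms) == 1 else f"{rid}.{t}"))

    return ReactionNetwork(species=dynamic,
                           initial_concentrations=inits,
                           reactions=reactions)
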