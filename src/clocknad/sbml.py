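"""SBML Level 3 export/import of the model.

The document carries the 11 species (with the fixture's initial amounts),
the full parameter table, and the 45 labeled reactions of
:mod:`clocknad.reactions` with their kinetic laws as content MathML.  The
writer is self-contained (lxml + sympy's MathML printer); the reader
extracts parameter values and species initial amounts, which is sufficient
to reconstitute a model configuration from an exported file.
"""

from __future__ import annotations

from lxml import etree
import sympy

from .parameters import (
    PARAM_NAMES,
    STATE_NAMES,
    ModelParameters,
    ModelState,
    NamedFixture,
)
from .reactions import REACTIONS, rate_expression

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _content_mathml(expr: sympy.Expr, parent: etree._Element) -> None:
    """Serialize a rational expression as content MathML (the subset SBML
    kinetic laws use: ci/cn, plus, times, divide, power, minus)."""
    q = "{%s}" % MATHML_NS

    def op(name, args):
        apply_el = etree.SubElement(parent_stack[-1], q + "apply")
        etree.SubElement(apply_el, q + name)
        parent_stack.append(apply_el)
        for a in args:
            walk(a)
        parent_stack.pop()

    def walk(e):
        if isinstance(e, sympy.Symbol):
            el = etree.SubElement(parent_stack[-1], q + "ci")
            el.text = str(e)
        elif isinstance(e, sympy.Integer):
            el = etree.SubElement(parent_stack[-1], q + "cn")
            el.set("type", "integer")
            el.text = str(int(e))
        elif isinstance(e, sympy.Rational):
            op("divide", (sympy.Integer(e.p), sympy.Integer(e.q)))
        elif isinstance(e, sympy.Float):
            el = etree.SubElement(parent_stack[-1], q + "cn")
            el.text = repr(float(e))
        elif isinstance(e, sympy.Add):
            op("plus", e.args)
        elif isinstance(e, sympy.Mul):
            num, den = e.as_numer_denom()
            if den != 1:
                op("divide", (num, den))
            else:
                op("times", e.args)
        elif isinstance(e, sympy.Pow):
            base, exponent = e.args
            if exponent == -1:
                op("divide", (sympy.Integer(1), base))
            elif exponent.is_negative:
                op("divide", (sympy.Integer(1), base ** (-exponent)))
            else:
                op("power", (base, exponent))
        else:  # pragma: no cover - the rate laws only use the forms above
            raise TypeError(f"cannot serialize {type(e).__name__} to MathML")

    parent_stack = [parent]
    walk(expr)


def _kinetic_law_mathml(expr: sympy.Expr) -> etree._Element:
    math = etree.Element("{%s}math" % MATHML_NS, nsmap={None: MATHML_NS})
    _content_mathml(expr, math)
    return math


def export_sbml(fixture: NamedFixture, path) -> None:
    """Write the model configuration as an SBML L3V1 document.

    One species per state variable, one (global) parameter per rate or
    binding constant, and one reaction per labeled process with its kinetic
    law.  Quantities are in arbitrary units, so no unit definitions are
    emitted.
    """
    nsmap = {None: SBML_NS}
    sbml = etree.Element("sbml", nsmap=nsmap, level="3", version="1")
    model = etree.SubElement(sbml, "model", id=f"clocknad_{fixture.name}",
                             name=f"clock/NAD model ({fixture.name})")

    compartments = etree.SubElement(model, "listOfCompartments")
    etree.SubElement(compartments, "compartment", id="cell", constant="true",
                     spatialDimensions="3", size="1")

    species_el = etree.SubElement(model, "listOfSpecies")
    for name in STATE_NAMES:
        etree.SubElement(
            species_el, "species", id=name, compartment="cell",
            initialAmount=repr(float(getattr(fixture.initial_state, name))),
            hasOnlySubstanceUnits="true", boundaryCondition="false",
            constant="false")

    params_el = etree.SubElement(model, "listOfParameters")
    for name in PARAM_NAMES:
        etree.SubElement(params_el, "parameter", id=name,
                         value=repr(float(getattr(fixture.parameters, name))),
                         constant="true")

    reactions_el = etree.SubElement(model, "listOfReactions")
    for reaction in REACTIONS:
        r_el = etree.SubElement(reactions_el, "reaction", id=reaction.label,
                                name=reaction.description, reversible="false")
        consumed = {s: -c for s, c in reaction.stoichiometry.items() if c < 0}
        produced = {s: c for s, c in reaction.stoichiometry.items() if c > 0}
        if consumed:
            lo = etree.SubElement(r_el, "listOfReactants")
            for s, c in consumed.items():
                etree.SubElement(lo, "speciesReference", species=s,
                                 stoichiometry=repr(float(c)), constant="true")
        if produced:
            lo = etree.SubElement(r_el, "listOfProducts")
            for s, c in produced.items():
                etree.SubElement(lo, "speciesReference", species=s,
                                 stoichiometry=repr(float(c)), constant="true")
        expr = rate_expression(reaction)
        modifiers = sorted(
            str(sym) for sym in expr.free_symbols
            if str(sym) in STATE_NAMES and str(sym) not in reaction.stoichiometry)
        if modifiers:
            lo = etree.SubElement(r_el, "listOfModifiers")
            for s in modifiers:
                etree.SubElement(lo, "modifierSpeciesReference", species=s)
        law = etree.SubElement(r_el, "kineticLaw")
        law.append(_kinetic_law_mathml(expr))

    tree = etree.ElementTree(sbml)
    tree.write(path, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def import_sbml(path) -> NamedFixture:
    """Read back a document written by :func:`export_sbml`.

    Returns a :class:`NamedFixture` with the parameter values and species
    initial amounts found in the file.
    """
    tree = etree.parse(path)
    root = tree.getroot()
    ns = {"s": SBML_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise ValueError("not an SBML document: no <model> element")
    name = (model.get("id") or "imported").removeprefix("clocknad_")

    params = {}
    for el in model.findall("s:listOfParameters/s:parameter", ns):
        params[el.get("id")] = float(el.get("value"))
    unknown = set(params) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameters in SBML file: {sorted(unknown)}")

    state = {}
    for el in model.findall("s:listOfSpecies/s:species", ns):
        state[el.get("id")] = float(el.get("initialAmount"))
    unknown = set(state) - set(STATE_NAMES)
    if unknown:
        raise ValueError(f"unknown species in SBML file: {sorted(unknown)}")

    return NamedFixture(name=name,
                        parameters=ModelParameters.from_mapping(params),
                        initial_state=ModelState(**state))
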