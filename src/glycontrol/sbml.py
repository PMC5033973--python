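"""SBML subset reader/writer (Level 3 Version 2 core, via lxml).

The writer emits a self-contained SBML document: one compartment, all
species with initial concentrations and boundary flags, and one reaction
element per model reaction whose kinetic law carries

* the rate expression as content MathML (species as ``<ci>`` symbols,
  kinetic constants substituted numerically), and
* a package annotation (namespace ``https://glycontrol.dev/sbml``) holding
  the rate-law family and its named constants, so a glycontrol model
  round-trips exactly.

The reader reconstructs models from the annotation when present; kinetic
laws without one are imported as *opaque* rate laws -- their content
MathML is parsed to a sympy expression and evaluated verbatim.  Documents
are checked structurally (unique ids, resolvable species references,
well-formed math) rather than against the XML schema.
"""

from __future__ import annotations

import json
import re
from typing import Mapping

import sympy as sp
from lxml import etree

from .errors import SBMLError
from .network import ModelDefinition, Reaction
from .rate_laws import FAMILIES, InhibitionMechanism, ReactionKinetics
from .symbolic import rate_expression

__all__ = ["read_sbml", "write_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
SBML_L2_NS_RE = re.compile(r"http://www\.sbml\.org/sbml/level2(/version\d+)?")
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
GLYC_NS = "https://glycontrol.dev/sbml"

_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _check_sid(name: str) -> str:
    if not _SID_RE.match(name):
        raise SBMLError(f"{name!r} is not a valid SBML identifier")
    return name


# ---------------------------------------------------------------------------
# Opaque kinetic laws (imported MathML without a glycontrol annotation)
# ---------------------------------------------------------------------------

def _eval_opaque(state: Mapping[str, float], k: ReactionKinetics) -> float:
    fn = k.options["rate_fn"]
    args = k.options["rate_args"]
    return float(fn(*[state[s] for s in args]))


FAMILIES.setdefault("opaque", _eval_opaque)


# ---------------------------------------------------------------------------
# Content MathML <-> sympy
# ---------------------------------------------------------------------------

_MATHML_OPS = {
    "plus": lambda *a: sp.Add(*a),
    "times": lambda *a: sp.Mul(*a),
    "minus": lambda *a: a[0] - a[1] if len(a) == 2 else -a[0],
    "divide": lambda a, b: a / b,
    "power": lambda a, b: a**b,
    "root": lambda a, b=None: sp.sqrt(a) if b is None else a ** (1 / b),
    "exp": sp.exp,
    "ln": sp.log,
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _mathml_to_sympy(node) -> sp.Expr:
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLError("math element must hold exactly one expression")
        return _mathml_to_sympy(children[0])
    if tag == "ci":
        return sp.Symbol(node.text.strip(), nonnegative=True)
    if tag == "cn":
        text = (node.text or "").strip()
        if node.get("type") == "e-notation":
            mant = text
            exp_el = node.find(f"{{{MATHML_NS}}}sep")
            # lxml keeps the exponent in the tail of <sep/>
            sep = [c for c in node if _local(c.tag) == "sep"]
            exponent = sep[0].tail.strip() if sep else "0"
            return sp.Float(f"{mant}e{exponent}")
        return sp.Float(text)
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = _local(children[0].tag)
        args = [_mathml_to_sympy(c) for c in children[1:]]
        if op not in _MATHML_OPS:
            raise SBMLError(f"unsupported MathML operator <{op}>")
        return _MATHML_OPS[op](*args)
    raise SBMLError(f"unsupported MathML element <{tag}>")


def _emit(parent, expr: sp.Expr) -> None:
    """Append the content-MathML form of ``expr`` to ``parent``."""
    M = lambda tag: f"{{{MATHML_NS}}}{tag}"
    if isinstance(expr, sp.Symbol):
        el = etree.SubElement(parent, M("ci"))
        el.text = expr.name
        return
    if expr.is_Number:
        el = etree.SubElement(parent, M("cn"))
        el.text = repr(float(expr))
        return
    if isinstance(expr, (sp.Add, sp.Mul)):
        ap = etree.SubElement(parent, M("apply"))
        etree.SubElement(ap, M("plus" if isinstance(expr, sp.Add) else "times"))
        for arg in expr.args:
            _emit(ap, arg)
        return
    if isinstance(expr, sp.Pow):
        ap = etree.SubElement(parent, M("apply"))
        etree.SubElement(ap, M("power"))
        _emit(ap, expr.base)
        _emit(ap, expr.exp)
        return
    raise SBMLError(f"cannot serialize expression node {type(expr).__name__}")


def _sympy_to_mathml_element(expr: sp.Expr):
    math = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
    _emit(math, expr)
    return math


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _kinetics_to_json(kin: ReactionKinetics) -> str:
    rec = {
        "family": kin.family,
        "constants": kin.constants,
        "roles": kin.roles,
        "inhibitors": list(kin.inhibitors),
        "mechanism": {"kind": kin.mechanism.kind, "alpha": kin.mechanism.alpha},
        "isoforms": None if kin.isoforms is None else [dict(i) for i in kin.isoforms],
        "options": {k: v for k, v in kin.options.items()
                    if isinstance(v, (str, int, float, bool, type(None)))},
    }
    return json.dumps(rec, sort_keys=True)


def write_sbml(model: ModelDefinition, path) -> None:
    """Serialize a model to an SBML L3v2 document.

    Raises :class:`SBMLError` for unserializable (opaque) kinetic laws and
    performs a structural self-check before writing.
    """
    nsmap = {None: SBML_NS, "glyc": GLYC_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap, level="3", version="2")
    mdl = etree.SubElement(root, f"{{{SBML_NS}}}model", id=_check_sid(
        re.sub(r"[^A-Za-z0-9_]", "_", model.name) or "model"
    ), name=model.name)
    ann = etree.SubElement(mdl, f"{{{SBML_NS}}}annotation")
    meta = etree.SubElement(ann, f"{{{GLYC_NS}}}model")
    meta.text = json.dumps({
        "condition": model.condition,
        "pathway_flux_reaction": model.pathway_flux_reaction,
        "flux_unit": model.flux_unit,
        "notes": model.notes,
        "species_order": model.species,
    })
    comps = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(comps, f"{{{SBML_NS}}}compartment", id="cell", size="1",
                     spatialDimensions="3", constant="true")
    sps = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for s in model.species:
        etree.SubElement(
            sps, f"{{{SBML_NS}}}species",
            id=_check_sid(s), compartment="cell",
            initialConcentration=repr(float(model.initial[s])),
            boundaryCondition="true" if s in model.fixed else "false",
            constant="false", hasOnlySubstanceUnits="false",
        )
    rxns = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for r in model.reactions:
        if r.kinetics.family == "opaque":
            raise SBMLError(f"reaction {r.name!r}: opaque kinetic law cannot be re-serialized")
        rx = etree.SubElement(rxns, f"{{{SBML_NS}}}reaction",
                              id=_check_sid(r.name), reversible="true")
        reactants = {s: -c for s, c in r.stoichiometry.items() if c < 0}
        products = {s: c for s, c in r.stoichiometry.items() if c > 0}
        if reactants:
            lo = etree.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for s, c in sorted(reactants.items()):
                etree.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                                 species=s, stoichiometry=repr(float(c)), constant="true")
        if products:
            lo = etree.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for s, c in sorted(products.items()):
                etree.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                                 species=s, stoichiometry=repr(float(c)), constant="true")
        modifiers = sorted(
            (set(r.kinetics.roles.values()) | set(r.kinetics.inhibitors))
            - set(r.stoichiometry)
        )
        if modifiers:
            lo = etree.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            for s in modifiers:
                etree.SubElement(lo, f"{{{SBML_NS}}}modifierSpeciesReference", species=s)
        kl = etree.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        kann = etree.SubElement(kl, f"{{{SBML_NS}}}annotation")
        kel = etree.SubElement(kann, f"{{{GLYC_NS}}}kinetics")
        kel.text = _kinetics_to_json(r.kinetics)
        kl.append(_sympy_to_mathml_element(rate_expression(r.kinetics)))
    _structural_check(root)
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _structural_check(root) -> None:
    ids = root.findall(f".//{{{SBML_NS}}}species")
    seen = set()
    for el in ids:
        sid = el.get("id")
        if sid in seen:
            raise SBMLError(f"duplicate species id {sid!r}")
        seen.add(sid)
    for ref in root.findall(f".//{{{SBML_NS}}}speciesReference"):
        if ref.get("species") not in seen:
            raise SBMLError(f"species reference to undeclared id {ref.get('species')!r}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _kinetics_from_json(text: str) -> ReactionKinetics:
    rec = json.loads(text)
    mech = rec.get("mechanism") or {}
    iso = rec.get("isoforms")
    return ReactionKinetics(
        family=rec["family"],
        constants=dict(rec.get("constants", {})),
        roles=dict(rec.get("roles", {})),
        inhibitors=tuple(rec.get("inhibitors", ())),
        mechanism=InhibitionMechanism(mech.get("kind", "competitive"), mech.get("alpha")),
        isoforms=None if iso is None else tuple(dict(i) for i in iso),
        options=dict(rec.get("options", {})),
    )


def _opaque_kinetics(math_el) -> ReactionKinetics:
    expr = _mathml_to_sympy(math_el)
    symbols = sorted(expr.free_symbols, key=lambda s: s.name)
    fn = sp.lambdify(symbols, expr, "math")
    return ReactionKinetics(
        family="opaque",
        options={
            "rate_fn": fn,
            "rate_args": [s.name for s in symbols],
            "expr": sp.srepr(expr),
        },
    )


def read_sbml(path) -> ModelDefinition:
    """Parse an SBML document (Level 2 or 3) into a model definition."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLError(f"cannot parse SBML document {path}: {exc}") from None
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLError(f"root element is <{_local(root.tag)}>, expected <sbml>")
    ns = root.tag[1:].split("}")[0]
    if ns != SBML_NS and not SBML_L2_NS_RE.match(ns):
        raise SBMLError(f"unsupported SBML namespace {ns!r}")
    q = lambda tag: f"{{{ns}}}{tag}"
    mdl = root.find(q("model"))
    if mdl is None:
        raise SBMLError("document has no <model> element")
    meta = {}
    meta_el = mdl.find(f"{q('annotation')}/{{{GLYC_NS}}}model")
    if meta_el is not None and meta_el.text:
        meta = json.loads(meta_el.text)
    species, initial, fixed = [], {}, set()
    for el in mdl.findall(f"{q('listOfSpecies')}/{q('species')}"):
        sid = el.get("id")
        species.append(sid)
        initial[sid] = float(el.get("initialConcentration", el.get("initialAmount", 0.0)))
        if el.get("boundaryCondition", "false") == "true":
            fixed.add(sid)
    order = meta.get("species_order")
    if order and set(order) == set(species):
        species = list(order)
    reactions = []
    for rx in mdl.findall(f"{q('listOfReactions')}/{q('reaction')}"):
        stoich = {}
        for ref in rx.findall(f"{q('listOfReactants')}/{q('speciesReference')}"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) - float(
                ref.get("stoichiometry", 1.0))
        for ref in rx.findall(f"{q('listOfProducts')}/{q('speciesReference')}"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) + float(
                ref.get("stoichiometry", 1.0))
        kl = rx.find(q("kineticLaw"))
        if kl is None:
            raise SBMLError(f"reaction {rx.get('id')!r} has no kinetic law")
        kin_el = kl.find(f"{q('annotation')}/{{{GLYC_NS}}}kinetics")
        if kin_el is not None and kin_el.text:
            kin = _kinetics_from_json(kin_el.text)
        else:
            math_el = kl.find(f"{{{MATHML_NS}}}math")
            if math_el is None:
                raise SBMLError(f"reaction {rx.get('id')!r} has neither annotation nor math")
            kin = _opaque_kinetics(math_el)
        reactions.append(Reaction(rx.get("id"), stoich, kin))
    return ModelDefinition(
        name=mdl.get("name", mdl.get("id", "model")),
        condition=meta.get("condition", "AS30D"),
        species=species,
        initial=initial,
        fixed=fixed,
        reactions=reactions,
        pathway_flux_reaction=meta.get(
            "pathway_flux_reaction",
            reactions[-1].name if reactions else "LDH",
        ),
        flux_unit=meta.get("flux_unit", "mM/min"),
        notes=meta.get("notes", ""),
    )
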