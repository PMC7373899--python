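"""SBML Level 3 export/import of the reaction network and parameters.

The exporter writes standard SBML L3v2: compartments, species with initial
amounts (from the steady-state transform), global parameters (natural
scale, including the derived basal rates) and reactions with content-MathML
kinetic laws generated from the rate expressions.  A structured annotation
(custom namespace) carries the exact builder configuration (variant, chain
lengths, log10 parameter values), which the importer uses to reconstruct
the network bit-identically; species/reaction counts are read from the SBML
lists themselves.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET

import sympy

from .network import build_network
from .params import ParameterSet
from .simulate import steady_state

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://ifnstat.invalid/sbml-annotation"

_COMPARTMENTS = ("cytoplasm", "nucleus", "membrane", "promoter")


def _content_mathml(e) -> str:
    """Content-MathML string for a sympy expression (plain <ci> names)."""
    if isinstance(e, sympy.Symbol):
        return f"<ci>{e.name}</ci>"
    if isinstance(e, (sympy.Integer, sympy.Float, sympy.Rational)):
        return f"<cn>{float(e)}</cn>"
    if isinstance(e, sympy.Add):
        return ("<apply><plus/>"
                + "".join(_content_mathml(a) for a in e.args)
                + "</apply>")
    if isinstance(e, sympy.Mul):
        num = [a for a in e.args
               if not (a.is_Pow and a.exp.is_negative)]
        den = [sympy.Pow(a.base, -a.exp) for a in e.args
               if a.is_Pow and a.exp.is_negative]

        def prod(terms):
            if not terms:
                return "<cn>1.0</cn>"
            if len(terms) == 1:
                return _content_mathml(terms[0])
            return ("<apply><times/>"
                    + "".join(_content_mathml(t) for t in terms)
                    + "</apply>")

        if den:
            return (f"<apply><divide/>{prod(num)}{prod(den)}</apply>")
        return prod(num)
    if isinstance(e, sympy.Pow):
        return ("<apply><power/>" + _content_mathml(e.base)
                + _content_mathml(e.exp) + "</apply>")
    raise ValueError(f"unsupported expression node {type(e).__name__}")


def _mathml(expr: str) -> ET.Element:
    """Content MathML element for a rate expression."""
    sym_expr = sympy.sympify(expr.replace("IFN", "IFN_input"))
    wrapped = (f'<math xmlns="{MATHML_NS}">'
               + _content_mathml(sym_expr) + "</math>")
    return ET.fromstring(wrapped)


def write_sbml(network, params: ParameterSet, path) -> None:
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", level="3", version="2")
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model",
                          id=f"ifn_jakstat_{network.variant}")
    annot = ET.SubElement(model, f"{{{SBML_NS}}}annotation")
    cfg = ET.SubElement(annot, f"{{{ANNOT_NS}}}config")
    cfg.text = json.dumps({
        "variant": network.variant,
        "chains": network.chains,
        "log10": {n: float(v) for n, v in zip(params.names, params.log10)},
    })
    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for c in _COMPARTMENTS:
        ET.SubElement(comps, f"{{{SBML_NS}}}compartment", id=c,
                      constant="true", spatialDimensions="3", size="1")
    x0, rt, _ = steady_state(params, network)
    sps = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp, v in zip(network.species, x0):
        ET.SubElement(sps, f"{{{SBML_NS}}}species", id=sp.name,
                      compartment=sp.compartment, initialAmount=repr(v),
                      hasOnlySubstanceUnits="true",
                      boundaryCondition="false", constant="false")
    pars = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name, val in zip(network.runtime_names(), rt):
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter", id=name,
                      value=repr(float(val)), constant="true")
    for extra in ("IFN_input", "KD", "OE"):
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter", id=extra,
                      value="0.0" if extra != "KD" else "1.0",
                      constant="false")
    rxns = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rxn in network.reactions:
        r = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction", id=rxn.name,
                          reversible="false")
        if rxn.reactants:
            lst = ET.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for name, nu in rxn.reactants:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              species=name, stoichiometry=str(nu),
                              constant="true")
        if rxn.products:
            lst = ET.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for name, nu in rxn.products:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              species=name, stoichiometry=str(nu),
                              constant="true")
        if rxn.modifiers:
            lst = ET.SubElement(r, f"{{{SBML_NS}}}listOfModifiers")
            for name in rxn.modifiers:
                ET.SubElement(lst, f"{{{SBML_NS}}}modifierSpeciesReference",
                              species=name)
        kl = ET.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_mathml(rxn.rate))
    ET.ElementTree(sbml).write(path, xml_declaration=True,
                               encoding="unicode")


def read_sbml(path):
    """Reconstruct (network, params) plus the document's raw counts.

    Returns ``(network, params, n_species, n_reactions)`` where the counts
    come from the SBML listOfSpecies/listOfReactions, independently of the
    reconstruction.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    model = root.find(f"{{{SBML_NS}}}model")
    n_species = len(model.find(f"{{{SBML_NS}}}listOfSpecies"))
    n_reactions = len(model.find(f"{{{SBML_NS}}}listOfReactions"))
    cfg_el = model.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}config")
    if cfg_el is None:
        raise ValueError("missing ifnstat config annotation")
    cfg = json.loads(cfg_el.text)
    network = build_network(cfg["variant"],
                            {g: int(v) for g, v in cfg["chains"].items()})
    params = ParameterSet.from_dict(cfg["log10"], variant=cfg["variant"],
                                    log10_scale=True)
    return network, params, n_species, n_reactions
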