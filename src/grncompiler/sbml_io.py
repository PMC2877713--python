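"""Minimal SBML Level 3 export/import for the reaction layer.

Writes species (constant inputs flagged), parameters and reactions with
mass-action kinetic laws so compiled networks can be loaded into external
simulators (COPASI etc.).  The reader understands the same subset and is
used for round-tripping; it is not a general-purpose SBML parser.
"""

from __future__ import annotations

from pathlib import Path
from xml.etree import ElementTree as ET

from .regulation_compiler import Reaction, ReactionNetwork

__all__ = ["to_sbml", "from_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def to_sbml(network: ReactionNetwork, path: str | Path | None = None,
            model_id: str = "regulatory_network") -> str:
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": model_id})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true"})

    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in network.species:
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", {
            "id": s,
            "compartment": "cell",
            "initialConcentration": repr(network.initial_conditions.get(s, 0.0)),
            "constant": "true" if s in network.constant_species else "false",
            "boundaryCondition": "true" if s in network.constant_species else "false",
            "hasOnlySubstanceUnits": "false",
        })

    params_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name, value in network.parameters.items():
        ET.SubElement(params_el, f"{{{SBML_NS}}}parameter",
                      {"id": name, "value": repr(value), "constant": "true"})

    rxns_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for i, r in enumerate(network.reactions):
        rx = ET.SubElement(rxns_el, f"{{{SBML_NS}}}reaction",
                           {"id": f"r{i}_{r.rate_name}", "reversible": "false"})
        if r.reactants:
            lor = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for s, n in r.reactants.items():
                ET.SubElement(lor, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": str(n),
                               "constant": "true"})
        if r.products:
            lop = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for s, n in r.products.items():
                ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": str(n),
                               "constant": "true"})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math_el = ET.SubElement(
            kl, "{http://www.w3.org/1998/Math/MathML}math"
        )
        _mass_action_mathml(math_el, r)

    ET.indent(sbml)
    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


MATHML = "http://www.w3.org/1998/Math/MathML"


def _mass_action_mathml(parent: ET.Element, r: Reaction) -> None:
    factors = [("ci", r.rate_name)]
    for s, n in r.reactants.items():
        for _ in range(n):
            factors.append(("ci", s))
    if len(factors) == 1:
        ci = ET.SubElement(parent, f"{{{MATHML}}}ci")
        ci.text = r.rate_name
        return
    apply_el = ET.SubElement(parent, f"{{{MATHML}}}apply")
    ET.SubElement(apply_el, f"{{{MATHML}}}times")
    for _, name in factors:
        ci = ET.SubElement(apply_el, f"{{{MATHML}}}ci")
        ci.text = name


def from_sbml(source: str | Path) -> ReactionNetwork:
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    root = ET.fromstring(text)
    ns = {"s": SBML_NS}
    model = root.find("s:model", ns)
    species, constant, initial = [], set(), {}
    for el in model.find("s:listOfSpecies", ns):
        sid = el.get("id")
        species.append(sid)
        if el.get("constant") == "true":
            constant.add(sid)
        ic = float(el.get("initialConcentration", "0"))
        if ic != 0.0 or sid in constant:
            initial[sid] = ic
    parameters = {}
    params_el = model.find("s:listOfParameters", ns)
    if params_el is not None:
        for el in params_el:
            parameters[el.get("id")] = float(el.get("value"))
    reactions = []
    rxns_el = model.find("s:listOfReactions", ns)
    if rxns_el is not None:
        for rx in rxns_el:
            rid = rx.get("id")
            rate_name = rid.split("_", 1)[1]
            reactants: dict[str, int] = {}
            products: dict[str, int] = {}
            lor = rx.find("s:listOfReactants", ns)
            if lor is not None:
                for sr in lor:
                    reactants[sr.get("species")] = int(
                        float(sr.get("stoichiometry", "1"))
                    )
            lop = rx.find("s:listOfProducts", ns)
            if lop is not None:
                for sr in lop:
                    products[sr.get("species")] = int(
                        float(sr.get("stoichiometry", "1"))
                    )
            reactions.append(
                Reaction(reactants, products, rate_name, parameters[rate_name])
            )
    net = ReactionNetwork(species, reactions, parameters, constant, initial)
    net.validate()
    return net
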