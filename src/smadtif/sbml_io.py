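"""SBML (Level 3 Version 1) export and import of a ModelSystem.

Kinetic laws are written as explicit mass-action formulas,
``k * V_location * c1 [* c2 [* c3]]``, matching the package's amount-flux
semantics, so a round trip reproduces the right-hand side exactly.  The
ligand input clamp (non-depletion mode) is exported as a boundary-condition
species.  Conserved-group membership is reconstructed on import from the
species catalog (species ids are preserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import libsbml

from .network import (_SPECIES_CATALOG, Compartment, Mechanism, ModelSystem,
                      ModelVariant, Reaction, Species)
from .parameters import DEFAULTS, ParameterSet


@dataclass
class SbmlDocumentHandle:
    level: int
    version: int
    n_species: int
    n_reactions: int
    n_parameters: int
    n_errors: int
    path: str

    @property
    def valid(self) -> bool:
        return self.n_errors == 0


class SbmlIOError(RuntimeError):
    pass


def _check(value, message: str):
    if value is None:
        raise SbmlIOError(f"libsbml failure: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise SbmlIOError(f"libsbml error {value}: {message}")
    return value


def export_sbml(system: ModelSystem, path: str) -> SbmlDocumentHandle:
    """Write ``system`` to an SBML L3V1 file and validate it."""
    doc = libsbml.SBMLDocument(3, 1)
    model = _check(doc.createModel(), "createModel")
    model.setId(f"smadtif_{system.variant.mechanism.value}")
    model.setTimeUnits("second")
    model.setExtentUnits("mole")
    model.setSubstanceUnits("mole")

    # units: nM == nanomole/liter
    conc = model.createUnitDefinition()
    conc.setId("nanomole_per_litre")
    u = conc.createUnit()
    u.setKind(libsbml.UNIT_KIND_MOLE); u.setScale(-9); u.setExponent(1)
    u.setMultiplier(1.0)
    u2 = conc.createUnit()
    u2.setKind(libsbml.UNIT_KIND_LITRE); u2.setScale(0); u2.setExponent(-1)
    u2.setMultiplier(1.0)

    for comp in system.compartments.values():
        c = model.createCompartment()
        c.setId(comp.name)
        c.setConstant(True)
        c.setSize(comp.volume)
        c.setSpatialDimensions(3)
        c.setUnits("litre")

    for sp in system.species:
        s = model.createSpecies()
        s.setId(sp.name)
        s.setCompartment(sp.compartment)
        s.setInitialConcentration(sp.initial_value)
        s.setSubstanceUnits("mole")
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)
        s.setBoundaryCondition(False)

    uses_input_ligand = any(r.uses_ligand for r in system.reactions)
    if uses_input_ligand:
        s = model.createSpecies()
        s.setId("TGFb")
        s.setCompartment("extracellular")
        s.setInitialConcentration(0.0)
        s.setSubstanceUnits("mole")
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)
        s.setBoundaryCondition(True)  # input clamp, not consumed

    emitted = set()
    for rx in system.reactions:
        symbol = rx.rate_constant
        if symbol not in emitted:
            p = model.createParameter()
            p.setId(symbol)
            p.setValue(system._resolve_constant(symbol))
            p.setConstant(True)
            emitted.add(symbol)

    for rx in system.reactions:
        r = model.createReaction()
        r.setId(rx.id)
        r.setReversible(False)
        r.setFast(False)
        for name, st in rx.reactants:
            ref = r.createReactant()
            ref.setSpecies(name); ref.setStoichiometry(float(st))
            ref.setConstant(True)
        for name, st in rx.products:
            ref = r.createProduct()
            ref.setSpecies(name); ref.setStoichiometry(float(st))
            ref.setConstant(True)
        for name in rx.modifiers:
            ref = r.createModifier()
            ref.setSpecies(name)
        factors = [rx.rate_constant, rx.location]
        for name, st in rx.reactants:
            factors.extend([name] * st)
        factors.extend(rx.modifiers)
        if rx.uses_ligand:
            factors.append("TGFb")
            mod = r.createModifier()
            mod.setSpecies("TGFb")
        law = r.createKineticLaw()
        math = libsbml.parseL3Formula(" * ".join(factors))
        _check(math, f"formula for {rx.id}")
        law.setMath(math)

    doc.checkConsistency()
    n_errors = doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR)
    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise SbmlIOError(f"cannot write SBML to {path}")
    n_state_species = sum(
        1 for i in range(model.getNumSpecies())
        if not model.getSpecies(i).getBoundaryCondition())
    return SbmlDocumentHandle(3, 1, n_state_species,
                              model.getNumReactions(),
                              model.getNumParameters(), int(n_errors),
                              str(path))


def _parse_mass_action(math, param_ids: set[str], comp_ids: set[str],
                       rx_id: str) -> tuple[str, str, list[str]]:
    """Decompose k * V * c1 [* c2 ...] into (constant, compartment, factors)."""
    names: list[str] = []

    def walk(node):
        if node.getType() == libsbml.AST_TIMES:
            for i in range(node.getNumChildren()):
                walk(node.getChild(i))
        elif node.getType() == libsbml.AST_NAME:
            names.append(node.getName())
        else:
            raise SbmlIOError(
                f"reaction {rx_id}: unsupported rate law (only mass-action "
                "products of identifiers are importable)")

    walk(math)
    consts = [n for n in names if n in param_ids]
    comps = [n for n in names if n in comp_ids]
    if len(consts) != 1 or len(comps) != 1:
        raise SbmlIOError(f"reaction {rx_id}: rate law is not of the form "
                          "k * V * concentrations")
    species = [n for n in names if n not in param_ids and n not in comp_ids]
    return consts[0], comps[0], species


def import_sbml(path: str) -> ModelSystem:
    """Reconstruct a ModelSystem from an SBML file written by export_sbml
    (or any file restricted to the same mass-action subset)."""
    reader = libsbml.SBMLReader()
    doc = reader.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise SbmlIOError(
            f"parse failure: {doc.getError(0).getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise SbmlIOError("no model element in document")

    compartments = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        compartments[c.getId()] = Compartment(c.getId(), c.getSize())

    species, boundary = [], set()
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        if s.getBoundaryCondition():
            boundary.add(s.getId())
            continue
        catalog = _SPECIES_CATALOG.get(s.getId())
        composition = dict(catalog[1]) if catalog else {}
        init = s.getInitialConcentration()
        species.append(Species(s.getId(), s.getCompartment(),
                               init if init == init else 0.0, composition))

    param_values, param_ids = {}, set()
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        if p.getValue() < 0:
            raise SbmlIOError(
                f"negative parameter {p.getId()} = {p.getValue()}")
        param_values[p.getId()] = p.getValue()
        param_ids.add(p.getId())

    known = {k: (param_values[k], DEFAULTS[k][1])
             for k in param_values if k in DEFAULTS}
    params = ParameterSet({**{k: v for k, v in DEFAULTS.items()}, **known})

    reactions = []
    depletion = False
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        law = r.getKineticLaw()
        if law is None or law.getMath() is None:
            raise SbmlIOError(f"reaction {r.getId()}: missing kinetic law")
        const, loc, factors = _parse_mass_action(
            law.getMath(), param_ids, set(compartments), r.getId())
        reactants = [(r.getReactant(j).getSpecies(),
                      int(r.getReactant(j).getStoichiometry()))
                     for j in range(r.getNumReactants())]
        products = [(r.getProduct(j).getSpecies(),
                     int(r.getProduct(j).getStoichiometry()))
                    for j in range(r.getNumProducts())]
        reactant_names = {n for n, _ in reactants}
        uses_ligand = "TGFb" in factors and "TGFb" in boundary
        if "TGFb" in reactant_names:
            depletion = True
        modifiers = [n for n in factors
                     if n not in reactant_names and n != "TGFb"
                     and any(sp.name == n for sp in species)]
        order = len(factors)
        rate_law = {0: "synthesis", 1: "mass_action_uni",
                    2: "mass_action_bi", 3: "mass_action_tri"}.get(
                        order, "mass_action_tri")
        if not products:
            rate_law = "degradation"
        reactions.append(Reaction(r.getId(), const, reactants, products,
                                  modifiers, rate_law, loc, uses_ligand))

    mech = Mechanism.BASE
    names = {sp.name for sp in species}
    if "pS24nTIF1g" in names:
        mech = Mechanism.INTEGRATED
    elif "S4nTIF1g" in names:
        mech = Mechanism.COMPETITION
    elif "S4ub_n" in names:
        mech = Mechanism.REPRESSOR
    variant = ModelVariant(mech, ligand_depletion=depletion,
                           fam_included="FAM" in names)

    if "k_in_complex" in param_values:
        # derived constant: fold back into CIF so resolution matches
        params = params.with_updates(
            CIF=param_values["k_in_complex"] / params["k_in_smad2"])

    return ModelSystem(variant, species, reactions, params, compartments)


def validate_report(path: str) -> dict:
    """SBML consistency-check report as a JSON-ready dict."""
    doc = libsbml.SBMLReader().readSBMLFromFile(str(path))
    doc.checkConsistency()
    issues = []
    for i in range(doc.getNumErrors()):
        e = doc.getError(i)
        issues.append({"severity": e.getSeverityAsString(),
                       "message": e.getMessage().strip(),
                       "line": e.getLine()})
    return {"path": str(path),
            "n_errors": doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR),
            "issues": issues}
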