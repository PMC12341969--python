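"""SBML Level-3 (+fbc) subset I/O.

Only the constructs constraint-based models need are handled: compartments,
species, reactions with stoichiometry, flux bounds via fbc parameters,
gene-product associations, and one maximization objective.  Subsystem labels
travel in reaction notes (``<p>SUBSYSTEM: ...</p>``, the cobrapy
convention).  Unknown constructs are ignored with a logged warning; this is
deliberately not a general SBML round-tripper.

Internally metabolite ids use the square-bracket compartment convention
(``glc__D[c]``); on export they become SBML-legal ``M_glc__D_c`` ids, and the
import path reverses the mangling.
"""

from __future__ import annotations

import logging
import re

import libsbml

from .errors import ModelParseError
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction, split_compartment, validate

logger = logging.getLogger(__name__)

_SUBSYSTEM_RE = re.compile(r"SUBSYSTEM:\s*([^<]*)")


def _sbml_safe(identifier: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "__", identifier)


def _species_to_internal(species_id: str, compartment: str) -> str:
    base = species_id
    if base.startswith("M_"):
        base = base[2:]
    suffix = "_" + compartment
    if compartment and base.endswith(suffix):
        base = base[: -len(suffix)]
    return f"{base}[{compartment}]" if compartment else base


def _gpa_to_string(association, label_of: dict[str, str]) -> str:
    if association is None:
        return ""
    if association.isGeneProductRef():
        ref = association.getGeneProduct()
        return label_of.get(ref, ref)
    parts = [
        _gpa_to_string(association.getAssociation(i), label_of)
        for i in range(association.getNumAssociations())
    ]
    joiner = " and " if association.isFbcAnd() else " or "
    return "(" + joiner.join(parts) + ")"


def read_sbml_model(path) -> MetabolicModel:
    document = libsbml.readSBMLFromFile(str(path))
    if document.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        error = document.getError(0)
        raise ModelParseError(
            f"{path}: SBML parse error at line {error.getLine()}: "
            f"{error.getMessage().strip()}"
        )
    sbml_model = document.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: file contains no SBML model element")
    fbc = sbml_model.getPlugin("fbc")

    parameters = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }

    label_of: dict[str, str] = {}
    genes: list[str] = []
    if fbc is not None:
        for gp in fbc.getListOfGeneProducts():
            label = gp.getLabel() or gp.getId()
            label_of[gp.getId()] = label
            genes.append(label)

    metabolites = []
    internal_of: dict[str, str] = {}
    for species in sbml_model.getListOfSpecies():
        internal = _species_to_internal(species.getId(), species.getCompartment())
        internal_of[species.getId()] = internal
        metabolites.append(Metabolite(id=internal, name=species.getName() or ""))

    reactions = []
    for sbml_reaction in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for i in range(sbml_reaction.getNumReactants()):
            ref = sbml_reaction.getReactant(i)
            met = internal_of[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for i in range(sbml_reaction.getNumProducts()):
            ref = sbml_reaction.getProduct(i)
            met = internal_of[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        if sbml_reaction.getNumModifiers() > 0:
            logger.warning(
                "ignoring modifier species on reaction %s", sbml_reaction.getId()
            )

        rfbc = sbml_reaction.getPlugin("fbc")
        lower, upper = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr = ""
        if rfbc is not None:
            if rfbc.getLowerFluxBound():
                lower = parameters.get(rfbc.getLowerFluxBound(), lower)
            if rfbc.getUpperFluxBound():
                upper = parameters.get(rfbc.getUpperFluxBound(), upper)
            gpr = _gpa_to_string(
                rfbc.getGeneProductAssociation().getAssociation()
                if rfbc.getGeneProductAssociation() is not None
                else None,
                label_of,
            )
        elif not sbml_reaction.getReversible():
            lower = 0.0

        subsystem = ""
        notes = sbml_reaction.getNotesString() if sbml_reaction.isSetNotes() else ""
        match = _SUBSYSTEM_RE.search(notes)
        if match:
            subsystem = match.group(1).strip()

        rid = sbml_reaction.getId()
        if rid.startswith("R_"):
            rid = rid[2:]
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                gpr=gpr,
                subsystem=subsystem,
                name=sbml_reaction.getName() or "",
            )
        )

    objective_id = ""
    if fbc is not None and fbc.getNumObjectives() > 0:
        objective = fbc.getObjective(0)
        if objective.getNumFluxObjectives() > 0:
            objective_id = objective.getFluxObjective(0).getReaction()
            if objective_id.startswith("R_"):
                objective_id = objective_id[2:]

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=sorted(set(genes)),
        objective_id=objective_id,
        name=sbml_model.getName() or sbml_model.getId() or "",
    )
    validate(model)
    return model


def write_sbml_model(model: MetabolicModel, path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    document = libsbml.SBMLDocument(ns)
    document.setPackageRequired("fbc", False)
    sbml_model = document.createModel()
    sbml_model.setId(_sbml_safe(model.name) or "fluxmark_model")
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(False)

    compartments = sorted({m.compartment or "default" for m in model.metabolites})
    for comp in compartments:
        compartment = sbml_model.createCompartment()
        compartment.setId(_sbml_safe(comp))
        compartment.setConstant(True)

    species_id: dict[str, str] = {}
    for met in model.metabolites:
        base, comp = split_compartment(met.id)
        sid = f"M_{_sbml_safe(base)}_{_sbml_safe(comp or 'default')}"
        species_id[met.id] = sid
        species = sbml_model.createSpecies()
        species.setId(sid)
        species.setName(met.name)
        species.setCompartment(_sbml_safe(comp or "default"))
        species.setHasOnlySubstanceUnits(False)
        species.setBoundaryCondition(False)
        species.setConstant(False)

    gene_id: dict[str, str] = {}
    for gene in sorted(model.genes):
        gid = "G_" + _sbml_safe(gene)
        gene_id[gene] = gid
        gp = fbc.createGeneProduct()
        gp.setId(gid)
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_parameter(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            parameter = sbml_model.createParameter()
            parameter.setId(pid)
            parameter.setValue(value)
            parameter.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    from .gpr import parse_gpr

    def gpa_infix(node) -> str:
        if node[0] == "gene":
            return gene_id[node[1]]
        joiner = " and " if node[0] == "and" else " or "
        return "(" + joiner.join(gpa_infix(child) for child in node[1]) + ")"

    for reaction in model.reactions:
        sbml_reaction = sbml_model.createReaction()
        sbml_reaction.setId("R_" + _sbml_safe(reaction.id))
        sbml_reaction.setName(reaction.name)
        sbml_reaction.setFast(False)
        sbml_reaction.setReversible(reaction.lower_bound < 0)
        for met_id, coeff in sorted(reaction.stoichiometry.items()):
            if coeff < 0:
                ref = sbml_reaction.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sbml_reaction.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(species_id[met_id])
            ref.setConstant(True)
        rfbc = sbml_reaction.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_parameter(reaction.lower_bound))
        rfbc.setUpperFluxBound(bound_parameter(reaction.upper_bound))
        gpr_ast = parse_gpr(reaction.gpr)
        if gpr_ast is not None:
            gpa = rfbc.createGeneProductAssociation()
            # usingId: the infix references fbc:id values, not labels
            gpa.setAssociation(gpa_infix(gpr_ast), True, False)
        if reaction.subsystem:
            sbml_reaction.setNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>SUBSYSTEM: {reaction.subsystem}</p></body>"
            )

    if model.objective_id:
        objective = fbc.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        fbc.setActiveObjectiveId("obj")
        flux_objective = objective.createFluxObjective()
        flux_objective.setReaction("R_" + _sbml_safe(model.objective_id))
        flux_objective.setCoefficient(1.0)

    libsbml.writeSBMLToFile(document, str(path))
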