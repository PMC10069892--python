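"""SBML I/O for stoichiometric models (Level 3 + fbc, Level 2 fallback).

The reader harvests flux bounds from the fbc plugin when present, falling
back to kinetic-law ``LOWER_BOUND``/``UPPER_BOUND`` parameters, and finally
to +/-1000 with a logged warning.  EC numbers are collected with a fixed
precedence: MIRIAM ``ec-code`` CV-term annotations first, then a regex over
the reaction notes/name, then an optional user-supplied reaction-id -> EC
mapping.  The writer emits Level 3 Version 1 with fbc version 2 and is used
by the synthetic model generator.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import libsbml

from .core import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

logger = logging.getLogger(__name__)

EC_PATTERN = re.compile(r"\b(\d+\.\d+\.\d+\.(?:\d+|-))(?!\d)")


class SBMLReadError(ValueError):
    pass


def _harvest_ec(rxn: libsbml.Reaction, mapping: dict[str, set[str]] | None) -> set[str]:
    # 1) CV-term / MIRIAM annotations
    found: set[str] = set()
    for i in range(rxn.getNumCVTerms()):
        term = rxn.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            if "ec-code" in uri or "ec-number" in uri:
                match = EC_PATTERN.search(uri)
                if match:
                    found.add(match.group(1))
    if found:
        return found
    # 2) regex over notes and name
    text = ""
    if rxn.isSetNotes():
        text += libsbml.XMLNode.convertXMLNodeToString(rxn.getNotes())
    text += " " + (rxn.getName() or "")
    found = set(EC_PATTERN.findall(text))
    if found:
        return found
    # 3) user-supplied mapping table
    if mapping and rxn.getId() in mapping:
        return set(mapping[rxn.getId()])
    return set()


def _species_annotations(sp: libsbml.Species) -> dict[str, list[str]]:
    annot: dict[str, list[str]] = {}
    for i in range(sp.getNumCVTerms()):
        term = sp.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            # identifiers.org style: .../<namespace>/<accession>
            parts = uri.rstrip("/").split("/")
            if len(parts) >= 2:
                namespace, accession = parts[-2], parts[-1]
                annot.setdefault(namespace, []).append(accession)
    return annot


def read_sbml(path: str | Path,
              ec_mapping: dict[str, set[str]] | None = None) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Parameters
    ----------
    path:
        SBML L2/L3 file, with fbc bounds or kinetic-law bound parameters.
    ec_mapping:
        Optional reaction-id -> set-of-EC fallback table, consulted only for
        reactions with no annotation- or notes-derived EC numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLReadError(
            f"{path}: SBML parse failure at line {err.getLine()}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLReadError(f"{path}: no model element")

    fbc: libsbml.FbcModelPlugin | None = sbml_model.getPlugin("fbc")

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        formula = None
        sp_fbc = sp.getPlugin("fbc")
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            formula = sp_fbc.getChemicalFormula() or None
        metabolites.append(Metabolite(
            id=sp.getId(), name=sp.getName() or "",
            compartment=sp.getCompartment() or "",
            formula=formula,
            is_boundary=bool(sp.getBoundaryCondition()),
            annotations=_species_annotations(sp),
        ))

    def parameter_value(pid: str) -> float | None:
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else None

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}

        lb = ub = None
        rxn_fbc = rxn.getPlugin("fbc")
        if rxn_fbc is not None:
            if rxn_fbc.isSetLowerFluxBound():
                lb = parameter_value(rxn_fbc.getLowerFluxBound())
            if rxn_fbc.isSetUpperFluxBound():
                ub = parameter_value(rxn_fbc.getUpperFluxBound())
        if lb is None or ub is None:
            kl = rxn.getKineticLaw()
            if kl is not None:
                for j in range(kl.getNumParameters()):
                    p = kl.getParameter(j)
                    if p.getId() == "LOWER_BOUND" and lb is None:
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND" and ub is None:
                        ub = p.getValue()
        if lb is None or ub is None:
            if lb is None:
                lb = -DEFAULT_BOUND
            if ub is None:
                ub = DEFAULT_BOUND
            logger.warning("reaction %s: missing flux bounds, defaulting to (%g, %g)",
                           rxn.getId(), lb, ub)

        reactions.append(Reaction(
            id=rxn.getId(), name=rxn.getName() or "",
            stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            ec_numbers=_harvest_ec(rxn, ec_mapping),
        ))

    objective: dict[str, float] = {}
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None:
            for j in range(active.getNumFluxObjectives()):
                fo = active.getFluxObjective(j)
                objective[fo.getReaction()] = fo.getCoefficient()

    model = MetabolicModel(
        id=sbml_model.getId() or path.stem,
        metabolites=metabolites, reactions=reactions, objective=objective,
    )
    model.validate()
    model.detect_exchanges_and_transports()
    # re-harvest exchange flag from SBML boundary species already handled above
    return model


# ----------------------------------------------------------------------
# Writer (Level 3 Version 1, fbc version 2) — used by the toy generator.
# ----------------------------------------------------------------------

def _check(code, message: str) -> None:
    if code is not None and isinstance(code, int) and code < 0:
        raise RuntimeError(f"libsbml call failed ({code}): {message}")


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write *model* as SBML Level 3 + fbc v2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    fbc: libsbml.FbcModelPlugin = sm.getPlugin("fbc")
    fbc.setStrict(False)

    compartments = sorted({m.compartment or "default" for m in model.metabolites})
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)
        c.setSize(1.0)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(m.compartment or "default")
        sp.setBoundaryCondition(m.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        sp.setInitialConcentration(0.0)
        if m.formula is not None:
            sp.getPlugin("fbc").setChemicalFormula(m.formula)
        if m.annotations:
            sp.setMetaId(f"meta_{m.id}")
            for namespace, accessions in sorted(m.annotations.items()):
                term = libsbml.CVTerm()
                term.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
                term.setBiologicalQualifierType(libsbml.BQB_IS)
                for acc in accessions:
                    term.addResource(f"https://identifiers.org/{namespace}/{acc}")
                sp.addCVTerm(term)

    bound_params: dict[float, str] = {}

    def bound_parameter(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        if r.name:
            rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for mid, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = rx.createReactant()
                ref.setSpecies(mid)
                ref.setStoichiometry(-coef)
            else:
                ref = rx.createProduct()
                ref.setSpecies(mid)
                ref.setStoichiometry(coef)
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_parameter(r.lower_bound))
        rfbc.setUpperFluxBound(bound_parameter(r.upper_bound))
        if r.ec_numbers:
            rx.setMetaId(f"meta_{r.id}")
            term = libsbml.CVTerm()
            term.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
            term.setBiologicalQualifierType(libsbml.BQB_IS)
            for ec in sorted(r.ec_numbers):
                term.addResource(f"https://identifiers.org/ec-code/{ec}")
            rx.addCVTerm(term)

    if model.objective:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, weight in sorted(model.objective.items()):
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(weight)
        fbc.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path}")
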