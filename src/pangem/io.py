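"""Standard-format I/O: SBML L3/FBC networks plus sidecar TSV tables.

The template reactome and strain models travel as SBML Level 3 documents
with the ``fbc`` package carrying formulas, charges, flux bounds and the
biomass objective.  Two pieces of information exceed what standard SBML
expresses and ride in sidecars or notes:

* multi-allelic GPR rules (several distinct allele sets per reaction) go in
  a TSV with columns ``reaction_id`` and ``allele_set`` (semicolon-joined
  alleles), one row per alternative;
* the reaction-type taxonomy (exchange / orphan / spontaneous / demand /
  sink / biomass / gene_associated) and subsystem are written into each
  reaction's SBML notes, and the NGAM reaction id into the model notes.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Dict, List, Optional, Union

import libsbml
import pandas as pd

from .model import (
    GPRRule,
    Medium,
    Metabolite,
    PanReactome,
    Reaction,
    StrainModel,
    ValidationError,
)

__all__ = [
    "SBMLParseError",
    "load_reactome",
    "write_reactome",
    "load_strain_model",
    "write_strain_model",
    "read_gpr_table",
    "write_gpr_table",
    "read_medium",
    "write_medium",
    "read_similarity_table",
    "write_similarity_table",
]


class SBMLParseError(ValueError):
    """The SBML document is malformed; the message names the line."""


_NOTE_RE = re.compile(r"(\w+)\s*:\s*([^<\n]+)")


def _note_fields(notes_xml: Optional[str]) -> Dict[str, str]:
    if not notes_xml:
        return {}
    return {m.group(1): m.group(2).strip() for m in _NOTE_RE.finditer(notes_xml)}


def _make_notes(fields: Dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in fields.items())
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _read_document(source: Union[str, Path, _io.IOBase]) -> libsbml.SBMLDocument:
    if hasattr(source, "read"):
        doc = libsbml.readSBMLFromString(source.read())
    else:
        doc = libsbml.readSBMLFromFile(str(source))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLParseError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
            )
    if doc.getModel() is None:
        raise SBMLParseError("SBML document contains no model")
    return doc


def _network_from_sbml(model: libsbml.Model):
    """Extract metabolites, reactions, biomass and NGAM ids from an SBML model."""
    metabolites: Dict[str, Metabolite] = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        plug = sp.getPlugin("fbc")
        formula = plug.getChemicalFormula() if plug and plug.isSetChemicalFormula() else None
        charge = plug.getCharge() if plug and plug.isSetCharge() else None
        metabolites[sp.getId()] = Metabolite(
            id=sp.getId(),
            name=sp.getName() or "",
            formula=formula or None,
            charge=charge,
            compartment=sp.getCompartment() or "c",
        )

    mplug = model.getPlugin("fbc")
    biomass_id = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()

    def bound_value(param_id: str, default: float) -> float:
        param = model.getParameter(param_id)
        return param.getValue() if param is not None else default

    reactions: Dict[str, Reaction] = {}
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rplug = rx.getPlugin("fbc")
        lb = bound_value(rplug.getLowerFluxBound(), 0.0) if rplug else 0.0
        ub = bound_value(rplug.getUpperFluxBound(), 1000.0) if rplug else 1000.0
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        fields = _note_fields(rx.getNotesString() if rx.isSetNotes() else None)
        rtype = fields.get("rtype")
        if rtype is None:
            if rx.getId() == biomass_id:
                rtype = "biomass"
            elif len(stoich) == 1 and rx.getId().startswith("EX_"):
                rtype = "exchange"
            else:
                rtype = "orphan"
        reactions[rx.getId()] = Reaction(
            id=rx.getId(),
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            name=rx.getName() or "",
            subsystem=fields.get("subsystem", ""),
            rtype=rtype,
        )

    model_fields = _note_fields(model.getNotesString() if model.isSetNotes() else None)
    ngam_id = model_fields.get("ngam", "NGAM")
    return metabolites, reactions, biomass_id, ngam_id


def load_reactome(
    sbml_source: Union[str, Path, _io.IOBase],
    gpr_table: Optional[Union[str, Path]] = None,
) -> PanReactome:
    """Load a template reactome from SBML plus an optional GPR sidecar TSV."""
    doc = _read_document(sbml_source)
    model = doc.getModel()
    metabolites, reactions, biomass_id, ngam_id = _network_from_sbml(model)
    if biomass_id is None:
        raise ValidationError("SBML model declares no biomass objective")
    reactome = PanReactome(
        metabolites=metabolites,
        reactions=reactions,
        biomass_id=biomass_id,
        ngam_id=ngam_id,
        name=model.getId() or "pan_reactome",
    )
    if gpr_table is not None:
        attach_gprs(reactome, read_gpr_table(gpr_table))
    reactome.validate()
    return reactome


def attach_gprs(reactome: PanReactome, gprs: Dict[str, GPRRule]) -> None:
    """Attach GPR rules, promoting the reactions to gene_associated."""
    for rid, rule in gprs.items():
        if rid not in reactome.reactions:
            raise ValidationError(f"GPR table references unknown reaction {rid}")
        rxn = reactome.reactions[rid]
        rxn.rtype = "gene_associated"
        rxn.gpr = rule


def write_reactome(reactome: PanReactome, sbml_path: Union[str, Path],
                   gpr_path: Optional[Union[str, Path]] = None) -> None:
    """Write the template to SBML (and its GPR rules to the sidecar TSV)."""
    _write_sbml(reactome, sbml_path)
    if gpr_path is not None:
        write_gpr_table(
            {rid: r.gpr for rid, r in reactome.reactions.items() if r.gpr is not None},
            gpr_path,
        )


def load_strain_model(sbml_source: Union[str, Path, _io.IOBase]) -> StrainModel:
    """Load a strain-specific model from SBML (GPRs are not needed here)."""
    doc = _read_document(sbml_source)
    model = doc.getModel()
    metabolites, reactions, biomass_id, ngam_id = _network_from_sbml(model)
    if biomass_id is None:
        raise ValidationError("SBML model declares no biomass objective")
    fields = _note_fields(model.getNotesString() if model.isSetNotes() else None)
    sm = StrainModel(
        strain_id=model.getId() or "strain",
        metabolites=metabolites,
        reactions=reactions,
        biomass_id=biomass_id,
        ngam_id=ngam_id,
        species=fields.get("species", ""),
    )
    sm.validate()
    return sm


def write_strain_model(model: StrainModel, sbml_path: Union[str, Path]) -> None:
    _write_sbml(model, sbml_path, extra_model_notes={"species": model.species})


def _write_sbml(network, path: Union[str, Path], extra_model_notes: Optional[Dict[str, str]] = None) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(getattr(network, "name", None) or getattr(network, "strain_id", "model"))
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    notes = {"ngam": network.ngam_id}
    notes.update(extra_model_notes or {})
    model.setNotes(_make_notes(notes))

    for comp_id in sorted({m.compartment for m in network.metabolites.values()} or {"c"}):
        comp = model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in network.metabolites.values():
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in network.reactions.values():
        rx = model.createReaction()
        rx.setId(rxn.id)
        rx.setName(rxn.name)
        rx.setReversible(rxn.lower_bound < 0)
        rx.setFast(False)
        rx.setNotes(_make_notes({"rtype": rxn.rtype, "subsystem": rxn.subsystem}))
        for met_id, coeff in rxn.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))

    objective = mplug.createObjective()
    objective.setId("obj_biomass")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(network.biomass_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj_biomass")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path}")


# --- sidecar tables ---------------------------------------------------------

def read_gpr_table(path: Union[str, Path]) -> Dict[str, GPRRule]:
    """Read the GPR sidecar TSV: one row per DNF alternative."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"reaction_id", "allele_set"}
    if not required <= set(df.columns):
        raise ValidationError(f"GPR table must have columns {sorted(required)}")
    alternatives: Dict[str, List[frozenset]] = {}
    for row in df.itertuples(index=False):
        alleles = frozenset(a.strip() for a in str(row.allele_set).split(";") if a.strip())
        if not alleles:
            raise ValidationError(f"empty allele set for reaction {row.reaction_id}")
        alternatives.setdefault(str(row.reaction_id), []).append(alleles)
    return {rid: GPRRule.from_sets(alts) for rid, alts in alternatives.items()}


def write_gpr_table(gprs: Dict[str, GPRRule], path: Union[str, Path]) -> None:
    rows = []
    for rid in sorted(gprs):
        for alt in sorted(gprs[rid].alternatives, key=lambda s: sorted(s)):
            rows.append({"reaction_id": rid, "allele_set": ";".join(sorted(alt))})
    pd.DataFrame(rows, columns=["reaction_id", "allele_set"]).to_csv(path, sep="\t", index=False)


def read_medium(path: Union[str, Path], name: Optional[str] = None) -> Medium:
    """Read a medium TSV (columns exchange_id, uptake_mmol_gDCW_h; '#' comments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"exchange_id", "uptake_mmol_gDCW_h"}
    if not required <= set(df.columns):
        raise ValidationError(f"medium table must have columns {sorted(required)}")
    limits = {str(r.exchange_id): float(r.uptake_mmol_gDCW_h) for r in df.itertuples(index=False)}
    return Medium(limits, name=name or Path(path).stem)


def write_medium(medium: Medium, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# medium: {medium.name}\n")
        fh.write("exchange_id\tuptake_mmol_gDCW_h\n")
        for ex in sorted(medium.uptake_limits):
            fh.write(f"{ex}\t{medium.uptake_limits[ex]:g}\n")


def read_similarity_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a bidirectional-search similarity TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"strain_id", "strain_gene", "allele", "pident_fwd", "pident_rev", "mutual_best"}
    if not required <= set(df.columns):
        raise ValidationError(f"similarity table must have columns {sorted(required)}")
    return df


def write_similarity_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)
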