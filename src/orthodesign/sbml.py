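"""SBML Level 3 (FBC) reader.

SBML carries no biomass/target/uptake semantics, so role designation comes
from a YAML sidecar (keys ``substrate_uptake``, ``biomass_reaction``,
``target_reaction``, ``precursors``, ``non_deletable``); when the sidecar
omits the biomass reaction, the active FBC objective is used instead.
Boundary-condition species become external metabolites.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import (
    Metabolite,
    ModelFormatError,
    Reaction,
    StoichiometricModel,
    retag_roles,
)


def read_sidecar(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ModelFormatError(f"sidecar {path} must be a mapping")
    return data


def load_sbml_model(path: str | Path, sidecar: str | Path | None = None) -> StoichiometricModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: no model element")

    seen = set()
    mets = []
    for sp in sbml_model.getListOfSpecies():
        if sp.getId() in seen:
            raise ModelFormatError(f"{path}: duplicate species id {sp.getId()!r}")
        seen.add(sp.getId())
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                is_external=bool(sp.getBoundaryCondition()),
            )
        )

    def _param(pid, default):
        p = sbml_model.getParameter(pid) if pid else None
        return p.getValue() if p is not None else default

    rxns = []
    rseen = set()
    for rx in sbml_model.getListOfReactions():
        if rx.getId() in rseen:
            raise ModelFormatError(f"{path}: duplicate reaction id {rx.getId()!r}")
        rseen.add(rx.getId())
        stoich: dict[str, float] = {}
        for sr in rx.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in rx.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        fbc = rx.getPlugin("fbc")
        reversible = rx.getReversible()
        lb = -1000.0 if reversible else 0.0
        ub = 1000.0
        if fbc is not None:
            lb = _param(fbc.getLowerFluxBound(), lb)
            ub = _param(fbc.getUpperFluxBound(), ub)
        rxns.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                reversible=bool(reversible),
                lower_bound=float(lb),
                upper_bound=float(ub),
            )
        )

    model = StoichiometricModel(metabolites=mets, reactions=rxns, name=sbml_model.getId() or "sbml")

    cfg = read_sidecar(sidecar) if sidecar else {}
    biomass = cfg.get("biomass_reaction")
    if biomass is None:
        fbc_model = sbml_model.getPlugin("fbc")
        if fbc_model is not None and fbc_model.getNumObjectives() > 0:
            obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
            if obj is not None and obj.getNumFluxObjectives() > 0:
                biomass = obj.getFluxObjective(0).getReaction()
    return retag_roles(
        model,
        uptake=cfg.get("substrate_uptake"),
        biomass=biomass,
        target=cfg.get("target_reaction"),
        precursors=cfg.get("precursors"),
        non_deletable=cfg.get("non_deletable"),
    )
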