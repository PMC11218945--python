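"""Reading and writing single-species models (SBML Level 3 + FBC, COBRA JSON).

Parsing is delegated to :mod:`cobra`, which handles both dialects; models are
converted to the package's uniform :class:`~commacparma.model.MetabolicModel`
representation.  JSON output is written directly in the COBRA JSON schema with
sorted keys so that serialisation is byte-stable.

Identifiers are treated as opaque strings: no cross-database normalisation is
attempted, because shared metabolites are matched by id within one model
collection.
"""

from __future__ import annotations

import json
from pathlib import Path

import cobra
import cobra.io

from .model import (
    BiomassNotIdentifiedError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

_FORMATS = ("sbml", "json")


def _guess_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return "json" if suffix == ".json" else "sbml"


def _identify_biomass(cmodel: cobra.Model) -> str:
    """Biomass reaction id: objective annotation first, then id/name match.

    Ambiguity (several objective reactions, or several 'biomass' candidates
    with no objective) is an error rather than a guess.
    """
    objective_rxns = [
        r.id for r in cmodel.reactions if r.objective_coefficient not in (0, 0.0)
    ]
    if len(objective_rxns) == 1:
        return objective_rxns[0]
    if len(objective_rxns) > 1:
        raise BiomassNotIdentifiedError(
            f"{cmodel.id}: multiple objective reactions {objective_rxns}; "
            "biomass not identified — set a single objective or override"
        )
    named = [
        r.id
        for r in cmodel.reactions
        if "biomass" in r.id.lower() or "biomass" in (r.name or "").lower()
    ]
    if len(named) == 1:
        return named[0]
    if not named:
        raise BiomassNotIdentifiedError(
            f"{cmodel.id}: biomass not identified — no objective annotation and "
            "no reaction id/name containing 'biomass'; supply biomass_reaction_id"
        )
    raise BiomassNotIdentifiedError(
        f"{cmodel.id}: biomass not identified — ambiguous candidates {named}"
    )


def from_cobra(cmodel: cobra.Model, biomass_reaction_id: str | None = None) -> MetabolicModel:
    """Convert a :class:`cobra.Model` to the package representation."""
    model = MetabolicModel(model_id=cmodel.id or "model")
    for met in cmodel.metabolites:
        model.metabolites.append(
            Metabolite(id=met.id, name=met.name or "", compartment=met.compartment or "")
        )
    for rxn in cmodel.reactions:
        model.reactions.append(
            Reaction(
                id=rxn.id,
                name=rxn.name or "",
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
            )
        )
    if biomass_reaction_id is None:
        biomass_reaction_id = _identify_biomass(cmodel)
    model.biomass_reaction_id = biomass_reaction_id
    # annotated boundary reactions win over the single-metabolite heuristic;
    # the biomass sink is never an exchange
    annotated = {r.id for r in cmodel.boundary} - {biomass_reaction_id}
    model.exchange_reaction_ids = annotated | model.detect_exchanges()
    model.validate()
    return model


def to_cobra(model: MetabolicModel) -> cobra.Model:
    """Convert back to a :class:`cobra.Model` (for SBML output and cross-checks)."""
    cmodel = cobra.Model(model.model_id)
    compartments = {m.compartment or "c" for m in model.metabolites}
    cmodel.compartments = {c: c for c in compartments}
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    cmodel.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        crxn = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(crxn)
    cmodel.add_reactions(rxns)
    for r in model.reactions:
        cmodel.reactions.get_by_id(r.id).add_metabolites(
            {mets[m]: c for m, c in r.stoichiometry.items()}
        )
    if model.biomass_reaction_id is not None:
        cmodel.objective = model.biomass_reaction_id
    return cmodel


def _to_cobra_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.model_id,
        "version": "1",
        "compartments": sorted({m.compartment for m in model.metabolites if m.compartment}),
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "objective_coefficient": 1.0 if r.id == model.biomass_reaction_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [],
        "exchanges": sorted(model.exchange_reaction_ids),
    }


def load_model(
    path: str | Path,
    format: str | None = None,
    biomass_reaction_id: str | None = None,
) -> MetabolicModel:
    """Load a model from SBML (Level 3 + FBC) or COBRA JSON.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"sbml"`` or ``"json"``; inferred from the suffix when omitted.
    biomass_reaction_id:
        Explicit override when the model carries no usable biomass annotation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _guess_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "json":
        raw = json.loads(path.read_text())
        model = _model_from_json_dict(raw, biomass_reaction_id)
    else:
        try:
            cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises a zoo of error types
            raise ModelValidationError(f"cannot parse SBML file {path}: {exc}") from exc
        model = from_cobra(cmodel, biomass_reaction_id)
    model.validate()
    return model


def _model_from_json_dict(raw: dict, biomass_reaction_id: str | None) -> MetabolicModel:
    try:
        model = MetabolicModel(model_id=raw.get("id", "model"))
        for met in raw["metabolites"]:
            model.metabolites.append(
                Metabolite(
                    id=met["id"],
                    name=met.get("name", ""),
                    compartment=met.get("compartment", ""),
                )
            )
        objective_rxns = []
        for rxn in raw["reactions"]:
            model.reactions.append(
                Reaction(
                    id=rxn["id"],
                    name=rxn.get("name", ""),
                    lower_bound=float(rxn.get("lower_bound", 0.0)),
                    upper_bound=float(rxn.get("upper_bound", 1000.0)),
                    stoichiometry={m: float(c) for m, c in rxn.get("metabolites", {}).items()},
                )
            )
            if rxn.get("objective_coefficient", 0.0):
                objective_rxns.append(rxn["id"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelValidationError(f"malformed COBRA JSON: {exc}") from exc
    if biomass_reaction_id is not None:
        model.biomass_reaction_id = biomass_reaction_id
    elif len(objective_rxns) == 1:
        model.biomass_reaction_id = objective_rxns[0]
    else:
        named = [r.id for r in model.reactions if "biomass" in r.id.lower()]
        if len(named) == 1:
            model.biomass_reaction_id = named[0]
        else:
            raise BiomassNotIdentifiedError(
                f"{model.model_id}: biomass not identified in JSON model"
            )
    declared = set(raw.get("exchanges", []))
    model.exchange_reaction_ids = declared | model.detect_exchanges()
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as COBRA JSON (byte-stable) or SBML Level 3 + FBC."""
    model.validate()
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "json":
        payload = json.dumps(_to_cobra_json_dict(model), indent=1, sort_keys=True)
        path.write_text(payload + "\n")
    else:
        cobra.io.write_sbml_model(to_cobra(model), str(path))
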