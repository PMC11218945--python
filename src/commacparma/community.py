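"""Joint community model construction.

Two or more single-species models are merged into one community network with a
shared extracellular compartment (the metabolite pool).  Each species keeps its
internal network under a ``species:`` prefix; every former per-species exchange
reaction of an extracellular metabolite becomes an internal transfer between
that species and the pool, and one new community exchange reaction per pool
metabolite connects the pool to the environment.

Direction conventions (all fluxes become nonnegative after splitting):

* transfer reaction (``species:EX_x``): positive flux = secretion into the
  pool, negative flux = uptake from the pool;
* community exchange (``EXC_x``): positive flux = export to the environment,
  negative flux = import from the environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .model import MetabolicModel, Metabolite, ModelValidationError, Reaction

#: default bound (mmol gDW^-1 h^-1) for each direction of a community exchange
DEFAULT_EXCHANGE_BOUND = 1000.0

POOL_COMPARTMENT = "pool"
COMMUNITY_EXCHANGE = "community_exchange"
EXCHANGE_PREFIX = "EXC_"


@dataclass
class CommunityModel:
    """Joint stoichiometric network of an n-species synthetic community.

    ``reactions`` hold the joint matrix S^c as per-reaction sparse columns.
    ``provenance`` maps each joint reaction back to (species_id, original
    reaction id, direction), where direction is ``as_is`` before splitting and
    ``forward``/``backward`` afterwards.
    """

    species: list[str] = field(default_factory=list)
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartment_of: dict[str, str] = field(default_factory=dict)  # met -> species or pool
    species_of_reaction: dict[str, str] = field(default_factory=dict)
    biomass_of: dict[str, str] = field(default_factory=dict)
    community_exchange_ids: set[str] = field(default_factory=set)
    #: (species_id, pool metabolite id) -> transfer reaction id
    transfer_of: dict[tuple[str, str], str] = field(default_factory=dict)
    provenance: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    # -- lookups -----------------------------------------------------------

    def reaction(self, rxn_id: str) -> Reaction:
        idx = self._index().get(rxn_id)
        if idx is None:
            raise KeyError(rxn_id)
        return self.reactions[idx]

    def _index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    @property
    def pool_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites if self.compartment_of[m.id] == POOL_COMPARTMENT]

    def community_exchange_of(self, pool_met: str) -> str:
        return EXCHANGE_PREFIX + pool_met

    def can_uptake(self, species: str, pool_met: str) -> bool:
        """True when the species' transfer reaction admits pool -> species flux."""
        rxn_id = self.transfer_of.get((species, pool_met))
        return rxn_id is not None and self.reaction(rxn_id).lower_bound < 0

    def can_secrete(self, species: str, pool_met: str) -> bool:
        rxn_id = self.transfer_of.get((species, pool_met))
        return rxn_id is not None and self.reaction(rxn_id).upper_bound > 0

    def validate(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        rxn_ids = {r.id for r in self.reactions}
        if len(met_ids) != len(self.metabolites) or len(rxn_ids) != len(self.reactions):
            raise ModelValidationError("duplicate ids in community model")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(f"reaction {r.id}: inverted bounds")
            for m in r.stoichiometry:
                if m not in met_ids:
                    raise ModelValidationError(f"reaction {r.id}: unknown metabolite {m}")
            if r.id not in self.species_of_reaction:
                raise ModelValidationError(f"reaction {r.id}: no species tag")
        for s, b in self.biomass_of.items():
            if b not in rxn_ids:
                raise ModelValidationError(f"biomass of {s} missing: {b}")


def _namespaced(species: str, identifier: str) -> str:
    return f"{species}:{identifier}"


def join_models(
    models: list[MetabolicModel],
    exchange_bound: float = DEFAULT_EXCHANGE_BOUND,
) -> CommunityModel:
    """Merge per-species models into one joint community model.

    Extracellular metabolites (those moved by each species' exchange
    reactions) with identical ids are merged into one pool metabolite; the
    species' exchange reactions become internal transfers to the pool, and a
    new reversible community exchange reaction per pool metabolite connects it
    to the environment with bounds ``[-exchange_bound, exchange_bound]``.
    """
    if len(models) < 2:
        raise ValueError("a community needs at least two models")
    species_ids = [m.model_id for m in models]
    if len(set(species_ids)) != len(species_ids):
        raise ValueError(f"duplicate species ids: {species_ids}")

    com = CommunityModel(species=list(species_ids))
    pool_seen: set[str] = set()

    for model in models:
        model.validate()
        s = model.model_id
        if model.biomass_reaction_id is None:
            raise ModelValidationError(f"{s}: biomass reaction required to join")
        if not model.exchange_reaction_ids:
            raise ModelValidationError(
                f"{s}: no extracellular (exchange) metabolites; cannot couple"
            )
        exchanged = {
            ex: model.exchanged_metabolite(ex) for ex in sorted(model.exchange_reaction_ids)
        }
        # internal (namespaced) metabolites: everything, including the species'
        # own extracellular compartment, keeps a per-species copy
        for met in model.metabolites:
            mid = _namespaced(s, met.id)
            com.metabolites.append(Metabolite(id=mid, name=met.name, compartment=mid.split(":")[0]))
            com.compartment_of[mid] = s
        for rxn in model.reactions:
            rid = _namespaced(s, rxn.id)
            stoich = {_namespaced(s, m): c for m, c in rxn.stoichiometry.items()}
            if rxn.id in exchanged:
                # former exchange reaction becomes a species <-> pool transfer;
                # the original convention (positive flux drains the species'
                # extracellular metabolite) makes positive flux = secretion
                pool_met = exchanged[rxn.id]
                if pool_met not in pool_seen:
                    pool_seen.add(pool_met)
                    com.metabolites.append(
                        Metabolite(id=pool_met, name=pool_met, compartment=POOL_COMPARTMENT)
                    )
                    com.compartment_of[pool_met] = POOL_COMPARTMENT
                # original boundary stoichiometry is {met: c} with c != 0;
                # pair it with the pool so matter is conserved
                (orig_met, orig_coef), = [
                    (m, c) for m, c in rxn.stoichiometry.items() if c != 0
                ]
                stoich = {_namespaced(s, orig_met): orig_coef, pool_met: -orig_coef}
                com.transfer_of[(s, pool_met)] = rid
            com.reactions.append(
                Reaction(
                    id=rid,
                    name=rxn.name,
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    stoichiometry=stoich,
                )
            )
            com.species_of_reaction[rid] = s
            com.provenance[rid] = (s, rxn.id, "as_is")
        com.biomass_of[s] = _namespaced(s, model.biomass_reaction_id)

    # one community exchange per pool metabolite, environment <-> pool
    for pool_met in sorted(pool_seen):
        ex_id = EXCHANGE_PREFIX + pool_met
        com.reactions.append(
            Reaction(
                id=ex_id,
                name=f"community exchange of {pool_met}",
                lower_bound=-exchange_bound,
                upper_bound=exchange_bound,
                stoichiometry={pool_met: -1.0},
            )
        )
        com.species_of_reaction[ex_id] = COMMUNITY_EXCHANGE
        com.community_exchange_ids.add(ex_id)
        com.provenance[ex_id] = (COMMUNITY_EXCHANGE, ex_id, "as_is")

    com.validate()
    return com


def shared_metabolites(community: CommunityModel, pair: tuple[str, str]) -> set[str]:
    """Overlapped metabolites of a pair: pool metabolites BOTH species can take up.

    This set is the denominator of the pairwise competition score.
    """
    for s in pair:
        if s not in community.species:
            raise KeyError(f"unknown species {s!r}")
    a, b = pair
    return {
        met
        for met in community.pool_metabolites
        if community.can_uptake(a, met) and community.can_uptake(b, met)
    }


# -- community model (de)serialisation -------------------------------------


def save_community(community: CommunityModel, path: str | Path) -> None:
    """Write a community model to JSON (sorted keys, byte-stable)."""
    community.validate()
    payload = {
        "species": community.species,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": community.compartment_of[m.id]}
            for m in community.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "species": community.species_of_reaction[r.id],
            }
            for r in community.reactions
        ],
        "biomass_of": community.biomass_of,
        "community_exchange_ids": sorted(community.community_exchange_ids),
        "transfer_of": [
            {"species": s, "metabolite": m, "reaction": r}
            for (s, m), r in sorted(community.transfer_of.items())
        ],
        "provenance": {
            rid: list(val) for rid, val in sorted(community.provenance.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_community(path: str | Path) -> CommunityModel:
    raw = json.loads(Path(path).read_text())
    com = CommunityModel(species=list(raw["species"]))
    for met in raw["metabolites"]:
        com.metabolites.append(
            Metabolite(id=met["id"], name=met.get("name", ""), compartment=met["compartment"])
        )
        com.compartment_of[met["id"]] = met["compartment"]
    for rxn in raw["reactions"]:
        com.reactions.append(
            Reaction(
                id=rxn["id"],
                name=rxn.get("name", ""),
                lower_bound=float(rxn["lower_bound"]),
                upper_bound=float(rxn["upper_bound"]),
                stoichiometry={m: float(c) for m, c in rxn["metabolites"].items()},
            )
        )
        com.species_of_reaction[rxn["id"]] = rxn["species"]
    com.biomass_of = dict(raw["biomass_of"])
    com.community_exchange_ids = set(raw["community_exchange_ids"])
    com.transfer_of = {
        (t["species"], t["metabolite"]): t["reaction"] for t in raw["transfer_of"]
    }
    com.provenance = {rid: tuple(val) for rid, val in raw.get("provenance", {}).items()}
    com.validate()
    return com
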