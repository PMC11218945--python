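"""In-memory representation of a single-species genome-scale metabolic model.

A genome-scale metabolic model (GEM) is a stoichiometric reconstruction of an
organism's reaction network: a set of metabolites M, a set of reactions R with
flux bounds (mmol gDW^-1 h^-1), a sparse stoichiometric matrix S whose entry
S[i, j] is the coefficient of metabolite i in reaction j, one biomass reaction
acting as the growth objective, and a set of exchange reactions that move
metabolites across the system boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class BiomassNotIdentifiedError(ModelValidationError):
    """Raised when no (or more than one) biomass reaction can be identified."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    # metabolite_id -> stoichiometric coefficient (negative = consumed)
    stoichiometry: dict[str, float] = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    """One species' stoichiometric network with bounds and annotations.

    Invariants (checked by :meth:`validate`):

    * every stoichiometry key references an existing metabolite,
    * ``lower_bound <= upper_bound`` for every reaction,
    * ``biomass_reaction_id`` names an existing reaction,
    * every exchange reaction touches exactly one metabolite.
    """

    model_id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_reaction_id: str | None = None
    exchange_reaction_ids: set[str] = field(default_factory=set)

    # -- lookups -----------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def stoichiometry(self) -> dict[tuple[str, str], float]:
        """Sparse (metabolite_id, reaction_id) -> coefficient mapping."""
        out: dict[tuple[str, str], float] = {}
        for r in self.reactions:
            for met_id, coef in r.stoichiometry.items():
                if coef != 0:
                    out[(met_id, r.id)] = coef
        return out

    # -- exchange handling -------------------------------------------------

    def detect_exchanges(self) -> set[str]:
        """Single-metabolite boundary reactions, plus ``EX_``-prefixed ids.

        Detection depends only on each reaction's own stoichiometry, so it is
        invariant to reaction ordering.  The biomass reaction is never an
        exchange, even when it drains a single precursor.
        """
        found = set()
        for r in self.reactions:
            if r.id == self.biomass_reaction_id:
                continue
            nonzero = [c for c in r.stoichiometry.values() if c != 0]
            if len(nonzero) == 1:
                found.add(r.id)
            elif r.id.upper().startswith("EX_"):
                found.add(r.id)
        return found

    def exchanged_metabolite(self, rxn_id: str) -> str:
        """The single metabolite moved by an exchange reaction."""
        rxn = self.reaction(rxn_id)
        mets = [m for m, c in rxn.stoichiometry.items() if c != 0]
        if len(mets) != 1:
            raise ModelValidationError(
                f"exchange reaction {rxn_id!r} touches {len(mets)} metabolites"
            )
        return mets[0]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        met_ids = set(self.metabolite_ids)
        rxn_ids = set(self.reaction_ids)
        if len(met_ids) != len(self.metabolites):
            raise ModelValidationError(f"{self.model_id}: duplicate metabolite ids")
        if len(rxn_ids) != len(self.reactions):
            raise ModelValidationError(f"{self.model_id}: duplicate reaction ids")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            for met_id in r.stoichiometry:
                if met_id not in met_ids:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in rxn_ids:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for ex_id in self.exchange_reaction_ids:
            if ex_id not in rxn_ids:
                raise ModelValidationError(f"exchange reaction {ex_id!r} not in model")
            self.exchanged_metabolite(ex_id)
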