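"""Canonical form for the feasibility programs.

The joint community model is preprocessed in three steps, in this order:

1. blocked reactions (flux range within ``[-tol, tol]`` under flux variability
   analysis with open community exchanges and no biomass constraint) are
   removed — detection runs on the unsplit model so that the futile two-cycles
   introduced by splitting cannot mask a dead end;
2. every reversible reaction is decomposed into irreversible forward and
   backward copies, so all fluxes are nonnegative and the irreversible set
   equals the whole reaction set;
3. reference fluxes are computed: each species' maximum biomass flux (plain
   FBA on the joint model, partner unconstrained) and, on demand, the minimum
   uptake flux a consumer requires for growth (FVA-style minimisation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._lp import FluxProblem, SolverError
from .community import CommunityModel, POOL_COMPARTMENT
from .model import Reaction

#: flux below which a reaction is considered blocked during FVA
DEFAULT_FVA_TOLERANCE = 1e-6
#: flux below which a value is treated as zero inside feasibility programs
DEFAULT_ZERO_TOLERANCE = 1e-9

FORWARD_SUFFIX = "__f"
BACKWARD_SUFFIX = "__b"


class InfeasibleCommunityError(RuntimeError):
    """The joint community admits no steady state at all."""


@dataclass
class PreprocessedCommunity:
    """Irreversible, unblocked community model plus reference fluxes.

    ``uptake_of``/``secretion_of`` map ``(species, pool metabolite)`` to the
    irreversible transfer copy moving the metabolite into / out of the
    species; ``import_of``/``export_of`` do the same for the community
    exchange of each pool metabolite.  A key is absent when that direction
    does not exist (bounds never allowed it or it was blocked and removed).
    """

    community: CommunityModel
    blocked_removed: set[str] = field(default_factory=set)
    split_map: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    v_biomass_max: dict[str, float] = field(default_factory=dict)
    fva_tolerance: float = DEFAULT_FVA_TOLERANCE
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE
    blocked_shared_uptakes: set[tuple[str, str]] = field(default_factory=set)
    uptake_of: dict[tuple[str, str], str] = field(default_factory=dict)
    secretion_of: dict[tuple[str, str], str] = field(default_factory=dict)
    import_of: dict[str, str] = field(default_factory=dict)
    export_of: dict[str, str] = field(default_factory=dict)
    #: community exchange ids in the split model (the set Exchange)
    exchange_ids: list[str] = field(default_factory=list)

    def problem(self) -> FluxProblem:
        """Fresh LP over the split flux cone (variables in model order)."""
        return FluxProblem(self.community.reactions, tolerance=self.zero_tolerance)

    def can_uptake(self, species: str, metabolite: str) -> bool:
        """True when the species had an uptake direction for the metabolite,
        whether it survived preprocessing or was blocked."""
        key = (species, metabolite)
        return key in self.uptake_of or key in self.blocked_shared_uptakes

    def overlapped_metabolites(self, pair: tuple[str, str]) -> set[str]:
        """Pool metabolites both species of the pair can take up (the
        competition-score denominator); blocked uptake directions count."""
        for s in pair:
            if s not in self.community.species:
                raise KeyError(f"unknown species {s!r}")
        a, b = pair
        mets = {m for s, m in self.uptake_of} | {m for s, m in self.blocked_shared_uptakes}
        return {m for m in mets if self.can_uptake(a, m) and self.can_uptake(b, m)}

    def biomass_reaction(self, species: str) -> str:
        return self.community.biomass_of[species]


def find_blocked_reactions(
    community: CommunityModel, tolerance: float = DEFAULT_FVA_TOLERANCE
) -> set[str]:
    """Reactions whose FVA flux range lies within ``[-tol, tol]``.

    No biomass constraint is imposed and community exchanges stay at their
    default (open) bounds.  Equivalent to 2n single-reaction LPs; a reaction
    already seen carrying flux in a previous optimum is skipped.
    """
    problem = FluxProblem(community.reactions)
    if not problem.is_feasible():
        raise InfeasibleCommunityError("community cannot achieve steady state")
    alive: set[str] = set()
    blocked: set[str] = set()
    for rxn in community.reactions:
        if rxn.id in alive:
            continue
        vmax = problem.optimize(rxn.id, "max")
        if vmax is None:
            raise SolverError(f"FVA failed on reaction {rxn.id}")
        if vmax > tolerance:
            _collect_alive(problem, alive, tolerance)
            continue
        vmin = problem.optimize(rxn.id, "min")
        if vmin is None:
            raise SolverError(f"FVA failed on reaction {rxn.id}")
        if vmin < -tolerance:
            _collect_alive(problem, alive, tolerance)
        else:
            blocked.add(rxn.id)
    return blocked


def _collect_alive(problem: FluxProblem, alive: set[str], tolerance: float) -> None:
    for rid, value in problem.primal().items():
        if abs(value) > tolerance:
            alive.add(rid)


def _directional_ranges(
    community: CommunityModel, reaction_ids: list[str]
) -> dict[str, tuple[float, float]]:
    """FVA ranges for selected reactions (used for blocked uptake directions)."""
    problem = FluxProblem(community.reactions)
    out = {}
    for rid in reaction_ids:
        vmax = problem.optimize(rid, "max")
        vmin = problem.optimize(rid, "min")
        if vmax is None or vmin is None:
            raise SolverError(f"FVA failed on reaction {rid}")
        out[rid] = (vmin, vmax)
    return out


def split_reversible(
    community: CommunityModel,
    blocked: set[str] | None = None,
    fva_tolerance: float = DEFAULT_FVA_TOLERANCE,
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE,
    transfer_ranges: dict[str, tuple[float, float]] | None = None,
) -> PreprocessedCommunity:
    """Remove ``blocked`` reactions and split the rest into irreversible copies.

    A reversible reaction ``v`` with bounds ``[lb, ub]`` (lb < 0 < ub) becomes
    a forward copy ``v__f`` with bounds ``[0, ub]`` and a backward copy
    ``v__b`` with negated stoichiometry and bounds ``[0, -lb]``; irreversible
    reactions pass through unchanged.  ``transfer_ranges`` (FVA ranges of
    species transfer reactions on the unsplit model) feed the record of
    blocked uptake directions used by the competition blocked-reaction rule.
    """
    blocked = blocked or set()
    split = CommunityModel(species=list(community.species))
    split.metabolites = list(community.metabolites)
    split.compartment_of = dict(community.compartment_of)
    split.biomass_of = dict(community.biomass_of)
    pre = PreprocessedCommunity(
        community=split,
        blocked_removed=set(blocked),
        fva_tolerance=fva_tolerance,
        zero_tolerance=zero_tolerance,
    )

    transfer_by_rxn = {rid: key for key, rid in community.transfer_of.items()}

    def _add(rxn: Reaction, species: str, prov: tuple[str, str, str]) -> None:
        split.reactions.append(rxn)
        split.species_of_reaction[rxn.id] = species
        split.provenance[rxn.id] = prov

    for rxn in community.reactions:
        species = community.species_of_reaction[rxn.id]
        is_exchange = rxn.id in community.community_exchange_ids
        transfer_key = transfer_by_rxn.get(rxn.id)
        if rxn.id in blocked:
            if transfer_key is not None and rxn.lower_bound < 0:
                pre.blocked_shared_uptakes.add(transfer_key)
            continue
        prov_species, prov_orig, _ = community.provenance.get(
            rxn.id, (species, rxn.id, "as_is")
        )
        forward_id: str | None = None
        backward_id: str | None = None
        if rxn.lower_bound >= 0:
            forward_id = rxn.id
            _add(
                Reaction(rxn.id, rxn.name, rxn.lower_bound, rxn.upper_bound,
                         dict(rxn.stoichiometry)),
                species, (prov_species, prov_orig, "as_is"),
            )
        elif rxn.upper_bound <= 0:
            backward_id = rxn.id + BACKWARD_SUFFIX
            _add(
                Reaction(backward_id, rxn.name, -rxn.upper_bound, -rxn.lower_bound,
                         {m: -c for m, c in rxn.stoichiometry.items()}),
                species, (prov_species, prov_orig, "backward"),
            )
        else:
            forward_id = rxn.id + FORWARD_SUFFIX
            backward_id = rxn.id + BACKWARD_SUFFIX
            _add(
                Reaction(forward_id, rxn.name, 0.0, rxn.upper_bound,
                         dict(rxn.stoichiometry)),
                species, (prov_species, prov_orig, "forward"),
            )
            _add(
                Reaction(backward_id, rxn.name, 0.0, -rxn.lower_bound,
                         {m: -c for m, c in rxn.stoichiometry.items()}),
                species, (prov_species, prov_orig, "backward"),
            )
        pre.split_map[rxn.id] = (forward_id, backward_id)

        if is_exchange:
            pool_met = rxn.id[len("EXC_"):]
            if forward_id is not None:
                split.community_exchange_ids.add(forward_id)
                pre.export_of[pool_met] = forward_id
            if backward_id is not None:
                split.community_exchange_ids.add(backward_id)
                pre.import_of[pool_met] = backward_id
        if transfer_key is not None:
            species_id, pool_met = transfer_key
            if forward_id is not None:
                pre.secretion_of[transfer_key] = forward_id
            if backward_id is not None:
                pre.uptake_of[transfer_key] = backward_id
            split.transfer_of[transfer_key] = forward_id or backward_id
            # an uptake direction whose FVA range never reaches below -tol is
            # blocked even when the whole reaction is not
            if transfer_ranges is not None and rxn.id in transfer_ranges:
                vmin, _ = transfer_ranges[rxn.id]
                if rxn.lower_bound < 0 and vmin >= -fva_tolerance:
                    pre.blocked_shared_uptakes.add(transfer_key)

    pre.exchange_ids = sorted(split.community_exchange_ids)
    split.validate()
    return pre


def preprocess(
    community: CommunityModel,
    fva_tolerance: float = DEFAULT_FVA_TOLERANCE,
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE,
    compute_biomass: bool = True,
) -> PreprocessedCommunity:
    """Full pipeline: blocked removal, splitting, biomass maxima."""
    blocked = find_blocked_reactions(community, fva_tolerance)
    # biomass reactions stay even when blocked: a species that cannot grow is
    # a result (max biomass 0), not a structural artifact
    blocked -= set(community.biomass_of.values())
    transfer_ids = [
        rid for rid in community.transfer_of.values() if rid not in blocked
    ]
    ranges = _directional_ranges(community, transfer_ids)
    pre = split_reversible(
        community,
        blocked=blocked,
        fva_tolerance=fva_tolerance,
        zero_tolerance=zero_tolerance,
        transfer_ranges=ranges,
    )
    if compute_biomass:
        problem = pre.problem()
        for species in pre.community.species:
            max_biomass(pre, species, problem=problem)
    return pre


def max_biomass(
    pre: PreprocessedCommunity, species: str, problem: FluxProblem | None = None
) -> float:
    """Maximum biomass flux of one species on the joint model (plain FBA).

    The partner's biomass is left unconstrained; the result is cached in
    ``v_biomass_max``.
    """
    if species in pre.v_biomass_max:
        return pre.v_biomass_max[species]
    problem = problem or pre.problem()
    value = problem.optimize(pre.biomass_reaction(species), "max")
    if value is None:
        raise InfeasibleCommunityError("community cannot achieve steady state")
    value = max(value, 0.0)
    pre.v_biomass_max[species] = value
    return value


def min_required_uptake(
    pre: PreprocessedCommunity,
    consumer: str,
    metabolite: str,
    fraction: float = 1.0,
    partner_fraction: float | None = None,
    problem: FluxProblem | None = None,
) -> float:
    """Minimum uptake flux of ``metabolite`` the consumer needs for growth.

    FVA-style minimisation of the consumer's uptake transfer subject to the
    consumer's biomass being at least ``fraction`` of its maximum (all other
    species floored at ``partner_fraction`` of theirs when given).  The result
    is the demand flux pinned by the commensalism/parasitism program.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    key = (consumer, metabolite)
    if key not in pre.uptake_of:
        raise KeyError(f"{consumer} has no uptake reaction for {metabolite}")
    problem = problem or pre.problem()
    slack = 1.0 - 1e-9  # keep the floor attainable at fraction == 1
    with problem.scoped():
        problem.set_lower(
            pre.biomass_reaction(consumer),
            fraction * max_biomass(pre, consumer) * slack,
        )
        if partner_fraction is not None:
            for other in pre.community.species:
                if other != consumer:
                    problem.set_lower(
                        pre.biomass_reaction(other),
                        partner_fraction * max_biomass(pre, other) * slack,
                    )
        value = problem.optimize(pre.uptake_of[key], "min")
    if value is None:
        raise InfeasibleCommunityError(
            f"biomass floor infeasible while minimising uptake of {metabolite}"
        )
    return max(value, 0.0) if not math.isnan(value) else 0.0
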