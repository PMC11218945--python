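"""COMMA: per-metabolite competition detection.

Two species have the potential to compete for a shared metabolite when no
feasible community flux state lets both survive without consuming it.  The
test is a mixed-integer feasibility program on the preprocessed (irreversible,
unblocked) joint model:

* both species' uptake fluxes of the metabolite are fixed to zero,
* each species' biomass flux must reach at least ``alpha`` times its maximum,
* mass balance ``S^c v = 0`` and box bounds hold with ``v >= 0``,
* at least one community exchange must carry flux of at least ``beta``
  (binary indicator per exchange, at least one indicator active), i.e. the
  community genuinely exchanges matter with some environment.

Infeasibility means no medium supports both species without the metabolite —
a competition verdict.  A feasible witness is a medium (active exchange set)
in which both survive while ignoring the metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from ._lp import FluxProblem, SolverError
from .preprocessing import PreprocessedCommunity, max_biomass

DEFAULT_ALPHA = 0.1
DEFAULT_BETA = 0.01


@dataclass(frozen=True)
class CommaConfig:
    """Competition-program parameters.

    alpha:
        biomass floor, fraction of each species' maximum biomass flux.
    beta:
        minimum flux (mmol gDW^-1 h^-1) an exchange must carry to count as
        active.
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    integer_tolerance: float = 1e-6
    zero_tolerance: float = 1e-9
    #: treat a blocked uptake reaction as an immediate competition verdict
    blocked_uptake_is_competed: bool = True

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")


class Verdict(str, Enum):
    COMPETED = "competed"
    NOT_COMPETED = "not_competed"
    COMPETED_BLOCKED_UPTAKE = "competed_blocked_uptake"


class SolverStatus(str, Enum):
    FEASIBLE = "feasible"
    INFEASIBLE = "infeasible"
    ERROR = "error"


@dataclass
class CompetitionResult:
    metabolite: str
    pair: tuple[str, ...]
    verdict: Verdict | None
    solver_status: SolverStatus
    witness: dict[str, float] | None = None
    active_exchanges: set[str] | None = None

    @property
    def competed(self) -> bool:
        return self.verdict in (Verdict.COMPETED, Verdict.COMPETED_BLOCKED_UPTAKE)


@dataclass
class PairwiseSummary:
    """Competition profile of one species pair.

    ``competition_score`` (the pair's competition rate) is the number of
    competed metabolites divided by the number of overlapped metabolites; it
    is None when the pair overlaps on no metabolite.
    """

    pair: tuple[str, str]
    n_overlapped: int
    n_competed: int
    competition_score: float | None
    per_metabolite: list[CompetitionResult] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(1 for r in self.per_metabolite if r.solver_status == SolverStatus.ERROR)


def _apply_survival_floors(problem: FluxProblem, pre: PreprocessedCommunity, alpha: float):
    for species in pre.community.species:
        problem.set_lower(
            pre.biomass_reaction(species), alpha * max_biomass(pre, species)
        )


def _add_active_exchange_milp(scope, problem: FluxProblem, pre, beta: float):
    """Eqs: v_k >= beta * theta_k for every community exchange, sum theta >= 1."""
    thetas = {}
    for ex_id in pre.exchange_ids:
        theta = scope.add_binary(f"theta__{ex_id}")
        scope.add_constraint(
            problem.variables[ex_id] - beta * theta, lb=0, name=f"act__{ex_id}"
        )
        thetas[ex_id] = theta
    scope.add_constraint(sum(thetas.values()), lb=1, name="one_active_exchange")
    return thetas


def _species_with_uptake(pre: PreprocessedCommunity, metabolite: str) -> list[str]:
    return [s for s in pre.community.species if (s, metabolite) in pre.uptake_of]


def comma_feasibility(
    pre: PreprocessedCommunity,
    metabolite: str,
    deactivate: list[str],
    config: CommaConfig,
    problem: FluxProblem | None = None,
    want_witness: bool = True,
) -> CompetitionResult:
    """Solve the competition MILP with ``deactivate`` species' uptakes zeroed."""
    problem = problem or pre.problem()
    pair = tuple(pre.community.species)
    try:
        with problem.scoped() as scope:
            for species in deactivate:
                key = (species, metabolite)
                if key in pre.uptake_of:
                    problem.fix(pre.uptake_of[key], 0.0)
            _apply_survival_floors(problem, pre, config.alpha)
            thetas = _add_active_exchange_milp(scope, problem, pre, config.beta)
            feasible = problem.is_feasible()
            if feasible and want_witness:
                witness = problem.primal()
                active = {
                    ex
                    for ex, theta in thetas.items()
                    if theta.primal is not None and theta.primal > 0.5
                }
            else:
                witness, active = None, None
    except SolverError:
        return CompetitionResult(
            metabolite, pair, verdict=None, solver_status=SolverStatus.ERROR
        )
    if feasible:
        return CompetitionResult(
            metabolite, pair, Verdict.NOT_COMPETED, SolverStatus.FEASIBLE,
            witness={k: v for k, v in witness.items()} if witness else None,
            active_exchanges=active,
        )
    return CompetitionResult(metabolite, pair, Verdict.COMPETED, SolverStatus.INFEASIBLE)


def comma_test(
    pre: PreprocessedCommunity,
    metabolite: str,
    config: CommaConfig | None = None,
    problem: FluxProblem | None = None,
) -> CompetitionResult:
    """Competition test for a shared metabolite of a pairwise community.

    Both species' uptake fluxes for the metabolite are fixed to zero;
    infeasibility of the resulting program is a ``competed`` verdict.
    """
    config = config or CommaConfig()
    if not any(pre.can_uptake(s, metabolite) for s in pre.community.species):
        raise KeyError(f"no species has an uptake reaction for {metabolite!r}")
    # blocked-removed uptakes are structurally zero; only surviving uptake
    # copies need an explicit deactivation constraint
    consumers = _species_with_uptake(pre, metabolite)
    return comma_feasibility(pre, metabolite, consumers, config, problem=problem)


def comma_test_blocked_rule(
    pre: PreprocessedCommunity,
    metabolite: str,
    config: CommaConfig | None = None,
    problem: FluxProblem | None = None,
) -> CompetitionResult:
    """Apply the blocked-uptake shortcut, else delegate to :func:`comma_test`.

    When either species' uptake reaction for the metabolite was blocked, the
    metabolite is reported as competed without solving (the verdict the
    algorithm assigns to shared metabolites with blocked reactions).  The
    shortcut can be disabled via ``CommaConfig.blocked_uptake_is_competed``.
    """
    config = config or CommaConfig()
    if config.blocked_uptake_is_competed:
        blocked = [
            s
            for s in pre.community.species
            if (s, metabolite) in pre.blocked_shared_uptakes
        ]
        if blocked:
            return CompetitionResult(
                metabolite,
                tuple(pre.community.species),
                Verdict.COMPETED_BLOCKED_UPTAKE,
                SolverStatus.INFEASIBLE,
            )
    return comma_test(pre, metabolite, config, problem=problem)


def comma_single(
    pre: PreprocessedCommunity,
    metabolite: str,
    species: str,
    config: CommaConfig | None = None,
    problem: FluxProblem | None = None,
) -> SolverStatus:
    """Single-deactivation program: only ``species``' uptake is zeroed.

    The alternative competition criterion declares competition when the
    program is infeasible for *both* species separately.
    """
    config = config or CommaConfig()
    result = comma_feasibility(
        pre, metabolite, [species], config, problem=problem, want_witness=False
    )
    return result.solver_status


def comma_group(
    pre: PreprocessedCommunity,
    metabolite: str,
    species_subset: set[str],
    config: CommaConfig | None = None,
    problem: FluxProblem | None = None,
) -> CompetitionResult:
    """Group extension: uptakes of every species in the subset are zeroed.

    Biomass floors apply to all community members, so the pairwise case with
    the full species set reduces exactly to :func:`comma_test`.
    """
    config = config or CommaConfig()
    if len(species_subset) < 2:
        raise ValueError("group competition needs at least two species")
    unknown = species_subset - set(pre.community.species)
    if unknown:
        raise KeyError(f"unknown species {sorted(unknown)}")
    return comma_feasibility(pre, metabolite, sorted(species_subset), config, problem=problem)


def competition_profile(
    pre: PreprocessedCommunity,
    pair: tuple[str, str] | None = None,
    config: CommaConfig | None = None,
) -> PairwiseSummary:
    """Run the blocked-rule competition test over every overlapped metabolite."""
    config = config or CommaConfig()
    pair = pair or tuple(pre.community.species[:2])  # type: ignore[assignment]
    overlapped = sorted(pre.overlapped_metabolites(pair))
    problem = pre.problem()
    results = []
    for met in overlapped:
        results.append(comma_test_blocked_rule(pre, met, config, problem=problem))
    n_competed = sum(1 for r in results if r.competed)
    score = n_competed / len(overlapped) if overlapped else None
    return PairwiseSummary(
        pair=pair,
        n_overlapped=len(overlapped),
        n_competed=n_competed,
        competition_score=score,
        per_metabolite=results,
    )
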