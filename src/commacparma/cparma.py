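"""CPARMA: commensalism / parasitism / mutualism classification.

For a shared metabolite and an ordered (giver, consumer) species pair, the
question is whether the giver can supply the consumer's demand without paying
a fitness price.  The demand is the consumer's minimum required uptake flux
for growth (FVA minimisation of the uptake transfer with the consumer's
biomass held at its optimum).  The main linear feasibility program pins the
giver's secretion flux of the metabolite to exactly that demand while

* the giver's biomass stays within a fraction ``epsilon`` of its maximum,
* the consumer's biomass reaches at least ``alpha`` of its maximum,
* community import of the tested metabolite is closed, so the giver is the
  sole external source and "supply without fitness price" is well-posed.

Feasible -> commensalism: the consumer grows on a by-product the giver can
afford.  Infeasible -> the parasitism/mutualism branch, disambiguated by two
probe programs:

* environment probe — the giver's secretion relaxes to [0, demand] and
  community import of the metabolite reopens; feasibility means consumer and
  giver plus environment can jointly cover the demand (mutualism/syntrophy);
* forced-supply probe — the secretion stays pinned to the demand but the
  giver's fitness floor drops to ``alpha``; feasibility means the giver could
  supply at a fitness cost (parasitism is possible).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from ._lp import FluxProblem, SolverError
from .preprocessing import (
    InfeasibleCommunityError,
    PreprocessedCommunity,
    max_biomass,
    min_required_uptake,
)

DEFAULT_EPSILON = 0.01
DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class CparmaConfig:
    """Commensalism/parasitism-program parameters.

    alpha:
        consumer survival floor (fraction of its maximum biomass flux).
    epsilon:
        giver fitness slack: the giver's biomass must stay above
        ``(1 - epsilon)`` of its maximum in the main program.
    demand_fraction:
        fraction of the consumer's maximum biomass at which the demanded
        uptake flux is computed (FVA convention: the optimum).
    """

    alpha: float = DEFAULT_ALPHA
    epsilon: float = DEFAULT_EPSILON
    demand_fraction: float = 1.0
    zero_tolerance: float = 1e-9

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if not 0 < self.demand_fraction <= 1:
            raise ValueError("demand_fraction must lie in (0, 1]")


class InteractionVerdict(str, Enum):
    COMMENSALISM = "commensalism"
    PARASITISM_OR_MUTUALISM = "parasitism_or_mutualism"
    MUTUALISM_SYNTROPHY = "mutualism_syntrophy"
    PARASITISM_POSSIBLE = "parasitism_possible"
    NO_DEMAND = "no_demand"
    ERROR = "error"


@dataclass
class InteractionClassification:
    metabolite: str
    giver: str
    consumer: str
    demanded_flux: float
    verdict: InteractionVerdict
    supply_feasible_at_full_fitness: bool = False
    environment_supplement_feasible: bool = False
    forced_supply_feasible: bool = False


def _floors(problem: FluxProblem, pre: PreprocessedCommunity, giver: str,
            consumer: str, giver_fraction: float, consumer_fraction: float) -> None:
    slack = 1.0 - 1e-9
    problem.set_lower(
        pre.biomass_reaction(giver), giver_fraction * max_biomass(pre, giver) * slack
    )
    problem.set_lower(
        pre.biomass_reaction(consumer),
        consumer_fraction * max_biomass(pre, consumer) * slack,
    )


def cparma_test(
    pre: PreprocessedCommunity,
    metabolite: str,
    giver: str,
    consumer: str,
    config: CparmaConfig | None = None,
    problem: FluxProblem | None = None,
) -> InteractionClassification:
    """Classify one giver -> consumer relationship for one shared metabolite."""
    config = config or CparmaConfig()
    if (giver, metabolite) not in pre.secretion_of:
        raise KeyError(f"{giver} has no secretion reaction for {metabolite}")
    if (consumer, metabolite) not in pre.uptake_of:
        raise KeyError(f"{consumer} has no uptake reaction for {metabolite}")
    problem = problem or pre.problem()

    try:
        demanded = min_required_uptake(
            pre,
            consumer,
            metabolite,
            fraction=config.demand_fraction,
            partner_fraction=config.alpha,
            problem=problem,
        )
    except (SolverError, InfeasibleCommunityError):
        return InteractionClassification(
            metabolite, giver, consumer, float("nan"), InteractionVerdict.ERROR
        )
    if demanded <= max(config.zero_tolerance, pre.fva_tolerance):
        return InteractionClassification(
            metabolite, giver, consumer, demanded, InteractionVerdict.NO_DEMAND
        )

    secretion = pre.secretion_of[(giver, metabolite)]
    import_rxn = pre.import_of.get(metabolite)

    def _solve(pin_secretion: bool, close_import: bool, giver_fraction: float) -> bool:
        with problem.scoped():
            if pin_secretion:
                problem.fix(secretion, demanded)
            else:
                problem.set_upper(secretion, demanded)
                problem.set_lower(secretion, 0.0)
            if close_import and import_rxn is not None:
                problem.fix(import_rxn, 0.0)
            _floors(problem, pre, giver, consumer, giver_fraction, config.alpha)
            return problem.is_feasible()

    try:
        main = _solve(pin_secretion=True, close_import=True,
                      giver_fraction=1.0 - config.epsilon)
        if main:
            return InteractionClassification(
                metabolite, giver, consumer, demanded,
                InteractionVerdict.COMMENSALISM,
                supply_feasible_at_full_fitness=True,
            )
        env = _solve(pin_secretion=False, close_import=False,
                     giver_fraction=1.0 - config.epsilon)
        forced = _solve(pin_secretion=True, close_import=True,
                        giver_fraction=config.alpha)
    except SolverError:
        return InteractionClassification(
            metabolite, giver, consumer, demanded, InteractionVerdict.ERROR
        )

    if env:
        verdict = InteractionVerdict.MUTUALISM_SYNTROPHY
    elif forced:
        verdict = InteractionVerdict.PARASITISM_POSSIBLE
    else:
        verdict = InteractionVerdict.PARASITISM_OR_MUTUALISM
    return InteractionClassification(
        metabolite, giver, consumer, demanded, verdict,
        supply_feasible_at_full_fitness=False,
        environment_supplement_feasible=env,
        forced_supply_feasible=forced,
    )


def classify_pair(
    pre: PreprocessedCommunity,
    pair: tuple[str, str] | None = None,
    config: CparmaConfig | None = None,
) -> list[InteractionClassification]:
    """All (metabolite, giver, consumer) classifications for a species pair.

    A triple is tested when the giver possesses a secretion reaction and the
    consumer an uptake reaction for the metabolite; both directions appear
    when both species can secrete and consume.  Per-triple solver errors are
    collected as ``error`` rows and the run continues.
    """
    config = config or CparmaConfig()
    pair = pair or tuple(pre.community.species[:2])  # type: ignore[assignment]
    a, b = pair
    problem = pre.problem()
    out: list[InteractionClassification] = []
    mets = sorted({m for (_s, m) in set(pre.uptake_of) | set(pre.secretion_of)})
    for met in mets:
        for giver, consumer in ((a, b), (b, a)):
            if (giver, met) in pre.secretion_of and (consumer, met) in pre.uptake_of:
                out.append(
                    cparma_test(pre, met, giver, consumer, config, problem=problem)
                )
    return out
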