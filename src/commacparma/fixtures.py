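"""Synthetic model generators with known ground-truth interaction structure.

Three generators cover the test surface without any model downloads:

* :func:`toy_pair` — a fixed two-species pair emulating the classic
  cross-feeding toy topology: each species imports its own carbon source,
  runs an internal conversion chain into biomass, and exchanges two shared
  metabolites — an ammonia-like metabolite essential to both biomasses (one
  species carries a capacity-limited internal synthesis route, the other
  none) and a succinate-like metabolite consumed at optimal growth but
  replaceable, at a carbon cost, through an internal synthesis reaction.
* :func:`build_toy_pair` — the same topology parametrised by per-metabolite
  essentiality / alternative-synthesis flags, for exhaustive grid sweeps with
  a closed-form competition ground truth.
* :func:`build_random_community` — seeded random species built around a
  planted feasible pathway, so every instance grows.

:func:`enumeration_oracle` re-decides the competition program by brute-force
enumeration of single-exchange LPs solved with scipy's HiGHS backend — an
implementation fully independent of the GLPK mixed-integer path it checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .comma import CommaConfig
from .model import MetabolicModel, Metabolite, Reaction
from .preprocessing import PreprocessedCommunity, max_biomass

BIG = 1000.0


# ---------------------------------------------------------------------------
# fixed paper-style toy pair
# ---------------------------------------------------------------------------

#: capacity of species 2's internal ammonia synthesis route; sits between its
#: own optimal-growth demand (10) and what giving plus near-optimal growth
#: requires (9.92), so ammonia stays essential yet shareable at no fitness cost
NH3_SYNTHESIS_CAP = 9.95


def _toy_species(
    model_id: str,
    carbon: str,
    biomass_stoich: dict[str, float],
    carbon_bound: float = 10.0,
    extra_metabolites: tuple[str, ...] = (),
    extra_reactions: tuple[Reaction, ...] = (),
) -> MetabolicModel:
    mets = [
        Metabolite(f"{carbon}_e", compartment="e"),
        Metabolite(f"{carbon}_c", compartment="c"),
        Metabolite("X_c", compartment="c"),
        Metabolite("succ_e", compartment="e"),
        Metabolite("succ_c", compartment="c"),
        Metabolite("nh3_e", compartment="e"),
        Metabolite("nh3_c", compartment="c"),
        *[Metabolite(m, compartment=m[-1]) for m in extra_metabolites],
    ]
    rxns = [
        Reaction(f"EX_{carbon}", lower_bound=-carbon_bound, upper_bound=BIG,
                 stoichiometry={f"{carbon}_e": -1.0}),
        Reaction(f"T_{carbon}", lower_bound=-BIG, upper_bound=BIG,
                 stoichiometry={f"{carbon}_e": -1.0, f"{carbon}_c": 1.0}),
        Reaction("C2X", lower_bound=-BIG, upper_bound=BIG,
                 stoichiometry={f"{carbon}_c": -1.0, "X_c": 1.0}),
        # irreversible: succinate must not double as a carbon source
        Reaction("X2S", lower_bound=0.0, upper_bound=BIG,
                 stoichiometry={"X_c": -1.0, "succ_c": 1.0}),
        Reaction("T_succ", lower_bound=-BIG, upper_bound=BIG,
                 stoichiometry={"succ_e": -1.0, "succ_c": 1.0}),
        Reaction("T_nh3", lower_bound=-BIG, upper_bound=BIG,
                 stoichiometry={"nh3_e": -1.0, "nh3_c": 1.0}),
        Reaction("EX_succ", lower_bound=-BIG, upper_bound=BIG,
                 stoichiometry={"succ_e": -1.0}),
        Reaction("EX_nh3", lower_bound=-BIG, upper_bound=BIG,
                 stoichiometry={"nh3_e": -1.0}),
        Reaction("BIOMASS", lower_bound=0.0, upper_bound=BIG,
                 stoichiometry=dict(biomass_stoich)),
        *extra_reactions,
    ]
    model = MetabolicModel(model_id=model_id, metabolites=mets, reactions=rxns,
                           biomass_reaction_id="BIOMASS")
    model.exchange_reaction_ids = model.detect_exchanges()
    model.validate()
    return model


def toy_pair() -> tuple[MetabolicModel, MetabolicModel]:
    """The fixed two-species toy pair with succinate- and ammonia-like exchange.

    Ground truth under the default configuration (alpha = 0.1, beta = 0.01,
    epsilon = 0.01):

    * ammonia is competed — species 1 has no internal nitrogen source, so
      zeroing both uptakes starves it; single-deactivation programs are
      infeasible for species 1 and feasible for species 2 (whose synthesis
      route covers survival-level growth);
    * succinate is not competed — both species can synthesise it from carbon
      at survival-level growth;
    * both ammonia supply directions are commensal, both succinate supply
      directions fail at full giver fitness (supplying optimal-growth demand
      costs carbon the giver cannot spare).
    """
    s1 = _toy_species(
        "species1",
        carbon="glc",
        biomass_stoich={"X_c": -1.0, "succ_c": -1.0, "nh3_c": -0.02},
    )
    s2 = _toy_species(
        "species2",
        carbon="fru",
        biomass_stoich={"X_c": -1.0, "succ_c": -1.0, "nh3_c": -1.0},
        extra_metabolites=("n2_e", "n2_c"),
        extra_reactions=(
            Reaction("EX_n2", lower_bound=-BIG, upper_bound=BIG,
                     stoichiometry={"n2_e": -1.0}),
            Reaction("T_n2", lower_bound=-BIG, upper_bound=BIG,
                     stoichiometry={"n2_e": -1.0, "n2_c": 1.0}),
            Reaction("N2A", lower_bound=0.0, upper_bound=NH3_SYNTHESIS_CAP,
                     stoichiometry={"n2_c": -1.0, "nh3_c": 1.0}),
        ),
    )
    return s1, s2


# ---------------------------------------------------------------------------
# parametrised toy grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyPairSpec:
    """Flags controlling a two-species toy pair over ``n_shared`` metabolites.

    ``essential``, ``alternative_synthesis`` and ``uptake_allowed`` are
    indexed ``[metabolite][species]``.  A metabolite essential to a species
    with neither an uptake route nor a synthesis route is inconsistent.
    """

    n_shared: int = 2
    essential: tuple[tuple[bool, bool], ...] = ((True, True), (False, False))
    alternative_synthesis: tuple[tuple[bool, bool], ...] = ((False, True), (False, False))
    uptake_allowed: tuple[tuple[bool, bool], ...] = ()
    bounds: float = 10.0
    seed: int = 0

    def resolved_uptake(self) -> tuple[tuple[bool, bool], ...]:
        if self.uptake_allowed:
            return self.uptake_allowed
        return tuple((True, True) for _ in range(self.n_shared))

    def validate(self) -> None:
        if self.n_shared < 1:
            raise ValueError("need at least one shared metabolite")
        for flags in (self.essential, self.alternative_synthesis):
            if len(flags) != self.n_shared:
                raise ValueError("flag tables must have one row per shared metabolite")
        for j, (ess, synth, upt) in enumerate(
            zip(self.essential, self.alternative_synthesis, self.resolved_uptake())
        ):
            for s in (0, 1):
                if ess[s] and not synth[s] and not upt[s]:
                    raise ValueError(
                        f"metabolite {j} essential to species {s + 1} but has "
                        "no acquisition route (no uptake, no synthesis)"
                    )


def build_toy_pair(spec: ToyPairSpec) -> tuple[MetabolicModel, MetabolicModel]:
    """Generate a flag-driven toy pair (deterministic for a fixed spec).

    Each species imports its own carbon source (bound ``spec.bounds``), turns
    it into a biomass precursor X, and exchanges ``n_shared`` metabolites.
    An essential metabolite enters the species' biomass reaction; an
    alternative-synthesis route makes it from X (one carbon per unit).
    """
    spec.validate()
    uptake = spec.resolved_uptake()
    models = []
    for s, carbon in enumerate(("glc", "fru")):
        mets = [
            Metabolite(f"{carbon}_e", compartment="e"),
            Metabolite(f"{carbon}_c", compartment="c"),
            Metabolite("X_c", compartment="c"),
        ]
        biomass = {"X_c": -1.0}
        rxns = [
            Reaction(f"EX_{carbon}", lower_bound=-spec.bounds, upper_bound=BIG,
                     stoichiometry={f"{carbon}_e": -1.0}),
            Reaction(f"T_{carbon}", lower_bound=-BIG, upper_bound=BIG,
                     stoichiometry={f"{carbon}_e": -1.0, f"{carbon}_c": 1.0}),
            Reaction("C2X", lower_bound=-BIG, upper_bound=BIG,
                     stoichiometry={f"{carbon}_c": -1.0, "X_c": 1.0}),
        ]
        for j in range(spec.n_shared):
            met = f"met{j}"
            mets.append(Metabolite(f"{met}_e", compartment="e"))
            mets.append(Metabolite(f"{met}_c", compartment="c"))
            lb = -BIG if uptake[j][s] else 0.0
            rxns.append(Reaction(f"EX_{met}", lower_bound=lb, upper_bound=BIG,
                                 stoichiometry={f"{met}_e": -1.0}))
            rxns.append(Reaction(f"T_{met}", lower_bound=-BIG, upper_bound=BIG,
                                 stoichiometry={f"{met}_e": -1.0, f"{met}_c": 1.0}))
            if spec.essential[j][s]:
                biomass[f"{met}_c"] = -1.0
            if spec.alternative_synthesis[j][s]:
                rxns.append(Reaction(f"SYN_{met}", lower_bound=0.0, upper_bound=BIG,
                                     stoichiometry={"X_c": -1.0, f"{met}_c": 1.0}))
        rxns.append(Reaction("BIOMASS", lower_bound=0.0, upper_bound=BIG,
                             stoichiometry=biomass))
        model = MetabolicModel(model_id=f"species{s + 1}", metabolites=mets,
                               reactions=rxns, biomass_reaction_id="BIOMASS")
        model.exchange_reaction_ids = model.detect_exchanges()
        model.validate()
        models.append(model)
    return models[0], models[1]


def expected_competed(spec: ToyPairSpec) -> set[str]:
    """Closed-form competition ground truth for :func:`build_toy_pair`.

    With both uptakes fixed to zero a species survives iff the metabolite is
    not essential to it or it owns a synthesis route; the program is
    infeasible — the metabolite is competed — as soon as one species starves.
    Only metabolites both species can take up are reported (others are not
    overlapped and never tested).
    """
    uptake = spec.resolved_uptake()
    out = set()
    for j in range(spec.n_shared):
        if not (uptake[j][0] and uptake[j][1]):
            continue
        starves = any(
            spec.essential[j][s] and not spec.alternative_synthesis[j][s]
            for s in (0, 1)
        )
        if starves:
            out.add(f"met{j}_e")
    return out


_T, _F = True, False

#: base specs for network-monotonicity sweeps: each carries at least one
#: not-competed metabolite (essential to both, synthesisable by both) whose
#: verdict must survive switching on any of the four absent synthesis routes
NETWORK_MONOTONICITY_SPECS = tuple(
    ToyPairSpec(n_shared=3, essential=ess, alternative_synthesis=syn)
    for ess, syn in [
        (((_T, _T), (_T, _T), (_T, _T)), ((_T, _T), (_F, _F), (_F, _F))),
        (((_T, _T), (_T, _T), (_F, _T)), ((_T, _T), (_F, _F), (_F, _F))),
        (((_T, _T), (_T, _T), (_T, _T)), ((_F, _F), (_T, _T), (_F, _F))),
        (((_T, _T), (_F, _F), (_T, _T)), ((_T, _T), (_F, _F), (_F, _F))),
        (((_T, _T), (_T, _F), (_F, _T)), ((_T, _T), (_F, _F), (_F, _F))),
    ]
)


# ---------------------------------------------------------------------------
# random communities
# ---------------------------------------------------------------------------


def build_random_community(
    n_species: int,
    n_shared: int,
    n_internal: int,
    seed: int,
    n_extra_reactions: int = 3,
) -> list[MetabolicModel]:
    """Seeded random species, each feasible by construction.

    Every species is built around a planted pathway — carbon import, a chain
    of ``n_internal`` conversions, biomass — guaranteeing positive maximal
    growth, then decorated with random shared-metabolite participation
    (random essentiality, random synthesis routes) and random extra internal
    reactions.  Identical ``seed`` yields identical models.
    """
    if min(n_species, n_shared, n_internal) < 1:
        raise ValueError("counts must be at least 1")
    rng = np.random.default_rng(seed)
    models = []
    for s in range(n_species):
        sid = f"sp{s + 1}"
        carbon = f"src{s + 1}"
        mets = [Metabolite(f"{carbon}_e", compartment="e")]
        internal = [f"I{k}_c" for k in range(n_internal)]
        mets += [Metabolite(m, compartment="c") for m in internal]
        rxns = [
            Reaction(f"EX_{carbon}", lower_bound=-10.0, upper_bound=BIG,
                     stoichiometry={f"{carbon}_e": -1.0}),
            Reaction(f"T_{carbon}", lower_bound=-BIG, upper_bound=BIG,
                     stoichiometry={f"{carbon}_e": -1.0, internal[0]: 1.0}),
        ]
        for k in range(n_internal - 1):
            reversible = bool(rng.integers(0, 2))
            rxns.append(Reaction(
                f"CHAIN{k}", lower_bound=-BIG if reversible else 0.0,
                upper_bound=BIG,
                stoichiometry={internal[k]: -1.0, internal[k + 1]: 1.0},
            ))
        biomass = {internal[-1]: -1.0}
        for j in range(n_shared):
            met = f"shared{j}"
            mets.append(Metabolite(f"{met}_e", compartment="e"))
            mets.append(Metabolite(f"{met}_c", compartment="c"))
            rxns.append(Reaction(f"EX_{met}", lower_bound=-BIG, upper_bound=BIG,
                                 stoichiometry={f"{met}_e": -1.0}))
            rxns.append(Reaction(f"T_{met}", lower_bound=-BIG, upper_bound=BIG,
                                 stoichiometry={f"{met}_e": -1.0, f"{met}_c": 1.0}))
            if rng.random() < 0.5:
                biomass[f"{met}_c"] = -float(np.round(rng.uniform(0.1, 1.0), 2))
            if rng.random() < 0.5:
                src = internal[int(rng.integers(0, n_internal))]
                rxns.append(Reaction(
                    f"SYN_{met}", lower_bound=0.0, upper_bound=BIG,
                    stoichiometry={src: -1.0, f"{met}_c": 1.0},
                ))
        for x in range(n_extra_reactions):
            i, j = rng.choice(n_internal, size=2, replace=False)
            reversible = bool(rng.integers(0, 2))
            rxns.append(Reaction(
                f"RND{x}", lower_bound=-BIG if reversible else 0.0,
                upper_bound=float(rng.integers(1, 20)),
                stoichiometry={internal[int(i)]: -1.0, internal[int(j)]: 1.0},
            ))
        rxns.append(Reaction("BIOMASS", lower_bound=0.0, upper_bound=BIG,
                             stoichiometry=biomass))
        model = MetabolicModel(model_id=sid, metabolites=mets, reactions=rxns,
                               biomass_reaction_id="BIOMASS")
        model.exchange_reaction_ids = model.detect_exchanges()
        model.validate()
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# independent competition oracle (scipy / HiGHS)
# ---------------------------------------------------------------------------


def _scipy_feasible(
    pre: PreprocessedCommunity,
    fixed_zero: list[str],
    lower_overrides: dict[str, float],
) -> bool:
    """Feasibility of {S v = 0, bounds} with overrides, via scipy linprog."""
    rxns = pre.community.reactions
    index = {r.id: i for i, r in enumerate(rxns)}
    met_index: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for r in rxns:
        for met, coef in r.stoichiometry.items():
            row = met_index.setdefault(met, len(met_index))
            rows.append(row)
            cols.append(index[r.id])
            vals.append(coef)
    a_eq = np.zeros((len(met_index), len(rxns)))
    a_eq[rows, cols] = vals
    bounds = []
    for r in rxns:
        lb, ub = r.lower_bound, r.upper_bound
        if r.id in fixed_zero:
            lb, ub = 0.0, 0.0
        if r.id in lower_overrides:
            lb = max(lb, lower_overrides[r.id])
        bounds.append((lb, ub))
    res = linprog(
        c=np.zeros(len(rxns)),
        A_eq=a_eq,
        b_eq=np.zeros(len(met_index)),
        bounds=bounds,
        method="highs",
    )
    return res.status == 0


def enumeration_oracle(
    pre: PreprocessedCommunity,
    metabolite: str,
    config: CommaConfig | None = None,
    deactivate: list[str] | None = None,
) -> str:
    """Brute-force competition decision: one LP per community exchange.

    For each exchange ``k`` the mixed-integer active-exchange constraints are
    replaced by the single linear constraint ``v_k >= beta``; the program is
    feasible iff any of these LPs is.  Mathematically equivalent to the MILP,
    but decided by an independent solver (HiGHS) and construction.

    Returns ``"feasible"`` or ``"infeasible"``.
    """
    config = config or CommaConfig()
    if len(pre.exchange_ids) > 50:
        raise ValueError("oracle intended for small fixtures (<= 50 exchanges)")
    if deactivate is None:
        deactivate = [
            s for s in pre.community.species if (s, metabolite) in pre.uptake_of
        ]
    fixed = [
        pre.uptake_of[(s, metabolite)]
        for s in deactivate
        if (s, metabolite) in pre.uptake_of
    ]
    floors = {
        pre.biomass_reaction(s): config.alpha * max_biomass(pre, s)
        for s in pre.community.species
    }
    for ex_id in pre.exchange_ids:
        overrides = dict(floors)
        overrides[ex_id] = max(overrides.get(ex_id, 0.0), config.beta)
        if _scipy_feasible(pre, fixed, overrides):
            return "feasible"
    return "infeasible"
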