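import numpy as np
import pytest
from scipy.optimize import linprog

from commacparma import join_models
from commacparma.fixtures import ToyPairSpec, build_toy_pair, toy_pair
from commacparma.model import Metabolite, Reaction
from commacparma.preprocessing import (
    find_blocked_reactions,
    max_biomass,
    min_required_uptake,
    preprocess,
    split_reversible,
)


def _scipy_max_flux(pre, rxn_id):
    """Independent FBA via scipy/HiGHS on the split community."""
    rxns = pre.community.reactions
    index = {r.id: i for i, r in enumerate(rxns)}
    met_index = {}
    a = {}
    for r in rxns:
        for met, coef in r.stoichiometry.items():
            met_index.setdefault(met, len(met_index))
            a[(met_index[met], index[r.id])] = coef
    a_eq = np.zeros((len(met_index), len(rxns)))
    for (i, j), coef in a.items():
        a_eq[i, j] = coef
    c = np.zeros(len(rxns))
    c[index[rxn_id]] = -1.0
    res = linprog(c, A_eq=a_eq, b_eq=np.zeros(len(met_index)),
                  bounds=[(r.lower_bound, r.upper_bound) for r in rxns],
                  method="highs")
    assert res.status == 0
    return -res.fun


def test_toy_community_has_no_blocked_reactions(toy_community):
    assert find_blocked_reactions(toy_community) == set()


def test_dead_end_reaction_is_blocked(toy_models):
    """A reaction producing a metabolite nothing consumes can carry no flux."""
    s1, s2 = toy_pair()
    s1.metabolites.append(Metabolite("dead_c", compartment="c"))
    s1.reactions.insert(0, Reaction("DEAD", lower_bound=0.0, upper_bound=10.0,
                                    stoichiometry={"X_c": -1.0, "dead_c": 1.0}))
    com = join_models([s1, s2])
    assert "species1:DEAD" in find_blocked_reactions(com)


def test_blocked_detection_agrees_with_exhaustive_lp_pairs(toy_models):
    """FVA-based blocked set equals the brute-force 2n-LP scan."""
    s1, s2 = toy_pair()
    s1.metabolites.append(Metabolite("dead_c", compartment="c"))
    s1.reactions.append(Reaction("DEAD", lower_bound=-5.0, upper_bound=10.0,
                                 stoichiometry={"X_c": -1.0, "dead_c": 1.0}))
    com = join_models([s1, s2])
    tol = 1e-6
    rxns = com.reactions
    index = {r.id: i for i, r in enumerate(rxns)}
    met_index = {}
    for r in rxns:
        for met in r.stoichiometry:
            met_index.setdefault(met, len(met_index))
    a_eq = np.zeros((len(met_index), len(rxns)))
    for r in rxns:
        for met, coef in r.stoichiometry.items():
            a_eq[met_index[met], index[r.id]] = coef
    bounds = [(r.lower_bound, r.upper_bound) for r in rxns]
    brute = set()
    for r in rxns:
        extremes = []
        for sign in (1.0, -1.0):
            c = np.zeros(len(rxns))
            c[index[r.id]] = sign
            res = linprog(c, A_eq=a_eq, b_eq=np.zeros(len(met_index)),
                          bounds=bounds, method="highs")
            assert res.status == 0
            extremes.append(res.x[index[r.id]])
        if all(abs(v) <= tol for v in extremes):
            brute.add(r.id)
    assert find_blocked_reactions(com, tol) == brute


def test_split_bounds_and_irreversibility(toy_pre):
    """Every split reaction is irreversible and original bounds are
    recoverable from the forward/backward copies."""
    pre = toy_pre
    com = pre.community
    for rxn in com.reactions:
        assert 0 <= rxn.lower_bound <= rxn.upper_bound
    for orig_id, (fwd, bwd) in pre.split_map.items():
        if fwd and bwd:
            f = com.reaction(fwd)
            b = com.reaction(bwd)
            assert f.lower_bound == 0 and b.lower_bound == 0
            for met, coef in f.stoichiometry.items():
                assert b.stoichiometry[met] == -coef


def test_irreversible_reaction_passes_through(toy_community, toy_pre):
    orig = toy_community.reaction("species1:BIOMASS")
    split = toy_pre.community.reaction("species1:BIOMASS")
    assert split.lower_bound == orig.lower_bound
    assert split.upper_bound == orig.upper_bound
    assert split.stoichiometry == orig.stoichiometry


def test_split_flux_maps_back_to_feasible_original(toy_community, toy_pre):
    """v = v_f - v_b of any feasible split flux satisfies the original
    network's mass balance and bounds."""
    problem = toy_pre.problem()
    value = problem.optimize(toy_pre.biomass_reaction("species1"), "max")
    assert value is not None
    split_flux = problem.primal()
    net = {}
    for orig_id, (fwd, bwd) in toy_pre.split_map.items():
        net[orig_id] = (split_flux.get(fwd, 0.0) if fwd else 0.0) - (
            split_flux.get(bwd, 0.0) if bwd else 0.0
        )
    balance = {}
    for rxn in toy_community.reactions:
        v = net.get(rxn.id, 0.0)
        assert rxn.lower_bound - 1e-6 <= v <= rxn.upper_bound + 1e-6
        for met, coef in rxn.stoichiometry.items():
            balance[met] = balance.get(met, 0.0) + coef * v
    assert max(abs(x) for x in balance.values()) < 1e-6


def test_max_biomass_matches_independent_solver(toy_pre):
    """GLPK FBA optimum equals the scipy/HiGHS optimum."""
    for species in ("species1", "species2"):
        ours = max_biomass(toy_pre, species)
        independent = _scipy_max_flux(toy_pre, toy_pre.biomass_reaction(species))
        assert ours == pytest.approx(independent, rel=1e-6)
        assert ours == pytest.approx(10.0, rel=1e-6)


def test_blocked_removal_preserves_max_biomass(toy_models):
    """Removing blocked reactions cannot change the biomass optimum."""
    s1, s2 = toy_pair()
    s1.metabolites.append(Metabolite("dead_c", compartment="c"))
    s1.reactions.append(Reaction("DEAD", lower_bound=0.0, upper_bound=10.0,
                                 stoichiometry={"X_c": -1.0, "dead_c": 1.0}))
    com = join_models([s1, s2])
    pre_removed = preprocess(com)
    pre_kept = split_reversible(com, blocked=set())
    assert "species1:DEAD" in pre_removed.blocked_removed
    for sp in ("species1", "species2"):
        assert max_biomass(pre_removed, sp) == pytest.approx(
            max_biomass(pre_kept, sp), rel=1e-9
        )


def test_zero_import_bound_gives_zero_biomass():
    """A species whose sole carbon import is shut cannot grow."""
    s1, s2 = toy_pair()
    s1.reaction("EX_glc").lower_bound = 0.0
    com = join_models([s1, s2])
    pre = preprocess(com)
    assert max_biomass(pre, "species1") == pytest.approx(0.0, abs=1e-9)
    assert max_biomass(pre, "species2") > 1.0


def test_min_required_uptake_closed_form():
    """Essential metabolite with 1:1 biomass stoichiometry and no synthesis:
    at a biomass floor f*mu_max the demand is exactly f*mu_max."""
    spec = ToyPairSpec(
        n_shared=1,
        essential=((True, True),),
        alternative_synthesis=((False, False),),
    )
    com = join_models(list(build_toy_pair(spec)))
    pre = preprocess(com)
    mu_max = max_biomass(pre, "species1")
    assert mu_max == pytest.approx(10.0, rel=1e-9)
    for fraction in (0.1, 0.5, 1.0):
        demand = min_required_uptake(pre, "species1", "met0_e", fraction=fraction)
        assert demand == pytest.approx(fraction * mu_max, rel=1e-6)


def test_min_required_uptake_monotone_in_fraction(toy_pre):
    fractions = [0.05, 0.1, 0.2, 0.5, 1.0]
    demands = [
        min_required_uptake(toy_pre, "species2", "nh3_e", fraction=f)
        for f in fractions
    ]
    assert all(a <= b + 1e-9 for a, b in zip(demands, demands[1:]))


def test_unneeded_metabolite_has_zero_demand():
    """A metabolite absent from biomass is never demanded."""
    spec = ToyPairSpec(
        n_shared=2,
        essential=((True, True), (False, False)),
        alternative_synthesis=((False, False), (True, True)),
    )
    com = join_models(list(build_toy_pair(spec)))
    pre = preprocess(com)
    assert min_required_uptake(pre, "species1", "met1_e", fraction=1.0) == pytest.approx(
        0.0, abs=1e-9
    )


def test_toy_demands_are_positive(toy_pre):
    """Both species need ammonia uptake at optimal growth."""
    d1 = min_required_uptake(toy_pre, "species1", "nh3_e", 1.0, partner_fraction=0.1)
    d2 = min_required_uptake(toy_pre, "species2", "nh3_e", 1.0, partner_fraction=0.1)
    assert d1 == pytest.approx(0.2, rel=1e-6)
    assert d2 == pytest.approx(0.05, rel=1e-4)
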