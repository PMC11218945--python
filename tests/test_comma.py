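import itertools

import pytest

from commacparma import (
    CommaConfig,
    SolverStatus,
    Verdict,
    comma_group,
    comma_single,
    comma_test,
    comma_test_blocked_rule,
    competition_profile,
    join_models,
    max_biomass,
    preprocess,
)
from commacparma.fixtures import ToyPairSpec, build_toy_pair

CFG = CommaConfig()


def test_ammonia_is_competed(toy_pre):
    """Neither medium lets both species survive without ammonia uptake:
    species 1 has no internal nitrogen source."""
    result = comma_test(toy_pre, "nh3_e", CFG)
    assert result.verdict == Verdict.COMPETED
    assert result.solver_status == SolverStatus.INFEASIBLE
    assert result.witness is None


def test_succinate_is_not_competed(toy_pre):
    """Both species synthesise succinate from carbon at survival-level growth."""
    result = comma_test(toy_pre, "succ_e", CFG)
    assert result.verdict == Verdict.NOT_COMPETED
    assert result.solver_status == SolverStatus.FEASIBLE


def test_witness_satisfies_program_constraints(toy_pre):
    """A feasible witness respects mass balance, zeroed uptakes, biomass
    floors, and carries at least one active community exchange."""
    result = comma_test(toy_pre, "succ_e", CFG)
    w = result.witness
    assert w is not None
    balance = {}
    for rxn in toy_pre.community.reactions:
        for met, coef in rxn.stoichiometry.items():
            balance[met] = balance.get(met, 0.0) + coef * w[rxn.id]
    assert max(abs(x) for x in balance.values()) < 1e-6
    for sp in ("species1", "species2"):
        assert w[toy_pre.uptake_of[(sp, "succ_e")]] <= 1e-9
        floor = CFG.alpha * max_biomass(toy_pre, sp)
        assert w[toy_pre.biomass_reaction(sp)] >= floor - 1e-6
    assert result.active_exchanges
    assert any(w[ex] >= CFG.beta - 1e-9 for ex in result.active_exchanges)


def test_single_deactivation_asymmetry(toy_pre):
    """Species 2 owns an alternative ammonia route; species 1 does not."""
    assert comma_single(toy_pre, "nh3_e", "species1", CFG) == SolverStatus.INFEASIBLE
    assert comma_single(toy_pre, "nh3_e", "species2", CFG) == SolverStatus.FEASIBLE


def test_single_is_relaxation_of_joint(toy_pre):
    """If the joint program is feasible, both single programs are feasible."""
    joint = comma_test(toy_pre, "succ_e", CFG)
    assert joint.verdict == Verdict.NOT_COMPETED
    for sp in ("species1", "species2"):
        assert comma_single(toy_pre, "succ_e", sp, CFG) == SolverStatus.FEASIBLE


def test_group_with_both_species_reduces_to_pair_test(toy_pre):
    for met in ("nh3_e", "succ_e"):
        pair_verdict = comma_test(toy_pre, met, CFG).verdict
        group_verdict = comma_group(
            toy_pre, met, {"species1", "species2"}, CFG
        ).verdict
        assert pair_verdict == group_verdict


def test_group_rejects_singletons_and_unknowns(toy_pre):
    with pytest.raises(ValueError):
        comma_group(toy_pre, "nh3_e", {"species1"}, CFG)
    with pytest.raises(KeyError):
        comma_group(toy_pre, "nh3_e", {"species1", "ghost"}, CFG)


def test_three_species_group_competition():
    """Group deactivation starves exactly the subsets containing the species
    without a synthesis route."""
    spec = ToyPairSpec(
        n_shared=1,
        essential=((True, True),),
        alternative_synthesis=((True, True),),
    )
    s1, s2 = build_toy_pair(spec)
    spec_b = ToyPairSpec(
        n_shared=1,
        essential=((True, True),),
        alternative_synthesis=((False, False),),
    )
    s3, _ = build_toy_pair(spec_b)
    s3.model_id = "species3"
    com = join_models([s1, s2, s3])
    pre = preprocess(com)
    # the pair with synthesis routes survives a joint deactivation
    ok = comma_group(pre, "met0_e", {"species1", "species2"}, CFG)
    assert ok.verdict == Verdict.NOT_COMPETED
    # any subset containing species3 (no synthesis) starves it
    bad = comma_group(pre, "met0_e", {"species1", "species3"}, CFG)
    assert bad.verdict == Verdict.COMPETED
    all3 = comma_group(pre, "met0_e", {"species1", "species2", "species3"}, CFG)
    assert all3.verdict == Verdict.COMPETED


def test_superset_monotonicity():
    """An infeasible subset program stays infeasible for any superset."""
    spec = ToyPairSpec(
        n_shared=1,
        essential=((True, True),),
        alternative_synthesis=((True, False),),
    )
    s1, s2 = build_toy_pair(spec)
    s3, _ = build_toy_pair(spec)
    s3.model_id = "species3"
    com = join_models([s1, s2, s3])
    pre = preprocess(com)
    sub = comma_group(pre, "met0_e", {"species1", "species2"}, CFG)
    sup = comma_group(pre, "met0_e", {"species1", "species2", "species3"}, CFG)
    assert sub.verdict == Verdict.COMPETED
    assert sup.verdict == Verdict.COMPETED


def test_blocked_uptake_rule_truth_table():
    """The blocked shortcut fires iff some species' uptake direction is a
    dead end (here: metabolite neither essential nor synthesisable), and
    independently of the partner's status."""
    for ess1, ess2 in itertools.product([True, False], repeat=2):
        spec = ToyPairSpec(
            n_shared=1,
            essential=((ess1, ess2),),
            alternative_synthesis=((False, False),),
        )
        pre = preprocess(join_models(list(build_toy_pair(spec))))
        result = comma_test_blocked_rule(pre, "met0_e", CFG)
        dead_end = not ess1 or not ess2  # that species can carry no uptake flux
        if dead_end:
            assert result.verdict == Verdict.COMPETED_BLOCKED_UPTAKE
        else:
            assert result.verdict == Verdict.COMPETED  # essential, no synthesis


def test_blocked_rule_can_be_disabled(toy_pre):
    cfg = CommaConfig(blocked_uptake_is_competed=False)
    assert comma_test_blocked_rule(toy_pre, "succ_e", cfg).verdict == Verdict.NOT_COMPETED


def test_live_uptakes_delegate_to_milp(toy_pre):
    for met in ("nh3_e", "succ_e"):
        assert (
            comma_test_blocked_rule(toy_pre, met, CFG).verdict
            == comma_test(toy_pre, met, CFG).verdict
        )


def test_competition_profile_counts(toy_pre):
    summary = competition_profile(toy_pre, ("species1", "species2"), CFG)
    assert summary.n_overlapped == 2
    assert summary.n_competed == 1
    assert summary.competition_score == pytest.approx(0.5)
    recount = sum(1 for r in summary.per_metabolite if r.competed)
    assert recount == summary.n_competed
    assert {r.metabolite for r in summary.per_metabolite} == {"nh3_e", "succ_e"}


def test_profile_with_no_overlap_is_not_applicable():
    """Species that exchange nothing in common have an undefined score."""
    spec = ToyPairSpec(
        n_shared=1,
        essential=((True, False),),
        alternative_synthesis=((False, True),),
        uptake_allowed=((True, False),),
    )
    pre = preprocess(join_models(list(build_toy_pair(spec))))
    summary = competition_profile(pre, ("species1", "species2"), CFG)
    assert summary.n_overlapped == 0
    assert summary.competition_score is None


def test_verdict_invariant_to_species_order(toy_models):
    s1, s2 = toy_models
    pre_ab = preprocess(join_models([s1, s2]))
    pre_ba = preprocess(join_models([s2, s1]))
    for met in ("nh3_e", "succ_e"):
        assert comma_test(pre_ab, met, CFG).verdict == comma_test(pre_ba, met, CFG).verdict


def test_config_validation():
    with pytest.raises(ValueError):
        CommaConfig(alpha=0.0)
    with pytest.raises(ValueError):
        CommaConfig(beta=1.5)
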