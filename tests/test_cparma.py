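import pytest

from commacparma import (
    CparmaConfig,
    InteractionVerdict,
    classify_pair,
    cparma_test,
    join_models,
    preprocess,
)
from commacparma.fixtures import ToyPairSpec, build_toy_pair

CFG = CparmaConfig()


def _by_key(classifications):
    return {(c.metabolite, c.giver, c.consumer): c for c in classifications}


def test_toy_pair_yields_four_classifications(toy_pre):
    """Two shared metabolites x two giver->consumer directions."""
    rows = classify_pair(toy_pre, ("species1", "species2"), CFG)
    assert len(rows) == 4
    keys = {(c.metabolite, c.giver, c.consumer) for c in rows}
    assert keys == {
        ("nh3_e", "species1", "species2"),
        ("nh3_e", "species2", "species1"),
        ("succ_e", "species1", "species2"),
        ("succ_e", "species2", "species1"),
    }


def test_ammonia_supply_is_commensal_both_ways(toy_pre):
    """Each species covers the other's ammonia demand at no fitness cost."""
    rows = _by_key(classify_pair(toy_pre, ("species1", "species2"), CFG))
    for giver, consumer in (("species1", "species2"), ("species2", "species1")):
        c = rows[("nh3_e", giver, consumer)]
        assert c.verdict == InteractionVerdict.COMMENSALISM
        assert c.supply_feasible_at_full_fitness
        assert c.demanded_flux > 0


def test_succinate_supply_fails_at_full_fitness(toy_pre):
    """Covering the partner's optimal-growth succinate demand costs carbon the
    giver cannot spare within its fitness slack; the environment can make up
    the shortfall (mutualism/syntrophy branch) and a fitness-paying giver
    could also supply it (parasitism possible)."""
    rows = _by_key(classify_pair(toy_pre, ("species1", "species2"), CFG))
    for giver, consumer in (("species1", "species2"), ("species2", "species1")):
        c = rows[("succ_e", giver, consumer)]
        assert not c.supply_feasible_at_full_fitness
        assert c.verdict == InteractionVerdict.MUTUALISM_SYNTROPHY
        assert c.environment_supplement_feasible
        assert c.forced_supply_feasible


def test_no_demand_skips_the_program():
    """A metabolite unnecessary even at optimal growth yields no_demand."""
    spec = ToyPairSpec(
        n_shared=2,
        essential=((True, True), (False, False)),
        alternative_synthesis=((False, True), (True, True)),
    )
    pre = preprocess(join_models(list(build_toy_pair(spec))))
    c = cparma_test(pre, "met1_e", "species1", "species2", CFG)
    assert c.verdict == InteractionVerdict.NO_DEMAND
    assert c.demanded_flux == pytest.approx(0.0, abs=1e-6)


def test_zero_demand_supply_is_trivially_feasible():
    """With the no-demand shortcut disabled conceptually: pinning a zero
    secretion keeps the base community feasible (giver unconstrained beyond
    its fitness floor)."""
    spec = ToyPairSpec(
        n_shared=1,
        essential=((False, False),),
        alternative_synthesis=((True, True),),
    )
    pre = preprocess(join_models(list(build_toy_pair(spec))))
    problem = pre.problem()
    from commacparma.preprocessing import max_biomass

    with problem.scoped():
        problem.fix(pre.secretion_of[("species1", "met0_e")], 0.0)
        problem.set_lower(
            pre.biomass_reaction("species1"),
            (1 - CFG.epsilon) * max_biomass(pre, "species1") * (1 - 1e-9),
        )
        problem.set_lower(
            pre.biomass_reaction("species2"),
            CFG.alpha * max_biomass(pre, "species2"),
        )
        assert problem.is_feasible()


def test_missing_direction_raises(toy_pre):
    with pytest.raises(KeyError):
        cparma_test(toy_pre, "glc_e", "species2", "species1", CFG)


def test_one_directional_exchange_lists_single_direction():
    """When one species can only secrete, only the giver->consumer row with
    that orientation appears for the metabolite."""
    spec = ToyPairSpec(
        n_shared=1,
        essential=((True, False),),
        alternative_synthesis=((False, True),),
        uptake_allowed=((True, False),),
    )
    pre = preprocess(join_models(list(build_toy_pair(spec))))
    rows = classify_pair(pre, ("species1", "species2"), CparmaConfig())
    assert [(c.metabolite, c.giver, c.consumer) for c in rows] == [
        ("met0_e", "species2", "species1")
    ]


def test_row_count_matches_triple_enumeration(toy_pre):
    rows = classify_pair(toy_pre, ("species1", "species2"), CFG)
    expected = 0
    for met in {m for (_s, m) in toy_pre.uptake_of}:
        for giver, consumer in (("species1", "species2"), ("species2", "species1")):
            if (giver, met) in toy_pre.secretion_of and (
                consumer,
                met,
            ) in toy_pre.uptake_of:
                expected += 1
    assert len(rows) == expected


def test_epsilon_relaxation_monotonicity(toy_pre):
    """A supply feasible at slack epsilon stays feasible at any larger slack."""
    previous = None
    for eps in (0.005, 0.01, 0.05):
        cfg = CparmaConfig(epsilon=eps)
        feasible = cparma_test(
            toy_pre, "nh3_e", "species2", "species1", cfg
        ).supply_feasible_at_full_fitness
        if previous is not None and previous:
            assert feasible
        previous = feasible


def test_config_validation():
    with pytest.raises(ValueError):
        CparmaConfig(alpha=1.5)
    with pytest.raises(ValueError):
        CparmaConfig(epsilon=0.0)
    with pytest.raises(ValueError):
        CparmaConfig(demand_fraction=0.0)
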