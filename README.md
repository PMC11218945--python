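# comma-cparma

Per-metabolite interaction prediction for pairwise microbial communities
built from genome-scale metabolic models (GEMs).

Microbial interactions — competition, commensalism, parasitism, mutualism —
are mediated by exchanged metabolites, but most constraint-based community
methods only compare growth rates and return one overall verdict per species
pair. This package answers the finer question *which metabolite* drives an
interaction, using two feasibility programs on a joint community model with a
shared extracellular pool, and without ever defining a community-level
objective function:

* **COMMA** (competition): a shared metabolite *i* is *competed* when the
  mixed-integer program

  ```
  find  v ≥ 0
  s.t.  S^c v = 0,  lb ≤ v ≤ ub
        v_i^1 = 0,  v_i^2 = 0                (both uptakes deactivated)
        v_biomass,s ≥ α·v_biomass,s^max      (both species survive)
        v_k ≥ β·θ_k,  θ_k ∈ {0,1},  Σ_k θ_k ≥ 1   (some exchange is active)
  ```

  is infeasible — i.e. no environment lets both species survive without
  consuming *i*. Defaults α = 0.1, β = 0.01.

* **CPARMA** (commensalism/parasitism/mutualism): for a giver → consumer
  direction, the consumer's demand `v_j^2(min_flux)` (FVA minimum of its
  uptake at optimal growth) is pinned onto the giver's secretion while the
  giver keeps ≥ (1−ε) of its maximal biomass (ε = 0.01). Feasible ⇒
  commensalism; infeasible ⇒ parasitism/mutualism branch, disambiguated by
  an environment-supplement probe and a forced-supply probe.

A pair's **competition score** is the fraction of overlapped metabolites
(those both species can take up) that are competed.

See `docs/methods.md` for the full model, conventions, and limitations.

## Worked example

The bundled fixture generator emulates the classic two-species toy
community: each species runs its own carbon source into biomass and both
exchange an ammonia-like metabolite (essential to both; species 2 owns a
capacity-limited internal synthesis route, species 1 none) and a
succinate-like metabolite (consumed at optimal growth, synthesisable from
carbon at a cost):

```sh
$ comma-cparma fixtures --preset toy -o models
wrote 2 models to models

$ comma-cparma join models/species1.json models/species2.json -o community.json
community of 2 species: 26 reactions, 5 pool metabolites -> community.json

$ comma-cparma comma community.json
# overlapped=2 competed=1 score=0.5
metabolite      verdict       solver_status  n_active_exchanges
nh3_e           competed      infeasible     0
succ_e          not_competed  feasible       1
```

Ammonia is competed: zeroing both uptakes starves species 1, which has no
internal nitrogen source, so no medium supports the pair (the program is
infeasible). Succinate is not competed: both species can synthesise it from
carbon at survival-level growth, and the witness medium keeps one community
exchange active. The pair's competition score is 1/2 = 0.5.

```sh
$ comma-cparma cparma community.json
metabolite  giver     consumer  demanded_flux  verdict             env_probe  forced_probe
nh3_e       species1  species2  0.05           commensalism        False      False
nh3_e       species2  species1  0.2            commensalism        False      False
succ_e      species1  species2  10.0           mutualism_syntrophy True       True
succ_e      species2  species1  10.0           mutualism_syntrophy True       True
```

Each species can cover the other's ammonia demand (0.05 and 0.2
mmol gDW⁻¹ h⁻¹) without losing more than 1 % of its own maximal growth —
commensalism in both directions. Neither can supply the partner's
optimal-growth succinate demand (10 mmol gDW⁻¹ h⁻¹) at full fitness; the
environment can make up the shortfall (mutualism/syntrophy) and a
fitness-paying giver could also cover it (parasitism possible), so both
probe flags are set.

The same analysis runs end-to-end over every pair of a larger community with
`comma-cparma run model1.xml model2.xml ... -o results/` (SBML Level 3 + FBC
or COBRA JSON inputs), writing `summary.tsv`, `competition.tsv`,
`interactions.tsv`, `report.json` and the resolved configuration.

The Python API mirrors the CLI:

```python
from commacparma import (CommaConfig, comma_test, competition_profile,
                         classify_pair, join_models, preprocess)
from commacparma.fixtures import toy_pair

pre = preprocess(join_models(list(toy_pair())))
print(comma_test(pre, "nh3_e").verdict)          # Verdict.COMPETED
print(competition_profile(pre).competition_score) # 0.5
```

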