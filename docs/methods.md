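# Methods

## Problem and model

Interactions inside a microbial community are largely mediated by exchanged
metabolites. Given genome-scale metabolic models (GEMs) of two (or more)
species, this package builds one joint stoichiometric model of the synthetic
community and asks, metabolite by metabolite, two questions:

1. **Competition (COMMA).** Is there *any* environment in which both species
   survive without consuming the shared metabolite? If not, the metabolite is
   essential to both simultaneously and the pair has the potential to compete
   for it.
2. **Commensalism / parasitism / mutualism (CPARMA).** Can one species (the
   giver) cover the other's (the consumer's) demand for a metabolite without
   sacrificing its own fitness? If yes, the consumer grows on the giver's
   by-product — commensalism; if not, the relationship is parasitic or
   mutualistic depending on who pays and whether the environment can make up
   the shortfall.

Neither question needs a community-level objective function: both are pure
feasibility problems over the community flux cone.

## Community construction

Each species keeps its internal network under a `species:` id prefix. Every
extracellular metabolite moved by a species' exchange reaction is merged, by
id, into a shared *pool* compartment; the former exchange reaction becomes an
internal transfer between the species and the pool (positive flux =
secretion, negative = uptake). One new reversible community exchange per pool
metabolite connects the pool to the environment (positive = export,
negative = import), with default bounds of 1000 mmol gDW⁻¹ h⁻¹ per
direction — deliberately permissive, because the algorithms search over
media rather than fixing one. All extracellular metabolites of either
species are pooled; the *overlapped* set of a pair (the competition-score
denominator) is the subset both species can take up.

The *n*-species join is supported (used by the group-competition extension);
the pairwise join is the default pipeline path.

## Preprocessing

In order:

1. **Blocked-reaction removal.** Flux variability analysis with open
   community exchanges and no biomass constraint; a reaction whose flux range
   lies within ±10⁻⁶ is removed. Detection runs on the *unsplit* model so
   the futile two-cycles created by splitting cannot hide a dead end.
   Biomass reactions are exempt from removal — a species with zero maximal
   growth is a result, not an artifact. Uptake *directions* that can carry no
   flux are recorded separately: the competition test reports such
   metabolites as competed without solving (the documented blocked-uptake
   rule; it can be disabled by configuration, because a metabolite whose
   uptake cannot carry flux is arguably not consumable at all).
2. **Reversible splitting.** Every reversible reaction becomes a forward and
   a backward irreversible copy (negated stoichiometry, bounds `[0, ub]` /
   `[0, -lb]`), so all fluxes are nonnegative and the irreversible set is the
   whole reaction set. Futile forward+backward two-cycles are permitted; the
   feasibility programs only fix fluxes to zero or bound them from below, so
   the cycles cannot change any verdict.
3. **Reference fluxes.** Each species' maximal biomass flux is computed by
   FBA *on the joint community model* with the partner unconstrained, so all
   reference quantities live in one flux space.

## The competition program

For shared metabolite *i* with uptake transfers `u₁, u₂` and biomass floors
at fraction α of each species' maximum `μₛ*`:

```
find v ≥ 0
s.t.  S^c v = 0,   lb ≤ v ≤ ub
      u₁ = 0,  u₂ = 0
      v_biomass,s ≥ α μₛ*          for each species s
      v_k ≥ β θ_k,  θ_k ∈ {0,1}    for each community exchange k
      Σ_k θ_k ≥ 1
```

The binary indicators force at least one community exchange to carry at
least β — the community must genuinely exchange matter with some
environment. Defaults α = 0.1, β = 0.01. Infeasibility ⇒ *competed*. Only
uptake-direction copies are fixed to zero; secretion stays free, because
competition is defined on consumption. The exactly-equivalent brute-force
check — one LP per exchange with `v_k ≥ β` replacing the integer
constraints — is implemented against an independent solver backend
(scipy/HiGHS) and serves as the central correctness oracle in the tests.

A single-deactivation variant (only one species' uptake zeroed) supports the
alternative criterion that declares competition only when *both*
single-species programs are infeasible; a group variant zeroes uptakes for
an arbitrary species subset with survival floors for all members.

Properties that hold by construction and are tested: feasibility is
monotone decreasing in α; adding reactions (columns of S^c) can only turn
competed into not-competed, never the reverse; the verdict is invariant to
the order of the two species.

## The supply (commensalism/parasitism) program

The consumer's *demand* for metabolite *j* is the minimum flux its uptake
transfer must carry while its biomass is held at the FBA optimum (the
standard FVA convention of fixing biomass at 100 % of optimum; the fraction
is configurable via `demand_fraction`, and partners are floored at α during
the minimisation). A zero demand short-circuits to a `no_demand` verdict.

The main LP pins the giver's secretion copy to exactly the demand, floors
the giver at (1−ε) of its maximum (ε = 0.01) and the consumer at α, and
*closes community import of the tested metabolite*, so the giver is the sole
external source — otherwise the environment would trivially satisfy any
demand and "supply without a fitness price" would be meaningless.
Feasible ⇒ commensalism.

When infeasible, two probe LPs disambiguate the branch (the published
outcome taxonomy describes the branches without printing a decision
procedure, so the probes are this package's design):

* **environment probe** — secretion relaxed to `[0, demand]`, import
  reopened, both fitness floors kept. Feasible ⇒ consumer can survive on
  giver plus environment: `mutualism_syntrophy`.
* **forced-supply probe** — secretion stays pinned, giver floor drops to α.
  Feasible ⇒ the giver *could* supply at a fitness cost:
  `parasitism_possible`.

Both probe flags are always reported; when both are positive the verdict
priority is environment-first. Supply feasibility is monotone increasing in
ε (tested).

Note that the secretion pin is a *gross* flux: a giver may cycle (take up
and re-secrete) the metabolite. Net supply obligations emerge through the
pool's mass balance.

## Summary metrics

* **Competition score (rate)** of a pair: competed / overlapped metabolites.
* **Interaction strength**: co-culture over monoculture biomass flux; above
  one = positive effect.
* **Chesson-style competitive ability**: the conventional rendering of the
  score groups μᵢ−1 with the two competition coefficients ambiguously, so
  the grouping is an explicit `variant` argument — `(μ−1)/(αᵢᵢ·αᵢⱼ)`
  (default), `(μ−1)·αᵢᵢ/αᵢⱼ`, or `(μ−1)/αᵢᵢ` — and is recorded with every
  output.
* **Pearson r** and **mean/sample-SD** summaries use scipy/numpy with the
  n−1 denominator (the sample SD is what reproduces the published spread of
  the phyllosphere competition rates: 0.009; a population denominator would
  give 0.008).

A bundled table (`datasets.phyllosphere_comparison`) carries the previously
reported metric panel for six phyllosphere strains against *Pantoea
eucalypti* 299R, used for regression checks of the statistics.

## Synthetic fixtures: what they do and do not show

`fixtures.toy_pair` reproduces the classic two-species toy topology: each
species imports its own carbon source (bound 10 mmol gDW⁻¹ h⁻¹), converts it
through an intermediate X into biomass, and both exchange a succinate-like
and an ammonia-like metabolite. Coefficients are small integers chosen so
that the qualitative structure is exact:

* biomass of species 1 = X + succinate + 0.02 ammonia; species 2 = X +
  succinate + ammonia;
* both species can make succinate from X (irreversible, one carbon per
  unit) — affordable at survival-level growth, unaffordable at the optimum;
* species 2 owns a nitrogen-assimilation route capped at 9.95, i.e. between
  "own optimal demand plus a partner's survival demand at 1 % fitness slack"
  (9.92) and its own optimal demand (10); species 1 has no nitrogen source.

That capacity window is what makes ammonia simultaneously *competed* (species
1 starves when uptakes are zeroed), *demanded* by both at optimal growth, and
*commensally shareable* in both directions. The synthesis routes are
deliberately irreversible: a reversible route would let the shared
metabolite double as a carbon source and destroy the ground truth.

`fixtures.build_toy_pair` parametrises the same topology with per-metabolite
essentiality/synthesis/uptake flags and a closed-form competition ground
truth (competed ⇔ some species finds the metabolite essential and owns no
synthesis route). `fixtures.build_random_community` plants a feasible
carbon-to-biomass pathway per species and decorates it with random shared
participation and random internal reactions, guaranteeing growth for every
seed.

These fixtures are desk-scale (tens of reactions): they exercise every
algorithmic branch and the MILP/oracle equivalence, but they cannot show how
verdicts behave on genome-scale networks with thousands of reactions,
cofactor coupling, or realistic media. Analyses of the published collections
(honeybee gut microbiome, phyllosphere panel, the *D. vulgaris* /
*M. maripaludis* and *G. sulfurreducens* / *R. ferrireducens* co-cultures)
require downloading the external model collections and are provided as an
optional script (`scripts/validate_external.py`), not as part of the bundled
test surface.

## Numerical choices

* Solver: GLPK through optlang for all LPs and the MILP; deterministic
  simplex with fixed variable ordering, so witnesses are reproducible.
* Blocked-reaction tolerance 10⁻⁶; zero tolerance inside feasibility
  programs 10⁻⁹ (standard flux-analysis practice).
* Biomass floors are implemented as variable lower bounds; floors derived
  from an optimum computed in the same model are multiplied by (1 − 10⁻⁹) so
  a 100 % floor remains attainable.
* A solver failure yields an explicit `error` status and the verdict is
  withheld — never silently reported as not-competed.
* Problem sizes in the bundled suites (toy pair ≈ 40 split reactions; random
  communities 2 species × 2 shared × 3 internal metabolites; 50 seeds in the
  oracle sweep) were chosen as the smallest instances that exercise every
  branch of the programs.

## Known limitations

* Shared metabolites are matched by identifier equality; nothing maps
  between metabolite namespaces, so cross-collection joins require curated
  ids.
* No abundance weighting (MICOM-style), no dynamic FBA, no loopless or
  thermodynamic constraints, and no medium enumeration: verdicts quantify
  *potential* interactions over all media, not realised ones.
* The blocked-uptake-implies-competed rule is kept for fidelity to the
  published procedure but is counterintuitive (a permanently inactive uptake
  cannot be consumed); it is configurable.
* Amensalism and neutralism are out of scope; the supply program
  distinguishes only the commensal and parasitism/mutualism branches.
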