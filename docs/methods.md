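# Methods

This note records the models and algorithms behind `orthodesign`, the
assumptions baked into each, and the places where a genuinely open design
choice had to be made.

## Problem setting

A production strain must serve two competing objectives: grow, and convert a
substrate into a target chemical. `orthodesign` treats the *separability* of
these objectives as a measurable network property. The analysis works on a
constraint-based stoichiometric model — internal metabolites balanced at
steady state (S·v = 0), irreversibility and flux bounds on reactions — with
three designated reactions: substrate uptake, biomass formation, and target
export. A configurable set of biomass *precursor* metabolites (default: the
canonical twelve of central carbon metabolism — G6P, F6P, R5P, E4P, GAP,
3PG, PEP, PYR, AcCoA, AKG, SucCoA, OAA) supports the precursor-level
diagnostics; the twelve-member default is a convention, not a property of
any particular model, and should be overridden for models with different
metabolite naming.

## Elementary flux modes

All scoring rests on elementary flux modes (EFMs): support-minimal
steady-state flux distributions, unique up to positive scaling. The
enumerator is a sequential double-description method: reversible reactions
are first split into irreversible forward/backward pairs, the ray list is
initialized to the standard basis of the nonnegative orthant, and each
balance row is imposed in turn, keeping rays with zero residual and
combining adjacent positive/negative pairs (the combinatorial adjacency
test: no third ray's zero set contains the pair's common zero set). For a
fully irreversible network, the extreme rays of the final cone are exactly
the EFMs. Two-cycle artifacts of reversible splitting are removed at the
end, and modes are ordered lexicographically by support so results are
identical run to run.

Arithmetic is exact (`fractions.Fraction` end to end, with coprime-integer
rescaling after each combination step). This choice costs speed but makes
support-minimality and steady-state residuals exact rather than
tolerance-dependent; the enumerator is intended for core-scale networks
(up to roughly 10^5 modes with the default `max_modes = 500000` budget),
not genome scale. The test-suite cross-checks it against an independent
oracle that tests every reaction subset for feasibility by LP.

## Orthogonality score

Modes are partitioned by their biomass and target fluxes: biomass-only
(S_x, size n), product-only (S_t, size m), coupled, or neither. For a pair
(t ∈ S_t, x ∈ S_x) the similarity is the fraction of the *biomass* mode's
reactions that the product mode shares,

    s(t, x) = |supp(t) ∩ supp(x)| / |supp(x)|,

the average similarity is AS = (1/(m·n)) Σ s(t, x), and the orthogonality
score is OS = 1 − AS, in [0, 1]: 1 means production is a biotransformation
fully separable from growth, 0 means complete overlap. When either set is
empty the score is undefined and the library raises a dedicated error —
n = 0 is precisely the strongly growth-coupled regime, where asking how far
production is from growth has no answer.

Supports include *all* reactions of the split network, uptake/exchange/
biomass/target columns included; this convention is recorded in every
result object. Intersections are unweighted (binary support membership,
not flux-weighted).

When the per-pair orthogonality values o = 1 − s form a bi- or multimodal
distribution, the mean is not representative; Sarle's sample-corrected
bimodality coefficient

    b = (g1² + 1) / (g2 + 3(N−1)²/((N−2)(N−3)))

with the conventional threshold 5/9 (the uniform distribution's limiting
value) flags this, and the score is then the location of the
highest-density mode of the o-distribution, estimated as the midpoint of
the tallest Freedman–Diaconis histogram bin with ties broken toward the
higher-orthogonality bin. The FD rule degenerates on strongly discrete
distributions (zero interquartile range); the estimator then falls back to
the most frequent distinct value. With fewer than four pairs the
correction is undefined and the distribution is treated as unimodal. The
estimator choice is a design decision — any reasonable density-mode
estimator would do; the histogram variant is deterministic and cheap.

Two score distributions (e.g. two candidate substrate-utilization
pathways) are compared with a two-sample Kolmogorov–Smirnov test on the
per-pair orthogonality values.

### Precursor metrics

For each product-only mode, the number of support reactions that *produce*
(positive stoichiometric coefficient toward) at least one precursor
metabolite is counted; the total over S_t and the per-mode average measure
how much chemical production still runs through biomass chemistry. For
split reversible reactions the forward and backward halves are classified
separately, since only one direction produces a given metabolite.

## ValveFind

The design loop searches for a branched topology hiding inside a network:

1. **Target modes.** Given a minimal product yield Y (default 1 mol/mol,
   with substrate uptake at 20 mmol gDW⁻¹ h⁻¹ — both configurable), the
   modes to eliminate are those with product-per-substrate yield < Y. This
   sweeps out all biomass-only modes and low-yield production modes; what
   survives guarantees the yield without demanding growth. An empty
   survivor set is an error (the demanded yield is unattainable).
2. **Minimal cut sets.** A cut set must intersect the support of every
   target mode, restricted to deletable reactions (by default everything
   except uptake/exchange/biomass/target). Minimal hitting sets are
   enumerated with Berge's incremental transversal algorithm up to a
   cardinality cap; the contract is algorithm-agnostic and the tests verify
   the family against exhaustive subset search and per-set minimality by
   member removal.
3. **Valves.** Within each cut set, each member reaction is tentatively
   left open while the rest are deleted; FBA gives the restored growth as
   a fraction of wild type. Members at or above the threshold (default
   0.9) are valve candidates. Among equal-growth candidates the valve with
   the fewest precursors synthesizable when closed wins (fewer leak paths
   through a closed valve), then lexicographic order.
4. **Audit and rank.** With the full cut set applied (valve closed), the
   design is audited by FBA: growth must be zero, product yield must meet
   the threshold, and each precursor's synthesizability is probed with a
   temporary drain reaction. The design's orthogonality score is computed
   on the reduced network with the valve *open* (cut set applied, valve
   restored); designs are ranked by that score, then by cut-set
   cardinality, then lexicographically. Reduced networks that lose all
   biomass-only or all product-only modes are flagged score-undefined and
   rank last rather than being dropped.

Nutrient-limitation pseudo-valves are excluded structurally: exchange and
uptake reactions are non-deletable by default and therefore never enter
cut sets. Standard fermentative knockouts can be expressed as a
`PathwayConfig` applied before the search.

## Production envelopes

A valve's authority is visualized by throttling: the reference flux is the
valve's FVA maximum with biomass fixed at the wild-type optimum, and for
each opening fraction f ∈ {1, 0.5, 0.2, 0.1, 0.05} the valve's upper bound
is capped at f times that reference. Biomass is swept over `n_points`
(default 50) from 0 to its constrained maximum; the product's min/max flux
at each point bound the envelope, and the trapezoidal area of the band
summarizes how much solution space the valve setting leaves. Envelopes at
smaller f are nested inside larger ones by construction (shrinking a bound
shrinks the feasible region). Axes can be reported as fluxes or as yields
per mole of substrate (fluxes divided by the uptake bound); the
reference-flux definition of "percent open" is a documented convention, as
is the yield normalization.

## Protein cost

Each reaction is modeled with a separable Michaelis–Menten rate law. At
driving force ΔG′ = ΔG′° + RT·Σᵢ νᵢ ln cᵢ (concentrations relative to
1 M), the enzyme works at a fraction

    η_therm = 1 − exp(ΔG′/RT)        (backward-flux penalty, ΔG′ < 0)
    η_sat   = Π_substrates (c/Km)/(1 + c/Km)   (substrate saturation)

of its capacity, so carrying a pathway-relative flux φ requires
φ·M/(kcat·η_sat·η_therm) grams of enzyme per mol s⁻¹ of pathway input —
the protein cost, in g s mol⁻¹. Product (reverse) saturation terms are
omitted; Km values are in molar, ΔG′° in kJ mol⁻¹, T = 298.15 K
(RT ≈ 2.479 kJ mol⁻¹), and concentrations live in a physiological window
of 1 µM–10 mM unless overridden per metabolite.

Minimizing total pathway cost over log-concentrations is not an LP — the
saturation terms are nonlinear — so the implementation is two-stage:
first the max–min driving force LP (variables: log-concentrations and the
worst-case driving force B; maximize B) certifies thermodynamic
feasibility exactly and names the bottleneck reactions when B ≤ 0; then a
deterministic L-BFGS-B descent starts from the MDF point, with a smooth
quadratic barrier keeping every ΔG′ below a small negative margin
(min(10⁻³, MDF/2) kJ mol⁻¹). The descent is local; the test-suite bounds
it against a dense grid search (50 points per dimension) on two- to
four-metabolite pathways and requires the optimizer to be within 1% of the
grid optimum. The thermodynamic contribution reported with each result is
the share of the total cost that disappears if every η_therm is forced to
1 — a strongly driven pathway has a contribution near zero.

## Synthetic fixtures

The package ships six deterministic toy networks
(`orthodesign.fixtures.build_fixture`). `branched_toy` is the normative
example: one substrate feeding a biomass branch (two parallel routes) and
a fully disjoint product branch; it has exactly three EFMs, score 0.8, and
the textbook single-reaction valve. `branched_toy_redundant` adds one
shortcut shared between the branches and demonstrates that redundancy
lowers orthogonality (score 47/60 ≈ 0.7833). `linear_chain` (no product
route, m = 0) and `strong_coupled` (biomass obligatorily co-produces the
target, n = 0) exercise the two undefined-score regimes; `diamond_coupled`
shares a two-reaction trunk between all modes; `mini_glycolysis` is a
lumped glycolysis variant with five precursor metabolites for the
precursor metrics.

These fixtures emulate topology, not physiology: they have unit
stoichiometry, no cofactors, no ATP/redox balancing, and single-digit mode
counts. Tests passing on them certify algorithmic correctness (enumeration,
scoring, hitting sets, LP contracts) — not that any particular organism's
network will score high or low. Genome-adjacent conclusions require a real
core model supplied by the user through the SBML reader.

## Problem sizes and numerics

Everything in the default test run and the acceptance script operates on
the fixture networks (≤ 10 reactions, ≤ 4 EFMs), 21–50-point envelope
sweeps, 2–3-metabolite cost pathways with up to 50³ grid points, and a
20 000-sample bimodality diagnostic; these sizes make every check exact or
tightly bounded while keeping runs to seconds. Flux zero-tolerance is
1e-9 (exact rational arithmetic makes it moot inside the EFM path); FBA
probes for precursor synthesizability use 1e-6 to stay above LP solver
noise. Ties are broken lexicographically everywhere a choice is arbitrary
(mode ordering, cut-set ordering, valve selection) so that all outputs are
byte-reproducible.

## Known limitations

* The EFM enumerator's exact arithmetic and dense adjacency test do not
  scale to genome-scale models; no sampling or shortest-mode approximation
  is provided.
* The orthogonality score depends on the support convention (exchanges
  included) and, for multimodal distributions, on the density-mode
  estimator; both are recorded in results but alternative conventions will
  move third-party numbers.
* The protein-cost descent is local. The grid-search bound in the tests
  covers small pathways; for larger pathways multistart from perturbed MDF
  points would be prudent.
* Gene–protein–reaction mapping is out of scope: cut sets are reaction
  sets, not gene sets.
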